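"""Shared helpers for randomly generated acyclic path models."""

import numpy as np


def build_random_dag(rng, n_vars, p_edge=0.5, saturated_exogenous=True):
    """Random acyclic model: edges oriented along a random variable order.

    With ``saturated_exogenous`` every exogenous pair gets a free
    covariance, so the likelihood factorises along the DAG and the
    per-equation closed form is the exact ML solution.
    """
    from gpresem import build_path_model

    names = [f"v{i}" for i in range(n_vars)]
    order = rng.permutation(n_vars)
    edges = []
    for a in range(n_vars):
        for b in range(a + 1, n_vars):
            if rng.random() < p_edge:
                s, t = names[order[a]], names[order[b]]
                edges.append((s, t, f"b_{s}_{t}"))
    covs = []
    if saturated_exogenous:
        exo = sorted(set(names) - {t for _, t, _ in edges})
        for i in range(len(exo)):
            for j in range(i + 1, len(exo)):
                covs.append((exo[i], exo[j], f"c_{exo[i]}_{exo[j]}"))
    return build_path_model(names, edges, covs)


def random_theta(rng, ram, path_scale=0.6):
    """Random parameter vector with positive variances."""
    theta = np.empty(ram.q)
    for k, (mat, i, j, _) in enumerate(ram.free_map):
        if mat == "A":
            theta[k] = rng.normal(scale=path_scale)
        elif i == j:
            theta[k] = rng.uniform(0.5, 2.0)
        else:
            theta[k] = rng.uniform(-0.3, 0.3)
    return theta
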