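"""Path-model specification and compilation to RAM matrices.

A path model here is a recursive (acyclic) structural equation model over
observed variables only: directed edges carry regression ("path")
coefficients, bidirected edges carry free covariances among exogenous
variables, every endogenous variable has a free residual variance and every
exogenous variable a free variance.  Models compile to the standard RAM
(reticular action model) pair ``(A, S)`` with implied covariance
``(I - A)^-1 S (I - A)^-T``; with no latent variables the filter matrix is
the identity and is omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PathModel",
    "RAMMatrices",
    "CycleError",
    "ModelSpecificationError",
    "build_path_model",
    "to_ram",
    "triticale_gpre_model",
    "parse_model_text",
    "model_to_text",
    "load_model_json",
]


class ModelSpecificationError(ValueError):
    """A model references unknown variables or repeats parameter labels."""


class CycleError(ModelSpecificationError):
    """The directed part of a path model contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("directed cycle: " + " -> ".join([*cycle, cycle[0]]))


@dataclass(frozen=True)
class PathModel:
    """A validated recursive path diagram.

    Attributes
    ----------
    variables : tuple of str
        All observed variables, in declaration order.
    directed_edges : tuple of (source, target, label)
        Regression paths (coefficient of ``source`` in the equation of
        ``target``).
    bidirected_edges : tuple of (var_a, var_b, label)
        Free covariances among exogenous variables.
    residual_labels : dict
        Endogenous variable -> residual-variance parameter label.
    exogenous_variance_labels : dict
        Exogenous variable -> variance parameter label.
    """

    variables: tuple[str, ...]
    directed_edges: tuple[tuple[str, str, str], ...]
    bidirected_edges: tuple[tuple[str, str, str], ...]
    residual_labels: dict[str, str]
    exogenous_variance_labels: dict[str, str]

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t, _ in self.directed_edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t, _ in self.directed_edges}
        return tuple(v for v in self.variables if v not in targets)

    def parents(self, variable: str) -> tuple[str, ...]:
        return tuple(s for s, t, _ in self.directed_edges if t == variable)

    def path_labels(self) -> dict[tuple[str, str], str]:
        return {(s, t): lab for s, t, lab in self.directed_edges}

    def topological_order(self) -> list[str]:
        return _topological_order(self.variables, self.directed_edges)

    @property
    def n_free_parameters(self) -> int:
        return (
            len(self.directed_edges)
            + len(self.bidirected_edges)
            + len(self.residual_labels)
            + len(self.exogenous_variance_labels)
        )


@dataclass(frozen=True)
class RAMMatrices:
    """RAM compilation of a :class:`PathModel`.

    ``A[i, j]`` is the coefficient of variable ``j`` in the equation of
    variable ``i``; ``S`` holds variances and covariances.  ``free_map``
    enumerates the free parameters as ``(matrix, row, col, label)`` with
    ``matrix`` in ``{"A", "S"}``; its order defines the parameter vector.
    """

    variables: tuple[str, ...]
    free_map: tuple[tuple[str, int, int, str], ...]

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def q(self) -> int:
        return len(self.free_map)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.q

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, _, lab in self.free_map)

    def fill(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scatter a parameter vector into dense (A, S) matrices."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise ValueError(f"theta must have length {self.q}, got {theta.shape}")
        A = np.zeros((self.p, self.p))
        S = np.zeros((self.p, self.p))
        for value, (mat, i, j, _) in zip(theta, self.free_map):
            if mat == "A":
                A[i, j] = value
            else:
                S[i, j] = value
                S[j, i] = value
        return A, S


def _topological_order(
    variables: Sequence[str], directed_edges: Sequence[tuple[str, str, str]]
) -> list[str]:
    """Kahn's algorithm; raises :class:`CycleError` naming a cycle."""
    indeg = {v: 0 for v in variables}
    children: dict[str, list[str]] = {v: [] for v in variables}
    for s, t, _ in directed_edges:
        indeg[t] += 1
        children[s].append(t)
    ready = [v for v in variables if indeg[v] == 0]
    order: list[str] = []
    while ready:
        v = ready.pop(0)
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) < len(variables):
        remaining = [v for v in variables if indeg[v] > 0]
        cycle = _find_cycle(remaining, directed_edges)
        raise CycleError(cycle)
    return order


def _find_cycle(
    candidates: Sequence[str], directed_edges: Sequence[tuple[str, str, str]]
) -> list[str]:
    children: dict[str, list[str]] = {}
    cand = set(candidates)
    for s, t, _ in directed_edges:
        if s in cand and t in cand:
            children.setdefault(s, []).append(t)
    start = candidates[0]
    seen: dict[str, int] = {}
    path = [start]
    while path[-1] not in seen:
        seen[path[-1]] = len(path) - 1
        path.append(children[path[-1]][0])
    return path[seen[path[-1]] : -1]


def build_path_model(
    variables: Sequence[str],
    directed_edges: Sequence[tuple[str, str, str]] = (),
    bidirected_edges: Sequence[tuple[str, str, str]] = (),
    residual_labels: dict[str, str] | None = None,
    exogenous_variance_labels: dict[str, str] | None = None,
) -> PathModel:
    """Validate and assemble a :class:`PathModel`.

    Residual and exogenous-variance labels are generated automatically
    (``resid(v)`` / ``var(v)``) when not supplied.

    Raises
    ------
    ModelSpecificationError
        On empty/duplicate names, unknown edge endpoints, self-loops or
        duplicate parameter labels.
    CycleError
        If the directed edges contain a cycle.
    """
    variables = tuple(variables)
    if not variables:
        raise ModelSpecificationError("at least one variable is required")
    if len(set(variables)) != len(variables):
        raise ModelSpecificationError("variable names must be unique")
    known = set(variables)
    directed = tuple((s, t, lab) for s, t, lab in directed_edges)
    bidirected = tuple((a, b, lab) for a, b, lab in bidirected_edges)
    for s, t, _ in directed:
        if s not in known or t not in known:
            raise ModelSpecificationError(f"edge {s}->{t} references an undeclared variable")
        if s == t:
            raise ModelSpecificationError(f"self-loop on {s} is not allowed")
    for a, b, _ in bidirected:
        if a not in known or b not in known:
            raise ModelSpecificationError(f"covariance {a}<->{b} references an undeclared variable")
    if len({(s, t) for s, t, _ in directed}) != len(directed):
        raise ModelSpecificationError("duplicate directed edge")
    _topological_order(variables, directed)

    targets = {t for _, t, _ in directed}
    endo = [v for v in variables if v in targets]
    exo = [v for v in variables if v not in targets]
    for a, b, _ in bidirected:
        if a in targets or b in targets:
            raise ModelSpecificationError(
                f"free covariance {a}<->{b} must connect exogenous variables"
            )
    residual_labels = dict(residual_labels or {})
    for v in endo:
        residual_labels.setdefault(v, f"resid({v})")
    if set(residual_labels) != set(endo):
        raise ModelSpecificationError("residual labels must cover exactly the endogenous variables")
    exogenous_variance_labels = dict(exogenous_variance_labels or {})
    for v in exo:
        exogenous_variance_labels.setdefault(v, f"var({v})")
    if set(exogenous_variance_labels) != set(exo):
        raise ModelSpecificationError("variance labels must cover exactly the exogenous variables")

    labels = (
        [lab for _, _, lab in directed]
        + [lab for _, _, lab in bidirected]
        + [residual_labels[v] for v in endo]
        + [exogenous_variance_labels[v] for v in exo]
    )
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ModelSpecificationError(f"duplicate parameter labels: {dupes}")
    return PathModel(variables, directed, bidirected, residual_labels, exogenous_variance_labels)


def to_ram(model: PathModel) -> RAMMatrices:
    """Compile a model to RAM form with a deterministic free-parameter order.

    Parameter order: directed edges as declared, then bidirected edges, then
    residual variances (declaration order of the endogenous variables), then
    exogenous variances.
    """
    pos = {v: i for i, v in enumerate(model.variables)}
    free: list[tuple[str, int, int, str]] = []
    for s, t, lab in model.directed_edges:
        free.append(("A", pos[t], pos[s], lab))
    for a, b, lab in model.bidirected_edges:
        free.append(("S", pos[a], pos[b], lab))
    for v in model.endogenous:
        free.append(("S", pos[v], pos[v], model.residual_labels[v]))
    for v in model.exogenous:
        free.append(("S", pos[v], pos[v], model.exogenous_variance_labels[v]))
    return RAMMatrices(model.variables, tuple(free))


#: Canonical variable order of the triticale anther-culture model
#: (exogenous first, then a topological order of the endogenous block).
TRITICALE_VARIABLES = ("Cu", "LMP", "SAM", "GSH", "CHH_DNMV", "CHH_SV", "GPRE")

#: Long descriptions of the model variables (units in brackets).
TRITICALE_VARIABLE_INFO = {
    "Cu": "Cu(II) concentration in the induction medium [uM]",
    "LMP": "ATR-FTIR absorbance 990-950 cm^-1, low-methylated pectins [a.u.]",
    "SAM": "ATR-FTIR absorbance 1630...1470 cm^-1, S-adenosyl-L-methionine [a.u.]",
    "GSH": "ATR-FTIR absorbance 2550-2540 cm^-1, glutathione [a.u.]",
    "CHH_DNMV": "metAFLP de novo methylation in the CHH context [%]",
    "CHH_SV": "metAFLP sequence variation in the CHH context [%]",
    "GPRE": "green plant regeneration efficiency [regenerants per 100 anthers]",
}


def triticale_gpre_model() -> PathModel:
    """The 7-variable green-plant-regeneration path model.

    Twelve paths (lambda1-lambda12), one free covariance Cu<->LMP, five
    residual variances (delta1-delta5) and two exogenous variances.  The
    residual labels delta1..delta5 follow the order in which the endogenous
    variables first appear as path targets (SAM, CHH_DNMV, GSH, CHH_SV,
    GPRE).
    """
    edges = [
        ("LMP", "SAM", "lambda1"),
        ("Cu", "CHH_DNMV", "lambda2"),
        ("SAM", "CHH_DNMV", "lambda3"),
        ("Cu", "GSH", "lambda4"),
        ("CHH_DNMV", "CHH_SV", "lambda5"),
        ("SAM", "GSH", "lambda6"),
        ("Cu", "CHH_SV", "lambda7"),
        ("Cu", "GPRE", "lambda8"),
        ("GSH", "GPRE", "lambda9"),
        ("SAM", "GPRE", "lambda10"),
        ("CHH_DNMV", "GPRE", "lambda11"),
        ("CHH_SV", "GPRE", "lambda12"),
    ]
    residuals = {
        "SAM": "delta1",
        "CHH_DNMV": "delta2",
        "GSH": "delta3",
        "CHH_SV": "delta4",
        "GPRE": "delta5",
    }
    exo_vars = {"Cu": "var(Cu)", "LMP": "var(LMP)"}
    return build_path_model(
        TRITICALE_VARIABLES,
        edges,
        [("Cu", "LMP", "cov(Cu,LMP)")],
        residual_labels=residuals,
        exogenous_variance_labels=exo_vars,
    )


# ---------------------------------------------------------------------------
# text / JSON serialisation


def model_to_text(model: PathModel) -> str:
    """One edge per line: ``source -> target [label]`` / ``a <-> b [label]``."""
    lines = ["# variables: " + " ".join(model.variables)]
    for s, t, lab in model.directed_edges:
        lines.append(f"{s} -> {t} [{lab}]")
    for a, b, lab in model.bidirected_edges:
        lines.append(f"{a} <-> {b} [{lab}]")
    return "\n".join(lines) + "\n"


def parse_model_text(text: str) -> PathModel:
    """Inverse of :func:`model_to_text`."""
    variables: list[str] = []
    directed: list[tuple[str, str, str]] = []
    bidirected: list[tuple[str, str, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# variables:"):
            variables = line.split(":", 1)[1].split()
            continue
        if line.startswith("#"):
            continue
        label = ""
        if "[" in line:
            line, rest = line.split("[", 1)
            label = rest.rsplit("]", 1)[0].strip()
        if "<->" in line:
            a, b = (x.strip() for x in line.split("<->"))
            bidirected.append((a, b, label or f"cov({a},{b})"))
        elif "->" in line:
            s, t = (x.strip() for x in line.split("->"))
            directed.append((s, t, label or f"path({s},{t})"))
        else:
            raise ModelSpecificationError(f"cannot parse model line: {raw!r}")
    if not variables:
        seen: list[str] = []
        for s, t, _ in directed + bidirected:
            for v in (s, t):
                if v not in seen:
                    seen.append(v)
        variables = seen
    return build_path_model(variables, directed, bidirected)


def load_model_json(source) -> PathModel:
    """Load a model from a JSON document (path, file object or dict).

    Expected keys: ``variables`` (list), ``paths`` (list of
    ``[source, target]`` or ``[source, target, label]``), ``covariances``
    (same shape, optional).
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    paths = [tuple(e) if len(e) == 3 else (e[0], e[1], f"path({e[0]},{e[1]})") for e in doc.get("paths", [])]
    covs = [
        tuple(e) if len(e) == 3 else (e[0], e[1], f"cov({e[0]},{e[1]})")
        for e in doc.get("covariances", [])
    ]
    return build_path_model(doc["variables"], paths, covs)


def model_to_json(model: PathModel) -> dict:
    return {
        "variables": list(model.variables),
        "paths": [list(e) for e in model.directed_edges],
        "covariances": [list(e) for e in model.bidirected_edges],
    }
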