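"""Direct, indirect and total effects of a recursive path model.

With ``B`` the endogenous-on-endogenous coefficient block and ``Gamma`` the
endogenous-on-exogenous block, total effects are

    total(endo <- exo)  = (I - B)^-1 Gamma
    total(endo <- endo) = (I - B)^-1 - I

and indirect = total - direct.  For an acyclic model ``B`` is nilpotent,
so ``(I - B)^-1 = I + B + B^2 + ...`` terminates and the matrix identity
equals the sum over all directed paths of the product of edge coefficients.
The decomposition applies to any coefficient vector — unstandardised ``b``
or standardised ``beta`` — one metric per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PathModel

__all__ = ["EffectMatrices", "EffectTables", "effect_decomposition", "decompose_metric", "effects_report"]


@dataclass(frozen=True)
class EffectMatrices:
    """Direct/indirect/total effect matrices for one coefficient metric.

    Each is a DataFrame with sources as rows (exogenous then endogenous
    variables) and endogenous targets as columns.
    """

    direct: pd.DataFrame
    indirect: pd.DataFrame
    total: pd.DataFrame


@dataclass(frozen=True)
class EffectTables:
    """Unstandardised (b) and standardised (beta) effect decompositions."""

    unstandardized: EffectMatrices
    standardized: EffectMatrices

    @property
    def sources(self) -> list[str]:
        return list(self.unstandardized.total.index)

    @property
    def targets(self) -> list[str]:
        return list(self.unstandardized.total.columns)


def decompose_metric(model: PathModel, coefficients: dict[str, float]) -> EffectMatrices:
    """Decompose one coefficient metric into direct/indirect/total effects.

    Parameters
    ----------
    model : PathModel
    coefficients : dict
        Path label -> coefficient; must cover every directed edge.

    Raises
    ------
    ValueError
        Naming any path label missing from ``coefficients``.
    """
    missing = [lab for _, _, lab in model.directed_edges if lab not in coefficients]
    if missing:
        raise ValueError(f"missing coefficients for paths: {missing}")
    endo = list(model.endogenous)
    exo = list(model.exogenous)
    ne, nx = len(endo), len(exo)
    epos = {v: i for i, v in enumerate(endo)}
    xpos = {v: i for i, v in enumerate(exo)}
    B = np.zeros((ne, ne))
    G = np.zeros((ne, nx))
    for s, t, lab in model.directed_edges:
        if s in epos:
            B[epos[t], epos[s]] = coefficients[lab]
        else:
            G[epos[t], xpos[s]] = coefficients[lab]
    inv = np.linalg.inv(np.eye(ne) - B)  # exact: B nilpotent for acyclic models
    tot_exo = inv @ G
    tot_endo = inv - np.eye(ne)
    sources = exo + endo
    direct = np.vstack([G.T, B.T])
    total = np.vstack([tot_exo.T, tot_endo.T])
    indirect = total - direct
    mk = lambda M: pd.DataFrame(M, index=sources, columns=endo)
    return EffectMatrices(direct=mk(direct), indirect=mk(indirect), total=mk(total))


def effect_decomposition(
    model: PathModel,
    coefficients: dict[str, float],
    standardized_coefficients: dict[str, float] | None = None,
) -> EffectTables:
    """Run the decomposition in the b metric and, optionally, the beta metric.

    When ``standardized_coefficients`` is omitted the standardised tables
    are a copy of the unstandardised ones (caller supplied only one metric).
    """
    unstd = decompose_metric(model, coefficients)
    if standardized_coefficients is None:
        std = unstd
    else:
        std = decompose_metric(model, standardized_coefficients)
    return EffectTables(unstandardized=unstd, standardized=std)


def effects_from_fit(fit) -> EffectTables:
    """Effect tables from a converged :class:`~gpresem.fit.FitResult`."""
    return effect_decomposition(fit.model, fit.estimates, fit.standardized)


def effects_report(tables: EffectTables, digits: int = 4) -> str:
    """Render the decomposition as a per-target listing.

    For every endogenous target and every source with a nonzero total
    effect in either metric: unstandardised direct/indirect/total followed
    by the standardised triple, ``digits`` decimals.
    """
    if isinstance(tables, EffectMatrices):
        tables = EffectTables(unstandardized=tables, standardized=tables)
    u, s = tables.unstandardized, tables.standardized
    lines: list[str] = []
    header = (
        f"{'effect':<28}{'b_direct':>10}{'b_indirect':>12}{'b_total':>10}"
        f"{'beta_direct':>13}{'beta_indirect':>15}{'beta_total':>12}"
    )
    for target in tables.targets:
        block: list[str] = []
        for source in tables.sources:
            vals = [
                u.direct.at[source, target],
                u.indirect.at[source, target],
                u.total.at[source, target],
                s.direct.at[source, target],
                s.indirect.at[source, target],
                s.total.at[source, target],
            ]
            if all(abs(v) < 10 ** (-digits) / 2 for v in vals):
                continue
            block.append(
                f"  {source + ' -> ' + target:<26}"
                + "".join(f"{v:>{w}.{digits}f}" for v, w in zip(vals, (10, 12, 10, 13, 15, 12)))
            )
        if block:
            lines.append(f"{target}:")
            lines.extend(block)
    if not lines:
        return ""
    return header + "\n" + "\n".join(lines) + "\n"
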