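"""Goodness-of-fit statistics for a fitted covariance-structure model.

Covers the full battery customarily reported alongside a path analysis:
absolute indices (RMR, SRMR, GFI, AGFI, PGFI), incremental indices against
the independence baseline (NFI, RFI, IFI, TLI, CFI and their parsimony
versions), noncentrality-based indices (RMSEA with a 90% confidence
interval and the PCLOSE test, ECVI with its interval) and Hoelter's
critical N.  Formula variants follow the conventions of mainstream SEM
software (AMOS/lavaan agree on all of these).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .fit import FitResult, SampleMoments

__all__ = ["FitIndexReport", "baseline_fit", "compute_indices", "hoelter_n", "rmsea_interval"]


@dataclass(frozen=True)
class FitIndexReport:
    """All scalar fit statistics for one model/baseline pair.

    ``None`` marks indices that are undefined for the model at hand
    (e.g. df = 0).  ``hoelter_05`` is an integer sample size.
    """

    chi_square: float
    p_value: float
    df: int
    chi_square_over_df: float | None
    rmr: float
    srmr: float
    gfi: float
    agfi: float | None
    pgfi: float
    nfi: float
    rfi: float | None
    ifi: float
    tli: float | None
    cfi: float
    pnfi: float
    pcfi: float
    rmsea: float | None
    rmsea_lo90: float | None
    rmsea_hi90: float | None
    pclose: float | None
    ecvi: float
    ecvi_lo90: float
    ecvi_hi90: float
    hoelter_05: int | None
    baseline_chi_square: float
    baseline_df: int

    def to_dict(self) -> dict:
        return asdict(self)


def baseline_fit(moments: SampleMoments) -> tuple[float, int]:
    """Chi-square and df of the independence (null) model.

    The independence model frees every variance and fixes all covariances
    to zero; its ML solution is the sample variances, so the minimised
    discrepancy is available in closed form as ``-ln|R|`` with ``R`` the
    sample correlation matrix.
    """
    S = moments.S
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("sample correlation matrix is not positive definite")
    chi2_b = -(moments.n - 1) * logdet
    df_b = moments.p * (moments.p - 1) // 2
    return float(chi2_b), df_b


def _noncentrality_bounds(chi2: float, df: int, level: float = 0.90) -> tuple[float, float]:
    """Bounds of the CI for the noncentrality parameter of chi2 ~ ncx2(df, ncp).

    Inverts the noncentral-chi-square CDF: the lower bound solves
    ``P(X <= chi2 | ncp) = (1+level)/2`` (0 if even ncp=0 gives a smaller
    tail) and the upper solves ``P(X <= chi2 | ncp) = (1-level)/2``.
    """
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def solve(target: float) -> float | None:
        if stats.chi2.cdf(chi2, df) < target:  # ncp = 0 already below target
            return None
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2
            if hi > 1e8:
                return None
        from scipy.optimize import brentq

        return brentq(lambda ncp: stats.ncx2.cdf(chi2, df, ncp) - target, 1e-12, hi, xtol=1e-10)

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    return (0.0 if lam_lo is None else lam_lo, 0.0 if lam_hi is None else lam_hi)


def rmsea_interval(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float, float]:
    """RMSEA point estimate and confidence bounds.

    ``rmsea = sqrt(max(chi2 - df, 0) / (df * (n - 1)))``; the bounds map the
    noncentrality-parameter interval through the same transform.
    """
    point = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    lam_lo, lam_hi = _noncentrality_bounds(chi2, df, level)
    lo = math.sqrt(lam_lo / (df * (n - 1)))
    hi = math.sqrt(lam_hi / (df * (n - 1)))
    return point, lo, hi


def hoelter_n(chi2: float, df: int, n: int, alpha: float = 0.05) -> int:
    """Hoelter's critical N: the largest sample size at which the model
    would not be rejected at ``alpha``; ``floor(chi2_crit / (chi2/(n-1))) + 1``."""
    crit = stats.chi2.ppf(1 - alpha, df)
    return int(math.floor(crit / (chi2 / (n - 1)))) + 1


def compute_indices(
    fit: FitResult,
    moments: SampleMoments | None = None,
    baseline: tuple[float, int] | None = None,
) -> FitIndexReport:
    """Assemble the full fit-index report for a converged fit.

    Parameters
    ----------
    fit : FitResult
    moments : SampleMoments, optional
        Defaults to the moments stored on the fit.
    baseline : (chi_square, df), optional
        Independence-model statistics; computed by :func:`baseline_fit`
        when omitted.
    """
    moments = moments or fit.moments
    if baseline is None:
        baseline = baseline_fit(moments)
    chi2_b, df_b = baseline
    chi2, df, n, p, q = fit.chi_square, fit.df, moments.n, moments.p, fit.q
    S, sigma = moments.S, fit.implied_sigma

    iu = np.triu_indices(p)
    resid = (S - sigma)[iu]
    rmr = float(np.sqrt(np.mean(resid**2)))
    d = np.sqrt(np.diag(S))
    resid_std = ((S - sigma) / np.outer(d, d))[iu]
    srmr = float(np.sqrt(np.mean(resid_std**2)))

    W = np.linalg.solve(sigma, S)
    gfi = float(1 - np.trace((W - np.eye(p)) @ (W - np.eye(p))) / np.trace(W @ W))
    agfi = None if df == 0 else float(1 - (p * (p + 1) / (2 * df)) * (1 - gfi))
    pgfi = float(gfi * df / (p * (p + 1) / 2))

    nfi = (chi2_b - chi2) / chi2_b
    rfi = None if df == 0 else 1 - (chi2 / df) / (chi2_b / df_b)
    ifi = (chi2_b - chi2) / (chi2_b - df)
    tli = None if df == 0 else ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1 - max(chi2 - df, 0.0) / denom
    pnfi = (df / df_b) * nfi
    pcfi = (df / df_b) * cfi

    if df > 0:
        rmsea, rmsea_lo, rmsea_hi = rmsea_interval(chi2, df, n)
        ncp_close = (n - 1) * df * 0.05**2
        pclose = float(stats.ncx2.sf(chi2, df, ncp_close))
    else:
        rmsea = rmsea_lo = rmsea_hi = pclose = None

    ecvi = (chi2 + 2 * q) / (n - 1)
    lam_lo, lam_hi = _noncentrality_bounds(chi2, max(df, 1))
    ecvi_lo = (lam_lo + df + 2 * q) / (n - 1)
    ecvi_hi = (lam_hi + df + 2 * q) / (n - 1)

    return FitIndexReport(
        chi_square=chi2,
        p_value=fit.p_value,
        df=df,
        chi_square_over_df=None if df == 0 else chi2 / df,
        rmr=rmr,
        srmr=srmr,
        gfi=gfi,
        agfi=agfi,
        pgfi=pgfi,
        nfi=float(nfi),
        rfi=None if rfi is None else float(rfi),
        ifi=float(ifi),
        tli=None if tli is None else float(tli),
        cfi=float(cfi),
        pnfi=float(pnfi),
        pcfi=float(pcfi),
        rmsea=rmsea,
        rmsea_lo90=rmsea_lo,
        rmsea_hi90=rmsea_hi,
        pclose=pclose,
        ecvi=float(ecvi),
        ecvi_lo90=float(ecvi_lo),
        ecvi_hi90=float(ecvi_hi),
        hoelter_05=None if (df == 0 or chi2 <= 0) else hoelter_n(chi2, df, n, 0.05),
        baseline_chi_square=float(chi2_b),
        baseline_df=df_b,
    )
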