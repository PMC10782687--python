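"""The triticale anther-culture analysis: fixtures and table reproduction.

The original experiment measured nine variables on 37 regenerants from
eight trials (A-H): the induction-medium design factors Cu(II), Ag(I) and
culture time, the metAFLP variation measures CHH_DNMV and CHH_SV, three
ATR-FTIR band absorbances (LMP, SAM, GSH) and the green plant regeneration
efficiency (GPRE).  The raw per-regenerant table was never published; what
is printed are the descriptive statistics, the Pearson correlation matrix
and the fitted-model tables.  Since an ML covariance-structure fit depends
on the data only through (S, N), the whole analysis is reproducible from
the printed summaries: reconstruct S = D R D from the printed SDs and
correlations, convert to the ML (divisor N) metric, fit, and compare.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectTables, effects_from_fit
from .fit import FitResult, SampleMoments, fit_ml
from .indices import FitIndexReport, compute_indices
from .model import TRITICALE_VARIABLES, PathModel, to_ram, triticale_gpre_model

__all__ = [
    "DescriptiveRow",
    "CorrelationFixture",
    "PackagingError",
    "load_descriptives",
    "load_correlations",
    "load_published_estimates",
    "load_published_fit_indices",
    "load_published_effects",
    "load_fixtures",
    "reconstruct_covariance",
    "triticale_moments",
    "published_theta",
    "descriptive_stats",
    "pearson_tests",
    "reproduce_tables",
    "StudyReport",
]

#: Fixture order of the nine observed variables.
ALL_VARIABLES = ("Cu", "Ag", "Time", "CHH_DNMV", "CHH_SV", "LMP", "SAM", "GSH", "GPRE")

N_REGENERANTS = 37


class PackagingError(RuntimeError):
    """A packaged fixture does not match its manifest checksum."""


@dataclass(frozen=True)
class DescriptiveRow:
    """One variable's descriptive statistics (all in the variable's units)."""

    variable: str
    minimum: float
    maximum: float
    mean: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float


@dataclass(frozen=True)
class CorrelationFixture:
    """A Pearson correlation matrix with per-cell significance flags."""

    r: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self):
        # NaN cells mark undefined correlations (zero-variance columns)
        R = self.r.to_numpy()
        if not np.allclose(R, R.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        diag = np.diag(R)
        if not np.allclose(diag[np.isfinite(diag)], 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(R)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")


def _fixture_bytes(name: str) -> bytes:
    return resources.files("gpresem.fixtures").joinpath(name).read_bytes()


def _read_fixture(name: str, **kw) -> pd.DataFrame:
    import io

    raw = _fixture_bytes(name)
    manifest = json.loads(_fixture_bytes("manifest.json"))
    expected = manifest["files"][name]["sha256"]
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise PackagingError(f"fixture {name} checksum mismatch: {digest} != {expected}")
    return pd.read_csv(io.BytesIO(raw), **kw)


def load_descriptives() -> pd.DataFrame:
    """Printed descriptive statistics, indexed by variable name."""
    return _read_fixture("descriptives.csv", index_col="variable")


def load_correlations() -> CorrelationFixture:
    """Printed 9x9 Pearson correlation matrix with significance flags."""
    r = _read_fixture("correlations.csv", index_col="variable")
    flags = _read_fixture("correlation_flags.csv", index_col="variable", keep_default_na=False)
    return CorrelationFixture(r=r, flags=flags)


def load_published_estimates() -> pd.DataFrame:
    """Printed parameter estimates of the fitted model, indexed by label."""
    return _read_fixture("published_estimates.csv", index_col="label", keep_default_na=False)


def load_published_fit_indices() -> pd.Series:
    return _read_fixture("published_fit_indices.csv", index_col="index")["value"]


def load_published_effects() -> pd.DataFrame:
    return _read_fixture("published_effects.csv")


def load_fixtures() -> tuple[list[DescriptiveRow], CorrelationFixture, pd.DataFrame]:
    """All packaged fixtures: descriptives, correlations, printed estimates."""
    desc = load_descriptives()
    rows = [DescriptiveRow(variable=v, **desc.loc[v].to_dict()) for v in desc.index]
    return rows, load_correlations(), load_published_estimates()


def reconstruct_covariance(
    sds,
    R,
    n: int,
    divisor: str = "n-1",
    variable_names=None,
) -> SampleMoments:
    """Rebuild a sample covariance matrix as ``S = D R D``.

    Parameters
    ----------
    sds : sequence of float
        Sample (N-1 divisor) standard deviations.
    R : array or DataFrame
        Correlation matrix aligned with ``sds``.
    n : int
        Sample size.
    divisor : {"n-1", "n"}
        Target convention; ``"n"`` multiplies by (n-1)/n to give the ML
        (biased) covariance that covariance-structure software fits.
    """
    if isinstance(R, pd.DataFrame):
        variable_names = tuple(R.columns)
        R = R.to_numpy(dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    S = np.outer(sds, sds) * np.asarray(R, dtype=float)
    if divisor == "n":
        S = S * (n - 1) / n
    if variable_names is None:
        variable_names = tuple(f"x{i}" for i in range(len(sds)))
    return SampleMoments(S, n, variable_names, divisor)


def triticale_moments(divisor: str = "n", variables=TRITICALE_VARIABLES) -> SampleMoments:
    """Moments of the study's model variables from the packaged fixtures.

    Drops the design variables Ag(I) and Time (they did not enter the
    model) and returns the covariance in the requested divisor convention.
    """
    desc = load_descriptives()
    corr = load_correlations().r
    names = list(variables)
    sds = desc.loc[names, "sd"].to_numpy()
    R = corr.loc[names, names]
    return reconstruct_covariance(sds, R, N_REGENERANTS, divisor=divisor)


def published_theta(model: PathModel | None = None) -> np.ndarray:
    """Printed estimates as a parameter vector in the model's free order."""
    model = model or triticale_gpre_model()
    ram = to_ram(model)
    est = load_published_estimates()["estimate"]
    return np.array([float(est[lab]) for lab in ram.labels()])


def descriptive_stats(x, variable: str = "x") -> DescriptiveRow:
    """Descriptive statistics in the convention of the printed tables.

    Sample SD/variance (N-1); skewness is the adjusted Fisher-Pearson G1
    ``n/((n-1)(n-2)) * sum(z^3)`` and kurtosis the small-sample-corrected
    excess G2 (the SPSS/Excel convention).  Constant input yields sd 0 and
    NaN shape statistics.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for skewness/kurtosis")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        g1 = g2 = float("nan")
    else:
        z = (x - mean) / sd
        g1 = n / ((n - 1) * (n - 2)) * float(np.sum(z**3))
        g2 = (
            n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(z**4))
            - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        )
    return DescriptiveRow(
        variable=variable,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=mean,
        sd=sd,
        variance=sd**2,
        skewness=g1,
        kurtosis=g2,
    )


def pearson_tests(X, alpha_1: float = 0.05, alpha_2: float = 0.01) -> CorrelationFixture:
    """Pairwise Pearson correlations with two-tailed significance flags.

    The test statistic is ``t = r sqrt(n-2)/sqrt(1-r^2)`` on n-2 degrees of
    freedom; flags are '*' below ``alpha_1`` and '**' below ``alpha_2``.
    Zero-variance columns get NaN correlations and blank flags.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    X = X.dropna()
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    cols = list(X.columns)
    R = X.corr().to_numpy()  # NaN for zero-variance columns
    flags = np.full(R.shape, "", dtype=object)
    for i in range(len(cols)):
        for j in range(len(cols)):
            r = R[i, j]
            if i == j or not np.isfinite(r):
                continue
            if abs(r) >= 1:
                p = 0.0
            else:
                t = r * math.sqrt(n - 2) / math.sqrt(1 - r**2)
                p = 2 * stats.t.sf(abs(t), n - 2)
            if p <= alpha_2:
                flags[i, j] = "**"
            elif p <= alpha_1:
                flags[i, j] = "*"
    return CorrelationFixture(
        r=pd.DataFrame(R, index=cols, columns=cols),
        flags=pd.DataFrame(flags, index=cols, columns=cols),
    )


@dataclass
class StudyReport:
    """Everything the one-command reproduction computes."""

    moments: SampleMoments
    fit: FitResult
    indices: FitIndexReport
    effects: EffectTables
    published_estimates: pd.DataFrame
    published_indices: pd.Series
    published_effects: pd.DataFrame

    def estimate_deviations(self) -> pd.DataFrame:
        """|computed - printed| per parameter for b, SE and beta."""
        rows = []
        for lab in self.fit.ram.labels():
            pub = self.published_estimates.loc[lab]
            beta_pub = pub["standardized"]
            rows.append(
                {
                    "parameter": lab,
                    "d_estimate": abs(self.fit.estimates[lab] - float(pub["estimate"])),
                    "d_se": abs(self.fit.standard_errors[lab] - float(pub["se"])),
                    "d_standardized": (
                        abs(self.fit.standardized[lab] - float(beta_pub))
                        if beta_pub != ""
                        else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def index_deviations(self) -> pd.Series:
        computed = self.indices.to_dict()
        out = {}
        for key, pub in self.published_indices.items():
            val = computed.get(key)
            out[key] = abs(val - float(pub)) if val is not None else np.nan
        return pd.Series(out, name="abs_deviation")

    def effect_deviations(self) -> pd.DataFrame:
        std = self.effects.standardized
        unstd = self.effects.unstandardized
        rows = []
        for _, row in self.published_effects.iterrows():
            s, t = row["source"], row["target"]
            rows.append(
                {
                    "effect": f"{s}->{t}",
                    "d_b_total": abs(unstd.total.at[s, t] - float(row["b_total"])),
                    "d_beta_total": abs(std.total.at[s, t] - float(row["beta_total"])),
                    "d_beta_indirect": abs(std.indirect.at[s, t] - float(row["beta_indirect"])),
                }
            )
        return pd.DataFrame(rows).set_index("effect")

    def render(self) -> str:
        from .effects import effects_report

        lines = ["== Model fit ==", ""]
        idx = self.indices.to_dict()
        for key in self.published_indices.index:
            val = idx.get(key)
            pub = self.published_indices[key]
            shown = "undefined" if val is None else f"{val:.4f}"
            lines.append(f"  {key:<20}{shown:>12}   (printed {pub})")
        lines += ["", "== Parameter estimates ==", ""]
        lines.append(self.fit.summary().round(4).to_string())
        lines += ["", "== Effect decomposition ==", ""]
        lines.append(effects_report(self.effects))
        return "\n".join(lines) + "\n"


def reproduce_tables(moments: SampleMoments | None = None) -> StudyReport:
    """Run the full published analysis from the packaged fixtures.

    Reconstructs the 7-variable ML covariance, fits the path model, computes
    the fit-index battery and the effect decomposition, and bundles the
    printed values for per-cell comparison.
    """
    model = triticale_gpre_model()
    if moments is None:
        moments = triticale_moments(divisor="n")
    fit = fit_ml(model, moments)
    indices = compute_indices(fit)
    effects = effects_from_fit(fit)
    return StudyReport(
        moments=moments,
        fit=fit,
        indices=indices,
        effects=effects,
        published_estimates=load_published_estimates(),
        published_indices=load_published_fit_indices(),
        published_effects=load_published_effects(),
    )
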