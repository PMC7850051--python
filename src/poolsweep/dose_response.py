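"""Probit dose-response analysis: LC50 with Fieller 95% confidence limits.

The model is a maximum-likelihood binomial GLM with a probit link on log10
concentration: ``Phi^-1(p) = alpha + beta * log10(dose)``, so
``LC50 = 10 ** (-alpha / beta)``. Confidence limits for the log-LC50 come
from Fieller's theorem applied to the ratio ``-alpha / beta``; when the
Pearson heterogeneity statistic exceeds its chi-squared 0.95 quantile the
covariance is inflated by the heterogeneity factor and a t quantile is used
in place of the normal one (toxicology convention). Populations are compared
by 95% CI overlap: disjoint intervals are called significantly different.

Replicate rows with the same concentration are pooled before fitting, making
the fit invariant to row order and replicate merging. No control-mortality
correction is applied by default; an Abbott correction is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssayTable",
    "ProbitFit",
    "SeparationError",
    "load_assays",
    "probit_fit",
    "compare_lc50",
]

_REQUIRED = ("population", "concentration", "n_exposed", "n_dead")


class SeparationError(RuntimeError):
    """All observations are 0% or 100% mortality: no finite MLE exists."""


@dataclass
class ProbitFit:
    population: str
    slope: float                 # probits per log10 ppm
    intercept: float
    lc50: float                  # ppm
    ci_low: float                # NaN when the Fieller interval is unbounded
    ci_high: float
    deviance: float
    pearson_chi2: float
    df: int
    heterogeneity: float         # Pearson chi2 / df (1.0 when df == 0)
    flagged: bool                # heterogeneity correction applied

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not self.ci_low <= self.lc50 <= self.ci_high:
                raise ValueError("confidence interval does not bracket LC50")

    @property
    def has_ci(self) -> bool:
        return bool(np.isfinite(self.ci_low) and np.isfinite(self.ci_high))


def load_assays(path) -> pd.DataFrame:
    """Read a dose-response assay CSV and validate it."""
    df = pd.read_csv(path)
    return validate_assays(df)


def validate_assays(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    if (df["concentration"] <= 0).any():
        raise ValueError("concentrations must be > 0")
    if (df["n_dead"] < 0).any() or (df["n_dead"] > df["n_exposed"]).any():
        raise ValueError("need 0 <= n_dead <= n_exposed")
    if (df["n_exposed"] <= 0).any():
        raise ValueError("n_exposed must be > 0")
    return df


def abbott_correct(df: pd.DataFrame, control_mortality: float) -> pd.DataFrame:
    """Abbott's correction for control mortality (off by default upstream)."""
    if not 0 <= control_mortality < 1:
        raise ValueError("control mortality must be in [0, 1)")
    out = df.copy()
    p = out["n_dead"] / out["n_exposed"]
    p_corr = np.clip((p - control_mortality) / (1 - control_mortality), 0, 1)
    out["n_dead"] = np.rint(p_corr * out["n_exposed"]).astype(int)
    return out


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.groupby("concentration", as_index=False)[["n_exposed", "n_dead"]]
        .sum()
        .sort_values("concentration")
        .reset_index(drop=True)
    )


def probit_fit(assay: pd.DataFrame, population: str | None = None) -> ProbitFit:
    """Fit the probit dose-response model for one population's assay rows."""
    df = validate_assays(assay) if "population" in assay.columns else assay.copy()
    if population is not None and "population" in df.columns:
        df = df[df["population"] == population]
    if population is None:
        pops = df["population"].unique() if "population" in df.columns else ["?"]
        population = str(pops[0])
    agg = _aggregate(df)
    if agg["concentration"].nunique() < 2:
        raise ValueError("need at least 2 distinct concentrations")
    p_obs = agg["n_dead"] / agg["n_exposed"]
    if ((p_obs == 0) | (p_obs == 1)).all():
        raise SeparationError(
            "every dose shows 0% or 100% mortality: probit MLE does not exist"
        )

    x = np.log10(agg["concentration"].to_numpy(dtype=float))
    X = sm.add_constant(x)
    endog = np.column_stack([
        agg["n_dead"].to_numpy(dtype=float),
        (agg["n_exposed"] - agg["n_dead"]).to_numpy(dtype=float),
    ])
    model = sm.GLM(endog, X, family=sm.families.Binomial(sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-fit / domain warnings on toy designs
        res = model.fit(maxiter=200)
    alpha, beta = res.params
    cov = np.asarray(res.cov_params())

    n_dose = len(agg)
    dfree = n_dose - 2
    pearson = float(res.pearson_chi2)
    deviance = float(res.deviance)
    heterogeneity = pearson / dfree if dfree > 0 else 1.0
    flagged = dfree > 0 and pearson > stats.chi2.ppf(0.95, dfree)

    lc50 = float(10.0 ** (-alpha / beta))

    if beta <= 0:
        warnings.warn(
            f"{population}: non-positive probit slope ({beta:.3f}); "
            "LC50 CI undefined",
            stacklevel=2,
        )
        ci_low = ci_high = float("nan")
    else:
        if flagged:
            cov = cov * heterogeneity
            crit = stats.t.ppf(0.975, dfree)
        else:
            crit = stats.norm.ppf(0.975)
        ci_low, ci_high = _fieller(alpha, beta, cov, crit)
    return ProbitFit(
        population=population,
        slope=float(beta), intercept=float(alpha),
        lc50=lc50, ci_low=ci_low, ci_high=ci_high,
        deviance=deviance, pearson_chi2=pearson, df=dfree,
        heterogeneity=float(heterogeneity), flagged=bool(flagged),
    )


def _fieller(alpha: float, beta: float, cov: np.ndarray, crit: float):
    """Fieller interval for x0 = -alpha/beta on the log10 scale -> ppm.

    Solves (alpha + beta x)^2 = crit^2 Var(alpha + beta x); an unbounded
    set (g >= 1) is reported as (NaN, NaN).
    """
    vaa, vab, vbb = cov[0, 0], cov[0, 1], cov[1, 1]
    c2 = crit * crit
    A = beta * beta - c2 * vbb
    B = 2.0 * (alpha * beta - c2 * vab)
    C = alpha * alpha - c2 * vaa
    if A <= 0:
        return float("nan"), float("nan")
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return float("nan"), float("nan")
    r = np.sqrt(disc)
    lo = (-B - r) / (2.0 * A)
    hi = (-B + r) / (2.0 * A)
    return float(10.0 ** lo), float(10.0 ** hi)


def compare_lc50(fit_a: ProbitFit, fit_b: ProbitFit) -> dict:
    """CI-overlap comparison of two LC50s.

    ``significant`` is True iff the 95% intervals are disjoint; None
    ("not assessable") when either interval is undefined. ``ratio`` is
    ``lc50_a / lc50_b`` (the resistance ratio).
    """
    ratio = float(fit_a.lc50 / fit_b.lc50)
    if not (fit_a.has_ci and fit_b.has_ci):
        return {"significant": None, "ratio": ratio}
    disjoint = fit_a.ci_high < fit_b.ci_low or fit_b.ci_high < fit_a.ci_low
    return {"significant": bool(disjoint), "ratio": ratio}
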