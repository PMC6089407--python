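"""Logistic-regression test of the parent-to-offspring frequency change.

The significance test runs on the tidy long table produced by
``mesocosm_data.to_long_counts``: one row per replicate-generation with
triploid (asexual female) and diploid (sexual) counts.  The model is a
binomial GLM with logit link,

    logit P(triploid) ~ generation + year (+ generation:year),

reference levels generation = parent and the first year observed.  Effects
are judged with likelihood-ratio tests; the generation odds ratio is
converted to a fold-increase in asexual frequency given the mean parental
proportion.  IRLS is delegated to statsmodels; the LRT, odds-ratio
extraction, profile-likelihood intervals and fold conversion live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2

__all__ = [
    "GlmSpec",
    "GlmFit",
    "LrtResult",
    "fit_logistic",
    "lrt",
    "generation_odds_ratio",
    "fold_change_from_or",
    "fold_increase_summary",
]


@dataclass(frozen=True)
class GlmSpec:
    """Which terms enter the logistic model."""

    generation: bool = True
    year: bool = True
    interaction: bool = False

    def __post_init__(self) -> None:
        if self.interaction and not (self.generation and self.year):
            raise ValueError("interaction requires both main effects")


@dataclass
class GlmFit:
    """A fitted binomial-logit GLM plus the pieces the tests need."""

    spec: GlmSpec
    params: pd.Series
    bse: pd.Series
    deviance: float
    df_resid: int
    llf: float
    converged: bool
    separation: bool
    result: object  # statsmodels GLMResults

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of nested binomial GLMs."""

    D: float
    df: int
    p: float


def _design(data: pd.DataFrame, spec: GlmSpec):
    """Design matrix with treatment coding: generation=parent, year=first level."""
    gen = (data["generation"].astype(str) == "offspring").to_numpy(dtype=float)
    years = sorted(data["year"].astype(str).unique())
    cols = {"Intercept": np.ones(len(data))}
    if spec.generation:
        cols["generation[offspring]"] = gen
    if spec.year:
        for y in years[1:]:
            cols[f"year[{y}]"] = (data["year"].astype(str) == y).to_numpy(dtype=float)
    if spec.interaction:
        for y in years[1:]:
            cols[f"generation[offspring]:year[{y}]"] = gen * cols[f"year[{y}]"]
    return pd.DataFrame(cols, index=data.index)


def fit_logistic(data: pd.DataFrame, spec: GlmSpec = GlmSpec(),
                 offset: np.ndarray | None = None) -> GlmFit:
    """Fit the binomial-logit model to long-format triploid/diploid counts.

    ``data`` needs columns ``generation`` ('parent'/'offspring'),
    ``year``, ``triploid``, ``diploid``.  Complete separation (a fitted
    cell with all-triploid or all-diploid counts) is flagged via the
    ``separation`` attribute rather than silently reported with absurd
    standard errors.
    """
    if data["generation"].astype(str).nunique() < 2:
        raise ValueError("need both parent and offspring generations")
    endog = data[["triploid", "diploid"]].to_numpy(dtype=float)
    exog = _design(data, spec)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(), offset=offset)
    result = model.fit()
    separation = bool(np.any(np.abs(result.params) > 15) or np.any(result.bse > 50))
    return GlmFit(
        spec=spec,
        params=result.params,
        bse=result.bse,
        deviance=float(result.deviance),
        df_resid=int(result.df_resid),
        llf=float(result.llf),
        converged=bool(result.converged) and not separation,
        separation=separation,
        result=result,
    )


def lrt(full: GlmFit, reduced: GlmFit) -> LrtResult:
    """Likelihood-ratio test of a reduced model nested in a full model.

    ``D = deviance(reduced) - deviance(full)``, df the parameter
    difference, p from the chi-squared upper tail.
    """
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("models are not nested: full model has fewer parameters")
    D = reduced.deviance - full.deviance
    if df == 0:
        # identical model classes: chi-squared with 0 df is a point mass at 0
        return LrtResult(D=float(D), df=0, p=1.0)
    return LrtResult(D=float(D), df=df, p=float(chi2.sf(D, df)))


def _profile_ci_generation(data: pd.DataFrame, fit: GlmFit,
                           level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for the generation coefficient.

    Fixes the coefficient at a trial value via an offset, refits the
    remaining terms, and finds where the deviance rises by the chi-squared
    quantile.
    """
    beta_hat = float(fit.params["generation[offspring]"])
    se = float(fit.bse["generation[offspring]"])
    gen = (data["generation"].astype(str) == "offspring").to_numpy(dtype=float)
    reduced_spec = GlmSpec(generation=False, year=fit.spec.year, interaction=False)
    crit = chi2.ppf(level, 1)
    dev_hat = fit.deviance

    def excess(beta: float) -> float:
        refit = fit_logistic(data, reduced_spec, offset=beta * gen)
        return (refit.deviance - dev_hat) - crit

    lo = brentq(excess, beta_hat - 10 * se, beta_hat, xtol=1e-8)
    hi = brentq(excess, beta_hat, beta_hat + 10 * se, xtol=1e-8)
    return lo, hi


def generation_odds_ratio(
    data: pd.DataFrame,
    fit: GlmFit,
    level: float = 0.95,
    method: str = "profile",
) -> tuple[float, tuple[float, float]]:
    """Odds ratio for the offspring-vs-parent contrast, with a CI.

    Profile-likelihood intervals by default; ``method='wald'`` falls back
    to the normal approximation (a warning is the caller's to issue — the
    Wald interval is symmetric on the log scale and can undercover).
    """
    beta = float(fit.params["generation[offspring]"])
    if method == "profile":
        lo, hi = _profile_ci_generation(data, fit, level)
    elif method == "wald":
        z = float(chi2.ppf(level, 1) ** 0.5)
        se = float(fit.bse["generation[offspring]"])
        lo, hi = beta - z * se, beta + z * se
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi)))


def fold_change_from_or(p0: float, or_value: float):
    """Fold-increase in frequency implied by an odds ratio at baseline ``p0``.

    Transforms the odds: ``odds1 = OR * p0/(1-p0)``; the new proportion is
    ``odds1/(1+odds1)`` and the fold-increase is that over ``p0``.  In the
    rare-outcome limit (``p0 -> 0``) the fold-increase equals the odds
    ratio itself.
    """
    p0 = float(p0)
    if not 0 < p0 < 1:
        raise ValueError("baseline proportion p0 must lie strictly in (0, 1)")
    or_value = np.asarray(or_value, dtype=float)
    if np.any(or_value <= 0):
        raise ValueError("odds ratio must be > 0")
    odds1 = or_value * p0 / (1.0 - p0)
    out = (odds1 / (1.0 + odds1)) / p0
    return out if out.ndim else float(out)


def fold_increase_summary(
    data: pd.DataFrame,
    level: float = 0.95,
    baseline: str = "pooled",
    ci_method: str = "profile",
) -> dict:
    """Generation LRT, odds ratio and fold-increase for a long counts table.

    The fold-increase uses the odds ratio from the no-interaction model and
    the mean parental asexual proportion; ``baseline='pooled'`` (default)
    pools all parental counts, ``baseline='mean_of_means'`` averages the
    per-replicate proportions instead.
    """
    full = fit_logistic(data, GlmSpec(generation=True, year=True))
    no_gen = fit_logistic(data, GlmSpec(generation=False, year=True))
    gen_test = lrt(full, no_gen)
    or_hat, (or_lo, or_hi) = generation_odds_ratio(
        data, full, level, method=ci_method
    )
    parents = data[data["generation"].astype(str) == "parent"]
    if baseline == "pooled":
        p0 = parents["triploid"].sum() / (
            parents["triploid"].sum() + parents["diploid"].sum()
        )
    elif baseline == "mean_of_means":
        p0 = (parents["triploid"] / (parents["triploid"] + parents["diploid"])).mean()
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    p0 = float(p0)
    return {
        "baseline_proportion": p0,
        "odds_ratio": or_hat,
        "odds_ratio_ci": (or_lo, or_hi),
        "fold_increase": fold_change_from_or(p0, or_hat),
        "fold_increase_ci": (
            fold_change_from_or(p0, or_lo),
            fold_change_from_or(p0, or_hi),
        ),
        "generation_lrt": {"D": gen_test.D, "df": gen_test.df, "p": gen_test.p},
    }
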