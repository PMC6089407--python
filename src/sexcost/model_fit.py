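"""Beta-binomial likelihood, candidate cost models, AICc selection, bootstrap.

Each replicate contributes a parental asexual frequency ``q_t`` and an
offspring triploid count ``k`` out of ``n`` genotyped.  A candidate model
maps ``q_t`` (and the replicate's year) to a predicted offspring frequency
through the cost-of-sex recursion, and the count is scored with a
mean-parameterized beta-binomial,

    k ~ BetaBinomial(n, alpha = q * theta, beta = (1 - q) * theta),

whose mean is ``q`` and whose extra-binomial variance grows as the
dispersion ``theta`` shrinks (``theta -> inf`` recovers Binomial(n, q)).
Overdispersion absorbs between-mesocosm heterogeneity (clone composition,
micro-environment) that a plain binomial would mistake for signal.

Four candidate parameterizations of the net cost of sex are compared:

* ``no_cost``     — c fixed at 1 (asexuals have no birth-rate advantage)
* ``two_fold``    — c fixed at 2 (the classic cost of males)
* ``mle``         — c a free parameter
* ``mle_by_year`` — a baseline cost ``c0`` for the first year plus free
  deviations ``d_j`` for each later year, ``c(year j) = c0 + d_j``

Models are ranked by AICc (sample size = number of replicates) and weighed
with Akaike weights; uncertainty comes from case-resampling bootstrap over
replicates, both for parameter percentile intervals and for the delta-AICc
limit that delineates a 95% confidence set of models.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .cost_model import next_frequency

__all__ = [
    "CandidateModel",
    "FitResult",
    "BootstrapConfidenceSet",
    "MODEL_IDS",
    "candidate_models",
    "betabinom_logpmf",
    "neg_loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "select_models",
    "bootstrap_confidence_set",
    "bootstrap_param_ci",
]

MODEL_IDS = ("no_cost", "two_fold", "mle", "mle_by_year")

_EPS_Q = 1e-9  # boundary truncation for predicted frequencies
_BIG = 1e12  # optimizer-safe stand-in for +inf inside Nelder-Mead
# Dispersion cap for fitting: at theta ~ 1e6 the beta-binomial already
# matches the binomial far beyond the resolution of these data (subsamples
# of ~70), so the likelihood is flat in log(theta) beyond it.  Underdispersed
# resamples put the theta MLE at +infinity; capping (with a quadratic nudge
# back, see _make_objective) lets the simplex terminate at the cap instead
# of drifting along the flat ridge forever.
_LOG_THETA_MAX = np.log(1e6)


# ---------------------------------------------------------------------------
# candidate models


@dataclass(frozen=True)
class CandidateModel:
    """One parameterization of the net cost of sex.

    ``free_parameters`` always starts with the dispersion ``theta``;
    ``cost_parameters`` is empty for the fixed-cost models, ``("c",)`` for
    the free-cost model, and ``("c0", "d_<year>", ...)`` for the
    year-indexed model (baseline = first year in ``years``).
    """

    id: str
    fixed_cost: float | None = None
    years: tuple[str, ...] = ()
    cost_parameters: tuple[str, ...] = ()

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return ("theta",) + self.cost_parameters

    @property
    def k(self) -> int:
        """Number of estimated parameters (dispersion included)."""
        return len(self.free_parameters)

    def costs(self, params: Mapping[str, float], year_codes: np.ndarray) -> np.ndarray:
        """Per-replicate cost of sex implied by ``params``.

        ``year_codes`` index into :attr:`years` (ignored unless the model
        is year-indexed).
        """
        n = len(year_codes)
        if self.fixed_cost is not None:
            return np.full(n, self.fixed_cost)
        if self.id == "mle":
            return np.full(n, params["c"])
        c_by_year = np.empty(len(self.years))
        c_by_year[0] = params["c0"]
        for j, year in enumerate(self.years[1:], start=1):
            c_by_year[j] = params["c0"] + params[f"d_{year}"]
        return c_by_year[year_codes]


def candidate_models(years: Sequence[str]) -> list[CandidateModel]:
    """The four candidate models for a dataset spanning ``years``.

    ``years`` are the distinct year labels in baseline-first order; the
    year-indexed model gets one deviation parameter per non-baseline year.
    """
    years = tuple(dict.fromkeys(str(y) for y in years))
    if not years:
        raise ValueError("need at least one year")
    deviations = tuple(f"d_{y}" for y in years[1:])
    return [
        CandidateModel(id="no_cost", fixed_cost=1.0),
        CandidateModel(id="two_fold", fixed_cost=2.0),
        CandidateModel(id="mle", cost_parameters=("c",)),
        CandidateModel(id="mle_by_year", years=years,
                       cost_parameters=("c0",) + deviations),
    ]


# ---------------------------------------------------------------------------
# likelihood


def betabinom_logpmf(k, n, q, theta):
    """Log-pmf of the mean-parameterized beta-binomial.

    ``log[ C(n,k) B(k + q*theta, n - k + (1-q)*theta) / B(q*theta, (1-q)*theta) ]``
    with ``alpha = q*theta`` and ``beta = (1-q)*theta``, evaluated through
    log-gamma so counts up to ~1e4 do not overflow.  Elementwise over
    array inputs.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    q = np.asarray(q, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any((k < 0) | (k > n)):
        raise ValueError("need 0 <= k <= n")
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("mean frequency q must lie strictly in (0, 1)")
    if np.any(theta <= 0):
        raise ValueError("dispersion theta must be > 0")
    a = q * theta
    b = (1.0 - q) * theta
    out = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )
    return out if out.ndim else float(out)


def _as_arrays(data, years: tuple[str, ...] | None = None):
    """Coerce paired-frequency data to (q, k, n, year_codes, years)."""
    if isinstance(data, pd.DataFrame):
        q = data["q_t"].to_numpy(dtype=float)
        k = data["offspring_k"].to_numpy(dtype=float)
        n = data["offspring_n"].to_numpy(dtype=float)
        year_labels = [str(y) for y in data["year"]]
    else:
        q = np.array([p.q_t for p in data], dtype=float)
        k = np.array([p.offspring_k for p in data], dtype=float)
        n = np.array([p.offspring_n for p in data], dtype=float)
        year_labels = [str(p.year) for p in data]
    if years is None:
        years = tuple(dict.fromkeys(year_labels))
    index = {y: j for j, y in enumerate(years)}
    codes = np.array([index[y] for y in year_labels], dtype=np.intp)
    return q, k, n, codes, years


def _nll(q, k, n, codes, model: CandidateModel, params: Mapping[str, float]) -> float:
    theta = params["theta"]
    if theta <= 0:
        return np.inf
    c = model.costs(params, codes)
    if np.any(c <= 0):
        return np.inf
    q_pred = c * q / (1.0 + q * (c - 1.0))
    q_pred = np.clip(q_pred, _EPS_Q, 1.0 - _EPS_Q)
    a = q_pred * theta
    b = (1.0 - q_pred) * theta
    ll = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )
    return float(-np.sum(ll))


def neg_loglik(model: CandidateModel, params: Mapping[str, float], data) -> float:
    """Negative log-likelihood of ``params`` under ``model`` for paired data.

    Sums ``-betabinom_logpmf(k_i, n_i, next_frequency(q_t_i, c(year_i)),
    theta)`` over replicates.  Predicted frequencies at the boundary
    (``q_t`` of 0 or 1) are truncated to ``[1e-9, 1 - 1e-9]`` so degenerate
    replicates stay in the likelihood rather than being discarded.  A
    parameter vector implying ``c <= 0`` or ``theta <= 0`` returns ``+inf``
    (optimizer-safe penalty).  Empty data gives 0.
    """
    q, k, n, codes, _ = _as_arrays(data, model.years or None)
    if len(q) == 0:
        return 0.0
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_t must lie in [0, 1]")
    return _nll(q, k, n, codes, model, params)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    model_id: str
    estimates: dict[str, float]
    logL: float
    k: int
    n: int
    aicc: float
    converged: bool
    delta_aicc: float | None = None
    akaike_weight: float | None = None
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    message: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.bootstrap_ci is not None:
            d["bootstrap_ci"] = {k: list(v) for k, v in self.bootstrap_ci.items()}
        return d


def _pack(model: CandidateModel, params: Mapping[str, float]) -> np.ndarray:
    """Natural-scale dict -> transformed optimizer vector (log theta, log c/c0, raw d)."""
    x = [np.log(params["theta"])]
    for name in model.cost_parameters:
        value = params[name]
        x.append(np.log(value) if name in ("c", "c0") else value)
    return np.array(x)


def _unpack(model: CandidateModel, x: np.ndarray) -> dict[str, float]:
    params = {"theta": float(np.exp(min(x[0], _LOG_THETA_MAX)))}
    for j, name in enumerate(model.cost_parameters, start=1):
        params[name] = float(np.exp(x[j])) if name in ("c", "c0") else float(x[j])
    return params


def _default_init(model: CandidateModel, q, k, n) -> dict[str, float]:
    params = {"theta": 20.0}
    if model.cost_parameters:
        q_bar = float(np.mean(q))
        p_bar = float(np.sum(k) / np.sum(n))
        q_bar = min(max(q_bar, 0.01), 0.99)
        p_bar = min(max(p_bar, 0.01), 0.99)
        c0 = (p_bar / (1 - p_bar)) / (q_bar / (1 - q_bar))
        c0 = min(max(c0, 0.2), 10.0)
        params[model.cost_parameters[0]] = c0
        for name in model.cost_parameters[1:]:
            params[name] = 0.0
    return params


def _make_objective(model: CandidateModel, q, k, n, codes):
    """Transformed-scale objective with the flat-ridge guard on dispersion.

    Above the dispersion cap the likelihood is flat in log(theta); a
    quadratic nudge back toward the cap lets Nelder-Mead terminate there
    instead of drifting along the ridge until it exhausts evaluations.
    """

    def objective(x):
        value = _nll(q, k, n, codes, model, _unpack(model, x))
        if not np.isfinite(value):
            return _BIG
        if x[0] > _LOG_THETA_MAX:
            value += (x[0] - _LOG_THETA_MAX) ** 2
        return value

    return objective


def _minimize(objective, x0: np.ndarray):
    return minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 10000, "maxfev": 10000},
    )


def fit_model(
    model: CandidateModel,
    data,
    init: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Minimizes the negative log-likelihood over the free parameters with
    Nelder-Mead on transformed coordinates (``log theta``; ``log c`` /
    ``log c0`` to enforce positivity; year deviations untransformed, with
    an infinite penalty whenever ``c0 + d_j <= 0``).  ``n_starts`` jittered
    restarts guard against local optima; the best optimum wins.  A fit that
    never converges is returned with ``converged=False`` and diagnostics in
    ``message`` — never a silent partial answer.
    """
    q, k, n, codes, _ = _as_arrays(data, model.years or None)
    n_obs = len(q)
    if n_obs < model.k:
        raise ValueError(
            f"model {model.id} has {model.k} parameters but only {n_obs} replicates"
        )
    params0 = dict(_default_init(model, q, k, n))
    if init is not None:
        params0.update(init)
    objective = _make_objective(model, q, k, n, codes)
    rng = np.random.default_rng(seed)
    x0 = _pack(model, params0)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(0.0, 0.5, size=x0.shape)
        starts.append(x0 + jitter)

    best = None
    any_success = False
    for x_start in starts:
        res = _minimize(objective, x_start)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    estimates = _unpack(model, best.x)
    logL = -float(best.fun)
    converged = bool(any_success and best.fun < _BIG / 2)
    return FitResult(
        model_id=model.id,
        estimates=estimates,
        logL=logL,
        k=model.k,
        n=n_obs,
        aicc=aicc(logL, model.k, n_obs),
        converged=converged,
        message="" if converged else f"optimizer did not converge: {best.message}",
    )


# ---------------------------------------------------------------------------
# information criteria


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``-2 logL + 2k + 2k(k+1)/(n - k - 1)``; ``n`` is the number of
    replicates, not the number of individuals genotyped.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta_aicc) -> np.ndarray:
    """Akaike weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``.

    Interpretable as the probability that model *i* is the best of the
    candidate set; invariant to a common shift of all AICc values.
    """
    delta = np.asarray(delta_aicc, dtype=float)
    if delta.size == 0:
        raise ValueError("akaike_weights needs at least one model")
    rel = np.exp(-0.5 * (delta - delta.min()))
    return rel / rel.sum()


def select_models(
    data,
    models: Sequence[CandidateModel] | None = None,
    seed: int | None = None,
    n_starts: int = 5,
) -> list[FitResult]:
    """Fit candidate models on identical data and rank them by AICc.

    Returns results sorted by AICc ascending with delta-AICc and Akaike
    weights populated.  Models whose fit fails are excluded with a warning.
    """
    if models is None:
        _, _, _, _, years = _as_arrays(data)
        models = candidate_models(years)
    results = []
    for model in models:
        fit = fit_model(model, data, seed=seed, n_starts=n_starts)
        if fit.converged:
            results.append(fit)
        else:
            warnings.warn(
                f"excluding model {model.id} from selection: {fit.message}",
                stacklevel=2,
            )
    if not results:
        raise RuntimeError("all candidate model fits failed")
    results.sort(key=lambda r: r.aicc)
    best = results[0].aicc
    weights = akaike_weights([r.aicc - best for r in results])
    for fit, w in zip(results, weights):
        fit.delta_aicc = fit.aicc - best
        fit.akaike_weight = float(w)
    return results


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapConfidenceSet:
    """Bootstrap delta-AICc distribution for a focal model and the 95% limit."""

    focal_model: str
    delta_limit: float
    actual_delta: dict[str, float]
    confidence_set: list[str]
    deltas: np.ndarray = field(repr=False)
    n_failed: int = 0
    B: int = 0
    warning: str = ""


def _resample_fits(
    models: Sequence[CandidateModel],
    q, k, n, codes,
    idx: np.ndarray,
    inits: Mapping[str, Mapping[str, float]],
):
    """Single-start refits of all models on one bootstrap resample."""
    out = {}
    qb, kb, nb, cb = q[idx], k[idx], n[idx], codes[idx]
    n_obs = len(idx)
    for model in models:
        objective = _make_objective(model, qb, kb, nb, cb)
        res = _minimize(objective, _pack(model, inits[model.id]))
        if not res.success or res.fun >= _BIG / 2:
            return None
        out[model.id] = aicc(-float(res.fun), model.k, n_obs)
    return out


def _prepare_bootstrap(data, models, seed):
    q, k, n, codes, years = _as_arrays(data)
    if models is None:
        models = candidate_models(years)
    full_fits = {m.id: fit_model(m, data, seed=seed) for m in models}
    inits = {mid: fit.estimates for mid, fit in full_fits.items()}
    return q, k, n, codes, models, full_fits, inits


def bootstrap_confidence_set(
    data,
    models: Sequence[CandidateModel] | None = None,
    B: int = 1000,
    focal_model: str = "two_fold",
    seed: int | None = None,
    indices: Sequence[np.ndarray] | None = None,
) -> BootstrapConfidenceSet:
    """Bootstrap the delta-AICc of a focal model to delineate a confidence set.

    Resamples the replicates with replacement ``B`` times; on each
    resample all candidate models are refit (single start, initialized at
    the full-data estimates) and the focal model's AICc minus the
    resample's best AICc is recorded.  The 95th percentile of that
    distribution is the delta-AICc limit; models whose *actual-data* delta
    does not exceed the limit form the 95% confidence set.

    ``seed`` is mandatory unless explicit ``indices`` (one index array per
    resample) are supplied — used mainly for deterministic testing.
    Resamples on which any fit fails are dropped and counted; more than 1%
    drops sets a warning on the result.
    """
    if seed is None and indices is None:
        raise ValueError("a seed is mandatory for reproducible bootstrapping")
    if B < 1:
        raise ValueError("need B >= 1 resamples")
    q, k, n, codes, models, full_fits, inits = _prepare_bootstrap(data, models, seed)
    if focal_model not in inits:
        raise ValueError(f"unknown focal model {focal_model!r}")
    n_obs = len(q)
    if indices is None:
        children = np.random.SeedSequence(seed).spawn(B)
        indices = [
            np.random.default_rng(child).integers(0, n_obs, n_obs)
            for child in children
        ]
    deltas = []
    n_failed = 0
    for idx in indices:
        fits = _resample_fits(models, q, k, n, codes, np.asarray(idx), inits)
        if fits is None:
            n_failed += 1
            continue
        deltas.append(fits[focal_model] - min(fits.values()))
    deltas = np.array(deltas)
    if deltas.size == 0:
        raise RuntimeError("every bootstrap resample failed to fit")
    limit = float(np.percentile(deltas, 95))
    best_aicc = min(f.aicc for f in full_fits.values())
    actual = {mid: f.aicc - best_aicc for mid, f in full_fits.items()}
    warning = ""
    if n_failed > 0.01 * len(indices):
        warning = f"{n_failed}/{len(indices)} bootstrap resamples failed to fit"
        warnings.warn(warning, stacklevel=2)
    return BootstrapConfidenceSet(
        focal_model=focal_model,
        delta_limit=limit,
        actual_delta=actual,
        confidence_set=[mid for mid, d in actual.items() if d <= limit],
        deltas=deltas,
        n_failed=n_failed,
        B=len(indices),
        warning=warning,
    )


def bootstrap_param_ci(
    data,
    model: CandidateModel,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    indices: Sequence[np.ndarray] | None = None,
    return_samples: bool = False,
):
    """Percentile bootstrap confidence intervals for a model's free parameters.

    Case-resamples the replicates ``B`` times, refits the model on each
    resample (single start at the full-data estimates), and returns the
    ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of each parameter.
    """
    if seed is None and indices is None:
        raise ValueError("a seed is mandatory for reproducible bootstrapping")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    q, k, n, codes, _ = _as_arrays(data, model.years or None)
    n_obs = len(q)
    full = fit_model(model, data, seed=seed)
    init = full.estimates
    x0 = _pack(model, init)
    if indices is None:
        children = np.random.SeedSequence(seed).spawn(B)
        indices = [
            np.random.default_rng(child).integers(0, n_obs, n_obs)
            for child in children
        ]
    samples: dict[str, list[float]] = {name: [] for name in model.free_parameters}
    n_failed = 0
    for idx in indices:
        idx = np.asarray(idx)
        qb, kb, nb, cb = q[idx], k[idx], n[idx], codes[idx]
        res = _minimize(_make_objective(model, qb, kb, nb, cb), x0)
        if not res.success or res.fun >= _BIG / 2:
            n_failed += 1
            continue
        est = _unpack(model, res.x)
        for name in model.free_parameters:
            samples[name].append(est[name])
    if n_failed > 0.01 * len(indices):
        warnings.warn(
            f"{n_failed}/{len(indices)} bootstrap resamples failed to fit",
            stacklevel=2,
        )
    lo = 100 * (1 - level) / 2
    hi = 100 - lo
    intervals = {
        name: (float(np.percentile(vals, lo)), float(np.percentile(vals, hi)))
        for name, vals in samples.items()
        if vals
    }
    if return_samples:
        return intervals, {k: np.array(v) for k, v in samples.items()}
    return intervals
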