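"""Synthetic mesocosm experiments with the structure the analysis assumes.

Emulates a replicated outdoor mesocosm design: in each of several years a
set of tanks is seeded with a mixed sexual/asexual snail population, one
generation elapses, and both generations are subsampled for ploidy by flow
cytometry while a dissection tally records sex and trematode infection.

Per mesocosm the generator

1. draws a latent parental asexual frequency ``q_t`` from a truncated
   normal across mesocosms,
2. propagates it through the cost-of-sex recursion to the expected
   offspring frequency ``q_{t+1} = c q_t / (1 + q_t (c - 1))``,
3. simulates the dissection of ``dissected_n`` parents (asexual w.p.
   ``q_t``; sexual snails male w.p. ``1 - s``; infection marks i.i.d. at
   ``infection_rate``, independent of reproductive mode by default),
4. draws a parental female flow subsample hypergeometrically from the
   uninfected dissected females (so the triploid fraction inherits the
   within-mesocosm finite-sample structure), and
5. draws the offspring triploid count from a beta-binomial with mean
   ``q_{t+1}`` and dispersion ``theta`` — the overdispersion the fitted
   likelihood assumes.

Flow-cytometry failures are emulated by binomial thinning of the subsample
sizes at the configured exclusion rates; the emitted counts are therefore
post-exclusion, matching what the instrument pipeline reports.

Defaults reproduce the study conditions the analysis is designed for:
4 years x 6 mesocosms, parental asexual frequency centred on 0.29, ~62
parental females and ~70 offspring genotyped per mesocosm, 150 dissected
parents, 9.82% infection, 6.01%/5.38% parent/offspring flow exclusions, a
true two-fold cost and dispersion theta = 40.

One integer master seed governs everything; each mesocosm gets an
independent substream keyed by (seed, year index, mesocosm index), so a
subset of mesocosms regenerates identically regardless of order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cost_model import next_frequency
from .mesocosm_data import MesocosmRecord

__all__ = ["SyntheticConfig", "generate_experiment", "paper_like_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic mesocosm experiment."""

    seed: int
    n_years: int = 4
    mesocosms_per_year: int = 6
    true_c: float | Mapping[str, float] = 2.0
    theta: float = 40.0
    s: float = 0.5
    q_mean: float = 0.29
    q_sd: float = 0.08
    q_bounds: tuple[float, float] = (0.02, 0.98)
    parent_subsample_mean: float = 62.0
    offspring_subsample_mean: float = 70.0
    dissected_n: int = 150
    infection_rate: float = 0.0982
    flow_exclusion_parent: float = 0.0601
    flow_exclusion_offspring: float = 0.0538
    first_year: int = 2012
    # Optional excess infection odds for asexuals; 0 keeps infection
    # independent of reproductive mode (the pipeline test, not parasite
    # selection).
    infection_mode_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.mesocosms_per_year < 1:
            raise ValueError("need at least one year and one mesocosm per year")
        costs = (
            self.true_c.values()
            if isinstance(self.true_c, Mapping)
            else [self.true_c]
        )
        if any(c <= 0 for c in costs):
            raise ValueError("true cost of sex must be > 0")
        if not self.theta > 0:
            raise ValueError("dispersion theta must be > 0")
        if not 0 < self.s <= 1:
            raise ValueError("primary sex ratio s must be in (0, 1]")
        lo, hi = self.q_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("q_bounds must satisfy 0 < lo < hi < 1")
        if not lo <= self.q_mean <= hi:
            raise ValueError("q_mean must lie inside q_bounds")
        for name in ("infection_rate", "flow_exclusion_parent",
                     "flow_exclusion_offspring"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.dissected_n < 1:
            raise ValueError("dissected_n must be positive")

    @property
    def years(self) -> tuple[str, ...]:
        return tuple(str(self.first_year + j) for j in range(self.n_years))

    def cost_for_year(self, year: str) -> float:
        if isinstance(self.true_c, Mapping):
            return float(self.true_c[year])
        return float(self.true_c)


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    # rejection sampling; the default window keeps acceptance > 75%
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed to accept")


def _betabinom_draw(rng, n: int, q: float, theta: float) -> int:
    if not np.isfinite(theta):
        p = q
    else:
        p = rng.beta(q * theta, (1.0 - q) * theta)
    return int(rng.binomial(n, p))


def _one_mesocosm(cfg: SyntheticConfig, year: str, year_idx: int,
                  meso_idx: int) -> tuple[MesocosmRecord, dict]:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed,
                               spawn_key=(year_idx, meso_idx))
    )
    q_t = _truncated_normal(rng, cfg.q_mean, cfg.q_sd, *cfg.q_bounds)
    c = cfg.cost_for_year(year)
    q_t1 = next_frequency(q_t, c)

    # dissection of parents: mode, then sex among sexuals, then infection
    n_asex = int(rng.binomial(cfg.dissected_n, q_t))
    n_sex = cfg.dissected_n - n_asex
    n_males = int(rng.binomial(n_sex, 1.0 - cfg.s))
    n_sex_females = n_sex - n_males
    p_inf_asex = min(cfg.infection_rate * (1.0 + cfg.infection_mode_bias), 0.999)
    inf_asex = int(rng.binomial(n_asex, p_inf_asex))
    inf_sexf = int(rng.binomial(n_sex_females, cfg.infection_rate))
    inf_males = int(rng.binomial(n_males, cfg.infection_rate))
    asex_ok = n_asex - inf_asex
    sexf_ok = n_sex_females - inf_sexf
    females_ok = asex_ok + sexf_ok

    # parental female flow subsample, thinned by instrument exclusions,
    # drawn without replacement from the uninfected dissected females
    n_target = max(1, int(rng.poisson(cfg.parent_subsample_mean)))
    n_kept = int(rng.binomial(n_target, 1.0 - cfg.flow_exclusion_parent))
    n_kept = max(1, min(n_kept, females_ok)) if females_ok > 0 else 0
    if n_kept > 0 and females_ok > 0:
        parent_tri = int(rng.hypergeometric(asex_ok, sexf_ok, n_kept))
    else:
        parent_tri = 0
    parent_dip = n_kept - parent_tri

    # offspring flow subsample: unsexed, overdispersed around q_{t+1}
    m_target = max(1, int(rng.poisson(cfg.offspring_subsample_mean)))
    m_kept = max(1, int(rng.binomial(m_target, 1.0 - cfg.flow_exclusion_offspring)))
    off_tri = _betabinom_draw(rng, m_kept, q_t1, cfg.theta)
    off_dip = m_kept - off_tri

    record = MesocosmRecord(
        year=year,
        mesocosm_id=f"{year}-M{meso_idx + 1}",
        parent_flow_triploid=parent_tri,
        parent_flow_diploid=parent_dip,
        dissected_males=n_males,
        dissected_females=n_asex + n_sex_females,
        offspring_flow_triploid=off_tri,
        offspring_flow_diploid=off_dip,
        infected_males=inf_males,
        infected_females=inf_asex + inf_sexf,
        infected_offspring=0,
    )
    truth = {
        "year": year,
        "mesocosm_id": record.mesocosm_id,
        "q_t_true": q_t,
        "q_t1_expected": float(q_t1),
        "c": c,
    }
    return record, truth


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[list[MesocosmRecord], dict]:
    """Generate one synthetic experiment plus its ground truth.

    Returns the raw records (same schema ``mesocosm_data.read_counts``
    parses) and a truth record holding the generating parameters and the
    per-mesocosm latent frequencies, for parameter-recovery tests.
    Identical configs (including seed) give byte-identical output.
    """
    records: list[MesocosmRecord] = []
    per_mesocosm: list[dict] = []
    for year_idx, year in enumerate(config.years):
        for meso_idx in range(config.mesocosms_per_year):
            record, truth = _one_mesocosm(config, year, year_idx, meso_idx)
            records.append(record)
            per_mesocosm.append(truth)
    truth = {
        "config": {
            **{k: (dict(v) if isinstance(v, Mapping) else v)
               for k, v in dataclasses.asdict(config).items()},
        },
        "mesocosms": per_mesocosm,
    }
    return records, truth


def paper_like_dataset(seed: int) -> list[MesocosmRecord]:
    """A default-parameter experiment: 24 mesocosms, true two-fold cost.

    The all-defaults convenience dataset used by the docs and tests as a
    synthetic stand-in for a real replicated mesocosm counts table.
    """
    records, _ = generate_experiment(SyntheticConfig(seed=seed))
    return records
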