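"""Mesocosm count tables and the preprocessing arithmetic behind them.

Each replicate mesocosm contributes, at the end of an experimental year:

* a dissection tally of the parental generation (males vs females, with
  trematode-infected — i.e. castrated — individuals flagged),
* a flow-cytometry subsample of parental *females* scored triploid
  (asexual) vs diploid (sexual), and
* a flow-cytometry subsample of unsexed offspring scored the same way.

Because parental flow cytometry sees females only, the diploid denominator
for the parental asexual frequency must add back the males: the number of
males consistent with a female subsample of size ``T + D`` is imputed from
the mesocosm-wide dissection sex ratio.  Offspring were genotyped unsexed,
so their triploid fraction needs no imputation.

Infected individuals are excluded throughout: castration removes them from
reproduction and would otherwise distort the relative fitness of sexual and
asexual females.

Input schema (CSV/TSV, one row per mesocosm-year; snake_case, required
unless marked optional):

====================== =====================================================
column                 meaning
====================== =====================================================
year                   experimental year (category, e.g. 2012)
mesocosm_id            replicate identifier within year
parent_flow_triploid   triploid count, parental female flow subsample
parent_flow_diploid    diploid count, parental female flow subsample
dissected_males        males in the dissection tally (incl. infected)
dissected_females      females in the dissection tally (incl. infected)
offspring_flow_triploid triploid count, offspring flow subsample
offspring_flow_diploid diploid count, offspring flow subsample
infected_males         optional, default 0
infected_females       optional, default 0
infected_offspring     optional, default 0
====================== =====================================================
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MesocosmRecord",
    "PairedFrequency",
    "SchemaError",
    "read_counts",
    "write_counts",
    "exclude_infected",
    "impute_males",
    "parental_frequency",
    "offspring_frequency",
    "tertiary_sex_ratio",
    "paired_frequencies",
    "paired_to_dataframe",
    "to_long_counts",
    "write_paired",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]

REQUIRED_COLUMNS = (
    "year",
    "mesocosm_id",
    "parent_flow_triploid",
    "parent_flow_diploid",
    "dissected_males",
    "dissected_females",
    "offspring_flow_triploid",
    "offspring_flow_diploid",
)
OPTIONAL_COLUMNS = ("infected_males", "infected_females", "infected_offspring")

_COUNT_COLUMNS = REQUIRED_COLUMNS[2:] + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """Raised when a counts table violates the documented schema."""


@dataclass(frozen=True)
class MesocosmRecord:
    """Raw per-mesocosm counts for one replicate-year."""

    year: str
    mesocosm_id: str
    parent_flow_triploid: int
    parent_flow_diploid: int
    dissected_males: int
    dissected_females: int
    offspring_flow_triploid: int
    offspring_flow_diploid: int
    infected_males: int = 0
    infected_females: int = 0
    infected_offspring: int = 0

    def __post_init__(self) -> None:
        for name in _COUNT_COLUMNS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool) or value < 0:
                raise ValueError(
                    f"{name} must be a non-negative integer, got {value!r}"
                )


@dataclass(frozen=True)
class PairedFrequency:
    """One replicate's parental frequency and offspring counts.

    The atomic datum of the likelihood: parental asexual frequency ``q_t``
    together with the offspring triploid count ``offspring_k`` out of
    ``offspring_n`` genotyped.
    """

    q_t: float
    offspring_k: int
    offspring_n: int
    year: str
    mesocosm_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.q_t <= 1:
            raise ValueError(f"q_t must lie in [0, 1], got {self.q_t}")
        if not 0 <= self.offspring_k <= self.offspring_n:
            raise ValueError(
                f"need 0 <= offspring_k <= offspring_n, got "
                f"{self.offspring_k}/{self.offspring_n}"
            )


def read_counts(path: str | Path) -> list[MesocosmRecord]:
    """Read a mesocosm counts table (CSV or TSV, sniffed) into records.

    Missing optional infection columns default to zero.  Raises
    :class:`SchemaError` for a missing required column and ``ValueError``
    (citing the offending row) for negative or non-integer counts.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"counts table {path} is missing column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {"year": str(row["year"]), "mesocosm_id": str(row["mesocosm_id"])}
        for name in _COUNT_COLUMNS:
            if name in OPTIONAL_COLUMNS and name not in df.columns:
                continue
            raw = row[name]
            try:
                value = int(raw)
                if value < 0 or float(raw) != value:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i + 2} of {path}: column {name!r} must be a "
                    f"non-negative integer, got {raw!r}"
                ) from None
            kwargs[name] = value
        records.append(MesocosmRecord(**kwargs))
    return records


def write_counts(records: Iterable[MesocosmRecord], path: str | Path) -> None:
    """Write records back to CSV/TSV with the canonical column order."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df = df[list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)]
    df.to_csv(path, sep=sep, index=False)


def exclude_infected(record: MesocosmRecord) -> MesocosmRecord:
    """Remove infected (castrated) individuals from the dissection tallies.

    Returns a record whose ``dissected_males``/``dissected_females`` count
    uninfected snails only, with the infected counts zeroed.  The flow
    subsamples are untouched: parental flow input was heads of dissected
    *uninfected* females, and offspring were born in trematode-free
    mesocosms, so both are uninfected by construction
    (``infected_offspring`` is carried for bookkeeping only).
    """
    if record.infected_males > record.dissected_males:
        raise ValueError(
            f"infected_males ({record.infected_males}) exceeds dissected_males "
            f"({record.dissected_males}) in mesocosm {record.mesocosm_id}"
        )
    if record.infected_females > record.dissected_females:
        raise ValueError(
            f"infected_females ({record.infected_females}) exceeds "
            f"dissected_females ({record.dissected_females}) in mesocosm "
            f"{record.mesocosm_id}"
        )
    return dataclasses.replace(
        record,
        dissected_males=record.dissected_males - record.infected_males,
        dissected_females=record.dissected_females - record.infected_females,
        infected_males=0,
        infected_females=0,
    )


def impute_males(n_female_subsample: int, males: int, females: int) -> float:
    """Male count consistent with a female flow subsample of the given size.

    Scales the mesocosm-wide dissection sex ratio: returns
    ``n_female_subsample * males / females``.  Kept fractional so the ratio
    is preserved exactly; round half-to-even when exporting integer tables.
    """
    if females <= 0:
        raise ValueError("sex ratio undefined: no females in the dissection tally")
    if males < 0 or n_female_subsample < 0:
        raise ValueError("counts must be non-negative")
    return n_female_subsample * males / females


def parental_frequency(record: MesocosmRecord) -> float:
    """Parental asexual frequency q_t = T / (T + D + M_hat).

    ``T``/``D`` are the triploid/diploid counts of the female flow
    subsample and ``M_hat`` the imputed male count for a subsample of that
    size.  Expects infected individuals already excluded
    (see :func:`exclude_infected`).
    """
    T = record.parent_flow_triploid
    D = record.parent_flow_diploid
    if T + D == 0:
        raise ValueError(
            f"degenerate record {record.mesocosm_id}: empty parental flow subsample"
        )
    m_hat = impute_males(T + D, record.dissected_males, record.dissected_females)
    return T / (T + D + m_hat)


def offspring_frequency(record: MesocosmRecord) -> tuple[int, int]:
    """Offspring triploid count and total genotyped, straight from flow.

    Offspring were genotyped unsexed, so no male imputation is needed:
    returns ``(k, n) = (triploid, triploid + diploid)``.
    """
    k = record.offspring_flow_triploid
    n = k + record.offspring_flow_diploid
    if n == 0:
        raise ValueError(
            f"degenerate record {record.mesocosm_id}: empty offspring flow subsample"
        )
    return k, n


def tertiary_sex_ratio(males: int, females: int) -> float:
    """Proportion female among sexual adults, females / (males + females).

    An observable proxy for the primary sex ratio ``s``.
    """
    if males + females <= 0:
        raise ValueError("tertiary sex ratio undefined for an empty tally")
    if males < 0 or females < 0:
        raise ValueError("counts must be non-negative")
    return females / (males + females)


def paired_frequencies(
    records: Sequence[MesocosmRecord],
) -> tuple[list[PairedFrequency], dict]:
    """Preprocess raw records into the likelihood's paired data.

    Applies infected exclusion, male imputation and the frequency
    arithmetic per record.  Records degenerate in either generation are
    dropped with a warning (the replicate, not the snail, is the unit of
    inference; imputing a whole generation is not defensible).  Returns the
    pairs plus a JSON-serializable run log of exclusions and imputations.
    """
    pairs: list[PairedFrequency] = []
    log: dict = {"n_input": len(records), "dropped": [], "imputed_males": {}}
    for record in records:
        clean = exclude_infected(record)
        try:
            q_t = parental_frequency(clean)
            k, n = offspring_frequency(clean)
        except ValueError as exc:
            warnings.warn(f"dropping replicate: {exc}", stacklevel=2)
            log["dropped"].append(
                {"year": record.year, "mesocosm_id": record.mesocosm_id,
                 "reason": str(exc)}
            )
            continue
        key = f"{clean.year}/{clean.mesocosm_id}"
        log["imputed_males"][key] = impute_males(
            clean.parent_flow_triploid + clean.parent_flow_diploid,
            clean.dissected_males,
            clean.dissected_females,
        )
        pairs.append(
            PairedFrequency(
                q_t=q_t, offspring_k=k, offspring_n=n,
                year=clean.year, mesocosm_id=clean.mesocosm_id,
            )
        )
    log["n_used"] = len(pairs)
    return pairs, log


def paired_to_dataframe(pairs: Sequence[PairedFrequency]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in pairs])


def to_long_counts(records: Sequence[MesocosmRecord]) -> pd.DataFrame:
    """Tidy long-format counts for the logistic regression stage.

    One row per replicate-generation with integer triploid/diploid counts.
    Parental diploids are flow diploids plus imputed males, rounded
    half-to-even (regression on counts needs integers; the fractional
    imputation is preserved in :func:`paired_frequencies`).
    """
    rows = []
    for record in records:
        clean = exclude_infected(record)
        T, D = clean.parent_flow_triploid, clean.parent_flow_diploid
        m_hat = impute_males(T + D, clean.dissected_males, clean.dissected_females)
        rows.append(
            {"year": clean.year, "mesocosm_id": clean.mesocosm_id,
             "generation": "parent", "triploid": T,
             "diploid": int(round(D + m_hat))}
        )
        k, n = offspring_frequency(clean)
        rows.append(
            {"year": clean.year, "mesocosm_id": clean.mesocosm_id,
             "generation": "offspring", "triploid": k, "diploid": n - k}
        )
    return pd.DataFrame(rows)


def write_paired(
    pairs: Sequence[PairedFrequency], log: dict, csv_path: str | Path,
    log_path: str | Path | None = None,
) -> None:
    """Export paired frequencies as tidy CSV plus the JSON run log."""
    paired_to_dataframe(pairs).to_csv(csv_path, index=False)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(log, indent=2, sort_keys=True))
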