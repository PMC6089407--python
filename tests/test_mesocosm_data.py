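"""Tests of the counts-table I/O and preprocessing arithmetic."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexcost import (
    MesocosmRecord,
    SchemaError,
    exclude_infected,
    impute_males,
    offspring_frequency,
    paired_frequencies,
    parental_frequency,
    read_counts,
    tertiary_sex_ratio,
    write_counts,
)
from sexcost.mesocosm_data import to_long_counts


def _record(**overrides):
    base = dict(
        year="2012", mesocosm_id="2012-M1",
        parent_flow_triploid=20, parent_flow_diploid=40,
        dissected_males=55, dissected_females=95,
        offspring_flow_triploid=34, offspring_flow_diploid=36,
    )
    base.update(overrides)
    return MesocosmRecord(**base)


def test_read_write_roundtrip(tmp_path, paper_like_records):
    path = tmp_path / "counts.csv"
    write_counts(paper_like_records, path)
    again = read_counts(path)
    assert again == paper_like_records
    tsv = tmp_path / "counts.tsv"
    write_counts(paper_like_records, tsv)
    assert read_counts(tsv) == paper_like_records


def test_read_counts_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("year,mesocosm_id,parent_flow_triploid\n2012,M1,5\n")
    with pytest.raises(SchemaError, match="offspring_flow_diploid"):
        read_counts(path)


def test_read_counts_negative_count_cites_row(tmp_path, paper_like_records):
    path = tmp_path / "neg.csv"
    write_counts(paper_like_records[:3], path)
    lines = path.read_text().splitlines()
    lines[2] = lines[2].replace(lines[2].split(",")[5], "-3", 1)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="row 3"):
        read_counts(path)


def test_exclude_infected_subtracts_tallies():
    rec = _record(infected_males=5, infected_females=9)
    clean = exclude_infected(rec)
    assert (clean.dissected_males, clean.dissected_females) == (50, 86)
    assert clean.infected_males == clean.infected_females == 0
    # flow counts untouched: subsample was uninfected by construction
    assert clean.parent_flow_triploid == rec.parent_flow_triploid


def test_exclude_infected_identity_when_uninfected():
    rec = _record()
    assert exclude_infected(rec) == rec


def test_exclude_infected_inconsistent_counts():
    with pytest.raises(ValueError, match="exceeds"):
        exclude_infected(_record(infected_males=60))


@pytest.mark.parametrize(
    "n_sub, males, females, expected",
    [(60, 50, 100, 30.0), (60, 0, 100, 0.0), (62, 55, 95, 62 * 55 / 95)],
)
def test_impute_males(n_sub, males, females, expected):
    assert impute_males(n_sub, males, females) == pytest.approx(expected, rel=1e-12)


def test_impute_males_no_females():
    with pytest.raises(ValueError, match="sex ratio"):
        impute_males(60, 10, 0)


@pytest.mark.parametrize(
    "T, D, males, females, expected",
    [
        (30, 30, 30, 60, 1 / 3),  # 1 male per 2 females: M_hat = 30
        (30, 30, 50, 50, 0.25),  # 1:1 sex ratio: M_hat = T + D = 60
        (0, 40, 55, 95, 0.0),
        (28, 20, 40, 80, 28 / 72),
    ],
)
def test_parental_frequency(T, D, males, females, expected):
    rec = _record(
        parent_flow_triploid=T, parent_flow_diploid=D,
        dissected_males=males, dissected_females=females,
    )
    assert parental_frequency(rec) == pytest.approx(expected, rel=1e-12)


def test_parental_frequency_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        parental_frequency(_record(parent_flow_triploid=0, parent_flow_diploid=0))


@pytest.mark.parametrize(
    "tri, dip, expected",
    [(37, 37, (37, 74)), (0, 70, (0, 70)), (34, 36, (34, 70))],
)
def test_offspring_frequency(tri, dip, expected):
    rec = _record(offspring_flow_triploid=tri, offspring_flow_diploid=dip)
    assert offspring_frequency(rec) == expected


@pytest.mark.parametrize(
    "males, females, expected", [(39, 61, 0.61), (50, 50, 0.5), (0, 10, 1.0)]
)
def test_tertiary_sex_ratio(males, females, expected):
    assert tertiary_sex_ratio(males, females) == pytest.approx(expected)


def test_tertiary_sex_ratio_empty():
    with pytest.raises(ValueError):
        tertiary_sex_ratio(0, 0)


@settings(deadline=None, max_examples=100)
@given(
    scale=st.integers(min_value=2, max_value=20),
    males=st.integers(min_value=1, max_value=200),
    females=st.integers(min_value=1, max_value=200),
)
def test_parental_frequency_scale_invariant(scale, males, females):
    """Doubling the dissection tallies leaves q_t unchanged: only the sex
    ratio enters the imputation."""
    rec = _record(dissected_males=males, dissected_females=females)
    scaled = dataclasses.replace(
        rec, dissected_males=males * scale, dissected_females=females * scale
    )
    assert parental_frequency(rec) == pytest.approx(parental_frequency(scaled))


def test_parental_frequency_without_males_is_female_fraction():
    rec = _record(parent_flow_triploid=20, parent_flow_diploid=40, dissected_males=0)
    assert parental_frequency(rec) == pytest.approx(20 / 60)


def test_paired_frequencies_pipeline(paper_like_records):
    pairs, log = paired_frequencies(paper_like_records)
    assert len(pairs) == 24
    assert log["n_used"] == 24 and not log["dropped"]
    assert len(log["imputed_males"]) == 24
    for p in pairs:
        assert 0 <= p.q_t <= 1
        assert 0 <= p.offspring_k <= p.offspring_n


def test_paired_frequencies_drops_degenerate(paper_like_records):
    broken = [
        dataclasses.replace(
            paper_like_records[0], parent_flow_triploid=0, parent_flow_diploid=0
        )
    ] + list(paper_like_records[1:])
    with pytest.warns(UserWarning, match="dropping replicate"):
        pairs, log = paired_frequencies(broken)
    assert len(pairs) == 23
    assert len(log["dropped"]) == 1


def test_to_long_counts_shape(paper_like_records):
    long_df = to_long_counts(paper_like_records)
    assert len(long_df) == 48
    assert set(long_df["generation"]) == {"parent", "offspring"}
    assert (long_df["triploid"] >= 0).all() and (long_df["diploid"] >= 0).all()
    # imputed males are rounded half-to-even: the table is integer-valued
    assert long_df["diploid"].dtype.kind in "iu"
    assert long_df["triploid"].dtype.kind in "iu"
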