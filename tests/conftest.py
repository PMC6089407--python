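import pytest

from sexcost import paired_frequencies, paper_like_dataset


@pytest.fixture(scope="session")
def paper_like_records():
    """One default-condition synthetic experiment: 24 mesocosms, true c = 2."""
    return paper_like_dataset(seed=1)


@pytest.fixture(scope="session")
def paper_like_pairs(paper_like_records):
    pairs, _ = paired_frequencies(paper_like_records)
    return pairs
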