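import numpy as np
import pytest

from teadgrammar.regions import ChromSizes, GenomicInterval, Peak


@pytest.fixture
def small_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_peak(
    chrom: str = "chr1",
    start: int = 1000,
    end: int = 1151,
    summit: int | None = None,
    score: float = 10.0,
    peak_id: str = "p1",
) -> Peak:
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, score, peak_id)


@pytest.fixture
def random_sequence(rng) -> str:
    return "".join(rng.choice(list("ACGT"), size=500))
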