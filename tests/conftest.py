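import numpy as np
import pytest

from patmetrics import PatRecord, RegionSpec


@pytest.fixture
def region10() -> RegionSpec:
    """A 10-CpG region starting at global CpG index 1."""
    return RegionSpec(chrom="chr1", first=1, last=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_records(region: RegionSpec, patterns: list[str], counts=None) -> list[PatRecord]:
    counts = counts or [1] * len(patterns)
    return [
        PatRecord(region.chrom, region.first, p, c) for p, c in zip(patterns, counts)
    ]
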