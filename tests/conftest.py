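import numpy as np
import pytest

from bcellkit.intervals import GenomicInterval
from bcellkit.synth import SpikeDesign, make_toy_genome


@pytest.fixture
def toy_genome():
    return make_toy_genome(1, 100_000, 20, seed=11)


@pytest.fixture
def spike_design():
    regions = tuple(
        GenomicInterval("chr1", s, s + 500) for s in (10_000, 40_000, 70_000)
    )
    return SpikeDesign(
        regions=regions,
        enrichment=(20.0, 20.0, 20.0),
        depth=100_000,
    )


def random_intervals(rng, n, chrom_len, max_width=400, chrom="chr1"):
    """n random intervals on one chromosome (may overlap)."""
    starts = rng.integers(0, chrom_len - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [GenomicInterval(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)]
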