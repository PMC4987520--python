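"""Two-condition differential accessibility over a shared region universe.

The decision rule: a region is differentially accessible when one condition
has at least four times more (normalized) reads than the other and the
Poisson upper-tail probability of the larger count given the smaller as
expectation is at most 0.01. Normalization is total-count scaling to the
mean library size; replicate libraries are summed within condition before
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals, sort_intervals
from .peaks import poisson_upper_tail
from .synth import RegionCountMatrix

DEFAULT_MIN_RATIO = 4.0
DEFAULT_MAX_P = 0.01
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DifferentialCall:
    """Per-region outcome of the differential-accessibility test.

    ``ratio`` is larger/smaller of the normalized condition totals (after
    pseudocount); ``direction`` is 'A' or 'B' for the more accessible
    condition of a differential region, 'none' otherwise.
    """

    region: GenomicInterval
    ratio: float
    pval: float
    direction: str

    @property
    def differential(self) -> bool:
        return self.direction != "none"


def build_universe(
    peaks_a: Sequence[GenomicInterval], peaks_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Union of two peak sets with overlapping regions merged; sorted, disjoint."""
    return merge_intervals(list(peaks_a) + list(peaks_b))


def count_fragments(
    regions: Sequence[GenomicInterval],
    fragments_by_library: Mapping[str, Sequence[GenomicInterval]],
    conditions: Mapping[str, str] | None = None,
) -> RegionCountMatrix:
    """Count fragments overlapping each region, per library.

    ``regions`` must be disjoint (merge first via :func:`build_universe`).
    A fragment spanning several regions counts once in each. ``conditions``
    maps library name to condition label; defaults to the library name.
    """
    srt = sort_intervals(regions)
    for a, b in zip(srt, srt[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("regions overlap; merge the universe first")

    lib_names = list(fragments_by_library)
    counts = np.zeros((len(regions), len(lib_names)), dtype=np.int64)
    order = sorted(range(len(regions)), key=lambda i: (regions[i].chrom, regions[i].start))
    by_chrom: dict[str, list[int]] = {}
    for i in order:
        by_chrom.setdefault(regions[i].chrom, []).append(i)

    for col, name in enumerate(lib_names):
        for frag in fragments_by_library[name]:
            for i in by_chrom.get(frag.chrom, ()):
                r = regions[i]
                if r.start >= frag.end:
                    break
                if r.end > frag.start:
                    counts[i, col] += 1
    cond = [conditions[n] if conditions else n for n in lib_names]
    return RegionCountMatrix(
        regions=list(regions), counts=counts, library_names=lib_names, conditions=cond
    )


def classify_differential(
    matrix: RegionCountMatrix,
    min_ratio: float = DEFAULT_MIN_RATIO,
    max_p: float = DEFAULT_MAX_P,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DifferentialCall]:
    """Apply the >=4-fold / P<=0.01 rule per region.

    Replicate columns are summed within each of the exactly two conditions,
    sums are scaled to the mean condition total (total-count normalization),
    and per region the Poisson upper tail of the larger normalized count
    given the smaller as expectation is computed. Both thresholds are
    inclusive. The count entering the Poisson tail is rounded to the nearest
    integer.
    """
    cond_names = sorted(set(matrix.conditions))
    if len(cond_names) != 2:
        raise ValueError(f"exactly two conditions required, got {cond_names}")
    cols_a = [i for i, c in enumerate(matrix.conditions) if c == cond_names[0]]
    cols_b = [i for i, c in enumerate(matrix.conditions) if c == cond_names[1]]
    raw_a = matrix.counts[:, cols_a].sum(axis=1).astype(float)
    raw_b = matrix.counts[:, cols_b].sum(axis=1).astype(float)

    tot_a, tot_b = raw_a.sum(), raw_b.sum()
    mean_tot = (tot_a + tot_b) / 2.0
    x_a = raw_a * (mean_tot / tot_a) if tot_a > 0 else raw_a
    x_b = raw_b * (mean_tot / tot_b) if tot_b > 0 else raw_b

    calls: list[DifferentialCall] = []
    for region, a, b in zip(matrix.regions, x_a, x_b):
        hi, lo = (a, b) if a >= b else (b, a)
        ratio = (hi + pseudocount) / (lo + pseudocount) if (lo + pseudocount) > 0 else np.inf
        pval = poisson_upper_tail(int(round(hi)), lo)
        if ratio >= min_ratio and pval <= max_p:
            direction = cond_names[0] if a >= b else cond_names[1]
        else:
            direction = "none"
        calls.append(DifferentialCall(region, float(ratio), float(pval), direction))
    return calls
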