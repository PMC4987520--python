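"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: toy genomes
with TSS annotations, IP/input read libraries with spiked enriched regions
over a homogeneous Poisson background, two-condition ATAC-like count
matrices with known differential regions, qPCR Ct tables consistent with
known rearrangement frequencies, and comet tail-moment samples with a known
outlier fraction. All generators are pure functions of their arguments
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import TSS, GenomicInterval
from .peaks import AlignedRead

DEFAULT_READ_LENGTH = 50  # matches 50-bp single-end sequencing


@dataclass(frozen=True)
class ToyGenome:
    """A small stand-in genome: chromosome sizes plus TSS annotations."""

    chrom_sizes: dict[str, int]
    tss: tuple[TSS, ...] = ()

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        for t in self.tss:
            if t.chrom not in self.chrom_sizes:
                raise ValueError(f"TSS on unknown chromosome {t.chrom!r}")
            if not 0 <= t.pos < self.chrom_sizes[t.chrom]:
                raise ValueError(f"TSS position {t.pos} outside {t.chrom}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class SpikeDesign:
    """Ground truth for a ChIP library: enriched regions over background.

    ``enrichment`` is the per-region fold-enrichment of read-start density
    inside the region relative to background (must exceed 1). When ``depth``
    is given, per-bp rates are scaled so the expected total read count equals
    ``depth``; ``background_rate`` then only sets the relative baseline.
    """

    regions: tuple[GenomicInterval, ...] = ()
    enrichment: tuple[float, ...] = ()
    background_rate: float = 1.0
    depth: int | None = None
    read_length: int = DEFAULT_READ_LENGTH
    fragment_size: int = 150

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.enrichment):
            raise ValueError("one enrichment value per region required")
        if any(e <= 1 for e in self.enrichment):
            raise ValueError("enrichment must be > 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        merged_len = len(self.regions)
        srt = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        for a, b in zip(srt, srt[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("spike regions must be non-overlapping")


def make_toy_genome(
    n_chrom: int, chrom_length: int, n_genes: int, seed: int
) -> ToyGenome:
    """Uniformly place ``n_genes`` distinct TSSs on ``n_chrom`` equal chromosomes."""
    if n_chrom < 1 or chrom_length < 10_000 or n_genes < 0:
        raise ValueError(
            "require n_chrom >= 1, chrom_length >= 10000, n_genes >= 0"
        )
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    chroms = list(chrom_sizes)
    tss: list[TSS] = []
    used: set[tuple[str, int]] = set()
    for g in range(n_genes):
        while True:
            chrom = chroms[int(rng.integers(n_chrom))]
            pos = int(rng.integers(chrom_length))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TSS(chrom, pos, strand, f"gene{g + 1:04d}"))
    tss.sort(key=lambda t: (t.chrom, t.pos))
    return ToyGenome(chrom_sizes, tuple(tss))


def simulate_chip_library(
    genome: ToyGenome,
    design: SpikeDesign,
    is_input: bool,
    seed: int,
) -> list[AlignedRead]:
    """Draw a read library from a piecewise-homogeneous Poisson model.

    Background read starts fall uniformly over the genome. In an IP library
    (``is_input=False``) each spike region receives additional reads so that
    the read-start density inside it is its fold-enrichment times the
    background: the extra reads are the 5' ends of ``fragment_size``-long
    fragments confined to the region (plus-strand reads at the fragment's
    left end, minus-strand reads ending at its right end), mimicking
    immunoprecipitated fragments centred on a binding site. Input libraries
    ignore the spikes, matching an IgG/input control.

    When ``depth`` is set, rates are scaled so the expected total read count
    equals ``depth``.
    """
    for r in design.regions:
        if r.chrom not in genome.chrom_sizes or r.end > genome.chrom_sizes[r.chrom]:
            raise ValueError(f"spike region {r} outside genome bounds")

    G = genome.total_length
    spike_extra = 0.0
    if not is_input:
        spike_extra = sum(
            (e - 1.0) * len(r) for r, e in zip(design.regions, design.enrichment)
        )
    if design.depth is not None:
        if design.depth == 0:
            return []
        base = design.depth / (G + spike_extra)
    else:
        base = design.background_rate

    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    rl = design.read_length

    for chrom, length in genome.chrom_sizes.items():
        n = rng.poisson(base * length)
        if n:
            starts = rng.integers(0, length, size=n)
            strands = rng.random(n) < 0.5
            for s, plus in zip(starts, strands):
                pos = min(int(s), max(0, length - rl))
                reads.append(AlignedRead(chrom, pos, "+" if plus else "-", rl))
    if not is_input:
        for region, enr in zip(design.regions, design.enrichment):
            n = rng.poisson(base * (enr - 1.0) * len(region))
            if n == 0:
                continue
            fsize = min(design.fragment_size, len(region))
            frag_starts = rng.integers(region.start, max(region.start + 1, region.end - fsize + 1), size=n)
            strands = rng.random(n) < 0.5
            for fs, plus in zip(frag_starts, strands):
                if plus:
                    pos = int(fs)
                else:
                    pos = int(fs) + fsize - rl
                reads.append(AlignedRead(region.chrom, max(0, pos), "+" if plus else "-", rl))
    return reads


@dataclass
class RegionCountMatrix:
    """Per-region fragment counts over a set of libraries.

    ``counts`` has one row per region and one column per library;
    ``conditions`` labels each column with its condition name.
    """

    regions: list[GenomicInterval]
    counts: np.ndarray
    library_names: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.library_names)):
            raise ValueError("counts shape must be (n_regions, n_libraries)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.conditions) != len(self.library_names):
            raise ValueError("one condition label per library required")

    @property
    def library_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def simulate_atac_counts(
    n_regions: int,
    n_differential: int,
    fold: float,
    base_mean: float,
    seed: int,
    *,
    region_width: int = 1_000,
    chrom: str = "chrSim",
) -> tuple[RegionCountMatrix, np.ndarray]:
    """Two-condition Poisson count matrix with known differential regions.

    The first ``n_differential`` regions (after a seeded shuffle of labels)
    have condition-A mean ``fold * base_mean`` versus ``base_mean`` in
    condition B; all other regions share mean ``base_mean`` in both. Returns
    the matrix and a boolean truth-label vector.
    """
    if n_regions < 0 or n_differential < 0 or n_differential > n_regions:
        raise ValueError("require 0 <= n_differential <= n_regions")
    if fold < 1 or base_mean < 0:
        raise ValueError("require fold >= 1 and base_mean >= 0")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_regions, dtype=bool)
    labels[:n_differential] = True
    rng.shuffle(labels)
    if fold == 1:
        labels[:] = False
    mean_a = np.where(labels, fold * base_mean, base_mean)
    mean_b = np.full(n_regions, float(base_mean))
    counts = np.column_stack([rng.poisson(mean_a), rng.poisson(mean_b)])
    regions = [
        GenomicInterval(chrom, i * 2 * region_width, i * 2 * region_width + region_width)
        for i in range(n_regions)
    ]
    matrix = RegionCountMatrix(
        regions=regions,
        counts=counts,
        library_names=["condA_rep1", "condB_rep1"],
        conditions=["A", "B"],
    )
    return matrix, labels


def simulate_ct_table(
    true_freqs: Sequence[float],
    ct_actb: float,
    noise_sd: float,
    seed: int,
    *,
    target: str = "Ig_kappa",
) -> pd.DataFrame:
    """Ct table whose implied 2^(Ct_Actb - Ct_Ig) equals the given frequencies.

    For each sample, Ct_Ig = Ct_Actb - log2(freq) + Gaussian noise; the Actb
    record carries ``ct_actb`` exactly. Noise-free tables round-trip exactly
    through the frequency calculation.
    """
    freqs = np.asarray(true_freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > 1):
        raise ValueError("frequencies must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, f in enumerate(freqs):
        sid = f"sample{i + 1:03d}"
        ct_ig = ct_actb - np.log2(f) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        rows.append((sid, "control", "Actb", ct_actb))
        rows.append((sid, "control", target, ct_ig))
    return pd.DataFrame(rows, columns=["sample_id", "group", "target", "ct"])


def simulate_tail_moments(
    n: int,
    outlier_frac: float,
    base_scale: float = 1.0,
    outlier_shift: float = 10.0,
    seed: int = 0,
    *,
    base_cv: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Comet tail-moment sample with a known outlier fraction.

    Non-outliers come from a tight normal distribution centred at
    ``base_scale`` (s.d. ``base_cv * base_scale``, truncated at 0, emulating
    undamaged nuclei); exactly ``round(n * outlier_frac)`` cells are shifted
    up by ``outlier_shift`` (damaged cells with long tails). Returns
    (tail_moments, truth_labels).
    """
    if not 0 <= outlier_frac <= 1:
        raise ValueError("outlier_frac must be in [0, 1]")
    if n < 0 or base_scale < 0 or outlier_shift < 0:
        raise ValueError("n, base_scale and outlier_shift must be non-negative")
    rng = np.random.default_rng(seed)
    n_out = round(n * outlier_frac)
    labels = np.zeros(n, dtype=bool)
    labels[:n_out] = True
    rng.shuffle(labels)
    values = np.maximum(rng.normal(base_scale, base_cv * base_scale, size=n), 0.0)
    values[labels] += outlier_shift
    return values, labels
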