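"""Genomic interval algebra, TSS-distance classification, gene association and
signal metaprofiles.

All coordinates are 0-based half-open ``[start, end)``. Overlap between two
intervals means they share at least one base pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PROXIMAL_MAX_BP = 5_000
DISTAL_MAX_BP = 500_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        Inclusive 0-based start.
    end : int
        Exclusive end; must satisfy ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class TSS(NamedTuple):
    """A transcription start site anchoring a gene."""

    chrom: str
    pos: int
    strand: str
    gene_id: str


@dataclass(frozen=True)
class TssDistanceClass:
    """Distance of a region to its nearest TSS and the resulting class.

    ``proximal`` means within 5 kb of a TSS (inclusive), ``distal`` between
    5 kb (exclusive) and 500 kb (inclusive), ``far`` beyond 500 kb or on a
    chromosome with no annotated TSS (``distance`` is then None).
    """

    label: str
    distance: int | None = None


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping (>= 1 shared bp) intervals into maximal intervals.

    Abutting intervals (``a.end == b.start``) are kept separate: they share
    no base.
    """
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    *,
    assume_sorted: bool = False,
) -> list[tuple[int, int, GenomicInterval]]:
    """All overlapping pairs between two interval lists.

    Returns tuples ``(i, j, overlap)`` where ``a[i]`` and ``b[j]`` share at
    least one base and ``overlap`` is their intersection interval. Output is
    sorted by the overlap's (chrom, start, end). Inputs are sorted internally
    unless ``assume_sorted`` is set (a log notice is emitted when sorting was
    needed).
    """
    a_idx = sorted(range(len(a)), key=lambda i: (a[i].chrom, a[i].start, a[i].end))
    b_idx = sorted(range(len(b)), key=lambda j: (b[j].chrom, b[j].start, b[j].end))
    if not assume_sorted and (a_idx != list(range(len(a))) or b_idx != list(range(len(b)))):
        logger.info("intersect: inputs were not sorted; sorting internally")

    out: list[tuple[int, int, GenomicInterval]] = []
    # Sweep per chromosome; interval lists here are modest so an active-list
    # sweep is ample.
    from collections import defaultdict

    by_chrom_b: dict[str, list[int]] = defaultdict(list)
    for j in b_idx:
        by_chrom_b[b[j].chrom].append(j)

    for i in a_idx:
        ai = a[i]
        for j in by_chrom_b.get(ai.chrom, ()):
            bj = b[j]
            if bj.start >= ai.end:
                break
            if bj.end > ai.start:
                ov = GenomicInterval(ai.chrom, max(ai.start, bj.start), min(ai.end, bj.end))
                out.append((i, j, ov))
    out.sort(key=lambda t: (t[2].chrom, t[2].start, t[2].end, t[0], t[1]))
    return out


def classify_tss_distance(
    peak: GenomicInterval,
    tss: Sequence[TSS],
    *,
    proximal_max: int = PROXIMAL_MAX_BP,
    distal_max: int = DISTAL_MAX_BP,
) -> TssDistanceClass:
    """Classify a peak by unsigned midpoint distance to the nearest TSS.

    A peak within ``proximal_max`` (default 5 kb, inclusive) of a TSS is
    promoter-proximal; between that and ``distal_max`` (default 500 kb,
    inclusive) it is distal (enhancer-like); beyond, far. A chromosome with
    no TSS yields ``far`` with distance None.
    """
    positions = [t.pos for t in tss if t.chrom == peak.chrom]
    if not positions:
        logger.warning("no TSS on chromosome %s; classifying as far", peak.chrom)
        return TssDistanceClass("far", None)
    mid = peak.midpoint
    d = min(abs(mid - p) for p in positions)
    if d <= proximal_max:
        return TssDistanceClass("proximal", d)
    if d <= distal_max:
        return TssDistanceClass("distal", d)
    return TssDistanceClass("far", d)


def _regulatory_domains(
    tss: Sequence[TSS],
    chrom_sizes: Mapping[str, int],
    basal_up: int,
    basal_down: int,
    max_ext: int,
) -> dict[str, GenomicInterval]:
    """Basal-plus-extension regulatory domain per gene.

    Basal domain: ``basal_up`` upstream and ``basal_down`` downstream of the
    TSS, strand-aware. The domain is then extended on each side up to
    ``max_ext`` from the TSS, but never past the midpoint of the gap to the
    neighbouring gene's basal domain, so extended domains of neighbouring
    genes do not overlap (basal domains themselves may). Clipped to the
    chromosome.
    """
    domains: dict[str, GenomicInterval] = {}
    by_chrom: dict[str, list[TSS]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, genes in by_chrom.items():
        clen = chrom_sizes[chrom]
        genes = sorted(genes, key=lambda t: t.pos)
        basal: list[tuple[int, int]] = []
        for t in genes:
            if t.strand == "-":
                lo, hi = t.pos - basal_down, t.pos + basal_up
            else:
                lo, hi = t.pos - basal_up, t.pos + basal_down
            basal.append((max(0, lo), min(clen, hi)))
        # nearest basal boundary on each side over *all* other genes (with
        # uneven basal widths the nearest boundary need not belong to the
        # adjacent gene)
        prefix_max_end = []
        cur = None
        for lo_hi in basal:
            prefix_max_end.append(cur)
            cur = lo_hi[1] if cur is None else max(cur, lo_hi[1])
        suffix_min_start = [None] * len(basal)
        cur = None
        for k in range(len(basal) - 1, -1, -1):
            suffix_min_start[k] = cur
            cur = basal[k][0] if cur is None else min(cur, basal[k][0])
        for k, t in enumerate(genes):
            b_lo, b_hi = basal[k]
            left_end = prefix_max_end[k]
            right_start = suffix_min_start[k]
            left_cap = 0 if left_end is None else (left_end + b_lo + 1) // 2
            right_cap = clen if right_start is None else (b_hi + right_start) // 2
            lo = min(b_lo, max(t.pos - max_ext, left_cap, 0))
            hi = max(b_hi, min(t.pos + max_ext, right_cap, clen))
            lo = max(0, lo)
            hi = min(clen, hi)
            if lo < hi:
                domains[t.gene_id] = GenomicInterval(chrom, lo, hi)
    return domains


def assign_genes(
    peaks: Sequence[GenomicInterval],
    tss: Sequence[TSS],
    chrom_sizes: Mapping[str, int],
    *,
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_ext: int = 1_000_000,
) -> dict[int, list[str]]:
    """Associate peaks with genes by basal-plus-extension regulatory domains.

    Each gene owns a strand-aware basal domain (default 5 kb upstream, 1 kb
    downstream of its TSS) extended up to ``max_ext`` toward its neighbours;
    the gap between two basal domains is split at its midpoint so extended
    domains never reach past a neighbouring gene. A peak is assigned to every
    gene whose domain contains the peak midpoint.

    Returns a map from peak index to sorted gene_id list (peaks hitting no
    domain map to an empty list).
    """
    domains = _regulatory_domains(tss, chrom_sizes, basal_up, basal_down, max_ext)
    result: dict[int, list[str]] = {}
    for i, pk in enumerate(peaks):
        mid = pk.midpoint
        hits = [
            g
            for g, dom in domains.items()
            if dom.chrom == pk.chrom and dom.start <= mid < dom.end
        ]
        result[i] = sorted(hits)
    return result


def overlap_counts(
    sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[tuple[str, ...], int]:
    """Venn-style membership counts for 2-3 named region sets.

    Each region of the *first-named* set is classified by which of the other
    sets it overlaps (>= 1 bp with any of their regions). Keys are tuples of
    the overlapping set names (always including the first set's name); values
    sum to the size of the first set. Each input set must be internally
    merged (no self-overlap).
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError(f"overlap_counts supports 2-3 sets, got {len(names)}")
    for name, regs in sets.items():
        merged = merge_intervals(regs)
        if len(merged) != len(regs):
            raise ValueError(f"set {name!r} contains self-overlapping regions")

    first = names[0]
    counts: dict[tuple[str, ...], int] = {}
    for region in sets[first]:
        members = [first]
        for other in names[1:]:
            if any(region.overlaps(r) for r in sets[other]):
                members.append(other)
        key = tuple(members)
        counts[key] = counts.get(key, 0) + 1
    return counts


def metaprofile(
    signal: Mapping[str, np.ndarray],
    anchors: Sequence[tuple[str, int]],
    *,
    flank: int = 2_000,
    n_bins: int = 100,
    resolution: int = 1,
) -> np.ndarray:
    """Mean signal in equal bins around a set of anchor points.

    ``signal`` maps chromosome name to a coverage vector with ``resolution``
    bp per element (1 for per-bp tracks, e.g. 50 for per-window tracks).
    For each anchor the window ``[center - flank, center + flank)`` is split
    into ``n_bins`` equal bins; the profile entry for bin b is the mean over
    anchors of the mean per-bp signal inside bin b. Anchors whose window
    runs off a chromosome edge are dropped (with a logged count).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(anchors) == 0:
        raise ValueError("empty anchor list")
    if (2 * flank) % n_bins != 0:
        raise ValueError("2*flank must be divisible by n_bins")
    bin_bp = 2 * flank // n_bins

    profiles = []
    dropped = 0
    for chrom, center in anchors:
        track = signal.get(chrom)
        chrom_len = 0 if track is None else len(track) * resolution
        lo, hi = center - flank, center + flank
        if track is None or lo < 0 or hi > chrom_len:
            dropped += 1
            continue
        bins = np.empty(n_bins)
        for b in range(n_bins):
            s, e = lo + b * bin_bp, lo + (b + 1) * bin_bp
            if resolution == 1:
                bins[b] = track[s:e].mean()
            else:
                # per-bp mean over elements covering [s, e)
                idx = np.arange(s, e) // resolution
                bins[b] = track[idx].mean()
        profiles.append(bins)
    if dropped:
        logger.info("metaprofile: dropped %d anchors truncated by chromosome edges", dropped)
    if not profiles:
        raise ValueError("all anchors were truncated by chromosome edges")
    return np.mean(profiles, axis=0)
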