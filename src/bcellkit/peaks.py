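"""Window/Poisson ChIP-seq peak caller.

The algorithm: remove clonal duplicates, extend each read to a 150-bp
fragment in its 3' direction, tile the genome in 50-bp windows, count
fragments overlapping each window for IP and input, scale the input counts
to the IP library size to obtain a per-window expectation lambda, compute
the Poisson upper-tail probability P(X >= k | lambda) per window, mark
windows significant at P < 1e-3, require both neighbours of a window to be
significant as well ("qualifying"), and merge maximal runs of significant
windows containing at least one qualifying window into peaks.

Everything here is deterministic: no randomness enters after the input
libraries are fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

DEFAULT_WINDOW = 50
DEFAULT_EXT = 150
DEFAULT_ALPHA = 1.0e-3


class EmptyLibraryError(ValueError):
    """Raised when a required read library is empty."""


@dataclass(frozen=True)
class AlignedRead:
    """A mapped sequencing read.

    ``pos`` is the leftmost 0-based coordinate (SAM convention); for a
    minus-strand read the biological 5' end is therefore ``pos + length - 1``.
    """

    chrom: str
    pos: int
    strand: str
    length: int = 50

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative read position {self.pos}")
        if self.length <= 0:
            raise ValueError(f"non-positive read length {self.length}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass
class WindowStats:
    """Per-window test results for one chromosome.

    Arrays are parallel over the chromosome's 50-bp tiling; the last window
    may be shorter than 50 bp where the chromosome length is not a multiple
    of the window size.
    """

    chrom: str
    window: int
    chrom_length: int
    ip_count: np.ndarray
    input_count: np.ndarray
    lam: np.ndarray
    pval: np.ndarray
    significant: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    qualifying: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_windows(self) -> int:
        return len(self.ip_count)

    def window_interval(self, i: int) -> GenomicInterval:
        start = i * self.window
        end = min((i + 1) * self.window, self.chrom_length)
        return GenomicInterval(self.chrom, start, end)


@dataclass(frozen=True)
class Peak:
    """A called peak: a maximal run of significant windows anchored by at
    least one qualifying window."""

    interval: GenomicInterval
    n_windows: int
    min_pval: float
    summit: int


@dataclass
class PeakCallerConfig:
    """Tunable parameters of the caller.

    ``extend_mode='fragment'`` replaces each read by an ``ext``-long fragment
    from its 5' end in the 3' direction; ``'length_plus'`` instead appends
    ``ext`` bases past the read's 3' end. ``lam_floor='auto'`` floors the
    per-window expectation at the genome-wide mean scaled input count per
    window, so zero-input windows cannot yield zero-probability calls.
    """

    window: int = DEFAULT_WINDOW
    ext: int = DEFAULT_EXT
    alpha: float = DEFAULT_ALPHA
    lam_floor: float | str = "auto"
    dedup: bool = True
    extend_mode: str = "fragment"
    dedup_key_stranded: bool = True


def dedupe_reads(
    reads: Sequence[AlignedRead], *, stranded: bool = True
) -> list[AlignedRead]:
    """Keep at most one read per (chrom, position, strand) key.

    Collapses clonal PCR duplicates: reads mapping to the same position are
    counted once. First occurrences are kept in input order. With
    ``stranded=False`` the key drops the strand.
    """
    seen: set[tuple] = set()
    out: list[AlignedRead] = []
    for r in reads:
        key = (r.chrom, r.pos, r.strand) if stranded else (r.chrom, r.pos)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def extend_read(
    read: AlignedRead,
    ext: int = DEFAULT_EXT,
    *,
    chrom_length: int | None = None,
    mode: str = "fragment",
) -> GenomicInterval:
    """Replace a read by its inferred fragment, extended in the 3' direction.

    In ``fragment`` mode (default) the result is ``ext`` bp long starting at
    the read's 5' end: ``[pos, pos+ext)`` for ``+`` reads and
    ``[pos+length-ext, pos+length)`` for ``-`` reads. In ``length_plus`` mode
    the read keeps its own length and gains ``ext`` extra 3' bases. The
    result is clipped to ``[0, chrom_length)``.
    """
    if ext <= 0:
        raise ValueError("ext must be positive")
    if mode == "fragment":
        if read.strand == "+":
            lo, hi = read.pos, read.pos + ext
        else:
            lo, hi = read.pos + read.length - ext, read.pos + read.length
    elif mode == "length_plus":
        if read.strand == "+":
            lo, hi = read.pos, read.pos + read.length + ext
        else:
            lo, hi = read.pos - ext, read.pos + read.length
    else:
        raise ValueError(f"unknown extension mode {mode!r}")
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if hi <= lo:
        # fully clipped away; return a 1-bp stub at the boundary
        lo, hi = max(0, hi - 1), max(1, hi)
    return GenomicInterval(read.chrom, lo, hi)


def count_windows(
    fragments: Iterable[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> dict[str, np.ndarray]:
    """Count fragments overlapping each fixed-width window per chromosome.

    Window i covers ``[i*window, (i+1)*window)``; a fragment increments every
    window it overlaps by at least one base.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    diffs = {
        chrom: np.zeros(-(-length // window) + 1, dtype=np.int64)
        for chrom, length in chrom_sizes.items()
    }
    for frag in fragments:
        d = diffs.get(frag.chrom)
        if d is None:
            raise KeyError(f"fragment on unknown chromosome {frag.chrom!r}")
        first = frag.start // window
        last = (frag.end - 1) // window  # inclusive
        last = min(last, len(d) - 2)
        if first > last:
            continue
        d[first] += 1
        d[last + 1] -= 1
    return {chrom: np.cumsum(d[:-1]) for chrom, d in diffs.items()}


def normalize_input(
    ip_total: int,
    input_total: int,
    input_count: float | np.ndarray,
    lam_floor: float = 0.0,
) -> float | np.ndarray:
    """Scale input window counts to the IP library size, with a floor.

    lambda = max(input_count * ip_total / input_total, lam_floor). The floor
    keeps zero-input windows from producing a degenerate zero expectation.
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    return np.maximum(np.asarray(input_count, dtype=float) * ip_total / input_total, lam_floor)


def poisson_upper_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam).

    Equals 1 for k = 0 (the whole support) and 0 for k > 0 when lam = 0.
    Accepts scalars or arrays.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    p = stats.poisson.sf(k_arr - 1, np.asarray(lam, dtype=float))
    return float(p) if np.isscalar(k) or k_arr.ndim == 0 else p


def flag_windows(stats_list: Sequence[WindowStats], alpha: float = DEFAULT_ALPHA) -> None:
    """Set per-window significance and neighbour-qualification flags in place.

    A window is significant when its P-value is strictly below ``alpha``;
    it qualifies when it and both immediate neighbours are significant.
    Terminal windows of a chromosome lack a neighbour and never qualify.
    """
    for ws in stats_list:
        sig = ws.pval < alpha
        qual = np.zeros_like(sig)
        if len(sig) >= 3:
            qual[1:-1] = sig[:-2] & sig[1:-1] & sig[2:]
        ws.significant = sig
        ws.qualifying = qual


def merge_peaks(stats_list: Sequence[WindowStats]) -> list[Peak]:
    """Assemble peaks from flagged windows.

    Each maximal run of consecutive significant windows containing at least
    one qualifying window becomes one peak spanning the whole run; runs with
    no qualifying window are discarded. The summit is the midpoint of the
    run's highest-IP-count window.
    """
    peaks: list[Peak] = []
    for ws in stats_list:
        sig = ws.significant
        n = len(sig)
        i = 0
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if ws.qualifying[i : j + 1].any():
                start = ws.window_interval(i).start
                end = ws.window_interval(j).end
                run = slice(i, j + 1)
                best = i + int(np.argmax(ws.ip_count[run]))
                summit_iv = ws.window_interval(best)
                peaks.append(
                    Peak(
                        interval=GenomicInterval(ws.chrom, start, end),
                        n_windows=j - i + 1,
                        min_pval=float(ws.pval[run].min()),
                        summit=(summit_iv.start + summit_iv.end) // 2,
                    )
                )
            i = j + 1
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def call_peaks(
    ip_reads: Sequence[AlignedRead],
    input_reads: Sequence[AlignedRead],
    chrom_sizes: Mapping[str, int],
    config: PeakCallerConfig | None = None,
) -> tuple[list[Peak], list[WindowStats]]:
    """Run the full caller: dedup, extend, count, normalize, test, flag, merge.

    ``chrom_sizes`` may be a plain chrom -> length mapping or any object
    with a ``chrom_sizes`` attribute (e.g. a :class:`~bcellkit.synth.ToyGenome`).
    Returns the called peaks and the per-chromosome window statistics (for
    bedGraph export of -log10 P tracks). Raises :class:`EmptyLibraryError`
    naming the offending library if either input is empty.
    """
    chrom_sizes = getattr(chrom_sizes, "chrom_sizes", chrom_sizes)
    cfg = config or PeakCallerConfig()
    if not ip_reads:
        raise EmptyLibraryError("IP library is empty")
    if not input_reads:
        raise EmptyLibraryError("input library is empty")

    if cfg.dedup:
        ip_reads = dedupe_reads(ip_reads, stranded=cfg.dedup_key_stranded)
        input_reads = dedupe_reads(input_reads, stranded=cfg.dedup_key_stranded)

    def fragments(reads):
        return [
            extend_read(r, cfg.ext, chrom_length=chrom_sizes[r.chrom], mode=cfg.extend_mode)
            for r in reads
        ]

    ip_counts = count_windows(fragments(ip_reads), chrom_sizes, cfg.window)
    in_counts = count_windows(fragments(input_reads), chrom_sizes, cfg.window)
    ip_total = len(ip_reads)
    input_total = len(input_reads)

    if cfg.lam_floor == "auto":
        n_windows = sum(len(v) for v in in_counts.values())
        scaled_sum = sum(float(v.sum()) for v in in_counts.values()) * ip_total / input_total
        lam_floor = scaled_sum / n_windows if n_windows else 0.0
    else:
        lam_floor = float(cfg.lam_floor)

    stats_list = []
    for chrom in sorted(chrom_sizes):
        ipc = ip_counts[chrom]
        inc = in_counts[chrom]
        lam = normalize_input(ip_total, input_total, inc, lam_floor)
        pval = poisson_upper_tail(ipc, lam)
        stats_list.append(
            WindowStats(
                chrom=chrom,
                window=cfg.window,
                chrom_length=chrom_sizes[chrom],
                ip_count=ipc,
                input_count=inc,
                lam=np.asarray(lam, dtype=float),
                pval=np.asarray(pval, dtype=float),
            )
        )
    flag_windows(stats_list, cfg.alpha)
    return merge_peaks(stats_list), stats_list
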