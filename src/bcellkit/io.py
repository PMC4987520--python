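"""Readers and writers for the plain-text interchange formats.

BED is the native interchange format; SAM is accepted read-only (and can be
written for simulated libraries). All genomic coordinates are 0-based
half-open internally; SAM's 1-based POS is converted at the boundary. TSV
files carry a header row and no quoting dialect: a tab inside a field is an
error.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import TSS, GenomicInterval
from .peaks import AlignedRead, Peak, WindowStats

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed record in an input file."""


# ---------------------------------------------------------------- alignments


def read_alignments(
    path: str | Path,
    fmt: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[AlignedRead]:
    """Read aligned reads from SAM/BAM or 6-column BED.

    Format is inferred from the extension unless given. Unmapped and
    zero-length records are dropped with a logged count. With
    ``chrom_sizes``, records on unknown chromosomes raise a
    :class:`FormatError` listing the offenders.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() in (".sam", ".bam") else "bed"
    if fmt == "sam":
        reads, dropped = _read_sam(path)
    elif fmt == "bed":
        reads, dropped = _read_bed_alignments(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if dropped:
        logger.info("%s: dropped %d unmapped/zero-length records", path, dropped)
    if chrom_sizes is not None:
        unknown = sorted({r.chrom for r in reads} - set(chrom_sizes))
        if unknown:
            raise FormatError(f"{path}: unknown chromosomes {unknown}")
    return reads


def _read_sam(path: Path) -> tuple[list[AlignedRead], int]:
    reads: list[AlignedRead] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_length == 0 and aln.infer_query_length() is None:
                dropped += 1
                continue
            length = aln.query_alignment_length or aln.infer_query_length() or 0
            if length <= 0:
                dropped += 1
                continue
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    pos=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    length=length,
                )
            )
    return reads, dropped


def _read_bed_alignments(path: Path) -> tuple[list[AlignedRead], int]:
    reads: list[AlignedRead] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                chrom, start, end, _, _, strand = fields[:6]
                start, end = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                dropped += 1
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            reads.append(AlignedRead(chrom, start, strand, end - start))
    return reads, dropped


def write_alignments_bed(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """Write reads as 6-column BED (name=read index, score=0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + r.length}\tread{i + 1}\t0\t{r.strand}\n")


def write_alignments_sam(
    reads: Sequence[AlignedRead], chrom_sizes: Mapping[str, int], path: str | Path
) -> None:
    """Write reads as a minimal mapped-only SAM with @SQ headers."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i + 1}"
            a.reference_id = tids[r.chrom]
            a.reference_start = r.pos
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 60
            a.cigarstring = f"{r.length}M"
            a.query_sequence = "N" * r.length
            fh.write(a)


# ------------------------------------------------------------------- genome


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                chrom, length = line.split()
                sizes[chrom] = int(length)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sizes


def write_tss_bed(tss: Sequence[TSS], path: str | Path) -> None:
    """Write TSSs as BED6 (1-bp intervals, name=gene_id)."""
    with open(path, "w") as fh:
        for t in tss:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t{t.gene_id}\t0\t{t.strand}\n")


def read_tss_bed(path: str | Path) -> list[TSS]:
    out: list[TSS] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            out.append(TSS(f[0], int(f[1]), f[5], f[3]))
    return out


# ---------------------------------------------------------- intervals / peaks


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write plain intervals as BED (3 or 6 columns depending on strand)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion{i + 1}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write called peaks as BED6: name=rank by min P, score=-10*log10(minP) capped at 1000."""
    ranked = sorted(peaks, key=lambda p: p.min_pval)
    rank = {id(p): i + 1 for i, p in enumerate(ranked)}
    with open(path, "w") as fh:
        for p in peaks:
            if p.min_pval <= 0:
                score = 1000
            else:
                score = int(min(1000, -10 * np.log10(p.min_pval)))
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak{rank[id(p)]}\t{score}\t.\n"
            )


def write_bedgraph(stats_list: Sequence[WindowStats], path: str | Path) -> None:
    """Write per-window -log10 P as sorted, non-overlapping bedGraph."""
    with open(path, "w") as fh:
        for ws in sorted(stats_list, key=lambda w: w.chrom):
            with np.errstate(divide="ignore"):
                score = -np.log10(ws.pval)
            for i in range(ws.n_windows):
                iv = ws.window_interval(i)
                v = score[i] if np.isfinite(score[i]) else 1000.0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.4f}\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a fixed-step bedGraph back into per-chromosome vectors.

    Assumes equal-width, non-overlapping, sorted steps per chromosome (the
    shape :func:`write_bedgraph` emits); returns one value per step.
    """
    vals: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, _s, _e, v = line.split("\t")
            vals.setdefault(chrom, []).append(float(v))
    return {c: np.asarray(v) for c, v in vals.items()}


# --------------------------------------------------------------------- TSV


def write_tsv(table: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV with optional '#' comment header lines.

    No quoting dialect: a tab inside a field is an error.
    """
    for col in table.columns:
        if table[col].dtype == object and table[col].astype(str).str.contains("\t").any():
            raise ValueError(f"column {col!r} contains a tab; TSV has no quoting dialect")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
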