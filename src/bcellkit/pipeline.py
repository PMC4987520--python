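"""End-to-end workflows tying the stages together.

Three workflows are provided: ``simulate`` writes a complete synthetic data
set (genome, ChIP IP/input libraries with spiked regions, two-condition
ATAC libraries with known differential regions, assay tables) with truth
sidecars; ``chip`` runs peak calling, TSS-distance classification, gene
association and a summit-anchored metaprofile; ``atac`` runs universe
construction, fragment counting, the differential-accessibility rule and
Venn overlap counts. Every run writes its resolved configuration next to
its outputs and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, diffacc, io, peaks, synth
from .intervals import (
    GenomicInterval,
    classify_tss_distance,
    assign_genes,
    metaprofile,
    overlap_counts,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Serializable description of one workflow run.

    ``params`` holds the stage parameters (window, ext, alpha, lam_floor,
    min_ratio, max_p, flank, n_bins, ...); ``inputs`` maps input roles to
    file paths. The resolved config is written as ``config.json`` next to
    the outputs, so any run is reproducible from its artifacts alone.
    """

    subcommand: str
    out_dir: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, path: Path) -> None:
        path.write_text(self.to_json() + "\n")


_SIM_DEFAULTS = dict(
    n_chrom=1,
    chrom_length=100_000,
    n_genes=20,
    n_spikes=10,
    spike_width=500,
    enrichment=20.0,
    depth=200_000,
    read_length=50,
    atac_shared=20,
    atac_only_a=10,
    atac_enrichment=10.0,
    atac_depth=100_000,
)


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a full synthetic data set with truth sidecars."""
    p = {**_SIM_DEFAULTS, **config.params}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    genome = synth.make_toy_genome(
        int(p["n_chrom"]), int(p["chrom_length"]), int(p["n_genes"]), seed
    )
    rng = np.random.default_rng(seed + 1)
    chrom = list(genome.chrom_sizes)[0]
    clen = genome.chrom_sizes[chrom]

    def sample_regions(n: int, width: int, forbidden: list[GenomicInterval]) -> list[GenomicInterval]:
        regions: list[GenomicInterval] = []
        taken = list(forbidden)
        tries = 0
        while len(regions) < n and tries < 10_000:
            tries += 1
            start = int(rng.integers(0, clen - width))
            cand = GenomicInterval(chrom, start, start + width)
            if all(not cand.overlaps(t) for t in taken):
                regions.append(cand)
                taken.append(cand)
        if len(regions) < n:
            raise PipelineError("simulate: could not place non-overlapping regions")
        return sorted(regions, key=lambda r: r.start)

    # --- ChIP libraries with spiked regions
    spikes = sample_regions(int(p["n_spikes"]), int(p["spike_width"]), [])
    design = synth.SpikeDesign(
        regions=tuple(spikes),
        enrichment=tuple([float(p["enrichment"])] * len(spikes)),
        depth=int(p["depth"]),
        read_length=int(p["read_length"]),
    )
    ip = synth.simulate_chip_library(genome, design, is_input=False, seed=seed + 2)
    inp = synth.simulate_chip_library(genome, design, is_input=True, seed=seed + 3)

    # --- two-condition ATAC libraries: shared accessible regions plus
    # A-only regions, which are the ground-truth differential set
    shared = sample_regions(int(p["atac_shared"]), 500, spikes)
    only_a = sample_regions(int(p["atac_only_a"]), 500, spikes + shared)
    enr = float(p["atac_enrichment"])
    design_a = synth.SpikeDesign(
        regions=tuple(sorted(shared + only_a, key=lambda r: r.start)),
        enrichment=tuple([enr] * (len(shared) + len(only_a))),
        depth=int(p["atac_depth"]),
        read_length=int(p["read_length"]),
    )
    design_b = synth.SpikeDesign(
        regions=tuple(shared),
        enrichment=tuple([enr] * len(shared)),
        depth=int(p["atac_depth"]),
        read_length=int(p["read_length"]),
    )
    atac_a = synth.simulate_chip_library(genome, design_a, is_input=False, seed=seed + 4)
    atac_b = synth.simulate_chip_library(genome, design_b, is_input=False, seed=seed + 5)

    artifacts: dict[str, Path] = {}

    def emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        artifacts[name] = path

    emit("genome.chrom.sizes", io.write_chrom_sizes, genome.chrom_sizes)
    emit("tss.bed", io.write_tss_bed, genome.tss)
    emit("chip_ip.bed", io.write_alignments_bed, ip)
    emit("chip_input.bed", io.write_alignments_bed, inp)
    emit("chip_ip.sam", lambda r, path: io.write_alignments_sam(r, genome.chrom_sizes, path), ip)
    emit("chip_spikes.bed", io.write_bed, spikes)
    emit("atac_a.bed", io.write_alignments_bed, atac_a)
    emit("atac_b.bed", io.write_alignments_bed, atac_b)
    emit("atac_peaks_a.bed", io.write_bed, sorted(shared + only_a, key=lambda r: r.start))
    emit("atac_peaks_b.bed", io.write_bed, shared)

    truth = pd.DataFrame(
        [(r.chrom, r.start, r.end, "A_only") for r in only_a]
        + [(r.chrom, r.start, r.end, "shared") for r in shared],
        columns=["chrom", "start", "end", "label"],
    ).sort_values(["chrom", "start"], kind="stable")
    emit("atac_truth.tsv", io.write_tsv, truth)

    config.write(out / "config.json")
    artifacts["config.json"] = out / "config.json"
    return artifacts


def run_chip(config: RunConfig) -> dict[str, Path]:
    """Peak calling, TSS classification, gene association, metaprofile."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    try:
        chrom_sizes = io.read_chrom_sizes(config.inputs["genome"])
        ip = io.read_alignments(config.inputs["ip"], chrom_sizes=chrom_sizes)
        inp = io.read_alignments(config.inputs["input"], chrom_sizes=chrom_sizes)
        tss = io.read_tss_bed(config.inputs["tss"]) if "tss" in config.inputs else []
    except (OSError, KeyError, ValueError) as exc:
        raise PipelineError(f"chip/load: {exc}") from exc

    cfg = peaks.PeakCallerConfig(
        window=int(p.get("window", 50)),
        ext=int(p.get("ext", 150)),
        alpha=float(p.get("alpha", 1e-3)),
        lam_floor=p.get("lam_floor", "auto"),
    )
    try:
        called, stats_list = peaks.call_peaks(ip, inp, chrom_sizes, cfg)
    except Exception as exc:
        raise PipelineError(f"chip/callpeaks: {exc}") from exc

    io.write_peaks_bed(called, out / "peaks.bed")
    io.write_bedgraph(stats_list, out / "windows.bedgraph")

    rows = []
    gene_map = assign_genes(
        [pk.interval for pk in called], tss, chrom_sizes,
        basal_up=int(p.get("basal_up", 5000)),
        basal_down=int(p.get("basal_down", 1000)),
        max_ext=int(p.get("max_ext", 1_000_000)),
    ) if tss else {}
    for i, pk in enumerate(called):
        cls = classify_tss_distance(pk.interval, tss) if tss else None
        rows.append(
            dict(
                chrom=pk.interval.chrom,
                start=pk.interval.start,
                end=pk.interval.end,
                n_windows=pk.n_windows,
                min_pval=pk.min_pval,
                summit=pk.summit,
                tss_class=cls.label if cls else "NA",
                tss_distance=cls.distance if cls and cls.distance is not None else "NA",
                genes=",".join(gene_map.get(i, [])) or "NA",
            )
        )
    io.write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "n_windows", "min_pval",
                "summit", "tss_class", "tss_distance", "genes",
            ],
        ),
        out / "peaks_annotated.tsv",
        header_comments=[
            f"alpha={cfg.alpha} window={cfg.window} ext={cfg.ext} lam_floor={cfg.lam_floor}",
            "coordinates are 0-based half-open",
        ],
    )

    # summit-anchored metaprofile of IP window counts
    flank = int(p.get("flank", 2000))
    n_bins = int(p.get("n_bins", 100))
    signal = {ws.chrom: ws.ip_count.astype(float) for ws in stats_list}
    anchors = [(pk.interval.chrom, pk.summit) for pk in called]
    usable = [
        (c, s)
        for c, s in anchors
        if s - flank >= 0 and s + flank <= chrom_sizes[c]
    ]
    if usable:
        prof = metaprofile(signal, usable, flank=flank, n_bins=n_bins, resolution=cfg.window)
        bin_bp = 2 * flank // n_bins
        offsets = -flank + bin_bp // 2 + bin_bp * np.arange(n_bins)
        io.write_tsv(
            pd.DataFrame({"bin_center_offset": offsets, "mean_signal": prof}),
            out / "metaprofile.tsv",
            header_comments=[f"flank={flank} n_bins={n_bins} anchors={len(usable)}"],
        )
    else:
        io.write_tsv(
            pd.DataFrame(columns=["bin_center_offset", "mean_signal"]),
            out / "metaprofile.tsv",
            header_comments=["no usable anchors"],
        )

    config.write(out / "config.json")
    return {
        name: out / name
        for name in ["peaks.bed", "windows.bedgraph", "peaks_annotated.tsv",
                     "metaprofile.tsv", "config.json"]
    }


def run_atac(config: RunConfig) -> dict[str, Path]:
    """Universe construction, counting, the differential rule, Venn counts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    try:
        peaks_a = io.read_bed(config.inputs["peaks_a"])
        peaks_b = io.read_bed(config.inputs["peaks_b"])
        reads_a = [io.read_bed(f) for f in _aslist(config.inputs["reads_a"])]
        reads_b = [io.read_bed(f) for f in _aslist(config.inputs["reads_b"])]
    except (OSError, KeyError, ValueError) as exc:
        raise PipelineError(f"atac/load: {exc}") from exc

    universe = diffacc.build_universe(peaks_a, peaks_b)
    frag_libs = {f"A_rep{i + 1}": frags for i, frags in enumerate(reads_a)}
    frag_libs.update({f"B_rep{i + 1}": frags for i, frags in enumerate(reads_b)})
    conditions = {name: name[0] for name in frag_libs}
    matrix = diffacc.count_fragments(universe, frag_libs, conditions)
    calls = diffacc.classify_differential(
        matrix,
        min_ratio=float(p.get("min_ratio", 4.0)),
        max_p=float(p.get("max_p", 0.01)),
        pseudocount=float(p.get("pseudocount", 1.0)),
    )

    io.write_bed(universe, out / "universe.bed")
    table = pd.DataFrame(
        [
            dict(
                chrom=c.region.chrom, start=c.region.start, end=c.region.end,
                ratio=round(c.ratio, 6), pval=c.pval, direction=c.direction,
            )
            for c in calls
        ],
        columns=["chrom", "start", "end", "ratio", "pval", "direction"],
    )
    io.write_tsv(
        table, out / "differential.tsv",
        header_comments=[
            f"min_ratio={p.get('min_ratio', 4.0)} max_p={p.get('max_p', 0.01)} "
            f"pseudocount={p.get('pseudocount', 1.0)}",
        ],
    )
    for cond in ("A", "B"):
        io.write_bed(
            [c.region for c in calls if c.direction == cond],
            out / f"differential_{cond}.bed",
        )

    venn = overlap_counts({"A": peaks_a, "B": peaks_b})
    io.write_tsv(
        pd.DataFrame(
            [("+".join(k), v) for k, v in sorted(venn.items())],
            columns=["membership", "count"],
        ),
        out / "venn.tsv",
    )
    config.write(out / "config.json")
    return {
        name: out / name
        for name in ["universe.bed", "differential.tsv", "differential_A.bed",
                     "differential_B.bed", "venn.tsv", "config.json"]
    }


def _aslist(x) -> list:
    return x if isinstance(x, list) else [x]


_RUNNERS = {"simulate": run_simulate, "chip": run_chip, "atac": run_atac}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Dispatch a workflow by its subcommand name."""
    try:
        runner = _RUNNERS[config.subcommand]
    except KeyError:
        raise PipelineError(f"unknown subcommand {config.subcommand!r}") from None
    return runner(config)
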