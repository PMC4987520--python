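# bcellkit

Analysis toolkit for regulatory genomics of B-lymphoid cells: a
window-based Poisson ChIP-seq peak caller, genomic-interval annotation
(TSS-distance classes, regulatory-domain gene association, overlap Venn
counts, signal metaprofiles), a two-condition differential chromatin
accessibility test, and the statistics used for common B-cell bench assays
(Ig V(D)J rearrangement frequency by qPCR, relative expression, comet-assay
outlier calling, γH2AX focus scoring, blood lineage counts). A
synthetic-data module generates every input with known ground truth, so the
whole pipeline is testable end to end without external downloads.

## Who it is for

Groups studying transcription-factor binding and chromatin accessibility in
lymphoid progenitors who want a small, transparent, fully deterministic
implementation of the classic windowed enrichment test — and of the simple,
auditable decision rules used in bench assays — rather than a large general
peak-calling framework.

## The statistics at the core

**Peak calling.** Reads are deduplicated per (chrom, position, strand),
extended to 150-bp fragments in their 3′ direction, and counted in 50-bp
windows tiled over the genome. Input counts are scaled to the IP library
size, giving a per-window expectation λ, and each window's IP count *k* is
tested with the Poisson upper tail

&nbsp;&nbsp;&nbsp;&nbsp;P = P(X ≥ k),&nbsp; X ~ Poisson(λ).

A window is significant when P < 10⁻³ and *qualifies* when both of its
neighbouring windows are significant too; maximal runs of significant
windows containing a qualifying window become peaks.

**Differential accessibility.** Over the merged universe of two peak sets,
a region is differentially accessible when one condition has at least four
times more normalized reads than the other *and* the Poisson upper-tail
probability of the larger count given the smaller as expectation is ≤ 0.01
(both thresholds inclusive).

**Bench assays.** Ig rearrangement frequency = 2^ΔCt with
ΔCt = Ct(Actb) − Ct(Ig); comet outliers are cells whose tail moment deviates
from the sample median by ≥ 3 (unscaled) median absolute deviations; γH2AX
scoring calls a cell positive at ≥ 4 foci; lineage counts multiply the
CBC white-cell concentration by flow-cytometry lineage fractions.

## Worked example

```python
from bcellkit import (
    GenomicInterval, SpikeDesign, make_toy_genome,
    simulate_chip_library, call_peaks, classify_tss_distance,
    rearrangement_frequency, mad_outlier_classify,
)

genome = make_toy_genome(n_chrom=1, chrom_length=100_000, n_genes=20, seed=11)
spike = GenomicInterval("chr1", 40_000, 40_500)
design = SpikeDesign(regions=(spike,), enrichment=(20.0,), depth=200_000)
ip = simulate_chip_library(genome, design, is_input=False, seed=1)
inp = simulate_chip_library(genome, design, is_input=True, seed=2)

peaks, stats = call_peaks(ip, inp, genome.chrom_sizes)
for pk in peaks:
    cls = classify_tss_distance(pk.interval, genome.tss)
    print(f"{pk.interval.chrom}:{pk.interval.start}-{pk.interval.end}  "
          f"windows={pk.n_windows}  min_p={pk.min_pval:.3g}  "
          f"{cls.label} ({cls.distance} bp to nearest TSS)")

print("Ig freq:", rearrangement_frequency(ct_actb=20.0, ct_ig=22.0))
res = mad_outlier_classify([2, 3, 3, 4, 20])
print("comet outliers:", res.flags.tolist(), "fraction:", res.outlier_fraction)
```

prints

```
chr1:40100-40450  windows=7  min_p=3.13e-21  proximal (4098 bp to nearest TSS)
Ig freq: 0.25
comet outliers: [False, False, False, False, True] fraction: 0.2
```

The single 500-bp region spiked at 20-fold enrichment is recovered as one
peak (position-level duplicate removal saturates the densest windows, which
trims the peak slightly inside the spike). A Ct difference of +2 cycles
between the Ig and Actb amplicons means one quarter of alleles rearranged,
and the damaged cell with tail moment 20 is the only MAD outlier.

The same workflows are available from the shell:

```sh
bcellkit simulate --out-dir sim --seed 4
bcellkit callpeaks --ip sim/chip_ip.bed --input sim/chip_input.bed \
    --genome sim/genome.chrom.sizes --tss sim/tss.bed --out-dir chip
bcellkit diffacc --peaks-a sim/atac_peaks_a.bed --peaks-b sim/atac_peaks_b.bed \
    --reads-a sim/atac_a.bed --reads-b sim/atac_b.bed --out-dir atac
```

Every run writes its resolved configuration (`config.json`) next to its
outputs; reruns with the same configuration are byte-identical.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
decisions, and the limits of what the synthetic benchmarks demonstrate.
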