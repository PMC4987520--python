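# Methods

## Window/Poisson peak caller

The caller implements the classic fixed-window enrichment test. Stages, in
order:

1. **Duplicate removal.** Reads sharing (chromosome, leftmost position,
   strand) are collapsed to one, suppressing clonal PCR amplification. The
   strand-aware key is the standard choice; a strand-blind key is available
   (`dedup_key_stranded=False`). With fixed-length single-end reads the two
   differ only for exactly antisense read pairs.
2. **Fragment extension.** Sequenced reads are the 5′ ends of longer
   immunoprecipitated fragments. Each read is replaced by a 150-bp interval
   starting at its 5′ end and running in the 3′ direction (default
   `extend_mode="fragment"`): `[pos, pos+ext)` on the plus strand and
   `[pos+length-ext, pos+length)` on the minus strand, clipped to the
   chromosome. The alternative reading — keep the read body and append
   `ext` extra 3′ bases — is available as `extend_mode="length_plus"`;
   the fragment interpretation is the default because extension-to-fragment
   size is the usual intent of a fixed 150-bp extension for ~50-bp reads.
3. **Window counting.** The genome is tiled in 50-bp windows
   (`[i·w, (i+1)·w)`; the terminal window may be shorter). A fragment
   increments every window it overlaps by ≥ 1 bp (binary overlap, not
   fractional assignment). Counting is done with a difference-array cumsum,
   O(reads + windows).
4. **Input normalization.** λᵢ = max(inputᵢ · N_IP / N_input, λ_floor),
   where N are the post-dedup library sizes. The floor (default: the
   genome-wide mean scaled input count per window) prevents the degenerate
   λ = 0, under which a single stray IP read would be infinitely
   significant. The floor is configurable (`lam_floor`), and the value in
   force is echoed in output headers.
5. **Poisson test.** P = P(X ≥ k | λ) via `scipy.stats.poisson.sf(k-1, λ)`.
   By convention P = 1 at k = 0 and P = 0 when λ = 0 and k > 0.
6. **Flagging.** Significant ⇔ P strictly < α (default 10⁻³; ties at
   exactly α are non-significant). Qualifying ⇔ the window and both
   immediate neighbours are significant; terminal windows of a chromosome
   lack a neighbour and never qualify.
7. **Peak assembly.** Each maximal run of consecutive significant windows
   containing at least one qualifying window becomes one peak spanning the
   whole run. Spanning the full run (rather than only its qualifying
   interior) is deliberate: the neighbour rule marks run interiors, and
   trimming to interiors would discard the flanking windows the rule itself
   requires to be significant. Runs of length ≤ 2 can never contain a
   qualifying window and yield no peak. The summit is the midpoint of the
   run's highest-IP-count window.

The caller is a pure function of its inputs — no randomness anywhere.
Replicate libraries are pooled by concatenation before dedup; per-replicate
calling is out of scope.

## Interval annotation

Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared
base pair (abutting intervals do not overlap). `intersect`,
`merge_intervals` and `overlap_counts` are plain sorted-sweep
implementations, each validated against per-base brute-force oracles in the
test suite.

**TSS-distance classes.** Distance is measured from the peak *midpoint* to
the nearest TSS (the midpoint is chosen for symmetry; edge-based distance
is not offered in v1). Boundaries are inclusive: ≤ 5 kb proximal
(promoter-like), ≤ 500 kb distal (enhancer-like), beyond that far. The
three classes partition any peak set.

**Gene association** uses a basal-plus-extension regulatory-domain rule,
a local approximation of the association step of web-based region-to-gene
tools (their enrichment statistics are not reproduced here). Each gene owns
a strand-aware basal domain (default 5 kb upstream, 1 kb downstream of its
TSS), extended on each side up to 1 Mb from the TSS but never past the
midpoint of the gap to the nearest neighbouring basal domain — so extended
domains of neighbouring genes never overlap and an intergenic peak is
credited to the gene whose basal domain is nearer, while overlapping
*basal* domains (genes very close together) still produce multi-gene
assignments. A peak is assigned to every gene whose domain contains its
midpoint.

**Metaprofiles** average a coverage track in `n_bins` equal bins over
`[center − flank, center + flank)` around each anchor. Tracks may be per-bp
or per-window (`resolution` bp per element). Anchors truncated by a
chromosome edge are dropped with a logged count. Defaults flank = 2 kb,
100 bins are package choices exposed as parameters, not assertions about
any particular dataset. The profile is linear in the signal and invariant
to anchor order.

## Differential accessibility

The two-condition rule operates on a merged, disjoint region universe
(union of both peak sets). Replicate libraries are summed within condition;
condition totals are brought to a common scale by total-count
normalization (each condition's summed counts are rescaled to the mean
condition total). Per region, with normalized totals x_A and x_B:

- ratio = (max + pseudocount) / (min + pseudocount), pseudocount default 1
  to stabilize ratios at low counts;
- P = Poisson upper tail of round(max) given min as expectation;
- differential ⇔ ratio ≥ 4 **and** P ≤ 0.01, both inclusive.

This reproduces the stated decision rule with a simple, fully documented
normalization; it is not a reimplementation of M-A robust-regression
normalization, and genome-scale results on real libraries can differ from
tools that use it. Swapping condition labels swaps call directions and
leaves the differential set unchanged.

## Bench-assay statistics

- **Rearrangement frequency**: 2^(Ct_Actb − Ct_Ig). The reference gene
  amplifies from every genome while the Ig amplicon requires the
  rearranged allele, so the cycle offset measures the rearranged fraction.
- **Relative expression**: 2^(Ct_Actb − Ct_gene) (ΔCt form).
  Normalization to a control group (`normalize_to_control`, control mean
  mapped to exactly 1.0) is kept separable, so the ΔΔCt quantity is the
  composition of the two.
- **Comet outliers**: flag cells with |x − median| ≥ 3 · MAD, MAD unscaled
  (no 1.4826 consistency factor). Degenerate case: when MAD = 0 the
  literal rule would flag every cell, so only cells with any nonzero
  deviation are flagged — preserving the rule's intent of marking
  departures from a tight distribution. At least 3 cells are required.
- **Focus scoring**: positive at ≥ 4 foci per cell; the per-sample
  positive fraction uses all scored cells as denominator, and samples
  with < 50 scored cells trigger a warning.
- **Lineage counts**: WBC/µL × lineage fraction.
- Group summaries report mean, s.d. and s.e.m. per group.

## Synthetic data

The generators produce exactly the inputs the pipeline consumes, with
ground truth carried separately (sidecar TSV, never encoded in BED names).
All are pure functions of their arguments including the seed.

- **Read libraries** follow a piecewise-homogeneous Poisson model — the
  same null the caller tests. Background read starts are uniform over the
  genome; each spiked region of an IP library receives extra reads whose
  start density equals (fold-enrichment − 1) × background. The extra reads
  are the 5′ ends of 150-bp fragments confined to the region (plus-strand
  reads at the fragment's left end, minus-strand reads at its right end),
  mimicking immunoprecipitated fragments around a binding site; the
  fragment size is a parameter, as no single value is canonical. When
  `depth` is set, rates are rescaled so the expected total read count
  equals `depth`. Read length defaults to 50 bp (typical single-end short
  reads) and is configurable. The model omits mappability gaps, GC bias,
  chromatin-dependent background and fragment-length dispersion, so
  passing benchmarks demonstrate algorithmic correctness and calibration
  under the caller's own null — not performance on real libraries.
- **ATAC count matrices** draw Poisson counts at `base_mean` per region and
  condition, with labelled differential regions at `fold × base_mean` in
  condition A. Defaults in the validation runs: 200 regions, 20
  differential, fold 8, base mean 200 — a regime where the ≥ 4-fold /
  P ≤ 0.01 rule should operate at high sensitivity and near-zero
  false-positive rate.
- **Ct tables** invert the frequency formula (Ct_Ig = Ct_Actb − log₂ f,
  plus optional Gaussian cycle noise), so the noise-free round trip through
  `rearrangement_frequency` is the identity, and the log2-frequency error
  under noise equals the injected cycle noise.
- **Tail moments**: non-outliers from a tight truncated normal at
  `base_scale` (CV 0.15, emulating undamaged nuclei), an exact count
  `round(n · outlier_frac)` of cells shifted up by `outlier_shift`.

## Problem sizes in the validation runs

The validation suite and `scripts/acceptance.py` use 100-kb toy genomes
(10-kb chromosomes for the per-base interval oracles), libraries of
10⁴–2×10⁵ reads, 10–20 random replicates per property, 1,000 qPCR samples
and 500-cell comet samples — sizes at which the brute-force oracles remain
exact and the full run completes in well under a minute per property,
while every statistical property under test (calibration, recovery,
agreement) is measured with comfortable margins.

## Known limitations

- The peak caller has no broad-peak mode, no paired-end fragment
  inference, and no mappability or blacklist handling.
- Differential accessibility uses total-count scaling; strongly asymmetric
  signal distributions between conditions can bias the scale factor (the
  usual argument for M-A-based normalization).
- The gene-association rule is a local approximation of basal-plus-
  extension association; no GO/pathway enrichment is provided.
- TSV I/O has no quoting dialect: fields must not contain tabs.
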