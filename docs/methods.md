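# Methods

## Scope and data model

`nucshift` analyzes matched nucleosome-occupancy and strand-specific
expression measurements of a mutant (or treatment) condition against
wild-type references. All internal coordinates are 1-based, fully closed;
BED/bedGraph/BEDPE output converts to 0-based half-open at the I/O boundary
only. Genes carry a curated TSS and TES; on the '-' strand TSS > TES in
chromosome coordinates, and every strand-aware rule (NDR windows, genic
numbering, shift signs, transfrag 5′ ends) reflects through that convention.

## Synthetic genomes (`synthio`)

The generator reproduces the stereotyped chromatin organization of budding
yeast genes: a nucleosome-depleted region (NDR) of 200 bp directly upstream of
the TSS, then a phased array of 147-bp cores separated by 18-bp linkers
(165-bp repeat). The +1 center is placed ⌈147/2⌉ = 74 bp downstream of the
TSS and subsequent centers every 165 bp while the full core fits inside the
gene body. Gene lengths and intergenic gaps are drawn around their means
(sd 15 % and 20 %); gaps never fall below the NDR width plus a 60-bp margin so
promoters stay intergenic. Strands are random by default; a `strands` cycle
pins promoter configurations (e.g. `("-", "+", "+")` alternates diverging and
tandem promoters) for signature tests.

**Occupancy.** Each nucleosome deposits a triangular kernel of half-width
73.5 bp (unit height), approximating MNase protection of a 147-bp core. The
expected linear probe intensity is a small background (0.1) plus the
depletion-scaled kernel sum; planted interval scale factors multiply the total
linear signal position-wise, which makes a factor f change the local log₂
signal by exactly log₂ f and keeps scaling monotone per probe. Probe noise is
multiplicative lognormal — intensity × 2^N(0, σ) — i.e. iid additive Gaussian
on the log₂ scale per probe and replicate; σ defaults to 0.2 log₂ units, a
convention (the source arrays publish no noise magnitude). A flat genomic-DNA
control column with the same noise model accompanies every occupancy matrix.

**Expression.** Genes contribute a constant intensity (400 over a background
of 50) on their own strand in both channels; planted cryptic transcripts
multiply the treatment channel by their fold change on their interval and
strand only. Planted-signature scenarios give each cryptic locus an NDR-like
occupancy drop straddling its start (250 bp upstream through 50 bp inside), so
the upstream occupancy rule is tested against a genuine promoter-scale dip
rather than against boundary jitter of the detected 5′ end.

**Read pairs.** Fragments are drawn per true nucleosome (Poisson mean =
`depth`), midpoint = center + discretized Gaussian jitter (sd 10 bp), length
147 bp, sorted output. The fragment midpoint estimates the nucleosome center.

What the generator does **not** emulate: sequence (no FASTA, no MNase sequence
bias or intrinsic-preference landscape), probe-specific affinity/GC effects,
cross-hybridization, spatially correlated noise, transcription-dependent
occupancy gradients, and replicate-level batch effects. Passing recovery
tests therefore demonstrates the pipeline's correctness and calibration under
idealized noise, not its robustness to array artifacts.

## Preprocessing (`preprocess`)

Array chain: quantile normalization across samples → running-median smoothing
over probes within ±30 nt → linear rescaling of each sample so its 1st/99th
percentiles match the cross-sample means (robust, order-preserving
operationalization of "a common data range") → log₂ ratio over the
genomic-DNA control → baseline removal by subtracting a running median over a
5-kb window. The ordering follows the narrative quantile → smooth → rescale;
detrending acts on the log-ratio track, since the ratio is what downstream
analyses must keep drift-free. The wavelet-based baseline-removal tool used by
the original array processing is deliberately replaced by the running median
at the same 5-kb window: both remove only slow baseline variation, and the
running median is transparent and exactly testable.

Two conventions matter in practice:

* The flat gDNA control is smoothed but **excluded from quantile
  normalization** — forcing a control with a different marginal distribution
  onto the nucleosomal samples' bimodal marginal corrupts the ratio.
* The pipeline runner normalizes **within each condition group** (the mutant
  replicates together, the parallel WT control replicates together, each
  panel condition alone). Quantile-mapping a mutant against the pooled panel
  distribution compresses condition-specific occupancy changes — rare low
  intensities are rank-outliers and get pulled toward the panel's tail.

Sequencing mode converges on the same `OccupancyTrack` container by binning
rounded fragment midpoints onto the probe grid (count-conserving; malformed
pairs are skipped and counted).

## Nucleosome calling (`nuccall`)

The occupancy track is convolved with a discretized normal kernel (mean 0,
sd 25 bp) truncated at ±50 bp — read as the kernel's half-support, consistent
with ±2 sd — sampled at grid multiples including zero and renormalized to unit
sum; truncated edge windows are renormalized. Local maxima are defined on the
probe grid (strictly greater than both neighbors; plateaus take their leftmost
point). Calling is greedy: the highest remaining local maximum is accepted
whenever it lies more than 100 bp from every already-called center, ties
broken toward the leftmost coordinate; the procedure provably matches
exhaustive greedy enumeration and every output satisfies the pairwise
\>100-bp separation invariant. The 10 % of calls with the lowest Gaussian
score are flagged `retained=False`, pooled globally across chromosomes per
analysis set, with score ties at the cutoff resolved by excluding the
leftmost first so the excluded count is exactly ⌊0.1 N⌋. Retained calls
strictly downstream of a TSS and at most 100 bp past the TES are numbered
+1, +2, … by strand-aware distance; overlapping opposite-strand genes may
share a call.

On clean tracks every local maximum is a real nucleosome, so the 10 %
exclusion necessarily flags true calls — recovery guarantees are therefore
stated over all calls, while downstream analyses use retained calls only.

## Shift statistics (`shiftstats`)

Each WT call is matched to the nearest condition call within ±100 bp;
equidistant candidates resolve toward the TSS, which is conservative against
inflating away-from-TSS shifts. Δ = strand-aware signed displacement
(positive away from the TSS). A nucleosome is significantly shifted when
(i) every replicate moved ≥ 10 bp in the same direction and (ii) a two-sample
**pooled-variance Student t-test** of the replicate center positions against
the center positions observed across the WT panel gives p < 0.05. The pooled
test (df = n_rep + n_panel − 2) is used rather than a Welch test because with
two replicates the Welch degrees of freedom collapse to ≈1 and the test loses
essentially all power; the panel's ~30 degrees of freedom legitimately carry
the variance estimate, and panel sds are floored at 1 bp to guard degenerate
zero-variance panels. Records with < 2 matched replicates or < 3 panel
positions are untestable, never significant. Per-genic-index medians and
quartiles summarize a condition (indices beyond +8 are computed but excluded
from summaries; data there are sparse); a condition is flagged when any index
has |median| ≥ 4 bp. Neighbor profiles group genes by the significance status
of a focal index (positive / negative / none, genes without a significant
focal shift defaulting to none) and report mean Δ ± 1.96·se per index.

## Transfrag segmentation (`transfrag`)

Per-probe statistics pool intensities from all probes within ±30 bp across
replicates in each channel; log₂ fold change is the ratio of pooled means and
the p-value a two-sided Wilcoxon rank-sum of the pooled windows. This replaces
the black-box tiling-array software used originally: absolute p-values differ,
but the thresholded behavior is the tested contract. The exact U null
distribution is used when both pooled windows hold ≤ 40 values (so
complete-separation windows reproduce the enumeration value 2/C(n+m, n); with
ties the tie-free exact distribution is conservative), the tie-corrected
normal approximation otherwise; windows with < 3 values per group return
p = 1.

Segmentation: probes pass at |log₂fc| ≥ log₂ 2 and p ≤ 0.05; runs break at
\> 48-bp gaps between passing probes or at sign changes; a run is emitted iff
it spans ≥ 80 bp (first to last passing probe, closed) *and* holds ≥ 10
passing probes. Merging joins neighbors iff gap ≤ 250 bp, same strand, same
direction, and every intervening probe's fold-change sign matches the
direction (p unconstrained); a single left-to-right sweep reaches the fixed
point. Transfrags with > 20 % (strictly) of their length covered by the union
of same-strand annotation are removed.

Orientation classes are decided by the nearest gene whose body or boundary
lies within 3 kb of the transfrag's 5′ end, after an overriding
intragenic-antisense check for any opposite-strand overlap. With T the 5′ end,
d the transfrag direction and (Gs, Ge, e) the gene's TSS/TES/direction:
diverging iff e = −d and (T − Gs)·d ≥ 0 (5′ ends reading outward from a shared
region); converging iff e = −d and the gene lies wholly ahead of T
(head-on); tandem-sense iff e = d and (T − Ge)·e > 0. The residual
tandem-antisense rule (e = −d, 5′ end past the gene's TES) is retained at the
lowest priority, but for a non-overlapping nearest gene its geometry coincides
with the converging case, which takes precedence — the class boundary between
the two is a documented convention, not settled by the source material.

## Signatures (`signatures`)

NDRs are the 200-bp windows directly upstream of each TSS (strand-aware,
abutting but excluding the TSS; chromosome-end truncation is flagged and the
mean taken over covered positions). A TCR hit is an up-regulated transfrag
(the ≥ 2-fold / p ≤ 0.05 / ≥ 80-nt expression requirement is guaranteed by the
transfrag invariants) whose mean change in log₂ occupancy over the 200 bp
upstream of its own 5′ end is ≤ −log₂ 1.5; the window anchors at the transfrag
because TCRs are novel transcripts without a curated TSS. Hits are
subtelomeric when the 5′ end lies within 25 kb of a chromosome end (a
configurable convention), else antisense when intragenic-antisense, else
intergenic. Detection is monotone in the fold requirement. PATs are
transfrags whose 5′ end falls inside some gene's NDR window (anchoring ties
resolve to the nearer TSS); the promoter configuration is the orientation of
the nearest gene on the far side of the NDR — opposite strand = diverging,
same strand = tandem. TSS-anchored profiles average occupancy per bp offset
across genes with '-'-strand coordinate reflection; NDR ranking sorts genes by
mean NDR occupancy change (ties by gene id) and reports the Spearman
correlation with expression change (NaN when undefined).

## Pipeline and configuration (`orchestrate`)

`PipelineConfig` carries every threshold with its standard default (kernel
sd 25 bp / support 50 bp, separation 100 bp, exclusion 0.10, match window
100 bp, min shift 10 bp, α 0.05, median flag 4 bp, probe bandwidth 30 bp,
fold 2, p 0.05, 80 nt / 10 probes / 48-nt gap / 250-bp merge / 20 % overlap /
3-kb flank, NDR 200 bp, occupancy fold 1.5, profile smoothing 25 bp, baseline
window 5 kb) and round-trips losslessly through YAML. `run_pipeline` executes
preprocess → calling → shifts → transfrags → signatures on a scenario
directory and writes TSV/BED/JSON outputs plus a manifest containing the
config hash and SHA-256 checksums of every input and output; reruns on
identical inputs are bit-identical. The `nucshift` CLI is a thin wrapper over
these functions.

## Problem sizes and test design

The suite and the acceptance script run on desk-scale simulations chosen to
give stable statistics: 500 genes (~1.1 Mb) for spacing recovery; 200 genes
with 150 injected +10..+30-bp shifts and a 31-condition WT panel (matching the
study design's panel size) for shift recovery and false-positive calibration;
20 planted fold-4 transcripts on a 250-kb genome for transfrag recovery; 12
full-signature loci plus 12 single-signal decoys on a 300-kb genome for TCR
specificity. Oracles are independent implementations: brute-force
convolution, exhaustive greedy enumeration, exact rank-sum enumeration, and
hand-computed rank means.

## Known limitations

* Peak positions inherit a small systematic tilt (up to ~10 bp) near sharp
  occupancy boundaries from the 5-kb running-median detrend; genic spacing
  and shift deltas are differences and largely cancel it.
* Quantile normalization compresses signal that manifests as rank-outliers;
  the per-group normalization above mitigates but does not remove this for
  very small genomes.
* The t-test treats called center positions as independent observations;
  replicate calls share the underlying biology, so p-values are calibrated
  only under the replicate-noise model the generator implements.
* Classification handles one nearest gene; dense multi-gene neighborhoods
  fall back to the stated priority order.
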