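# Methods

This note documents the statistical models behind `cryptmeth`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the design choices made where the underlying procedure was
genuinely open.

## Differential methylation enrichment peaks (DMEPs)

**Input model.** The unit of measurement is a tiling probe inside one
promoter region (by convention −1300..+500 bp of the TSS) carrying one
log2(MeDIP/Input) value per biological replicate of each of two groups
(control, case; 3 vs 3 in the emulated design). Array normalization and
background correction are upstream of this package: it consumes log2 ratios
as given.

**Peak assembly.** Within each promoter, maximal runs of consecutive probes
whose pooled mean (over all samples of both groups) exceeds
`probe_call_threshold` (default 0.2 log2 units) become peaks; runs shorter
than `min_probes_per_peak` (default 2) are dropped; peaks never cross
promoter boundaries. The vendor software that performed this step for the
original arrays is unpublished, so assembly here is a deliberately simple,
fully parameterized run-based rule. Consequences: peak *scores* exported to
BED are |M′|·1000 (capped at 1000), not vendor-compatible "probability of
positive enrichment" scores.

**Differential filter.** Each peak is scored with
M′ = grand mean of log2 ratios over (peak probes × case replicates) minus
the same grand mean for the control group. For complete data this equals
the mean of per-sample means, so the two readings of "average" coincide.
Two criteria gate the DMEP call:

1. *Enrichment*: at least one group's median — the median over the peak's
   probes of per-probe group means (configurable to the median over all
   probe×replicate values) — is ≥ `median_min` (default 0.3), and M′ ≠ 0.
   The direction criterion is applied symmetrically with the class set by
   sign(M′): a one-sided M′ > 0 reading would forbid control-higher calls,
   yet the emulated study reports differential peaks in both directions, so
   the symmetric reading is the default and `one_sided=True` restores the
   literal one.
2. *Reproducibility*: in **both** groups, at least `cv_pass_fraction_min`
   (default 0.5) of the peak's probes have replicate CV = sd/|mean| ≤
   `cv_max` (default 0.8). CV is computed on the log2 scale by default
   (`cv_scale="linear"` transforms to 2^x first); a zero mean yields an
   infinite CV, which fails any finite threshold.

Note a structural property of this filter: it has **no magnitude threshold
on M′**. A region enriched equally in both groups still gets classified by
the sign of its noise-level M′. On real arrays the vendor's differential
peak detection evidently imposed additional structure (the study reports
1,216 differential peaks among 3,146 methylated promoters); with the
published criteria alone, every methylated peak is nominally "differential".
The synthetic recovery benchmarks therefore plant only truly differential
peaks when measuring sensitivity and false discovery.

**Summary statistics.** `summarize_dmeps` reports the class counts, the
number of promoters with at least one peak meeting the enrichment level
("methylated promoters"), and a two-sample comparison of per-sample mean
enrichment over DMEP probes. The comparison is an unpaired two-tailed
Student's t test by default — the test named by the study's statistical
methods — with Welch's form available (`equal_var=False`). At 3 vs 3
replicates this choice matters: the pooled test is exactly calibrated
(measured ≈5.1% rejection at α=0.05 over 100k simulated nulls) whereas
Welch's approximation is conservative (≈3.6%).

## Synthetic promoter array

`ArraySimSpec` defaults are the emulated study's dimensions: 22,327
promoters tiled by 180,000 probes (8–9 probes per promoter, evenly spaced
bins across the 1800-bp window), 3 replicates per group. Each probe's value
is its planted mean plus i.i.d. Gaussian noise (`probe_noise_sd`, default
0.2). Planted structure:

* `methylated_fraction` (default ≈0.086) of promoters get an
  enriched-but-equal run: both groups' means raised by
  `peak_base_enrichment` (default 0.5) over `planted_peak_probes`
  (default 4) consecutive probes;
* `dmep_fraction` (default ≈0.054) get the same base enrichment plus
  `effect_size` (default 0.6) added to one group (direction 50/50),
  so that together ≈14% of promoters are methylated and ≈5% differential,
  mirroring the study's reported proportions;
* `cv_inflation_fraction` (default 0.1) of probes get their noise sd
  multiplied by `cv_inflation_factor` (default 5), producing probes that
  clearly violate the CV criterion — the feature criterion (ii) exists to
  guard against.

The base enrichment on *both* sides of a differential peak is essential:
the CV criterion divides by the replicate mean, so a group with mean ≈ 0
fails it almost surely, and a planted peak enriched in only one group would
be undetectable under the study's own filter.

Not emulated: dye bias, spatial artifacts, probe GC effects, correlated
noise between neighboring probes, and any vendor peak-score model. Passing
recovery tests therefore demonstrate correctness of the implemented rules
under idealized noise, not robustness to array artifacts.

All generators draw from one `numpy.random.default_rng(seed)` stream, so
fixtures are bit-reproducible per seed.

## CpG-density promoter classes

Thresholds follow the Gardiner-Garden style convention: for a window,
O/E = (N_CpG · L)/(N_C · N_G) and GC = (C+G)/(A+C+G+T), with N positions
excluded from all counts and from L. HCP requires a 500-bp window **fully
inside** −700..+200 of the TSS (the stricter reading of "within") with
GC ≥ 0.55 and O/E ≥ 0.6; LCP requires that no 500-bp window anywhere in the
assayed region reaches O/E ≥ 0.4 (the classification region, unstated in
the source convention, is taken as the whole −1300..+500 promoter); ICP is
the remainder. The scan uses cumulative-sum window statistics, step 1 bp by
default (exact; larger steps trade exactness for speed). Sequences shorter
than 500 bp are scored by their single full-length window; sequences over
50% N get no label, with a warning.

The sequence generator builds each class constructively (CpG-suppressed
background for LCP; a CpG-retaining core inside −700..+200 for HCP/ICP)
and rejection-samples until the planted windows clear the thresholds with a
margin (HCP core: GC ≥ 0.57, O/E ≥ 0.70; ICP: every window GC ≤ 0.535 with
core O/E ≥ 0.6), so generated labels are unambiguous under step-1 scanning.

## Bisulfite clone matrices

Each clone (sequenced bacterial colony) is one row of per-CpG calls in
{methylated, unmethylated, undetermined}. Ratios exclude undetermined calls
from numerator and denominator; the region ratio equals the
determined-count-weighted mean of per-clone ratios. Group comparison is a t
test on per-clone ratios (n = 10 clones per group in the emulated design),
matching bar-graph-with-t-test reporting; a per-site variant is available
(`per="site"`). A pooled 2×2 count test would treat CpG calls as
independent across sites within a clone, which they are not. The generator
draws i.i.d. Bernoulli(p_meth) calls masked to undetermined with
probability `p_undetermined` (default 0.05); defaults
p_meth = (0.685, 0.508) reproduce the emulated crypt comparison. Real
bisulfite data's within-clone site correlation is not modeled.

## ChIP-peak element annotation

Assignment is by summit position (configurable peak-width overlap rules
were considered and rejected: summits are reproducible across callers,
interval widths are not). Per gene, categories are evaluated in precedence
order promoter → exon → intron → enhancer → extended enhancer; across
genes the highest-precedence category wins and ties break by smaller
|TSS offset|. Windows: promoter ±2 kb of TSS; enhancer from 50 kb upstream
of the gene's 5′ end to 5 kb downstream of its 3′ end (gene-oriented),
minus the gene body and promoter; extended enhancer likewise with 100 kb.
"Extended enhancer" is only ever assigned when nothing tighter qualifies,
so with the upstream reaches set equal the two enhancer classes coincide.
TSS offsets are signed in gene orientation (negative = upstream): for a −
strand gene, offset = TSS − summit.

## Relative expression and regulation calls

ΔΔCt: ΔCt = Ct(target) − Ct(reference gene) per sample; ΔΔCt relative to
the reference condition's mean; fold = 2^(−ΔΔCt). The reference condition's
fold is exactly 1, and adding any constant to all Ct values leaves folds
unchanged. Standard errors are propagated on the ΔΔCt scale
(SE² = SE²_cond + SE²_ref) and reported as `se_log2`. Luciferase folds are
ratios of mean firefly/Renilla well ratios, active over empty vector; wells
with non-positive Renilla signal are excluded with a warning.

The regulation caller requires *both* perturbation arms to be significant
(p < α, default 0.05, per-gene without multiple-testing correction — a
deliberate match to per-gene reporting practice; a Benjamini–Hochberg step
can be applied upstream by the caller of the library) and concordant:
knockdown-down with overexpression-up ⇒ activated target; the mirror ⇒
repressed target; anything else ⇒ no regulation, with significant
same-sense arms flagged discordant. A single significant arm is
conservatively "no regulation".

## Numerical and testing notes

* Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
  inclusive convention is converted only at the I/O boundary.
* Probe tables are validated on construction (sorted, non-overlapping
  probes; contiguous promoters; complete sample columns; exactly two
  groups).
* Test problem sizes: the DMEP literal-criteria equivalence check runs 500
  random promoters of ≤10 probes against a plain-Python probe-by-probe
  oracle; planted-peak recovery uses 2,000 promoters with 200 planted
  differential peaks; null calibration uses 1,000 seeded replicates of a
  40-promoter array; the CpG oracle check uses 200 random 1800-mers against
  exhaustive substring evaluation. These sizes keep the default suite fast
  while leaving the estimates' Monte-Carlo error well inside the asserted
  bands.
* Known limitations: no vendor-compatible peak scores; no array
  normalization; idealized noise models (see above); regulation calls
  depend on the chosen α and inherit the per-gene testing convention.
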