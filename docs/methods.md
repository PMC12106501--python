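# Methods

## Problem and model

The target is a rare germline heterozygous deletion of a single exon —
the 3,538 bp *MLH1* exon 16 founder deletion at GRCh38 3:37044575–37048112
— screened from SNP-array probe intensities in a large cohort genotyped on
two array versions with overlapping probe content. A heterozygous carrier
retains one of two chromosomal copies, so the expected total fluorescence
of every probe set inside the deleted segment is halved, while flanking
loci are unaffected. The method makes no use of genotype calls, B-allele
frequencies or Log R ratios: it operates directly on summed raw
intensities, normalized cohort-wide by rank.

Coordinates are 1-based and inclusive at both ends throughout (so the
deletion length is end − start + 1 = 3,538). The deletion region carries
18 unique loci interrogated by 21 probe sets; 50 flanking loci (25 per
side by default, configurable) provide the within-sample baseline, and
only probe sets present on both array versions are used in the flanks so
the two sub-cohorts can be pooled.

## Pipeline stages

1. **Locus summation.** For each sample and locus, the intensities of
   both alleles (A, B) of all probe sets interrogating the locus are
   summed into one total signal value. Summation is version-aware: a
   probe set absent from the sample's array contributes nothing and does
   not create a missing value; a locus with no records at all for a
   sample is missing, and missingness propagates (no imputation — the
   upstream handling of incomplete samples is surfaced by
   `completeness_report` instead of guessed). Internally alleles are
   summed within probe set before probe sets are summed within locus, in
   fixed map order, so results are independent of record order on disk.

2. **Inverse-normal transform.** Each locus's totals are mapped to
   standard-normal quantiles across the cohort: ascending ranks with
   average ranks for ties, then z = Φ⁻¹((r − c)/(N + d)). The default
   offset is Hazen (c = ½, d = 0), which is symmetric about zero and
   bounded; Blom and van der Waerden are selectable. N counts non-missing
   samples only; loci with fewer than two values normalize to all-missing
   with a warning. Both array versions are normalized in one joint pool
   by default (mirroring a pooled cohort analysis); per-version pooling
   is a flag. The transform is invariant to any strictly increasing
   distortion of a locus's raw scale — and therefore also blind to a
   shift shared by all samples, a limitation asserted as a test (a cohort
   in which *everyone* carries the deletion yields zero calls).

3. **Features.** Each sample reduces to
   (median difference, piecewise MAD). The median difference is the
   deletion-region median minus the pooled-flanks median of the
   normalized values. With k carriers among N samples and no noise,
   carriers tie at the bottom of every deletion locus with average rank
   (k+1)/2, giving the analytic location Φ⁻¹(k/2N) (≈ −3.29 for k=1,
   N=1000); this closed form is exposed as
   `simulate.expected_feature_location` and used as a test oracle.
   The piecewise MAD takes absolute deviations of each locus value from
   *its own region's* median (deletion; pooled flanks), pools the
   deviations of both regions, and returns their median. Computing the
   deviations piecewise is what keeps a true carrier — two tight bands at
   different levels — at low MAD (the defining contract case: deletion
   values all −4, flank values all 0 give piecewise MAD 0 where a pooled
   MAD would give 2). Two alternative one-number combinations (max of
   the two region MADs; locus-count-weighted mean) are available behind a
   switch for sensitivity analysis. No 1.4826 normal-consistency factor
   is applied: the feature feeds a threshold rule, not a variance
   estimate, so the constant would only be absorbed into the threshold.

4. **Calling.** Explicit thresholds rather than a clustering algorithm:
   with one tiny cluster against an overwhelming main cluster, generic
   clustering is unstable, while the two features make the decision
   boundary a pair of interpretable constants. A sample is ambiguous if
   its MAD exceeds `mad_max` (default 1.5), else carrier if its median
   difference is at most `diff_max` (default −2.0), else negative;
   missing features give no_call. Ambiguity takes precedence over the
   carrier test because a high-variance sample can reach far-negative
   differences by chance, and silently calling it would corrupt precision
   accounting. The defaults sit between the main cluster (centered at 0,
   sub-unit MAD spread) and the analytic carrier tail (≈ −3.3 in any
   cohort of 10³ or more); they were validated by a parameter sweep on
   simulated cohorts before release (below). `suggest_thresholds`
   replaces visual cluster-plot inspection with a reproducible rule —
   mad_max as the Tukey outer fence Q3 + 3·IQR of the MADs, diff_max as
   min(−2, median − 5·1.4826·MAD) of the differences among fence-passing
   samples — and is returned, never silently applied.

5. **Evaluation.** Ambiguous and no-call samples are excluded from the
   2×2 confusion table but always counted alongside it; ratios with empty
   denominators are reported as undefined, never 0. Report percentages
   round half-up at fixed precisions (prevalence to three decimals,
   proportions to whole percent) with raw fractions retained — the
   rounding rules reproduce 29/121,073 → 0.024%, 24/29 → 83%,
   5/29 → 17% exactly.

## Synthetic cohorts

The simulator generates the statistical structure the detector relies on,
not array physics. Per record (sample × probe set):

intensity = baseline(probe set) × sample_scale × copy_factor × exp(ε)

with per-probe-set baselines lognormal around `baseline_mean` (1000
arbitrary units, log-sd 0.2), per-sample scale lognormal
(`sample_scale_sd`, default 0.05), ε ~ N(0, `probe_noise_sd`) (default
0.15) and copy_factor = `deletion_signal_ratio` (default 0.5,
heterozygous) at deletion probe sets of carriers, 1 otherwise. A noisy
minority class (`noisy_fraction`, default 0.1%) has ε inflated by
`noisy_extra_sd` (default 0.45). Each probe-set total is split between
the A and B alleles by a Beta(5,5) draw — only the A+B sum matters
downstream, but the split keeps the I/O schema honest; the smaller share
is computed as an exact floating-point complement so allele summation
reproduces the total bit-exactly, which keeps deliberately identical
samples exactly tied after summation (the noiseless oracle tests depend
on this). Cohorts default to 28%/72% v1/v2 array membership with all
flanking probe sets shared and a configurable minority (default 2) of
surplus deletion probe sets version-specific; carrier status is a
Bernoulli draw at 0.024% prevalence, or an exact planted count via
`n_carriers`. One `numpy.random.default_rng(rng_seed)` stream drives
everything, so a config is a complete recipe and reruns are
byte-identical.

### Noise-parameter calibration

The multiplicative-lognormal form is a standard idealization for
fluorescence data (positive, right-skewed), and the rank-based transform
downstream makes results insensitive to the exact marginal shape. The
amplitudes were set by a release-validation sweep with two qualitative
targets: a carrier's log-signal shift (log 0.5 ≈ −0.69) should be several
times the per-locus noise scale (here √(0.05² + 0.15²) ≈ 0.16, a ~4σ
shift), and the noisy class should scatter over the full normalized range
with clearly elevated MAD, as real high-variance samples do. Two
instructive failure modes shaped the final values. First, a sample with
unusually low overall scale drags its *flank* median down while its
deletion loci are already saturated in the rank tail, shrinking the
median difference — large `sample_scale_sd` therefore creates borderline
carriers, and 0.05 reflects that upstream summarization/normalization
leaves little inter-sample scale. Second, the noisy class is
non-monotone in its own amplitude: extreme noise rank-compresses a
sample's values into the two tails, which can *lower* its MAD; the
chosen amplitude (total noisy sd ≈ 3.8× the population per-locus sd)
sits where the class is ~99.8% ambiguous. Under the frozen defaults,
150 cohorts of 10,000 samples with 8 planted carriers each gave 1,200
true positives, 0 false positives and 0 false negatives. A residual
false-positive leak of order 10⁻⁴ per noisy sample is geometrically
irreducible at these thresholds, so an isolated false positive can still
appear in a long run (pooled PPV then ≈ 99.7%).

### What the simulator does not emulate

No genotype clusters or B-allele structure, no GC/wave or plate-position
artefacts, no batch effects, no homozygous deletions, no linkage between
noisy status and array version. Passing tests therefore demonstrate that
the pipeline's logic is correct under its stated signal model — halved
total intensity against a stable flanking baseline — not that real-cohort
performance (which depends on artefact structure the simulator omits)
will match.

## Problem sizes and numerics

Validation cohorts use 10,000 samples × 68 loci (71 probe sets), with 50
seeded replicates for the headline precision check — large enough that a
lone carrier sits beyond −3.2 on the normalized scale and the geometry
matches a biobank-scale run, while one replicate completes in about a
second. Ranking uses average ties throughout; medians of even counts are
midpoint means. Degenerate inputs are defined behaviors, not crashes:
empty regions give missing features (flagged, kept), loci with fewer than
two observations normalize to missing with a warning, zero-spread cohorts
make `suggest_thresholds` raise, and infeasible simulation configs fail
at construction. All data outputs use fixed float formats and contain no
timestamps, so identical inputs and config produce identical bytes; the
pipeline stamps outputs with a SHA-256 config hash instead.

## Known limitations

Rank normalization cannot see population-wide copy changes; sensitivity
claims rest on simulated truth only; the thresholds are calibrated to the
two-feature geometry at cohort sizes ≥ ~10³ and should be re-examined (or
re-suggested) for small cohorts; flank-count ambiguity (50 total vs per
side) is resolved as 50 total and configurable; the piecewise-MAD
combination rule is one defensible reading of a one-number "piecewise"
dispersion and the alternatives remain switchable.
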