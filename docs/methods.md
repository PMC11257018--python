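# Methods

`pursuitgwas` implements a two-part analysis: (i) extraction of smooth-pursuit
phenotypes from 1 kHz horizontal eye-position recordings, and (ii) a
quantitative-trait genome-wide association analysis of those phenotypes with
permutation-based familywise correction, LD clumping and analytic power. No
raw data ship with the package; a synthetic-data layer generates both
recording sessions and genotype cohorts with a complete ground-truth log so
that every stage is testable end to end.

## Oculomotor phenotyping

**Task model.** A pursuit trial shows a target fixating centrally for a
uniform-random 500–1500 ms, then moving horizontally at a constant speed
(10, 20 or 30 deg/s) between ±15 deg in a triangular waveform for 5.5 cycles;
eight trials per speed. Interleaved calibration blocks fixate a seven-point
grid (±15, ±10, ±5, 0 deg) for 1000 ms per point.

**Calibration.** Gain and offset are ordinary least squares of the mean
oculographic signal per fixation (the central 200–950 ms of each, to skip the
acquisition saccade) against the grid values; calibrated position is
`(signal − offset)/gain`, applied to everything recorded after that
calibration until the next. Calibrations with fewer than two distinct targets
or |gain| < 10⁻³ are rejected.

**Differentiation.** Raw 1 kHz position with ≈6 arcmin sensor noise cannot be
double-differenced directly. Position is differentiated with a 21 ms
second-order Savitzky–Golay filter; acceleration is the same filter applied
to the velocity (a cascade). The window length is the one numerical constant
the derivative estimates are sensitive to; 21 ms retains most of the
acceleration of a 30–80 ms saccade while reducing the noise floor by an order
of magnitude.

**Blink handling.** Samples are artifactual when the signal is off-scale
(|position| > 30 in calibrated units), the instantaneous velocity exceeds
1000 deg/s, or the recording flags them invalid; artifact intervals are
padded by 50 ms on each side and masked. Trials with under 50% valid samples
are dropped.

**Saccade detection.** The threshold is participant-relative: six times the
median, over trials, of the acceleration SD in the first 80 ms of each trial
(initial fixation, hence noise floor). Runs of |acceleration| above threshold
are merged across gaps under 20 ms, extended to the 20%-of-threshold
re-crossings, and discarded if shorter than 10 ms, overlapping masked
samples, or moving the eye by less than 0.3 deg — the last rule removes the
acceleration transient at target direction reversals, where smooth pursuit
reverses velocity without a position jump.

**Classification.** Position error is evaluated 5 ms outside the event bounds
to avoid transient overshoot. A saccade in the direction of target motion
that decreases |eye − target| is a catch-up saccade; one in the pursuit
direction that increases the error and exceeds 1.5 deg is anticipatory;
everything else is "other". Every detected event receives exactly one class.

**Phenotypes.** RMSE is the root mean square of eye-minus-target over all
valid samples (saccades included, blinks excluded); the session value is the
unweighted mean of per-trial values across all speeds (a pooled-sample RMS is
available via `aggregate="pooled"`). Gain is the mean of signed eye velocity
over signed target velocity on valid, non-saccadic samples with target
eccentricity ≤ 10 deg (this also skips the latency transient after each
reversal); saccade rates are class counts over total valid tracking seconds.
Spearman rank correlations (average ranks on ties) serve both the
between-measure correlation matrix and test–retest reliability.

## Session simulator

The simulated eye integrates a first-order pursuit model:
`du = g·dT_λ + (T_λ − u − s)·dt/τ`, where `T_λ` is the target delayed by the
pursuit latency (default 100 ms, a typical human value), `g` the pursuit
gain, `s` the cumulative saccadic displacement and τ = 0.7 s a slow
position-error feedback that bounds the lag a low-gain eye accumulates. With
g = 1 and no events the recursion is exact — the eye equals the
latency-shifted target — which pins the simulator to an analytically known
case. Recorded signal is `cal_gain · position + cal_offset` plus Gaussian
sensor noise (default SD 0.1 deg ≈ 6 arcmin).

Catch-up and anticipatory saccades are scheduled as Poisson processes over
the motion period. Each scheduled event is shifted forward to the first
sample where its class geometry genuinely holds (catch-up: error at least
0.5 deg in the pursuit direction; anticipatory: a saccade of the configured
amplitude, default 2.5 deg, in the pursuit direction would increase the
error), and never within the pursuit latency of a direction reversal, where
the lagged smooth eye still moves with the old direction and the class
geometry is ill-defined. This keeps the truth-log count Poisson while
guaranteeing that every logged event is a true instance of its label.
Saccades follow a minimum-jerk position profile with a main-sequence-like
duration (30 + 8·amplitude ms, clipped to 30–80 ms). Catch-up amplitude is
90% of the momentary error. Blinks clamp the signal to an off-scale constant
(−45) with 50 ms tapered edges and mark the interval invalid.

What the simulator does *not* emulate: vertical/torsional movements, head
movement, pursuit initiation dynamics, microsaccades, drift in calibration
within a session, and instrument nonlinearity. Passing tests therefore show
that the pipeline recovers the phenotypes of this plant, not that it handles
every artifact of real oculography.

## Cohort simulator

Genotypes are binomial(2, p) draws under Hardy–Weinberg equilibrium;
ancestral frequencies are uniform on a configurable MAF range (default
0.05–0.5), and population structure uses a Balding–Nichols draw of
cluster-specific frequencies with an Fst-like divergence parameter. The
phenotype is built on a standardized scale:
`y = β·g_causal + s_sex·z_sex + s_cluster·z_cluster + e`, with the residual
variance set so total variance is 1. β is therefore directly the per-allele
effect in phenotype SD units, and the causal SNP explains `β²·2p(1−p)` of the
variance — at the default operating point (MAF 0.49, β 0.29) about 0.042.
Defaults: n = 980 individuals, sex effect 0.1 SD, no cluster effect on the
phenotype (the `cluster_effect_sd` knob exists because stratification only
inflates test statistics when the phenotype co-varies with cluster).
Missingness is completely at random. A separate generator builds an LD block
(haplotypes copying a causal haplotype with fidelity 0.92, pairwise r² ≈
0.5–0.9) surrounded by independent null SNPs, with a block effect (0.5 SD per
allele) strong enough that the index-SNP threshold p ≤ 10⁻⁵ is nearly always
reached — the clumping checks validate geometry, not detection power.

## Association analysis

**QC order** (each step on the survivors of the previous): samples with call
rate < 0.97; SNPs with missingness > 2%; SNPs with MAF < 1% (MAF computed
after the sample exclusions). HWE is computed and reported per SNP but is not
an exclusion filter unless a threshold is passed explicitly. Optional
pre-filters mirror array practice: near-duplicate removal at pairwise IBS
similarity > 0.95 and population outliers at |PC z-score| > 6. After QC the
matrix is minor-allele oriented (allele 1 frequency ≤ 0.5 everywhere).

**HWE exact test.** Two-sided exact test of the heterozygote count
conditional on the allele counts: the p-value sums the probabilities of all
heterozygote counts no more probable than the observed one. Probabilities are
built by the stable ratio recurrence outward from the mode, so counts in the
thousands remain exact; a mid-p variant exists but is off by default.

**Regression.** Per SNP, OLS of the phenotype on the 0/1/2 minor-allele count
plus covariates (sex coded 1 = female, top-3 genotype PCs by default) and an
intercept; two-sided p from the t distribution on `n_used − p` df. Samples
missing that SNP's genotype are dropped for that SNP only (complete-case per
SNP). SNP columns without missing values go through a single vectorized
Frisch–Waugh–Lovell pass, algebraically identical to the per-SNP fit (tested
against it and against an independent OLS implementation). An optional rank
transform replaces the phenotype by average ranks before regression.
P-values are floored at 10⁻³⁰⁰. Genotype PCA standardizes each SNP by
`sqrt(2p̂(1−p̂))` with per-SNP mean imputation for the decomposition only, and
fixes signs so each component's largest-magnitude loading is positive.

**Genomic inflation.** λ is the median of the per-SNP 1-df chi-square
quantiles divided by 0.4549364 (the chi-square-1 median) — the standard
genomic-control estimator. Note the estimator itself is noisy: at m = 5000
SNPs the Monte-Carlo SD of λ is ≈ 0.03, so calibration statements about λ
average several seeds.

## Permutation, clumping, power

**Max-T permutation.** Observed per-SNP |t| statistics are compared with the
permutation distribution of the genome-wide maximum |t|; the corrected
p-value is `(1 + #{perm max ≥ observed})/(n_perm + 1)` (add-one estimator,
never zero, monotone in the raw p). Phenotype rows are permuted only within
population clusters from complete-linkage clustering on identity-by-state
distance (IBS share 0/1/2 per SNP, pairwise-complete over missing data;
deterministic relabeling by lowest member index). Covariates travel with the
phenotype; the implementation applies the inverse permutation to the genotype
rows instead, which yields identical statistics and lets the covariate basis
be orthonormalized once. Missing genotypes are mean-imputed inside the
permutation engine only, so observed and permuted statistics come from the
same exchangeable computation; with QC-level missingness (≤ 2%) the
difference from complete-case fitting is negligible. Both a per-permutation
refit mode (default) and a residualize-once mode are provided; they agree
exactly when there are no covariates.

**Clumping.** Greedy, PLINK-style: the smallest-p unclumped SNP with
p ≤ p1 = 10⁻⁵ seeds a clump; unclumped SNPs with p ≤ p2 = 0.01 on the same
chromosome within 1250 kb and composite-LD r² ≥ 0.1 with the index join it;
repeat. Ties in p break by SNP id. Clumps partition the assigned SNPs. LD is
the squared Pearson correlation of genotype codes over pairwise-complete
samples.

**Power.** `power = 1 − F_ncf(Fcrit | ν1, ν2, λ)` with
`λ = [r²/(1−r²)]·ν2` and `Fcrit` the (1−α) central-F quantile. At r² = 0 the
power equals α exactly. At the operating point r² = 0.043, ν = (1, 977),
α = 5×10⁻⁷ the formula gives 0.9402 (verified against a 10⁶-draw Monte-Carlo
simulation of the noncentral F from its definition).

**Sex-difference test.** The observed statistic is |β_A − β_B| at one SNP
from separate fits in the two groups of the real split; the null re-splits
the cohort at random into groups of the same sizes, with the add-one p
estimator. Draws leaving the SNP monomorphic in a group are redrawn and
counted.

## Numerical and design choices

- All randomness flows from one integer seed per generator/test; identical
  seeds reproduce byte-identical outputs (the pipeline manifest checksums
  verify this).
- Output floats are serialized with 10 significant digits.
- The internal genotype matrix TSV is the canonical interchange format
  (PED/MAP loses minor-allele orientation; VCF is supported read-only via
  cyvcf2).
- Degenerate inputs raise rather than warn: monomorphic genotypes, collinear
  designs, all-invalid traces, calibrations with < 2 targets, λ on < 100
  p-values.
- Test problem sizes: the calibration suites use n = 980 cohorts with 200–5000
  SNPs, 200 replicates for permutation calibration and 200 seeds for
  parameter recovery — large enough that binomial/Monte-Carlo error is well
  inside the asserted bands, small enough to keep the default suite quick.

## Known limitations

- Session-level and cohort-level simulation are linked only statistically
  (the cohort phenotype is the standardized RMSE analogue), not by running
  980 full oculomotor sessions per cohort.
- The saccade detector's class accuracy degrades near direction reversals by
  construction of the task; the simulator avoids injecting events there, and
  real recordings analyzed with this detector inherit the same caveat.
- Composite (genotype) LD, not haplotype LD; no imputation, dosages,
  mixed models, or X-chromosome handling.
- The max-T engine assumes a common residual df across SNPs (exact without
  missing data; an approximation under mean imputation).
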