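# Methods

## Model and procedure

**Cleavage classification.** Trypsin cleaves C-terminal to K/R. A
peptide terminus *conforms* when it abuts such a cleavage site or a
protein terminus. Both termini conforming → fully tryptic; exactly one →
semi-tryptic (a truncation product of a fully tryptic peptide, the
molecular signature of proteolytic degradation); neither → non-tryptic.
The two semi-tryptic subtypes (N- or C-side ragged) are tracked but
collapse into one category for scoring. The proline rule (no cleavage
before P) is off by default — semi-tryptic search engines typically do
not enforce it — and, when enabled, is applied at both termini.
Classification comes either from a `cleavage` column of the input matrix
or from exact substring lookup of each peptide in its assigned FASTA
protein; for peptides occurring at several positions the most conforming
occurrence wins (ties: leftmost), since identification cannot
distinguish copies and the conservative reading under-counts
degradation.

**Scoring.** Per protein and sample, iPIS = 1 − (Σ normalized
semi-tryptic intensity)/(Σ normalized total intensity). Intensities are
square-root-normalized by default, damping the dynamic range so a single
intense peptide does not dominate the ratio; identity normalization is
available. Per sample, PIN is the unweighted mean of defined iPIS
values. Both statistics are ratios of sums homogeneous in intensity, so
they are invariant to per-sample rescaling and need no between-sample
normalization. Missing cells mean "not detected by targeted extraction"
and are excluded from sums rather than imputed as zero. Non-tryptic
peptides are excluded from both sums by default (a semi-tryptic search
space cannot produce them); a switch counts them as degradation
products. A protein observed only through semi-tryptic peptides scores
iPIS = 0, not missing — that is positive evidence of degradation. The
cohort-averaged iPIS of a protein is the unweighted mean over the
samples where it is scorable; proteins below 0.8 (default) are reported
as degradation-prone.

**Pre-filters** (defaults as commonly published for SWATH cohort
analyses): keep only proteotypic peptides; keep proteins detected in
strictly more than 50 % of samples ("over half", read literally); merge
technical replicates cell-wise by mean over non-missing values (sum and
max available); duplicate (peptide, run) rows in long-format input pool
by sum, since charge states and repeated features of one precursor key
carry the same peptide's signal. Protein quantification, used only by
the clustering-stability report, takes each protein's most consistently
detected peptide (ties: higher median intensity).

**Null model.** Cohort PINs of intact samples are modeled as
Weibull(λ, k); the degradation P-value of PIN x is the lower tail
F(x; λ, k) = 1 − exp(−(x/λ)^k). Because degraded samples contaminate
the fit, fitting iterates: (A) maximum-likelihood fit on currently
included samples and KS distance D on those samples; (B) P-values for
*all* samples from the current fit, excluding those with P < 0.02
(cumulative — an excluded sample never re-enters). Iteration stops when
the excluded set is stable or when D worsens relative to the best seen,
in which case the best-D iteration's model is returned; a hard cap of
50 iterations guarantees termination. Finally every sample is scored
with the converged parameters and flagged at P < 0.01 by default. No
multiple-testing correction is applied: fixed raw-P thresholds are the
convention for this kind of QC score.

## Numerical choices

- Weibull MLE via the one-dimensional profile likelihood in k: the
  score Σxᵏln x/Σxᵏ − 1/k − mean(ln x) is increasing in k from −∞ to a
  positive limit, so a bracketed Brent root search (relative tolerance
  1e−10, moment-based start k₀ ≈ 1.2825/CV) is deterministic and
  bit-stable; λ follows in closed form as (mean xᵏ)^(1/k). Data are
  pre-scaled by their maximum (the fit is scale-equivariant) to avoid
  overflow of xᵏ at the large shapes (k ≈ 100–300) that tight PIN
  cohorts produce. Cross-checked in the test suite against an
  independent generic MLE (`scipy.stats.weibull_min.fit(floc=0)`).
- The KS distance is evaluated at both one-sided limits of every ECDF
  jump (D = max(i/n − Fᵢ, Fᵢ − (i−1)/n)); verified against exhaustive
  breakpoint enumeration on small instances and `scipy.stats.kstest`.
- P-values use `-expm1` for precision in the extreme lower tail; PIN = 0
  is clamped to the smallest positive float so the map stays defined.
- Fitting requires ≥ 5 samples with non-zero variance; a cohort whose
  every PIN is identical (e.g. all exactly 1) is scored without
  P-values and the reason is recorded in `null_model.json` rather than
  failing the whole pipeline.
- Spearman p-values are exact (full permutation enumeration) for n ≤ 10
  and use the t-approximation above, so small-cohort reports are
  deterministic; ties get average ranks.
- Dendrogram comparison defaults to complete linkage on Euclidean
  distances of log2(x+1) abundances — the choice is exposed because the
  stability statistic (Pearson correlation of cophenetic distance
  vectors) is about comparing trees, not about one canonical tree.

## The simulator: what it emulates, what it does not

`simulate_peptide_matrix` emulates a protease-treatment calibration
experiment: proteins with 3–8 tryptic peptides (K/R-free interiors,
K/R C-terminus, conforming flanks), log-normal base intensities
(ln-mean 11.5, ln-sd 1.5 — a realistic raw-MS dynamic range of roughly
1e3–1e7), mild per-(peptide,sample) multiplicative noise (ln-sd 0.2),
and a per-sample degradation fraction grid defaulting to
{0.30, 0.20, 0.10, 0.05, 0.02, 0.01}, a dose series from heavy
degradation to near-intact. Degradation is modeled as **mass transfer**:
fraction f of each peptide's intensity moves to one semi-tryptic
truncation product (random interior cut; configurable ladder depth).
Mass conservation makes the ground truth exact: identity-normalized
PIN = 1 − f regardless of intensity noise, and sqrt-normalized
PIN = 1 − √f/(√f + √(1−f)) — note this lies *below* 1 − f for f < ½,
because sqrt compression up-weights the lower-intensity truncation
product. Per-sample RNG streams are split from the master seed so one
sample's parameters never perturb another's draw.

Not emulated: retention-time drift, interference, FDR-controlled
identification noise, peptide-specific degradation propensity
(real degradation-prone proteins are a specific minority; simulated
degradation is proteome-uniform), and intensity-dependent missingness.
Passing tests therefore demonstrate correctness of the scoring and the
statistics under controlled conditions, not robustness to every
real-data artifact.

`simulate_cohort_pins` draws cohort PIN vectors from a known Weibull
null truncated to (0, 1], appending degraded-sample PINs verbatim as
contaminants. Calibration and contamination studies use a null of
Weibull(0.956, 300) — matching a tissue cohort whose intact samples
have mean PIN ≈ 0.954 and SD ≈ 0.004 — and contaminant PINs
{0.645, 0.714, 0.850, 0.868}, the scores of heavily protease-treated
benchmark samples. Contaminants only slightly below the null bulk
(e.g. 0.94 against that null) sit at null quantiles of a few percent
and are *not* reliably separable by any cohort-level test at n ≈ 60;
the detection task this package is built for is the benchmark-scale
separation.

## Known limitations

- The iterative exclude-and-refit rule is mildly anti-conservative: on
  pure-null cohorts of n = 68 the empirical type-I error at α = 0.01 is
  ≈ 0.012–0.014 rather than 0.010 (a single non-iterative MLE fit is
  calibrated at ≈ 0.0099). Keeping the smallest-D fit selectively
  accepts refits in which low null draws were excluded, slightly
  tightening the null. The effect shrinks at larger α (within binomial
  noise at 0.05) and is the price of robustness to genuinely degraded
  contaminants.
- PIN says nothing about proteins below the detection limit, and a
  cohort consisting *entirely* of degraded samples has no intact
  reference: the null then describes degraded samples and flags nothing
  (the PIN values themselves remain informative, as in a dose-series
  design).
- Averaged iPIS is unweighted across samples; cohorts mixing very
  different detection depths weight samples equally, not by evidence.
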