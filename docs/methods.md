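# Methods

`ctbskit` implements the analysis chain of a pediatric cTBS plasticity-biomarker
study design: single-pulse MEP blocks recorded before and at fixed times after
continuous theta-burst stimulation of M1, compared between an ASD and a
typically developing (TD) group. This note records the model, the numerical
choices, and what the synthetic-data tests do and do not establish.

## MEP preprocessing

A *block* is a set of single-pulse MEP peak-to-peak amplitudes (mV) recorded
together: baseline blocks (ASD layout 3 × 30 trials, TD layout 2 × 20) and one
30- (ASD) or 20-trial (TD) block at each of 5, 10, 20, 30, 40, 50, 60 min
post-cTBS.

Cleaning rules, in order:

1. **Pre-stimulus EMG filter** (optional, default ceiling 100 µV): trials with
   background EMG above the ceiling are flagged. The rule exists to catch
   incomplete hand relaxation; it runs first so contaminated trials do not
   enter the outlier statistics.
2. **2.5-SD outlier rule**: within each block, trials whose amplitude deviates
   from the block mean by more than 2.5 sample standard deviations (n − 1
   denominator) are flagged. The pass is *single*: mean and SD are computed
   once over the block's unflagged trials and the flags applied once.
   Iterative re-exclusion would remove progressively more trials and is not
   what a one-sentence exclusion rule usually means; the single pass is also
   idempotent, which makes reprocessing safe. A zero-SD block flags nothing.
   Flags are never deleted — every downstream subset inherits them.
3. **Trial-count equalization** (optional): reduces the ASD layout to the TD
   trial counts — the *last 40* baseline trials in block-then-trial order, and
   the *centered 20 of 30* in each post block. "Centered" is implemented as a
   symmetric trim, indices 6–25 of 30; for a general block of n trials and
   target m, the first ⌊(n − m)/2⌋ are dropped. Subjects already at the
   target counts pass through unchanged.

**Baseline amplitude** is the unweighted mean of baseline-block retained
means (mean of block means, not the pooled trial mean). With unequal retained
counts these differ; the block-mean convention weighs each block's sampling
epoch equally and is applied uniformly to both layouts.

## Plasticity metrics

For each subject and post-cTBS time *t*,

ΔMEP(t) = ln( post-block retained mean / baseline amplitude ).

Negative values are suppression (the LTD-like response), positive values
facilitation. The log-ratio is invariant to common rescaling of baseline and
post means and turns multiplicative MEP noise into additive noise. A
percent-change representation is available for description only; all
inference runs on the log scale.

* **ΔMEP_Max** — the most negative ΔMEP over the subject's available times
  (possibly positive when nothing suppresses); "maximum suppression".
* **Cumulative signed AUC** — the trapezoidal integral of ΔMEP against time
  in minutes from T5 to each interval end (10, 20, …, 60 min). The abscissa
  starts at the first measured point (no synthetic t = 0 anchor), and
  positive and negative lobes cancel. `auc_normalize` divides by interval
  length, giving a time-weighted mean ΔMEP that is comparable across
  intervals; it is off by default. Minutes are used as the abscissa unit
  throughout; any fixed rescaling of the abscissa rescales every AUC and
  leaves t statistics, p-values and effect sizes unchanged.
* **Dropout**: a subject missing a grid time is excluded from that interval
  and all longer ones. Nothing is interpolated.

## Group inference

Per interval, an independent-samples **pooled-variance (Student) t-test**
(df = n1 + n2 − 2 — the df convention matching a t(27) for groups of 11 and
18); Cohen's d = mean difference / pooled SD. The six interval p-values form
one multiplicity family, adjusted by **Benjamini–Yekutieli** step-up FDR
(with the Σ1/i factor), which remains valid under the strong positive
dependence that nested cumulative AUCs have by construction;
Benjamini–Hochberg is available as a config switch. Age relationships use
the Pearson correlation with the two-tailed p from the t transform.

Two sensitivity reruns:

* **Predicate exclusion** — rerun the comparisons after dropping subjects
  matching a metadata predicate (e.g. ADHD comorbidity).
* **Baseline-matched subgroups** — the largest subset pair whose baseline
  amplitudes do not differ at p ≤ 0.05 (pooled t). The search enumerates
  removal sets in order of increasing size, so the first qualifying pair is
  maximal; ties are broken by the smaller absolute mean difference. The
  enumeration is used up to 25 total subjects within a 2·10⁵-combination
  budget; beyond either limit a greedy trim repeatedly removes the one
  subject whose removal most increases the comparability p-value. Only the
  post-condition (comparability, maximal size) is specified; the search
  strategy is this package's choice.

## Genotype-composition confound

With genotype data available in only one group, the question is: how likely
is it that two groups of 11 and 18 subjects drawn from the same population
differ significantly in BDNF Met−:Met+ ratio? Under Hardy–Weinberg
equilibrium at rs6265 MAF 0.153 the Met− (Val/Val) prevalence is ≈ 0.718
(the package default uses the 0.718:0.282 ratio directly; the HWE-derived
0.71741 is available via `hwe_genotype_probs`). The procedure:

1. per-group Met− count distributions — exact Binomial(n, 0.718) or a
   Monte-Carlo estimate (10,000 iterations of n Bernoulli draws, the
   default mirroring the original instrument);
2. for every scenario (k1, k2) ∈ {0..n1} × {0..n2} — including k = 0,
   which carries mass ~10⁻⁶ — a two-tailed Fisher exact test of
   [[k1, n1−k1], [k2, n2−k2]];
3. the **overall discordance probability** = Σ P(k1)·P(k2) over significant
   scenarios (mutually exclusive events).

The two-tailed Fisher p is the point-probability sum (all same-margin tables
whose point probability is ≤ the observed one, with 10⁻⁷ relative slack
against float ties) — the convention shared by R, SciPy, Stata and MATLAB.
Zero-margin tables are uninformative and get p = 1. At n = 11/18, p = 0.718,
α = 0.05 the exact computation gives **0.0302** (96 significant scenarios);
an independent R `fisher.test` enumeration agrees. Alternative two-tailed
conventions give 0.018 (doubled one-tail), 0.036 (one-sided union) and 0.049
(mid-p).

## Power analysis

Exact noncentral-t computation, the algorithm class of dedicated power
calculators: power = P(|T′| > t_crit) with T′ noncentral t at
df = n1 + n2 − 2 and noncentrality δ = d·√(n1 n2/(n1 + n2)), t_crit the
central two-tailed critical value. The sample-size solver starts at the
normal approximation 2(z₁₋α/₂ + z_power)²/d² and walks to the smallest
integer n with power ≥ the target (checked minimal: power(n−1) < target).
Post hoc power in the pipeline uses each interval's observed |d| with the
full group sizes at every interval.

## Synthetic cohort generator

No raw recordings are distributed with this package, so the generator
provides trial-level cohorts with the structure the analysis assumes, with
known ground truth. Defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| group sizes | 11 ASD / 18 TD | study design |
| ages | uniform 10–16 y | enrollment range (ages are only binned in the source tables) |
| baseline MEP | ASD 0.37 ± 0.27 mV, TD 1.19 ± 0.41 mV, floor 0.05 mV | printed group summaries |
| modulation curves | ASD +0.06…+0.02 (facilitatory), TD −0.25…−0.02 recovering by 60 min | direction/shape of the reported group time courses; classic ~25% cTBS suppression in TD |
| between-subject ΔMEP SD | 0.35 | chosen so interval effect sizes fall in the reported 0.65–0.85 range |
| trial noise | log-normal, CV 0.5 | MEP amplitude variability; positivity |
| outlier rate | 0.015, ×5–10 amplitude | ≈ 4.6 excluded of 300 ASD trials reported |
| age slope (ASD only) | −0.2 ΔMEP/year at the subject's nadir | derived from the reported r = −0.67 and the spread of maximum suppression (≈ r·sd(ΔMEP_Max)/sd(age)) |
| dropout | ASD subject 1 after T10 | one reported technical dropout |
| genotypes | HWE at MAF 0.153; 3 ASD subjects unknown | genetic-testing description |
| ADHD | 5 of 11 ASD subjects | comorbidity table |

Mechanics: each subject gets a truncated-normal baseline, a constant
additive ΔMEP offset (between-subject heterogeneity), and the group curve;
ASD subjects additionally get age_slope·(age − 13) added *at the nadir* of
their true curve, so older subjects' maximum suppression deepens while the
rest of the curve is untouched. Trials are log-normal around the block true
mean with the configured CV (mean-preserving parameterization, so CV = 0
reproduces true means exactly). `generate_null_cohort` copies the TD curve
to both groups and zeroes the age slope.

Notes and limitations:

* The 0.05 mV floor (resample-until-positive truncation) raises the
  *realized* ASD baseline mean to ≈ 0.43 mV (analytic truncated-normal
  mean); tests compare sampled means to that analytic value, not to the
  nominal 0.37.
* The nadir-concentrated age term is clipped for younger subjects (a
  positive term just moves the nadir elsewhere), so the generator's
  age–ΔMEP_Max correlation at n = 11 is attenuated (≈ −0.3 on average)
  relative to the reported −0.67; the large-n recovery tests are about the
  *sign and exclusivity* of the trend, not its magnitude.
* Subject heterogeneity is a single time-constant offset; there are no
  time-varying random effects, no within-session drifts, no RMT/intensity
  variation, and no non-HWE population structure. Passing tests therefore
  show the pipeline's statistical machinery is correct under this model,
  not that real MEP data satisfy the model.

## Numerical and testing choices

* Sample SDs everywhere (ddof = 1). Degenerate cases are explicit: zero
  pooled variance with equal means → t = 0, p = 1; with unequal means → an
  error; zero-SD blocks flag no outliers.
* `binomial_pmf` is computed in log space (log-gamma binomial coefficient,
  `log1p` for the failure term) for stability at extreme p.
* Every delegated statistic (Fisher exact, pooled t, Pearson r, BY/BH
  adjustment) is cross-checked in the test suite against an independently
  written oracle: full hypergeometric enumeration, the hand-pooled t
  formula, the harmonic-sum step-up procedure.
* Simulation-based checks use fixed seeds and study-scale problem sizes:
  1,000 null cohorts for type-I calibration (the per-interval rejection
  rate must sit inside the binomial 95% band around 0.05), 200 cohorts for
  effect-direction recovery under a configured ≥ 0.8-SD AUC shift, and
  n = 200 per group for the age-trend recovery check.
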