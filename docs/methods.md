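# Methods

This note documents the statistical models behind `kinasign`, the choices
made where several defensible options existed, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## Differential phosphorylation

Per site, the two-group contrast on log2 intensities uses a pooled-variance
linear-model statistic with empirical-Bayes moderation. Residual variances
s² with d degrees of freedom are modelled as draws from a scaled
inverse-chi-square prior (s₀², d₀); the prior is fitted by moment matching
on log s² — the mean and variance of log s² are equated to their
digamma/trigamma expressions and d₀ obtained by Newton inversion of the
trigamma function. The moderated statistic uses the shrunken variance
(d₀s₀² + d s²)/(d₀ + d) and a t reference with d + d₀ degrees of freedom,
capped at the summed residual degrees of freedom across sites. When the
observed variances are under-dispersed relative to pure chi-square
sampling noise the prior degrees of freedom are infinite and the prior
variance is the mean observed variance. A unit test verifies exact
agreement (1e-8 on t and p) with the Bioconductor limma reference
implementation on a 300-site fixture; forcing the prior degrees of freedom
to zero recovers the ordinary pooled two-sample t exactly.

Missing intensities are not imputed: a site is tested only when it has at
least two observed values in each group, and is otherwise reported
untested. Selection uses Benjamini–Hochberg (plain step-up, π₀ = 1) at
q < 0.15. Sites with zero residual variance get p = 0 if the group means
differ and p = 1 otherwise.

Consensus clustering of samples resamples a configurable fraction
(default 0.8) of samples, clusters each draw hierarchically
(average linkage) under 1 − Pearson distance, and accumulates the
co-clustering frequency of each co-sampled pair; the final assignment
cuts an average-linkage tree on 1 − consensus. Constant-profile samples
are excluded with a warning. The default of 1000 resampling iterations
matches standard consensus-clustering practice; tests use 20–50
iterations, which already stabilise two well-separated groups.

## Motif mapping

A motif is a vector of 15 per-position residue constraints centred on the
phosphoacceptor (±7 residues, `_`-padded at protein termini; the padding
satisfies only wildcard positions). This position-constraint dialect covers
kinase linear motifs without regex quantifiers and is exactly testable.
Matching is site-level; substrate sets outside [5, 500] members are
excluded, following gene-set-analysis convention. Phosphatase and SH2
motifs are matched and scored identically to kinase motifs and keep their
category label — an enriched phosphatase set is interpreted as substrate
accumulation, not phosphatase activity.

## Kinase-set enrichment

Sites are ranked by a signed metric — moderated t by default, log2 fold
change or group mean-intensity difference as options (the ranking signal
named in the source protocol is ambiguous between abundance and
regulation, so all three are exposed). Ties break lexicographically by
site id, making the ranking invariant to input row order. The enrichment
score is the signed supremum of the weighted Kolmogorov–Smirnov running
sum (hit weight |r|^p with p = 1 by default, miss penalty 1/(N − N_h));
the leading edge is the set members at or before the extremum (after, for
negative ES). A set spanning the whole list has an undefined miss penalty
and is reported as ES = 0 with a `degenerate` flag. If all member weights
are zero the hit increments fall back to 1/N_h. At an exact
|max| = |min| tie of the running sum the reported sign follows the first
extremum — a measure-zero convention for continuous metrics.

Two permutation nulls are provided. *Phenotype* relabelling permutes the
group labels and recomputes metric, ranking and ES per draw; it requires
at least 7 samples per group and otherwise falls back, with a warning, to
*set* permutation, which scores random same-size site sets against the
observed ranking. NES divides ES by the mean magnitude of same-sign null
scores; the nominal p is the same-sign null tail fraction; FDR q compares
the pooled signed-NES null tail with the observed NES tail, clipped to
[0, 1] and made monotone in |NES| within each sign. With a single set the
q-value reduces to the nominal p.

Choice of null for planted-signal experiments: under phenotype
relabelling the substrates of a strongly regulated kinase remain mutually
correlated through the true phenotype, so that set's own null widens and
its NES is *deflated* exactly when the signal is overwhelming — with a
2-log2-unit planted shift the planted set scores ES = 1.0 yet ranks below
noise sets on NES in most runs. The substrate-set permutation null
measures the question actually planted in the simulation — are these
specific sites more concentrated than a random set of the same size? —
and recovers the planted kinase as top NES with q < 0.05 essentially
always. The signal-recovery and calibration experiments therefore use set
permutation; phenotype permutation remains the default preference for
real cohorts, where effects are weaker and inter-site correlation is a
confounder to protect against, and both modes are first-class options.

## Stratification

H-score = (3·%high + 2·%medium + 1·%low)/100, in [0, 3]. The printed
source formula's third term nominally references the *high*-staining area
again; it is read here as the low-staining area, the only reading under
which the 3/2/1 weighting is coherent. Area fractions must be nonnegative
and sum to ≤ 100.

Quartile binarisation uses the linear-interpolation quantile (the common
numerical default; with [1, 2, 3, 4] the 75th percentile is 3.25) and
codes "high" as *strictly above* the threshold, so threshold ties are low;
both conventions are recorded in the result's derivation metadata. With
any continuous score distribution this marks ≈25% of patients per kinase.
Quartiles are computed per cohort. K-high is the OR of the six signature
statuses in the fixed order PRKCE, c-Kit, p-ERK, p-P70S6K, p-PNKP, CDK6;
the same order defines the bits of the activation-pattern strings
(2⁶ = 64 possible). K-test variables are ORs over configured subsets of
2–5 kinases; the specific nine subsets used in the source study are not
published, so the composition is configuration. Mutation overlay is pure
cross-tabulation of activation patterns against distinct mutation
profiles, with no inference.

## Survival

Kaplan–Meier, log-rank and Cox fitting are delegated to lifelines. Cox
models use the Efron approximation for tied event times (less biased than
Breslow at moderate tie rates) and Newton iterations tightened to
precision 1e-9 so that small-sample estimates agree with direct
partial-likelihood maximisation to 1e-4; non-convergence (e.g. monotone
likelihood under perfect separation) raises a typed error. T, N and G
enter as numeric ordinal scores; the median of a KM curve is the smallest
observed time with S(t) ≤ 0.5, else "not reached". Each kinase indicator
(and K-high, and any K-test variable) gets its own Cox model with the
shared T/N/G/age adjusters, and the kinase-term Wald p-values are
Bonferroni-corrected across the tested variables. Tests verify the
algebraic identity between the log-rank statistic and the Cox score test
at β = 0 for a binary covariate, and 92–98% coverage of 95% Wald
intervals at n = 500.

## Preclinical scoring

Tumor volume is the ellipsoid approximation V = D·d²/2 (mm³) with D the
largest and d the shortest caliper diameter; the printed source formula
is typographically corrupted and this is the standard reading consistent
with the stated diameter roles. TGI compares the ratio of arm *mean*
volumes between the final and initial time points (ratio of means, not
mean of per-animal ratios; the source is ambiguous and ratio of means is
robust to animals measured at one time point only). The final time point
defaults to the last day shared by both arms — the last measurement of
whichever arm was terminated first. TGI is scale-invariant and monotone
decreasing in the treated growth ratio. Arm comparisons at a fixed time
use Welch's unequal-variance t-test.

## Synthetic cohorts: what they emulate

The generator is the package's definition of the study conditions:

* **Motif library** — 224 kinase, 23 phosphatase, 80 SH2 motifs by
  default (the 327-motif annotation scale of the source protocol). Each
  motif fixes its centre residue and three further positions to one or
  two residues, making incidental matches to random windows rare
  (~10⁻⁴ per window), so planted substrate sets stay close to their
  nominal size.
* **Proteome and sites** — site windows are drawn to satisfy their
  assigned motif (round-robin over the library, active kinases first) and
  concatenated into protein sequences; the planted site→motif table is
  the truth for matching-recall tests (recall is 1.0 by construction;
  precision is deliberately unconstrained).
* **Intensities** — log2 intensities are Normal(site baseline, noise_sd)
  with baselines Normal(25, 2) on the log2 scale, typical of label-free
  MS1 intensities; substrates of active kinases gain `effect_log2fc` in
  the "relapsed" group. Dropout is logistic in the true log2 intensity
  (slope 0.5 per log2 unit, anchored at `missing_rate_base` for
  baseline-abundance values) — a deliberately simple
  missing-not-at-random mechanism.
* **Clinical cohort** — six continuous H-scores per patient
  (3·Beta(2, 2), so ≈25% exceed each cohort quartile), T/N/G/age drawn
  from plausible TNBC marginals, and exponential relapse times with
  baseline median 60 months multiplied by per-kinase hazard ratios on
  each "high" status and, optionally, a K-high-level hazard ratio
  (`khigh_hr`, added so that a cohort-level planted effect like HR 9.22
  can be expressed; per-kinase ratios cannot produce it exactly).
  Censoring is independent uniform on (0, c_max) with c_max solved so the
  expected censored fraction matches `censor_rate` at the mean hazard
  (exact only under homogeneous hazards; the realised fraction deviates
  by a few percent in planted-effect cohorts).
* **Growth curves** — V(t) = 500·exp(r·m·t) mm³ with per-arm multiplier
  m, day grid 0–21 by 3, six animals per arm, lognormal measurement noise
  (`growth_noise_sd`, default 0.1; set to 0 for exact formula checks),
  and caliper diameters emitted consistently with the volume formula at
  aspect ratio 1.25.

What passing tests on these cohorts do **not** show: the generator has
site-independent noise (no correlated phosphoproteome blocks beyond the
planted sets), clean group labels, a single-variance noise model, no
batch structure, exponential (proportional-hazards-exact) survival, and
intensity distributions that are not calibrated to any deposited dataset.
Recovery rates on real cohorts will be lower and FDRs less exact than the
calibration measured here.

## Problem sizes and numerical settings

Calibration and recovery experiments use 1000–1500 sites, 50 motif sets,
10+10 samples, 100–200 permutations and 10–20 replicate cohorts; hazard
recovery uses n = 2000 patients with 20% censoring (chosen so the Wald
standard error of the planted log-HR supports a ±25% recovery check).
These sizes make the full suite run in about a minute while leaving
Monte-Carlo error well inside the asserted margins. Seeds are explicit
everywhere; every generator and the full pipeline are byte-reproducible
under a fixed seed. Known numerical conventions: BH is plain step-up
(no π₀ estimation); the trigamma inversion runs Newton to 1e-8; Cox
convergence is declared at Newton precision 1e-9 with at most 500 steps.

## Limitations

Phosphosite localisation probabilities, peptide-to-site collapsing,
normalisation beyond per-protein division, batch correction, imputation,
time-varying covariates, competing risks and drug-combination synergy
indices are out of scope. The KSEA FDR is the pooled-permutation
procedure, whose q-values are approximate for small set counts; the
Bonferroni correction applies only to the survival-stage kinase tests.
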