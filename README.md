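# kinasign

Phosphoproteomics-driven kinase-signature analysis for triple-negative
breast cancer (TNBC)-style cohorts.

Relapsed and non-relapsed TNBC tumors differ in their phosphoproteomes,
but individual phosphosites are hard to interpret and harder to assay in
the clinic. This package implements, as a tested and reusable pipeline,
the analysis chain that turns a phosphosite intensity matrix into a small
immunohistochemistry-ready kinase signature:

1. **Differential phosphorylation** — per-site two-group contrast with
   empirical-Bayes variance moderation (moderated *t*), Benjamini–Hochberg
   FDR, sites selected at *q* < 0.15; consensus clustering
   (1 − Pearson distance, resampled hierarchical clustering) of
   phosphoprofiles.
2. **Motif mapping** — each phosphosite's ±7-residue flanking window is
   matched against a library of linear kinase / phosphatase / SH2 motifs
   (by default 224 + 23 + 80 = 327 motifs), yielding per-kinase substrate
   sets.
3. **Kinase-set enrichment (KSEA)** — a GSEA-style weighted
   Kolmogorov–Smirnov running sum asks whether a kinase's substrates
   concentrate at one end of the ranked site list:
   hits add |r<sub>i</sub>|<sup>p</sup>/N<sub>R</sub>, misses subtract
   1/(N − N<sub>h</sub>), ES is the signed supremum; permutation nulls
   give NES = ES / mean |ES<sub>null, same sign</sub>|, nominal *p*, and a
   pooled signed-NES FDR (*q* < 0.05 significant, *q* < 0.25 relaxed).
4. **Prognostic stratification** — IHC H-score
   = (3·%high + 2·%medium + 1·%low)/100 ∈ [0, 3] per kinase and patient;
   patients strictly above the cohort 75th percentile are "high"; K-high
   is the OR over the six signature kinases (PRKCE, c-Kit, p-ERK,
   p-P70S6K, p-PNKP, CDK6); the per-patient 6-bit status vector defines
   one of 2⁶ = 64 possible activation patterns.
5. **Survival analysis** — Kaplan–Meier curves and log-rank tests per
   indicator; Cox proportional-hazards models adjusted for T, N, grade
   and age (Efron ties), Bonferroni-corrected across kinase tests.
6. **Preclinical scoring** — tumor volume V = D·d²/2 from caliper
   diameters and tumor growth inhibition
   TGI = [1 − (T_F/T_0)_treated / (T_F/T_0)_vehicle] × 100 per arm.

A first-class synthetic-data module generates every input with planted
ground truth — active kinases with known substrates, planted hazard
ratios, treatment effects — so each stage has a recoverable answer.

## Worked example

Run the whole pipeline on a synthetic cohort with one planted active
kinase (`KIN_013`, 30 substrates shifted by 2 log2 units in the relapsed
group) and a planted K-high hazard ratio of 9.22:

```sh
kinasign run-all --config example.yaml
```

with `example.yaml`:

```yaml
seed: 7
outdir: example_run
n_perm: 100
sim:
  seed: 7
  n_sites: 1500
  n_proteins: 75
  n_kinase_motifs: 50
  n_phosphatase_motifs: 0
  n_sh2_motifs: 0
  active_kinases: [KIN_013]
  effect_log2fc: 2.0
  noise_sd: 0.3
  n_patients: 113
  khigh_hr: 9.22
  censor_rate: 0.2
  growth_effect: {vehicle: 1.0, palbociclib: 0.4, combo: 0.1}
```

prints (from `example_run/summary.json`):

```json
{
 "khigh_hr": 11.173720806901544,
 "khigh_logrank_p": 8.307032009821634e-08,
 "n_khigh": 93,
 "n_kinase_sets": 50,
 "n_ksea_relaxed": 1,
 "n_ksea_significant": 1,
 "n_patterns_observed": 35,
 "n_patterns_possible": 64,
 "n_sites_selected": 34,
 "n_sites_tested": 1498,
 "seed": 7,
 "tgi_by_arm": {
  "combo": 85.38622285145819,
  "palbociclib": 72.33596719202714
 },
 "top_nes_kinase": "KIN_013"
}
```

Reading the output: the planted kinase `KIN_013` is recovered as the top
normalized enrichment score and is the single set significant at
FDR < 0.05; 34 of 1498 tested sites pass the differential *q* < 0.15 cut
(the 30 planted substrates plus a few borderline sites); the cohort of
113 patients shows 35 of the 64 possible kinase-activation patterns; the
planted K-high effect is estimated at HR ≈ 11.2 (true 9.22, n = 113 —
the estimate tightens to within a few percent at n = 2000); and the two
treated xenograft arms show 72% and 85% tumor growth inhibition versus
vehicle. The run directory also contains per-stage TSV tables
(`differential.tsv`, `ksea.tsv`, `ksea_running_sums.tsv`,
`kinase_status.tsv`, `patterns.tsv`, `survival.tsv`, `tgi.tsv`), the
config snapshot and input checksums; re-running with the same seed
reproduces every file byte for byte.

Each stage is also available separately (`kinasign simulate / diff /
ksea / stratify / survival / tgi`) and as plain library functions.

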