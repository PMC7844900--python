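# Methods

This note documents the models and procedures implemented in `cfomics`,
the parameters that matter, the numerical choices taken where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Duplex-UMI consensus calling (`cfomics.umi`)

A sequencing library built with duplex UMIs tags both strands of each
original cfDNA fragment. Reads are grouped into families by
`(chrom, frag_start, frag_end, canonical UMI pair)` where the canonical
pair is the lexicographically sorted `(umi_a, umi_b)`, so top- and
bottom-strand reads of one molecule collapse into one family.
Coordinates are 0-based half-open internally; emitted variant tables are
1-based (VCF convention).

Consensus is per position: bases below `min_baseq` (default Phred 30)
are discarded; each strand calls the base reaching at least
`majority_frac` (default 0.9) of its surviving bases, else N; when both
strands have coverage the duplex consensus is their common call, or N on
any disagreement. Families smaller than `min_family_size` or with an
N-fraction above `max_n_frac` (0.2) are dropped. Variants are called per
site from molecule counts: with `require_duplex` (default true) only
duplex-confirmed molecules count; a call needs `min_alt_molecules` ≥ 3
and `min_depth_molecules` ≥ 100. These defaults are standard stringent
duplex-sequencing practice; every threshold is surfaced in
`ConsensusParams` because published pipelines differ in exactly these
numbers. Only SNVs are modelled; indels, UMI mismatch clustering
(sequencing errors inside the tag split families) and multi-allelic
sites are out of scope.

One consequence of the strict duplex-disagreement→N rule is worth
stating: with family size ~5 and 1% per-read error, roughly 1–2% of
molecules resolve to N at a position (mostly single-read strands), so
"recovery of the true allele" is ≥ 99% only among molecules with a
confident non-N consensus; the total recovery matches the closed-form
majority-vote calculation (~98%). N is a no-call, not an error, and
N molecules are excluded from both depth and alt counts.

## CH filtering and burden scores (`cfomics.mutscore`)

Clonal hematopoiesis seeds plasma with blood-derived somatic variants.
A cfDNA variant is labelled WBC-shared iff a record with the identical
`(patient_id, chrom, pos, ref, alt)` key exists in that patient's WBC
variant table — exact matching, no AF tolerance, which is the simplest
rule consistent with "shared variants". Patients without WBC data keep
all variants as somatic (WBC is typically only assayed for
cfDNA-positive participants); the count is logged.

SUMAF is the plain sum of somatic AFs; wSUMAF weights each variant by
`w_tcga` (default 3) if TCGA-driver-flagged, `w_cosmic` (default 2) if
COSMIC-flagged, combined by `max` (configurable `sum`) when both, else 1.
The magnitudes are free parameters — the only constraint the science
imposes is weights > 1 for hotspots — and are surfaced in
`WeightScheme`. wSUMAF is centered at the cohort median so that the sign
dichotomizes the cohort at zero; whether the original score used
standardization or log-AFs before thresholding is not documented
anywhere we could verify, so median-centering is our explicit stand-in.

Group contrasts use Pearson's chi-squared without continuity correction;
this choice exactly reproduces the worked contingency-table examples the
tests pin down. AF correlations between compartments are Pearson on
log10 AFs.

## DMR calling (`cfomics.methyl`)

β of a region is the pooled ratio Σmeth/Σtotal over its CpGs (not the
mean of per-CpG ratios), missing when pooled depth < `min_region_depth`
(10) or covered CpGs < `min_cpg` (3). Regions are non-overlapping
windows or a user BED; the generator uses 200-bp tiles.

Per region with ≥ `min_pairs` (10) complete tumor/NAT pairs, the caller
computes the mean paired difference and a paired Wilcoxon signed-rank
p-value (a paired t-test is available via `DmrParams.test`), applies
Benjamini–Hochberg across tested regions, and emits a DMR iff q < 0.05
and |Δβ| > 0.2. Wilcoxon was chosen over the t-test as the default
because β differences are bounded and frequently skewed; the 0.2
effect-size threshold is the methy.diff convention. Hierarchical
clustering is average-linkage on pairwise-complete Euclidean distances
(missing β tolerated, as in depth-gapped heatmaps); sample pairs with no
overlapping features are pushed beyond the largest observed distance.
Classifier feature matrices instead use per-feature median imputation,
because forests need complete inputs.

## Diagnostic modelling (`cfomics.diagnostic`)

`DiagnosticModel.fit()` runs a stratified k-fold (default 6) random
forest (500 trees, √p features per split, fixed seed). With
`top_m_per_fold` set, each training fold fits a forest on all features,
keeps that fold's top-m by impurity importance (ties broken by feature
id), and refits on the reduced set before scoring its held-out fold; the
reported selection is the union over folds. Selection thus never sees
the test fold — where the alternative (selecting once on pooled CV
importances) is leaky, we implement the leakage-free reading and verify
it with a permuted-label test that must stay at chance AUC.

AUC uses the rank (Mann–Whitney) formulation with ties counted ½; the
operating point maximizes Youden's J with ties resolved toward the lower
cutoff, predicting positive at score ≥ cutoff. The DeLong test for
correlated ROC curves is implemented from placement values with the
paired variance estimate; identical score vectors return p = 1 exactly.
Serum markers get a two-sided two-sample t-test (equal-variance default,
Welch optional) plus the marker's raw AUC. Multi-analyte evaluation
(`combine_omics`) first intersects samples with complete measurements
for every requested analyte, then evaluates all models on that identical
set so AUCs are DeLong-comparable; univariate analytes (wSUMAF, CEA) are
evaluated as raw scores rather than through a forest, since a monotone
transform cannot change their AUC.

## Prognosis (`cfomics.prognosis`)

The MPS is the dot product of L1-penalized Cox coefficients with the
sample's selected DMR βs. The penalty path comes from a lasso Cox
(coordinate-descent path); by default the chosen penalty is the path
point whose active set is closest to `target_features` (12, matching the
size of the published signature), because cross-validated penalties on
small cohorts give unstable selected-set sizes; `mode="cv"` (k-fold
concordance along the path) and a fixed alpha are available.

Risk grouping is strict: high iff wSUMAF > 0 **and** MPS > the
training-set median (boundary values fall low). Train/test splitting is
70/30 stratified by event status with a fixed seed. Kaplan–Meier curves
and the log-rank test follow the standard product-limit and
observed-minus-expected/hypergeometric-variance constructions (verified
against a hand-built risk-set-table oracle); nested continuous models
are compared by refitting both unpenalized Cox models (Efron tie
handling) and reporting Harrell's concordance per model plus the
likelihood-ratio chi-squared with df = covariate difference. Concordance
is used as the discrimination measure for continuous survival models;
survival-ROC variants would need a time horizon the data do not fix.

## The synthetic-data generator (`cfomics.synth`)

The generator's defaults encode the cohort structure the analyses
assume: 128 LC / 94 BLN participants; 68% / 42% of samples carrying ≥ 1
cfDNA variant; per-positive variant counts Poisson(2) truncated ≥ 1;
AFs log10-normal (mean −2.886, sd 0.55) truncated to [0.03%, 6%], giving
a median near 0.13%; 20.7% / 39.1% of variants WBC-shared, with WBC AF =
cfDNA AF × 10^N(0, 0.2) so the compartments correlate strongly on log
scale; 35% of variants hotspot-flagged; CEA normal with means 4.5 / 3.5
ng/mL and sd 3 (a deliberately modest shift — marginal t-tests at this
effect size are expected). Stage and smoking columns follow the
clinicopathological distribution of such cohorts.

Methylation: 250 regions of 200 bp with 10 CpGs each; 40 hyper and 3
hypo planted DMRs (the ~13:1 hyper:hypo ratio typical of tumor tissue,
scaled down); tissue Δβ = 0.3 between 25 tumor/NAT pairs with
beta-distributed sample noise (precision 60) and Poisson(30) per-CpG
coverage; plasma carries the tissue signal attenuated by 0.5 and further
scaled per LC sample by a Gamma(2, 0.5) weight (mean 1, capped at
1/attenuation) modelling heterogeneous circulating-tumor-DNA fraction;
5% of region×sample entries drop out. Survival is exponential
proportional hazards: rate = `baseline_rate`·exp(β_mut·mut + β_mps·mps),
administratively censored (defaults 0.02/month, censoring at 60 months).

What the generator does **not** emulate: real sequence context (UMI
collisions, strand bias, indels), copy number, stage- or
histology-dependent effect sizes, correlated CpGs within regions,
batch effects, or the heavy overlap between LC and BLN plasma
methylomes seen in practice. The planted plasma signal, even with
per-sample tumor-fraction weights, remains far cleaner than real cfDNA:
synthetic diagnostic AUCs land near 0.98 where real cohorts report
0.7–0.8. Passing tests therefore demonstrate correctness of the
machinery (partitions, scores, FDR control, leakage-free CV, calibrated
type-I error, parameter recovery) — not clinical performance.

## Problem sizes and tolerances

Simulation-based checks run at sizes chosen to keep the full suite in a
few minutes while leaving comfortable statistical margins: planted-DMR
recovery at 25 pairs × 250 regions × 20 seeds (sensitivity ≥ 0.9,
observed FDR ≤ 0.1); null-classifier calibration at 200 samples × 10
seeds (mean AUC within 0.5 ± 0.07); log-rank type-I error at 500
replicates of n = 60 (0.05 ± 0.02); Cox coefficient CI coverage at 100
replicates of n = 300 (≥ 90%); DeLong variance against an explicit
placement-value enumeration to 1e-8; AUC against pair counting to 1e-12
on inputs ≤ 30 samples. Distinct generator streams are always seeded
with distinct offsets — reusing one integer seed across two generators
correlates their variates and visibly distorts null calibration.
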