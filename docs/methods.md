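# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical conventions used where the
procedure leaves room for choice.

## Data model and preprocessing

An omics layer is a molecule × sample matrix of non-negative abundances
with missing measurements encoded as zero. Three encodings (`""`, `NA`,
`NaN`) all map to 0 on read, giving one canonical sparse representation.
The clinical table fixes the sample order for every matrix, which removes
any chance of silent column misalignment between layers.

Rows in which more than half of the samples are zero are removed before
any analysis (at 49 samples: 25 zeros removed, 24 kept). Zeros that
survive the filter participate in all row statistics — they are data
(below detection limit), not holes. Two row normalizations follow, each
tied to a downstream analysis: min–max scaling for differential analysis
(fold changes of group means stay interpretable on a common [0, 1] row
scale) and z-scoring for clustering (rows from different layers become
commensurable). Row SD uses the sample (n − 1) denominator. Constant rows
break both formulas and carry no contrast; they are dropped with a
warning rather than zero-filled.

## Differential molecules

Each disease group (n = 7) is compared with the healthy group (n = 7) by
the two-group Kruskal–Wallis rank-sum test: tie-corrected H referred to
χ²(1). A molecule is differential when p < 0.05 and |log₂ FC| > 1, with
FC the ratio of group means on the min–max scale (a raw-scale FC exists
behind a flag). No multiple-testing correction is applied by default —
the fixed joint threshold *is* the decision rule — but Benjamini–Hochberg
is available (`correction="bh"`). When the healthy mean is zero the fold
change is undefined; such molecules are excluded from DEM status with a
logged count rather than silently given a value.

A note on small-sample calibration: at n = 4 + 4 the χ²(1) reference
differs from the exact permutation distribution of H by up to ~0.1 in
p in the mid-range (enumerable: 70 splits). The test suite checks the
implementation against permutation oracles at both n = 4 + 4 (ordering
plus agreement within the approximation's known accuracy in the reported
range) and n = 30 + 30 (agreement within Monte-Carlo error). Users drawing
conclusions at n = 7 + 7 should treat p-values near the threshold as
approximate — as is inherent to the rank test with a χ² reference at this
size.

## Two-step stratification

**Feature selection.** For each layer and each basic disease (two key
factors per disease: BMI/WaistCir for obesity, FPG/OGTT-2hPG for
hyperglycemia, SBP/DBP for hypertension, TG/HDL for hyperlipidemia),
molecules are ranked by |Spearman ρ| separately per factor; a molecule
qualifies only if it ranks in the top 30% for *both* factors
(rank ≤ ⌊0.3·n⌋, ties by minimum rank), and at most 50 qualify per
(layer, disease), kept by mean |ρ|. The cap is applied per (layer,
disease) — the selection is repeated per layer and per disease and the
results merged — this is configurable, as is the 30% fraction. The union
across layers and diseases, on the z-score scale, is the merged matrix
M_r.

**Consensus clustering.** 1000 resamples (configurable), each drawing 80%
of samples without replacement; average-linkage hierarchical clustering
on the 1 − Pearson distance between sample columns of M_r, cut at
k_final = 7 (k_max = 10 bounds the admissible k). The consensus entry for
a sample pair is co-clustered/co-sampled counts; final labels come from
average-linkage clustering of 1 − consensus at k_final, relabelled
C1..C7 by decreasing size (ties by first sample) for determinism. 1000 ×
80% resamples make a never-co-sampled pair essentially impossible; if it
happens the run aborts with advice to raise `reps` rather than emitting
an undefined entry.

**Diagnostics.** Silhouette widths use the same 1 − Pearson distance;
singleton clusters get width 0 by convention. Cluster-vs-disease
enrichment is the one-sided (greater) hypergeometric tail — identical to
a one-sided Fisher exact test — computed by exact integer arithmetic, one
implementation shared with pathway over-representation.

**Second step.** Clusters of at least `min_cluster_size = 4` samples
(excluding the small tail clusters) are summarized by the mean of every
clinical factor; factors are ranked by the SD of those means and the top
half retained. SD is taken on the raw factor scale by default — this
follows the stated procedure most literally, but it weights factors with
large units more heavily, so a coefficient-of-variation option
(`sd_scale="cv"`) is provided. Retained mean profiles are z-scored across
clusters and clustered with average linkage on euclidean distance; the
dendrogram cut at `n_groups = 3` proposes the merge map, and
`merge_groups` applies any user-edited partition. Samples in excluded
small clusters remain unlabeled and are counted.

One linkage (average) is used for the inner, final and second-step
clusterings — a single consistent default, each configurable.

## Group characterization

One-vs-rest contrasts use the two-sided Wilcoxon rank-sum test (exact
where sample sizes permit, tie-corrected normal approximation otherwise)
and log₂ of the ratio of group means; molecular fold changes are computed
on the min–max scale, whose non-negative rows keep the ratio defined
(the rank-sum p is unaffected by the choice of row-monotone scale).
Random-forest importances are mean-decrease-impurity from 1000 trees with
√p candidate features per split, seeded. Classification performance uses
leave-one-out evaluation of a linear-kernel SVM (C = 1): each sample is
held out exactly once, the one-vs-rest decision scores of the held-out
samples are pooled, and per-class ROC curves are macro-averaged into one
AUC (micro-averaging available). Leave-one-out is known to be
pessimistically biased under the null at very small n with strongly
clustered features (the held-out sample's class is underrepresented in
training); at the cohort scale this bias is small, and the null AUC sits
near 0.5.

## Heterogeneous networks

Only pairs from different layers are tested. The biweight midcorrelation
uses Tukey weights (1 − u²)² for |u| < 1 with u = (x − med)/(9·MAD), MAD
unscaled; a variable with zero MAD (possible at n = 7–22 group sizes,
especially with censored zeros) falls back to Pearson weighting for that
variable, with a warning — the per-variable fallback standard in robust
correlation practice. Two-sided Student p-values use
t = r·√((n−2)/(1−r²)) with df = n − 2; |r| = 1 is reported as the p = 0
limit. Edges need |r| > 0.6 and p < 0.01 in at least one final group (no
multiplicity adjustment — the fixed joint threshold is the rule); the
union network records per-group coefficients, pass flags and signs, and
overlap summaries report node/edge intersections, unions and Jaccard
indices per group pair. Groups below n = 4 are excluded with a warning.

## Pathway activity scores

Per sample and omics source, molecules are ranked descending by z-scored
value and the unweighted (classic KS) running-sum statistic is computed
for each pathway with ≥ 3 members in the profile: +1/m at a hit,
−1/(N−m) at a miss, ES the deviation of maximal magnitude. Significance
is a two-sided permutation tail over random member sets of the same size,
p = (1 + #{|ES*| ≥ |ES|})/(nperm + 1), nperm = 1000 by default.
Sample-label permutation is impossible for a per-sample score, so
molecule-label (gene-set) permutation is the null. Because the unweighted
statistic of a random set depends only on (N, m), null distributions are
cached per (N, m) with a generator derived deterministically from the
seed and the key, making scores independent of evaluation order. The
statistic lies on a rational lattice, so exact null ties occur; they are
counted as ≥ with a tolerance far below the lattice spacing. The signed
score is GS = −log₁₀(p) if ES > 0 (up-regulated) and +log₁₀(p) if
ES < 0; p = 1 maps to 0 under both branches, and an exact tie between the
up- and down-deviations (direction genuinely ambiguous) is reported with
the positive branch. Peptide profiles are first aggregated to source
proteins (mean per sample; median available), dropping unannotated
peptides with a count and warning below 80% coverage.

Group contrasts of pathway scores rank pathways by forest importance,
keep the top half (display cap 30), subtract each pathway's minimum score
(making all values non-negative) and report one-vs-rest rank-sum p and
log₂ fold changes.

## Synthetic cohorts

The generator emulates the study design end-to-end: 49 samples in seven
disease groups of seven (healthy a through T2D g), three log-normal omics
layers (300 metabolites, 400 proteins, 200 peptides), a clinical panel of
the 8 key factors plus an extended panel (LDL, ApoB, TCH, GPT, GOT,
fasting and 0.5 h postprandial insulin, HOMA1 indices), and a latent
three-group structure: G1 favorable baseline; G2 dyslipidemia-like (lipid
metabolite block and TG/LDL/ApoB/TCH/WaistCir up, an LCAT-like protein
block down); G3 glucose-dysregulated (FPG up, 0.5 h insulin down, an
immune-peptide block and, weakly, its source proteins up). Disease labels
map to latent groups stochastically (all MTS → G2, T2D mostly → G3,
hypertension mostly → G1), mirroring the observed disease-to-group flows.

Mechanics and the reasoning behind the defaults:

* **Latent severity axes.** Each sample carries lipid, glucose and
  blood-pressure severities; the first two are shifted by
  δ_lipid = δ_gluc = 3 (in units of the log-scale noise SD σ = 1) in
  their group, with within-group SD 0.6 — discrete subtypes with moderate
  internal spread. Planted molecules load their axis with coefficient 1,
  so the realized group shift of a planted molecule is 3σ on the log
  scale. Clinical factors load the axes too (e.g. TG, FPG with
  coefficient 1 in factor-SD units), which is what makes planted
  molecules and their key factor correlated (mean |Spearman ρ| ≈ 0.5–0.7
  at defaults) and lets the clinically guided selection find them.
* **Block sizes.** 60 lipid metabolites (20% of the metabolome — lipid
  species are a large share of serum profiles), 30 LCAT-like proteins,
  48 immune peptides mapping 2:1 onto 24 measured source proteins, and a
  15-protein blood-pressure block with no group shift (so hypertension's
  key factors have molecular correlates without touching the latent
  groups).
* **Clinical realism.** Factor baselines are healthy-reference means/SDs
  in clinical units; additive disease shifts are sized so group means
  respect the diagnostic criteria (waist ≥ 85/90 cm, FPG ≥ 6.1/7 mmol/L,
  2hPG ≥ 7.8/11.1 mmol/L, BP ≥ 130/85 mmHg, TG > 1.7 or HDL < 1.04
  mmol/L; MTS meets three or more). HOMA1 indices are computed, not
  sampled.
* **Missingness.** Zeros are per-row left-censoring of the lowest values
  (detection-limit missingness, the dominant MS mechanism), with per-row
  censored fractions uniform on [0, 2 × 0.2] and capped at half the
  samples so the sparsity filter keeps every simulated molecule.
  Censoring, unlike random zeroing, preserves the rank structure that the
  Spearman-based selection and the rank tests rely on — as real
  below-LOD missingness does.

What the generator does **not** emulate: instrument batch effects and QC
drift, correlated background (non-planted molecules are independent
noise), peptide-level missingness that differs from other layers,
non-log-normal heavy tails, and any real biochemical identity of the
molecules. Passing tests therefore demonstrate that the pipeline recovers
planted structure of realistic size and sign under clean conditions —
they do not certify performance on data with batch structure or
correlated confounding.

With zero effect sizes the planted blocks are exactly null (their latent
axes lose the group shift but remain shared), which is what the type-I
checks use; a config that asserts a positive expected planted correlation
while setting both effects to zero is rejected as inconsistent.

## Numerical conventions and determinism

All randomness flows from `numpy.random.default_rng` seeded per stage;
cluster labels and group names are assigned by deterministic rules (size,
then first occurrence; dendrogram groups by smallest member cluster), so
a fixed seed reproduces every output byte-for-byte across the whole CLI
chain. Enrichment p-values are exact integer tail sums (float only at the
final division). Spearman correlations are computed by rank-transforming
both sides once and using matrix products. Degenerate cases are explicit:
constant rows dropped, zero MAD → Pearson fallback, |r| = 1 → p = 0
limit, GSEA overlap < 3 → score missing and logged, HOMA1 %B undefined at
FPG ≤ 3.5 → NaN with warning.

## Problem sizes used in tests

The suite runs the full default cohort (49 samples, 900 molecules) for
end-to-end checks; statistical property tests use reduced layers (tens of
molecules) and 100–500 resamples/permutations, chosen so each property is
measured with comfortable margin at interactive runtimes. The acceptance
script runs the complete default pipeline (1000 consensus resamples, 1000
GSEA permutations) in well under a minute.

## Known limitations

* DEM p-values at n = 7 + 7 inherit the χ² approximation of the rank
  test (see above); exact permutation p-values are not implemented.
* The second-step factor ranking on raw SDs favors large-unit factors;
  prefer `sd_scale="cv"` when factor units are heterogeneous.
* The LOOCV AUC is slightly pessimistic under the null at small n.
* Network p-values and DEM calls are intentionally not multiplicity
  corrected (fixed-threshold decision rules); interpret single-edge
  significance accordingly.
* The pathway score's permutation null treats molecules as exchangeable
  within a profile; correlated molecule blocks make the null slightly
  liberal for pathways overlapping them.
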