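# metastrat

Multi-omics stratification of metabolic-disease cohorts.

Metabolic diseases — obesity, hyperglycemia, hypertension, hyperlipidemia,
metabolic syndrome (MTS) and type 2 diabetes (T2D) — overlap heavily at the
molecular level, and patients carrying the same diagnosis can have very
different serum profiles. `metastrat` implements a complete analysis
pipeline that integrates three omics layers (metabolomics, proteomics,
peptidomics) with routine clinical chemistry to (1) call differential
molecules per disease against healthy controls, (2) re-stratify the cohort
into molecularly and clinically coherent groups by a clinically guided
two-step consensus clustering, and (3) characterize the resulting groups
by univariate contrasts, random-forest importance, leave-one-out SVM
classification, group-conditional heterogeneous correlation networks and
per-sample pathway activity scores. A synthetic cohort generator emulating
the 49-sample, seven-disease study design makes every stage testable
without access to patient data.

It is aimed at computational biologists working with molecule × sample
abundance matrices (TSV), a clinical table (CSV) and GMT pathway sets.

## The method

**Preprocessing.** Rows (molecules) with more than half of samples zero
are removed. For differential analysis rows are min–max scaled,
x′ᵢⱼ = (xᵢⱼ − minᵢ)/(maxᵢ − minᵢ); for clustering they are standardized,
Z(xᵢⱼ) = (xᵢⱼ − mᵢ)/sdᵢ.

**Differential molecules (DEMs).** Each disease group is compared to the
healthy group with the Kruskal–Wallis rank-sum test; fold changes are
ratios of group means. A molecule is a DEM when p < 0.05 and
|log₂ FC| > 1. DEM sets are partitioned into disease-specific and shared
components.

**Two-step stratification.** Per omics layer and per basic disease, each
molecule is ranked by |Spearman ρ| against the disease's two key clinical
factors (BMI/WaistCir, FPG/2hPG, SBP/DBP, TG/HDL); molecules in the top
30% of *both* rankings (at most 50, by mean |ρ|) form the merged matrix
M_r. Samples are consensus-clustered over M_r (repeated 80% subsampling,
hierarchical clustering on 1 − Pearson distance, k = 7); cluster quality
is diagnosed by silhouette widths and one-sided Fisher (hypergeometric)
enrichment of clusters in the original diseases. Clusters of n ≥ 4 are
then described by their mean clinical-factor values, the top half of
factors by SD is retained, and hierarchical clustering of these profiles
merges the clusters into three final groups G1–G3.

**Group characterization.** One-vs-rest Wilcoxon rank-sum contrasts
(two-sided) with log₂ fold changes; mean-decrease-impurity importances
from a 1000-tree random forest; leave-one-out linear-SVM classification
with one-vs-rest macro-averaged ROC/AUC per feature set.

**Networks.** Within each final group, every heterogeneous molecule pair
(metabolite–protein, protein–peptide, metabolite–peptide) from M_r is
scored by the biweight midcorrelation (Tukey biweights around the median,
u = (x − med)/(9·MAD)) with Student t p-values,
t = r·√((n−2)/(1−r²)); pairs with |r| > 0.6 and p < 0.01 in any group form
the union network, tagged by the groups in which they hold.

**Pathway activity.** For each sample and omics source, molecules are
ranked by z-scored abundance and an unweighted KS-type running-sum
statistic (GSEA) asks whether a pathway's members concentrate at the top
or bottom of the list; significance comes from permuting molecule labels,
and the signed score is GS = −log₁₀(p) for up-regulation and +log₁₀(p)
for down-regulation. Peptides enter through their source proteins. A
HOMA1 calculator (IR = G·I/22.5, %B = 20·I/(G − 3.5)) completes the
clinical panel.

## Worked example

```python
import metastrat as ms

mats, clinical, design = ms.generate_cohort(ms.SimulationConfig(seed=1))
model = ms.StratificationModel(mats, clinical, design)
results = model.fit(seed=1)
print(results.summary())
```

```
Two-step multi-omics stratification
======================================
samples: 49   selected molecules (M_r): 361
  metabolite: 128, peptide: 95, protein: 138

first-step clusters (consensus, k=7, reps=1000):
  C1: n=17  mean silhouette=+0.108  top enrichment: MTS (p=4.84e-03)
  C2: n=13  mean silhouette=+0.016  top enrichment: healthy (p=1.02e-02)
  C3: n= 9  mean silhouette=+0.125  top enrichment: T2D (p=1.18e-03)
  C4: n= 5  mean silhouette=+0.063  top enrichment: healthy (p=1.43e-01)
  C5: n= 2  mean silhouette=+0.123  top enrichment: obesity (p=1.79e-02)
  C6: n= 2  mean silhouette=+0.059  top enrichment: obesity (p=2.68e-01)
  C7: n= 1  mean silhouette=+0.000  top enrichment: hypertension (p=1.43e-01)

final groups (second-step merge of cluster clinical means):
  G1 = C1: n=17
  G2 = C2+C4: n=18
  G3 = C3: n=9
  excluded (small clusters C5+C6+C7): n=5
ARI vs planted latent groups: 0.863
```

The fitted cohort is re-stratified into three groups: a group dominated by
the MTS-like dyslipidemia subtype (here C1), a favorable group and a
glucose-dysregulated, T2D-enriched group; the adjusted Rand index of
0.863 measures agreement with the latent groups the generator planted.
Downstream analyses hang off the results object
(`results.characterize_clinical()`, `results.build_networks()`,
`results.pathway_scores(db)`), and

```python
ir, beta = ms.homa1(fpg=6.1, fpi=12.0)   # -> IR = 3.25, %B = 92.3
```

computes the HOMA1 indices from fasting glucose (mmol/L) and insulin
(µU/mL).

The same pipeline runs from the shell on plain-text files:

```sh
metastrat simulate   --seed 1 --out run/
metastrat dems       --cohort run/ --seed 1 --out run/
metastrat stratify   --cohort run/ --seed 1 --out run/
metastrat characterize --cohort run/ --seed 1 --out run/
metastrat network    --cohort run/ --seed 1 --out run/
metastrat pathways   --cohort run/ --seed 1 --out run/
```

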