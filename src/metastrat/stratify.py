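"""Clinically guided two-step stratification of a multi-omics cohort.

This is the analytical core of the package.  The procedure:

1. **Feature selection** — per omics layer and per basic disease, rank all
   molecules by the absolute Spearman correlation with each of the
   disease's two key clinical factors; keep molecules ranking in the top
   30% for *both* factors, capped at the 50 largest mean absolute
   correlations.  The union over layers and diseases forms the merged,
   z-scored matrix ``M_r``.
2. **First-step consensus clustering** — repeated subsampling of samples,
   hierarchical clustering on the 1 − Pearson distance over ``M_r``
   columns at the final cluster number (7); the consensus matrix entry for
   a sample pair is its co-clustering frequency among resamples containing
   both.  Final cluster labels come from hierarchical clustering of
   1 − consensus.  Cluster quality is summarized by silhouette widths and
   by one-sided Fisher (hypergeometric) enrichment of each cluster in each
   original disease.
3. **Second-step clustering** — clusters of at least ``min_cluster_size``
   samples are described by their mean clinical-factor values; factors are
   ranked by SD across cluster means and the top half retained; the
   cluster-mean profiles are hierarchically clustered and cut into the
   final groups (3), each final group a union of first-step clusters.

:class:`StratificationModel` wraps the whole procedure statsmodels-style:
build it from cohort data, call :meth:`~StratificationModel.fit`, and the
returned :class:`StratificationResults` carries labels, the consensus
matrix, diagnostics and a :meth:`~StratificationResults.summary` table,
with characterization, network and pathway analyses hanging off it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from ._stats import hypergeom_tail
from .data import (DISEASES, ClinicalTable, CohortDesign, KeyFactorMap,
                   OmicsMatrix)
from .preprocess import NormalizedMatrix, preprocess_all

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def spearman_molecule_factor(values: pd.DataFrame, factors: pd.DataFrame
                             ) -> pd.DataFrame:
    """Spearman rho between every molecule row and every clinical factor."""
    x = np.apply_along_axis(rankdata, 1, values.to_numpy())
    y = np.apply_along_axis(rankdata, 0, factors.to_numpy())
    x = (x - x.mean(axis=1, keepdims=True))
    y = (y - y.mean(axis=0, keepdims=True))
    xn = np.linalg.norm(x, axis=1)
    yn = np.linalg.norm(y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (x @ y) / np.outer(xn, yn)
    return pd.DataFrame(rho, index=values.index, columns=factors.columns)


@dataclass
class FeatureSelection:
    """Ranked correlation table plus the merged clustering matrix M_r."""

    table: pd.DataFrame      # per (layer, disease, molecule) ranking record
    m_r: pd.DataFrame        # MultiIndex (layer, molecule_id) x samples, zscore

    def selected(self, layer: str | None = None,
                 disease: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["selected"]]
        if layer is not None:
            t = t[t["layer"] == layer]
        if disease is not None:
            t = t[t["disease"] == disease]
        return t


def select_clinical_relevant(zmats: dict[str, NormalizedMatrix],
                             clinical: ClinicalTable,
                             key_factor_map: KeyFactorMap | None = None,
                             top_frac: float = 0.3,
                             max_selected: int = 50) -> FeatureSelection:
    """Select key-clinical-factor-relevant molecules and build ``M_r``.

    Per (layer, disease): molecules must rank within the top ``top_frac``
    of |rho| for *both* of that disease's key factors; if more than
    ``max_selected`` qualify, the ``max_selected`` largest mean |rho| win.
    """
    key_factor_map = key_factor_map or KeyFactorMap()
    records = []
    selected_by_layer: dict[str, set[str]] = {layer: set() for layer in zmats}
    for layer, norm in zmats.items():
        if norm.data.shape[0] < 10:
            raise ValueError(f"layer {layer} has <10 molecules after filtering")
        factors = clinical.data.loc[norm.sample_ids]
        rho = spearman_molecule_factor(norm.data, factors)
        n = rho.shape[0]
        cutoff = int(np.floor(top_frac * n + 1e-9))
        for disease, (f1, f2) in key_factor_map.items():
            a1, a2 = rho[f1].abs(), rho[f2].abs()
            rank1 = a1.rank(ascending=False, method="min")
            rank2 = a2.rank(ascending=False, method="min")
            mean_abs = (a1 + a2) / 2.0
            qualifies = (rank1 <= cutoff) & (rank2 <= cutoff)
            qualified = pd.DataFrame({
                "mean_abs_rho": mean_abs[qualifies],
            }).sort_values(["mean_abs_rho"], ascending=False)
            keep = set(qualified.index[:max_selected]) if len(qualified) \
                else set()
            if not keep:
                logger.warning("select_clinical_relevant: no survivors for "
                               "layer=%s disease=%s", layer, disease)
            selected_by_layer[layer] |= keep
            for mol in rho.index:
                records.append((layer, disease, mol,
                                rho.loc[mol, f1], rho.loc[mol, f2],
                                int(rank1[mol]), int(rank2[mol]),
                                mean_abs[mol], mol in keep))
    table = pd.DataFrame(records, columns=[
        "layer", "disease", "molecule_id", "rho_f1", "rho_f2",
        "rank_f1", "rank_f2", "mean_abs_rho", "selected"])

    blocks = []
    for layer, norm in zmats.items():
        mols = sorted(selected_by_layer[layer])
        if not mols:
            continue
        block = norm.data.loc[mols].copy()
        block.index = pd.MultiIndex.from_product(
            [[layer], block.index], names=["layer", "molecule_id"])
        blocks.append(block)
    if not blocks:
        raise ValueError("no molecules selected in any layer")
    m_r = pd.concat(blocks)
    return FeatureSelection(table=table, m_r=m_r)


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def pearson_distance(samples: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns."""
    corr = np.corrcoef(samples.to_numpy().T)
    return pd.DataFrame(1.0 - corr, index=samples.columns,
                        columns=samples.columns)


def _hier_labels(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    z = scipy_linkage(condensed, method=method)
    return fcluster(z, t=k, criterion="maxclust")


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw cluster ids to 1..k in decreasing size (ties: first sample)."""
    order = sorted(set(raw),
                   key=lambda c: (-int(np.sum(raw == c)),
                                  int(np.argmax(raw == c))))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame            # sample x sample co-clustering frequency
    labels: pd.Series                  # sample -> "C1".."Ck"
    k_final: int
    reps: int
    subsample_frac: float
    linkage: str


def consensus_cluster(m_r: pd.DataFrame, k_final: int = 7, k_max: int = 10,
                      reps: int = 1000, subsample_frac: float = 0.8,
                      linkage: str = "average",
                      seed: int = 0) -> ConsensusResult:
    """Consensus clustering of samples over the merged matrix ``M_r``.

    Each resample draws ``subsample_frac`` of the samples without
    replacement and hierarchically clusters them at ``k_final`` on the
    1 - Pearson distance.  ``consensus[i, j]`` is the fraction of resamples
    containing both i and j in which they co-clustered.  Final labels come
    from hierarchical clustering of 1 - consensus at ``k_final``.
    ``k_max`` bounds the admissible ``k_final`` (the cluster-number scan
    ceiling); raises if a sample pair is never co-sampled.
    """
    n = m_r.shape[1]
    if not 2 <= k_final <= min(k_max, n):
        raise ValueError(f"k_final={k_final} outside [2, min(k_max={k_max}, n={n})]")
    rng = np.random.default_rng(seed)
    m = max(k_final, int(round(subsample_frac * n)))
    values = m_r.to_numpy()
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = values[:, idx]
        dist = 1.0 - np.corrcoef(sub.T)
        lab = _hier_labels(dist, k_final, linkage)
        same = (lab[:, None] == lab[None, :]).astype(float)
        together[np.ix_(idx, idx)] += same
        co_sampled[np.ix_(idx, idx)] += 1.0
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(co_sampled[off_diag] == 0):
        raise ValueError("some sample pair was never co-sampled; "
                         "increase reps or subsample_frac")
    with np.errstate(invalid="ignore"):
        consensus = together / co_sampled
    np.fill_diagonal(consensus, 1.0)
    final = _hier_labels(1.0 - consensus, k_final, linkage)
    final = _relabel_by_size(final)
    labels = pd.Series([f"C{c}" for c in final], index=m_r.columns,
                       name="cluster")
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=m_r.columns,
                               columns=m_r.columns),
        labels=labels, k_final=k_final, reps=reps,
        subsample_frac=subsample_frac, linkage=linkage)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def silhouette_widths(labels: pd.Series, dist: pd.DataFrame
                      ) -> tuple[pd.Series, pd.Series]:
    """Per-sample silhouette widths and per-cluster means.

    ``s(i) = (b - a) / max(a, b)`` with a = mean distance to own cluster,
    b = smallest mean distance to another cluster.  Samples in singleton
    clusters get width 0 by convention.
    """
    clusters = labels.unique()
    if len(clusters) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    d = dist.loc[labels.index, labels.index].to_numpy()
    lab = labels.to_numpy()
    widths = np.zeros(len(lab))
    for i in range(len(lab)):
        own = lab == lab[i]
        if own.sum() == 1:
            widths[i] = 0.0
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, lab == c].mean() for c in clusters if c != lab[i])
        widths[i] = (b - a) / max(a, b)
    per_sample = pd.Series(widths, index=labels.index, name="silhouette")
    per_cluster = per_sample.groupby(labels).mean().rename("mean_silhouette")
    return per_sample, per_cluster


def cluster_disease_enrichment(labels: pd.Series, design: CohortDesign
                               ) -> pd.DataFrame:
    """One-sided hypergeometric enrichment p per (cluster, disease)."""
    common = labels.index.intersection(design.sample_ids)
    lab = labels.loc[common]
    dis = design.disease.loc[common]
    n_total = len(common)
    clusters = sorted(lab.unique(), key=lambda c: (len(c), c))
    diseases = sorted(dis.unique())
    out = pd.DataFrame(index=clusters, columns=diseases, dtype=float)
    for c in clusters:
        in_c = lab == c
        for d in diseases:
            in_d = dis == d
            out.loc[c, d] = hypergeom_tail(
                int((in_c & in_d).sum()), int(in_d.sum()),
                int(in_c.sum()), n_total)
    out.index.name = "cluster"
    out.columns.name = "disease"
    return out


# ---------------------------------------------------------------------------
# second-step clustering and merging
# ---------------------------------------------------------------------------

@dataclass
class SecondStepResult:
    cluster_means: pd.DataFrame        # eligible cluster x all factors
    retained_factors: list[str]
    profile: pd.DataFrame              # cluster x retained factors, z across clusters
    linkage_matrix: np.ndarray
    eligible: list[str]
    excluded: list[str]
    linkage: str

    def propose_merge(self, n_groups: int = 3) -> dict[str, list[str]]:
        """Cut the dendrogram into ``n_groups`` final groups G1..Gk."""
        if not 1 <= n_groups <= len(self.eligible):
            raise ValueError(f"n_groups={n_groups} not in [1, {len(self.eligible)}]")
        cut = fcluster(self.linkage_matrix, t=n_groups, criterion="maxclust")
        parts: dict[int, list[str]] = {}
        for cluster, g in zip(self.eligible, cut):
            parts.setdefault(int(g), []).append(cluster)
        ordered = sorted(parts.values(), key=lambda cs: min(cs))
        return {f"G{i + 1}": sorted(cs) for i, cs in enumerate(ordered)}


def second_step_cluster(labels: pd.Series, clinical: ClinicalTable,
                        min_cluster_size: int = 4, top_frac: float = 0.5,
                        sd_scale: str = "raw",
                        linkage: str = "average") -> SecondStepResult:
    """Cluster the first-step clusters on their mean clinical profiles.

    Clusters below ``min_cluster_size`` are excluded.  Factors are ranked
    by the SD of their per-cluster means — on the raw scale by default,
    or by coefficient of variation with ``sd_scale="cv"`` — and the top
    ``top_frac`` retained; retained mean profiles are z-scored across
    clusters and hierarchically clustered (euclidean distance).
    """
    sizes = labels.value_counts()
    eligible = sorted(sizes.index[sizes >= min_cluster_size],
                      key=lambda c: (len(c), c))
    excluded = sorted(sizes.index[sizes < min_cluster_size],
                      key=lambda c: (len(c), c))
    if len(eligible) < 2:
        raise ValueError(f"need >= 2 clusters of size >= {min_cluster_size}; "
                         f"have {len(eligible)}")
    factors = clinical.data.loc[labels.index]
    means = factors.groupby(labels).mean().loc[eligible]

    sd = means.std(axis=0, ddof=1)
    if sd_scale == "cv":
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = sd / means.mean(axis=0).abs()
    elif sd_scale != "raw":
        raise ValueError(f"unknown sd_scale {sd_scale!r}")
    sd = sd.replace([np.inf, -np.inf], np.nan).dropna()
    n_keep = int(np.floor(top_frac * len(sd) + 1e-9))
    retained = sd.sort_values(ascending=False).index[:n_keep].tolist()

    profile = means[retained]
    col_sd = profile.std(axis=0, ddof=1)
    usable = col_sd.index[col_sd > 0]
    z = (profile[usable] - profile[usable].mean(axis=0)) / col_sd[usable]
    lm = scipy_linkage(z.to_numpy(), method=linkage, metric="euclidean")
    return SecondStepResult(cluster_means=means, retained_factors=retained,
                            profile=z, linkage_matrix=lm, eligible=eligible,
                            excluded=excluded, linkage=linkage)


def merge_groups(labels: pd.Series, merge_map: dict[str, list[str]]
                 ) -> pd.Series:
    """Apply a cluster -> final-group partition to the sample labels.

    ``merge_map`` maps each final group name to a disjoint set of first-step
    clusters; samples in clusters outside the map are left unlabeled (NA).
    """
    seen: dict[str, str] = {}
    for g, clusters in merge_map.items():
        for c in clusters:
            if c in seen:
                raise ValueError(f"cluster {c} assigned to both {seen[c]} and {g}")
            seen[c] = g
    out = labels.map(seen).astype("object")
    out.name = "group"
    n_excluded = int(out.isna().sum())
    if n_excluded:
        logger.info("merge_groups: %d sample(s) in excluded clusters left "
                    "unlabeled", n_excluded)
    return out


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

@dataclass
class StratifyConfig:
    """Tunable parameters of the two-step stratification."""

    top_frac: float = 0.3
    max_selected: int = 50
    k_final: int = 7
    k_max: int = 10
    reps: int = 1000
    subsample_frac: float = 0.8
    linkage: str = "average"
    min_cluster_size: int = 4
    n_groups: int = 3
    second_top_frac: float = 0.5
    sd_scale: str = "raw"


class StratificationModel:
    """Two-step multi-omics stratification model for one cohort.

    Parameters
    ----------
    matrices
        Raw layer -> :class:`OmicsMatrix` (metabolite, protein, peptide).
    clinical
        Clinical table covering every sample; its sample order is enforced.
    design
        Original disease assignment (needed for enrichment diagnostics).
    key_factor_map, config
        Optional overrides of the key-factor pairs and tuning parameters.
    """

    def __init__(self, matrices: dict[str, OmicsMatrix],
                 clinical: ClinicalTable, design: CohortDesign,
                 key_factor_map: KeyFactorMap | None = None,
                 config: StratifyConfig | None = None):
        from .io import align_to_clinical

        self.matrices = align_to_clinical(matrices, clinical)
        self.clinical = clinical
        self.design = design
        self.key_factor_map = key_factor_map or KeyFactorMap()
        self.config = config or StratifyConfig()

    @classmethod
    def from_cohort_dir(cls, path, config: StratifyConfig | None = None
                        ) -> "StratificationModel":
        from .io import load_cohort_dir

        matrices, clinical, design, _db = load_cohort_dir(path)
        return cls(matrices, clinical, design, config=config)

    def fit(self, seed: int = 0) -> "StratificationResults":
        cfg = self.config
        zmats = preprocess_all(self.matrices, "zscore")
        selection = select_clinical_relevant(
            zmats, self.clinical, self.key_factor_map,
            top_frac=cfg.top_frac, max_selected=cfg.max_selected)
        consensus = consensus_cluster(
            selection.m_r, k_final=cfg.k_final, k_max=cfg.k_max,
            reps=cfg.reps, subsample_frac=cfg.subsample_frac,
            linkage=cfg.linkage, seed=seed)
        dist = pearson_distance(selection.m_r)
        sil_samples, sil_clusters = silhouette_widths(consensus.labels, dist)
        enrichment = cluster_disease_enrichment(consensus.labels, self.design)
        second = second_step_cluster(
            consensus.labels, self.clinical,
            min_cluster_size=cfg.min_cluster_size,
            top_frac=cfg.second_top_frac, sd_scale=cfg.sd_scale,
            linkage=cfg.linkage)
        merge_map = second.propose_merge(cfg.n_groups)
        groups = merge_groups(consensus.labels, merge_map)
        return StratificationResults(
            model=self, zmats=zmats, selection=selection, consensus=consensus,
            silhouette_samples=sil_samples, silhouette_clusters=sil_clusters,
            enrichment=enrichment, second_step=second, merge_map=merge_map,
            group_labels=groups, seed=seed)


@dataclass
class StratificationResults:
    """Fitted stratification: labels, consensus matrix and diagnostics."""

    model: StratificationModel
    zmats: dict[str, NormalizedMatrix]
    selection: FeatureSelection
    consensus: ConsensusResult
    silhouette_samples: pd.Series
    silhouette_clusters: pd.Series
    enrichment: pd.DataFrame
    second_step: SecondStepResult
    merge_map: dict[str, list[str]]
    group_labels: pd.Series
    seed: int

    @property
    def first_labels(self) -> pd.Series:
        return self.consensus.labels

    @property
    def m_r(self) -> pd.DataFrame:
        return self.selection.m_r

    def recovery_ari(self) -> float | None:
        """Adjusted Rand index of final groups vs planted truth (synthetic)."""
        truth = self.model.design.true_group
        if truth is None:
            return None
        from sklearn.metrics import adjusted_rand_score

        labeled = self.group_labels.dropna()
        return float(adjusted_rand_score(truth.loc[labeled.index], labeled))

    def summary(self) -> str:
        lines = ["Two-step multi-omics stratification", "=" * 38]
        lines.append(f"samples: {len(self.first_labels)}   "
                     f"selected molecules (M_r): {self.m_r.shape[0]}")
        per_layer = self.m_r.groupby(level="layer").size()
        lines.append("  " + ", ".join(f"{k}: {v}" for k, v in per_layer.items()))
        lines.append("")
        lines.append("first-step clusters (consensus, k="
                     f"{self.consensus.k_final}, reps={self.consensus.reps}):")
        sizes = self.first_labels.value_counts()
        for c in sorted(sizes.index, key=lambda x: (len(x), x)):
            sil = self.silhouette_clusters.get(c, float("nan"))
            best_d = self.enrichment.loc[c].idxmin()
            best_p = self.enrichment.loc[c].min()
            lines.append(f"  {c}: n={sizes[c]:2d}  mean silhouette={sil:+.3f}  "
                         f"top enrichment: {DISEASES[best_d]} (p={best_p:.2e})")
        lines.append("")
        lines.append("final groups (second-step merge of cluster clinical means):")
        gsizes = self.group_labels.value_counts()
        for g in sorted(self.merge_map):
            members = "+".join(self.merge_map[g])
            lines.append(f"  {g} = {members}: n={int(gsizes.get(g, 0))}")
        n_excl = int(self.group_labels.isna().sum())
        if n_excl:
            lines.append(f"  excluded (small clusters "
                         f"{'+'.join(self.second_step.excluded)}): n={n_excl}")
        ari = self.recovery_ari()
        if ari is not None:
            lines.append(f"ARI vs planted latent groups: {ari:.3f}")
        return "\n".join(lines)

    # ---- downstream analyses ------------------------------------------
    def characterize_clinical(self):
        """One-vs-rest clinical contrasts of the final groups."""
        from .characterize import one_vs_rest_contrasts

        labeled = self.group_labels.dropna()
        feats = self.model.clinical.data.loc[labeled.index].T
        return one_vs_rest_contrasts(feats, labeled)

    def characterize_molecular(self, seed: int | None = None):
        """One-vs-rest molecular contrasts + random-forest importances.

        Contrasts (rank-sum p and fold change) are computed on the min-max
        scale, whose non-negative row ranges keep group-mean ratios
        defined; the forest ranks the z-scored profiles.
        """
        from .characterize import one_vs_rest_contrasts, rf_importance

        labeled = self.group_labels.dropna()
        mm = preprocess_all(self.model.matrices, "minmax")
        blocks = []
        for layer in self.zmats:
            if layer not in self.m_r.index.get_level_values("layer"):
                continue
            mols = self.m_r.xs(layer, level="layer").index
            mols = [m for m in mols if m in mm[layer].data.index]
            block = mm[layer].data.loc[mols, labeled.index].copy()
            block.index = [f"{layer}:{m}" for m in block.index]
            blocks.append(block)
        feats_mm = pd.concat(blocks)
        contrasts = one_vs_rest_contrasts(feats_mm, labeled)
        feats_z = self.m_r.loc[:, labeled.index].copy()
        feats_z.index = [f"{l}:{m}" for l, m in feats_z.index]
        importance = rf_importance(feats_z, labeled,
                                   seed=self.seed if seed is None else seed)
        return contrasts, importance

    def build_networks(self, r_threshold: float = 0.6,
                       p_threshold: float = 0.01):
        """Group-conditional heterogeneous correlation networks over M_r."""
        from .network import build_group_networks

        layer_mats = {
            layer: self.zmats[layer].data.loc[
                self.m_r.xs(layer, level="layer").index]
            for layer in self.zmats
            if layer in self.m_r.index.get_level_values("layer")}
        return build_group_networks(layer_mats, self.group_labels.dropna(),
                                    r_threshold=r_threshold,
                                    p_threshold=p_threshold)

    def pathway_scores(self, db, nperm: int = 1000, seed: int | None = None):
        """Per-sample signed pathway activity scores for all three sources."""
        from .pathway import score_all_sources

        return score_all_sources(
            self.zmats, db,
            annotations=self.model.matrices["peptide"].annotations,
            nperm=nperm, seed=self.seed if seed is None else seed)

    # ---- plots ---------------------------------------------------------
    def plot_consensus(self, ax=None):
        from .plotting import plot_consensus

        return plot_consensus(self, ax=ax)

    def plot_silhouette(self, ax=None):
        from .plotting import plot_silhouette

        return plot_silhouette(self, ax=ax)
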