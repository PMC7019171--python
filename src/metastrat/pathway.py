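"""Pathway enrichment and per-sample signed GSEA activity scores.

Two complementary analyses:

* **Over-representation** — one-sided Fisher (hypergeometric) tests of the
  overlap between a molecule set of interest (e.g. network nodes) and each
  pathway's members, run separately for metabolite members and for
  protein/gene members (peptides enter through their source proteins).
  This is the same enrichment primitive used for cluster-vs-disease
  composition, called on a different universe.

* **Per-sample pathway activity** — for every sample, molecules of one
  omics source are ranked by their (z-scored) abundance and an unweighted
  Kolmogorov–Smirnov-style running-sum enrichment statistic asks whether a
  pathway's members concentrate at the top or bottom of that list.
  Significance comes from permuting molecule labels (random member sets of
  the same size); the signed score is ``GS = -log10(p)`` for up-regulated
  pathways and ``GS = +log10(p)`` for down-regulated ones, so the sign of
  GS encodes direction and p = 1 maps to GS = 0 under either branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import hypergeom_tail
from .data import PathwayDB
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def fisher_pathway_enrichment(query: set[str], universe: set[str],
                              db: PathwayDB) -> pd.DataFrame:
    """One-sided enrichment p of ``query`` in each pathway, within ``universe``.

    Pathway members are intersected with the universe first; pathways with
    no member in the universe are skipped.  ``query`` must be a subset of
    ``universe``.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_univ, n_query = len(universe), len(query)
    records = []
    for pid, entry in db:
        members = set(entry["members"]) & universe
        if not members:
            continue
        overlap = len(query & members)
        p = hypergeom_tail(overlap, len(members), n_query, n_univ)
        records.append((pid, entry["name"], entry["category"],
                        len(members), overlap, p))
    return pd.DataFrame(records, columns=[
        "pathway_id", "name", "category", "n_members_in_universe",
        "n_overlap", "p_value"]).set_index("pathway_id")


# ---------------------------------------------------------------------------
# per-sample GSEA score
# ---------------------------------------------------------------------------

def _enrichment_score(positions: np.ndarray, n: int) -> np.ndarray:
    """Signed maximal running-sum deviation for hit positions.

    ``positions``: (n_perm, m) 0-based hit indices (sorted ascending) in a
    ranked list of length ``n``.  Unweighted statistic: +1/m at each hit,
    -1/(n-m) at each miss; returns the deviation of maximal magnitude.
    """
    if positions.ndim == 1:
        positions = positions[None, :]
    m = positions.shape[1]
    i = np.arange(1, m + 1)
    up = i / m - (positions + 1 - i) / (n - m)          # just after hit i
    down = (i - 1) / m - (positions - (i - 1)) / (n - m)  # just before hit i
    es_pos = up.max(axis=1)
    es_neg = down.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


@dataclass
class GseaNullCache:
    """Cached permutation null distributions of |ES|, keyed by (n, m).

    The unweighted enrichment statistic of a random member set depends only
    on the list length and the set size, so one null serves every sample
    and pathway sharing those; each key draws its own deterministic
    generator from ``seed`` so results do not depend on evaluation order.
    """

    nperm: int = 1000
    seed: int = 0
    _cache: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def null_abs_es(self, n: int, m: int) -> np.ndarray:
        key = (n, m)
        if key not in self._cache:
            rng = np.random.default_rng([self.seed, n, m])
            u = rng.random((self.nperm, n))
            positions = np.sort(np.argpartition(u, m, axis=1)[:, :m], axis=1)
            self._cache[key] = np.abs(_enrichment_score(positions, n))
        return self._cache[key]


def gsea_sample_score(profile: pd.Series, members: set[str],
                      nperm: int = 1000, seed: int = 0,
                      cache: GseaNullCache | None = None
                      ) -> tuple[float, float, float]:
    """Signed pathway activity score for one sample profile.

    ``profile`` maps molecule id to its (z-scored) value; the list is
    ranked descending.  Returns ``(es, p, gs)``; raises when fewer than 3
    pathway members appear in the profile.  ``p`` is the two-sided
    permutation tail ``(1 + #{|ES_perm| >= |ES|}) / (nperm + 1)``.
    """
    members_in = [m for m in profile.index if m in members]
    if len(members_in) < 3:
        raise ValueError(f"only {len(members_in)} pathway member(s) in "
                         "profile; need >= 3")
    n = len(profile)
    order = np.argsort(-profile.to_numpy(), kind="stable")
    ranked_ids = profile.index.to_numpy()[order]
    member_mask = np.isin(ranked_ids, list(members))
    positions = np.where(member_mask)[0]
    es = float(_enrichment_score(positions, n)[0])
    if cache is None or cache.nperm != nperm:
        cache = GseaNullCache(nperm=nperm, seed=seed)
    null = cache.null_abs_es(n, len(positions))
    # the unweighted statistic lies on a rational lattice, so exact null
    # ties are common; count them as >= (tolerance well below lattice step)
    p = float((1 + int(np.sum(null >= abs(es) - 1e-12))) / (nperm + 1))
    gs = -np.log10(p) if es > 0 else (np.log10(p) if es < 0 else 0.0)
    return es, p, float(gs)


def map_peptides_to_proteins(matrix: pd.DataFrame,
                             annotations: dict[str, str] | None,
                             agg: str = "mean") -> pd.DataFrame:
    """Relabel a peptide matrix by source protein, aggregating duplicates.

    Multiple peptides of one protein are combined by the mean (or median)
    of their values per sample; unannotated peptides are dropped with a
    logged count, and coverage below 80% triggers a warning.
    """
    if not annotations:
        raise ValueError("peptide annotations are required for "
                         "protein-level mapping")
    annotated = [p for p in matrix.index if p in annotations]
    n_dropped = len(matrix.index) - len(annotated)
    if n_dropped:
        logger.info("map_peptides_to_proteins: dropped %d unannotated "
                    "peptide(s)", n_dropped)
    coverage = len(annotated) / len(matrix.index) if len(matrix.index) else 0
    if coverage < 0.8:
        warnings.warn(f"peptide annotation coverage {coverage:.0%} < 80%",
                      stacklevel=2)
    if agg not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {agg!r}")
    sub = matrix.loc[annotated]
    proteins = pd.Index([annotations[p] for p in annotated], name="protein_id")
    grouped = sub.groupby(proteins)
    out = grouped.mean() if agg == "mean" else grouped.median()
    out.attrs["n_dropped_peptides"] = n_dropped
    return out


@dataclass
class PathwayScoreMatrix:
    """Pathway x sample signed activity scores for one omics source."""

    source: str                     # metabolomics | proteomics | peptidomics
    gs: pd.DataFrame                # signed scores
    p: pd.DataFrame                 # underlying permutation p-values
    es: pd.DataFrame                # enrichment statistics
    skipped: dict[str, str] = field(default_factory=dict)


_SOURCE_LAYER = {"metabolomics": "metabolite", "proteomics": "protein",
                 "peptidomics": "peptide"}


def score_source(norm: NormalizedMatrix, db: PathwayDB, source: str,
                 annotations: dict[str, str] | None = None,
                 nperm: int = 1000, seed: int = 0) -> PathwayScoreMatrix:
    """Score every pathway in every sample for one omics source.

    Peptidomics profiles are first mapped to source proteins.  Pathways
    with fewer than 3 members in the profile are skipped (recorded in
    ``skipped``).
    """
    data = norm.data
    if source == "peptidomics":
        data = map_peptides_to_proteins(data, annotations)
    cache = GseaNullCache(nperm=nperm, seed=seed)
    universe = set(data.index)
    gs_rows, p_rows, es_rows, kept, skipped = [], [], [], [], {}
    for pid, entry in db:
        members = set(entry["members"]) & universe
        if len(members) < 3:
            skipped[pid] = f"{len(members)} member(s) in profile"
            continue
        kept.append(pid)
        gs_row, p_row, es_row = [], [], []
        for sample in data.columns:
            es, p, gs = gsea_sample_score(data[sample], members,
                                          nperm=nperm, seed=seed, cache=cache)
            gs_row.append(gs)
            p_row.append(p)
            es_row.append(es)
        gs_rows.append(gs_row)
        p_rows.append(p_row)
        es_rows.append(es_row)
    if skipped:
        logger.info("score_source[%s]: skipped %d pathway(s): %s", source,
                    len(skipped), dict(list(skipped.items())[:3]))
    cols = data.columns
    return PathwayScoreMatrix(
        source=source,
        gs=pd.DataFrame(gs_rows, index=kept, columns=cols),
        p=pd.DataFrame(p_rows, index=kept, columns=cols),
        es=pd.DataFrame(es_rows, index=kept, columns=cols),
        skipped=skipped)


def score_all_sources(zmats: dict[str, NormalizedMatrix], db: PathwayDB,
                      annotations: dict[str, str] | None = None,
                      nperm: int = 1000, seed: int = 0
                      ) -> dict[str, PathwayScoreMatrix]:
    return {
        source: score_source(zmats[layer], db, source,
                             annotations=annotations, nperm=nperm, seed=seed)
        for source, layer in _SOURCE_LAYER.items()}


# ---------------------------------------------------------------------------
# group contrasts of pathway scores
# ---------------------------------------------------------------------------

def pathway_group_contrasts(scores: PathwayScoreMatrix,
                            group_labels: pd.Series, seed: int = 0,
                            top_frac: float = 0.5, display_cap: int = 30
                            ) -> pd.DataFrame:
    """Top differential pathways between the final groups.

    Pathways are ranked by random-forest importance of their scores in
    predicting the group labels; the top ``top_frac`` (at most
    ``display_cap``) are retained and, for each, one-vs-rest Wilcoxon p and
    the log2 fold change of minimum-subtracted scores are reported.
    Constant-score pathways are skipped.
    """
    from .characterize import one_vs_rest_contrasts, rf_importance

    labeled = group_labels.dropna()
    gs = scores.gs.loc[:, labeled.index]
    variable = gs.index[(gs.max(axis=1) - gs.min(axis=1)) > 0]
    if len(variable) < len(gs):
        logger.info("pathway_group_contrasts: skipped %d constant pathway(s)",
                    len(gs) - len(variable))
    gs = gs.loc[variable]
    if gs.empty:
        raise ValueError("no variable pathway scores")
    importance = rf_importance(gs, labeled, seed=seed)
    n_keep = min(int(np.ceil(top_frac * len(importance))), display_cap)
    top = importance.index[:n_keep]

    shifted = gs.loc[top].sub(gs.loc[top].min(axis=1), axis=0)
    contrasts = one_vs_rest_contrasts(shifted, labeled)
    contrasts = contrasts.rename(columns={"feature": "pathway_id"})
    contrasts["importance"] = contrasts["pathway_id"].map(importance)
    contrasts["rank"] = contrasts["pathway_id"].map(
        {p: i + 1 for i, p in enumerate(importance.index)})
    return contrasts.sort_values(["rank", "group"]).reset_index(drop=True)
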