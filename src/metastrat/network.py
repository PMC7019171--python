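"""Group-conditional heterogeneous correlation networks.

Associations between molecules of *different* omics layers
(metabolite-protein, protein-peptide, metabolite-peptide) are estimated
with the biweight midcorrelation — a robust correlation that downweights
observations far from the median with Tukey biweights — separately within
each final patient group.  Student t p-values accompany each coefficient,
and a pair enters the network if |r| > 0.6 and p < 0.01 in any group; the
union network records in which groups each association holds and its sign.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _biweight_transform(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-centered, Tukey-biweight-weighted copy of ``x``.

    Weights ``(1 - u^2)^2`` for |u| < 1 with ``u = (x - med) / (9 * MAD)``
    (MAD unscaled).  Returns the transformed vector and a flag marking a
    degenerate MAD of zero, in which case the mean-centered vector is
    returned (Pearson fallback).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - x.mean(), True
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return (x - med) * w, False


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors (n >= 4).

    Falls back to the Pearson correlation, with a warning, for a vector
    whose median absolute deviation is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("bicor needs two equal-length vectors with n >= 4")
    tx, fx = _biweight_transform(x)
    ty, fy = _biweight_transform(y)
    if fx or fy:
        warnings.warn("zero MAD: falling back to Pearson correlation",
                      stacklevel=2)
    denom = np.linalg.norm(tx) * np.linalg.norm(ty)
    if denom == 0:
        return np.nan
    return float(np.clip(np.dot(tx, ty) / denom, -1.0, 1.0))


def bicor_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All pairwise bicor between rows of ``a`` and rows of ``b``.

    Columns (samples) must align.  Rows with zero MAD use the Pearson
    fallback (one summary warning).
    """
    xa = a.to_numpy(dtype=float)
    xb = b.to_numpy(dtype=float)
    ta = np.empty_like(xa)
    tb = np.empty_like(xb)
    n_fallback = 0
    for i in range(xa.shape[0]):
        ta[i], f = _biweight_transform(xa[i])
        n_fallback += f
    for i in range(xb.shape[0]):
        tb[i], f = _biweight_transform(xb[i])
        n_fallback += f
    if n_fallback:
        warnings.warn(f"zero MAD in {n_fallback} row(s): Pearson fallback",
                      stacklevel=2)
    na = np.linalg.norm(ta, axis=1)
    nb = np.linalg.norm(tb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ta @ tb.T) / np.outer(na, nb)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=a.index, columns=b.index)


def bicor_pvalue(r, n: int):
    """Two-sided Student p for a correlation: t = r sqrt((n-2)/(1-r^2))."""
    if n <= 2:
        raise ValueError("p-value needs n > 2")
    r = np.asarray(r, dtype=float)
    limit = np.abs(r) >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = np.where(limit, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    if np.any(limit):
        logger.info("bicor_pvalue: |r| = 1 reached; p reported as the 0 limit")
    if p.ndim == 0:
        return float(p)
    return p


@dataclass
class GroupNetworks:
    """Union heterogeneous network with per-group statistics.

    ``edges`` has one row per molecule pair passing the thresholds in at
    least one group, with per-group r, p, a pass flag and the sign in the
    groups where it passes.
    """

    edges: pd.DataFrame
    groups: list[str]
    r_threshold: float
    p_threshold: float
    group_sizes: dict[str, int]

    def edges_in(self, group: str) -> pd.DataFrame:
        return self.edges[self.edges[f"pass_{group}"]]

    def nodes_in(self, group: str) -> set[str]:
        e = self.edges_in(group)
        return set(e["molecule_a"]) | set(e["molecule_b"])

    def edge_counts(self) -> pd.DataFrame:
        """Positive/negative edge counts per group and layer pair."""
        records = []
        for g in self.groups:
            e = self.edges_in(g)
            for pair, sub in e.groupby("layer_pair"):
                signs = np.sign(sub[f"r_{g}"])
                records.append((g, pair, int((signs > 0).sum()),
                                int((signs < 0).sum())))
        return pd.DataFrame(records, columns=["group", "layer_pair",
                                              "positive", "negative"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.edges.iterrows():
            groups_in = [gr for gr in self.groups if row[f"pass_{gr}"]]
            g.add_node(row["molecule_a"], layer=row["layer_a"])
            g.add_node(row["molecule_b"], layer=row["layer_b"])
            g.add_edge(row["molecule_a"], row["molecule_b"],
                       layer_pair=row["layer_pair"],
                       groups=",".join(groups_in),
                       **{f"r_{gr}": float(row[f"r_{gr}"]) for gr in self.groups})
        return g


def build_group_networks(layer_mats: dict[str, pd.DataFrame],
                         group_labels: pd.Series, r_threshold: float = 0.6,
                         p_threshold: float = 0.01, min_group_size: int = 4
                         ) -> GroupNetworks:
    """Test all heterogeneous molecule pairs within each final group.

    ``layer_mats`` maps layer name to a molecule x sample matrix restricted
    to the clinical-factor-relevant molecules.  Groups smaller than
    ``min_group_size`` are excluded with a warning.  An edge is retained if
    it passes |r| > ``r_threshold`` and p < ``p_threshold`` in any group.
    """
    sizes = group_labels.value_counts()
    groups = sorted(sizes.index[sizes >= min_group_size])
    skipped = sorted(sizes.index[sizes < min_group_size])
    if skipped:
        warnings.warn(f"groups {skipped} below n={min_group_size} excluded "
                      "from network estimation", stacklevel=2)
    if not groups:
        raise ValueError("no group large enough for network estimation")

    layer_pairs = list(itertools.combinations(sorted(layer_mats), 2))
    frames = []
    group_sizes = {g: int(sizes[g]) for g in groups}
    for la, lb in layer_pairs:
        a_all, b_all = layer_mats[la], layer_mats[lb]
        pair_index = pd.MultiIndex.from_product([a_all.index, b_all.index])
        stats_cols: dict[str, np.ndarray] = {}
        for g in groups:
            samples = group_labels.index[group_labels == g]
            a = a_all.loc[:, samples]
            b = b_all.loc[:, samples]
            r = bicor_matrix(a, b)
            p = bicor_pvalue(r.to_numpy(), n=len(samples))
            stats_cols[f"r_{g}"] = r.to_numpy().ravel()
            stats_cols[f"p_{g}"] = np.asarray(p).ravel()
        df = pd.DataFrame(stats_cols, index=pair_index)
        keep = np.zeros(len(df), dtype=bool)
        for g in groups:
            passes = (df[f"r_{g}"].abs() > r_threshold) & \
                     (df[f"p_{g}"] < p_threshold)
            df[f"pass_{g}"] = passes
            keep |= passes.to_numpy()
        df = df[keep].reset_index(names=["molecule_a", "molecule_b"])
        df.insert(2, "layer_a", la)
        df.insert(3, "layer_b", lb)
        df.insert(4, "layer_pair", f"{la}-{lb}")
        frames.append(df)
    edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    for g in groups:
        edges[f"sign_{g}"] = np.where(
            edges[f"pass_{g}"], np.sign(edges[f"r_{g}"]), 0).astype(int) \
            if len(edges) else []
    logger.info("build_group_networks: %d union edges over %d layer pairs, "
                "groups %s", len(edges), len(layer_pairs), groups)
    return GroupNetworks(edges=edges, groups=groups, r_threshold=r_threshold,
                         p_threshold=p_threshold, group_sizes=group_sizes)


def network_overlap(networks: GroupNetworks) -> pd.DataFrame:
    """Node- and edge-set overlaps (intersection, union, Jaccard) per group pair."""
    groups = networks.groups
    if len(groups) < 2:
        raise ValueError("need >= 2 group networks")
    records = []
    edge_sets = {
        g: {frozenset((a, b)) for a, b in
            zip(networks.edges_in(g)["molecule_a"],
                networks.edges_in(g)["molecule_b"])}
        for g in groups}
    node_sets = {g: networks.nodes_in(g) for g in groups}
    for ga, gb in itertools.combinations(groups, 2):
        for kind, sets in (("node", node_sets), ("edge", edge_sets)):
            inter = len(sets[ga] & sets[gb])
            union = len(sets[ga] | sets[gb])
            jac = inter / union if union else np.nan
            records.append((ga, gb, kind, len(sets[ga]), len(sets[gb]),
                            inter, union, jac))
    return pd.DataFrame(records, columns=[
        "group_a", "group_b", "kind", "size_a", "size_b",
        "intersection", "union", "jaccard"])
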