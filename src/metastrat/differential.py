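"""Differential molecule calling: each disease group versus the healthy group.

A molecule is a DEM (differentially expressed molecule) for a disease when
the Kruskal–Wallis rank-sum p-value of disease vs healthy is below 0.05 and
the |log2 fold change| of group means exceeds 1.  Fold changes are computed
on the min-max normalized values, following the stated analysis order
(normalize for the differential analysis, then compare group means); a
raw-scale fold change is available behind ``scale="raw"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DISEASES, CohortDesign
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

HEALTHY = "a"


def kruskal_wallis(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-group Kruskal–Wallis rank-sum test.

    Returns ``(H, p)`` with the tie-corrected H statistic referred to a
    chi-squared distribution with 1 degree of freedom.  If every pooled
    value is identical there is no rank information and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)


def fold_change(disease_values: np.ndarray, healthy_values: np.ndarray) -> float:
    """log2 of (mean disease / mean healthy); NaN when the healthy mean is 0."""
    md = float(np.mean(disease_values))
    mh = float(np.mean(healthy_values))
    if mh <= 0:
        return np.nan
    if md <= 0:
        return -np.inf
    return float(np.log2(md / mh))


@dataclass
class DemTable:
    """Per-disease differential results: one row per retained molecule."""

    disease: str
    table: pd.DataFrame  # columns: layer, p_value, log2fc, is_dem

    @property
    def dems(self) -> pd.Index:
        return self.table.index[self.table["is_dem"]]


def call_dems(norm: NormalizedMatrix, design: CohortDesign, disease: str,
              p_threshold: float = 0.05, lfc_threshold: float = 1.0,
              correction: str | None = None) -> DemTable:
    """Call DEMs for one disease vs healthy on a min-max normalized layer.

    ``correction="bh"`` applies Benjamini–Hochberg before thresholding
    (off by default, matching the fixed-threshold convention).
    Molecules with zero healthy mean have undefined fold change and are
    excluded from DEM status with a warning.
    """
    if disease not in set(design.disease):
        raise KeyError(f"disease {disease!r} absent from design "
                       f"(known: {sorted(set(design.disease))})")
    if HEALTHY not in set(design.disease):
        raise ValueError("healthy group 'a' absent from design")
    cols = norm.data.columns
    dis_samples = [s for s in design.samples_of(disease) if s in cols]
    healthy_samples = [s for s in design.samples_of(HEALTHY) if s in cols]
    dis = norm.data.loc[:, dis_samples].to_numpy()
    healthy = norm.data.loc[:, healthy_samples].to_numpy()

    records = []
    n_undefined = 0
    for i, mol in enumerate(norm.data.index):
        h, p = kruskal_wallis(dis[i], healthy[i])
        lfc = fold_change(dis[i], healthy[i])
        if np.isnan(lfc):
            n_undefined += 1
        records.append((mol, p, lfc))
    if n_undefined:
        logger.warning("call_dems[%s/%s]: %d molecule(s) with zero healthy mean; "
                       "fold change undefined, excluded from DEM status",
                       norm.layer, disease, n_undefined)
    table = pd.DataFrame(records, columns=["molecule_id", "p_value", "log2fc"]
                         ).set_index("molecule_id")
    table.insert(0, "layer", norm.layer)
    p_use = table["p_value"].to_numpy()
    if correction == "bh":
        p_use = stats.false_discovery_control(p_use, method="bh")
        table["p_adjusted"] = p_use
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    with np.errstate(invalid="ignore"):
        table["is_dem"] = (p_use < p_threshold) & (
            np.abs(table["log2fc"].to_numpy()) > lfc_threshold)
    table["is_dem"] = table["is_dem"].fillna(False)
    return DemTable(disease=disease, table=table)


def call_dems_all(norms: dict[str, NormalizedMatrix], design: CohortDesign,
                  diseases: list[str] | None = None, **kwargs
                  ) -> dict[str, pd.DataFrame]:
    """Call DEMs for every (disease, layer); returns disease -> pooled table."""
    if diseases is None:
        diseases = sorted(d for d in set(design.disease) if d != HEALTHY)
    out = {}
    for disease in diseases:
        parts = [call_dems(norm, design, disease, **kwargs).table
                 for norm in norms.values()]
        out[disease] = pd.concat(parts)
    return out


def partition_shared_specific(dems_by_disease: dict[str, pd.DataFrame]
                              ) -> dict[str, object]:
    """Shared/specific partition of DEM sets across diseases.

    For each molecule called in at least one disease, records the calling
    subset; a molecule is disease-specific when called by exactly one
    disease.  Also returns the per-layer pairwise shared-count matrices
    (symmetric, diagonal = per-disease DEM count).
    """
    if len(dems_by_disease) < 2:
        raise ValueError("need DEM results for at least 2 diseases")
    diseases = sorted(dems_by_disease)
    calls: dict[tuple[str, str], set[str]] = {}
    layer_of: dict[str, str] = {}
    for d, table in dems_by_disease.items():
        flagged = table[table["is_dem"]]
        for mol, layer in zip(flagged.index, flagged["layer"]):
            calls.setdefault((layer, mol), set()).add(d)
            layer_of[mol] = layer

    membership = pd.DataFrame(
        [(layer, mol, ",".join(sorted(ds)), len(ds) == 1)
         for (layer, mol), ds in sorted(calls.items())],
        columns=["layer", "molecule_id", "called_by", "specific"])

    layers = sorted({layer for layer, _ in calls})
    pairwise = {}
    for layer in layers + ["all"]:
        mat = pd.DataFrame(0, index=diseases, columns=diseases, dtype=int)
        for (lyr, _mol), ds in calls.items():
            if layer != "all" and lyr != layer:
                continue
            for d1 in ds:
                for d2 in ds:
                    mat.loc[d1, d2] += 1
        pairwise[layer] = mat

    specific = {
        d: sorted(mol for (_l, mol), ds in calls.items() if ds == {d})
        for d in diseases}
    return {"membership": membership, "pairwise_shared": pairwise,
            "specific": specific}


def dem_counts(dems_by_disease: dict[str, pd.DataFrame]) -> pd.Series:
    """Pooled (all layers) DEM count per disease."""
    return pd.Series({d: int(t["is_dem"].sum()) for d, t in dems_by_disease.items()},
                     name="n_dems").sort_index()
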