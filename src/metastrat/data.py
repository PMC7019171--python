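"""Domain containers for multi-omics metabolic-disease cohorts.

The pipeline operates on three molecule-by-sample abundance matrices
(metabolomics, proteomics, peptidomics), a sample-by-factor clinical table
and the original disease assignment of each sample.  All containers wrap
pandas objects and validate the invariants the downstream stages rely on
(unique identifiers, non-negative finite abundances, presence of the eight
key clinical factors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Recognised omics layers.
LAYERS = ("metabolite", "protein", "peptide")

#: Original disease labels: single-letter code -> human-readable disease.
DISEASES = {
    "a": "healthy",
    "b": "obesity",
    "c": "MTS",
    "d": "hyperglycemia",
    "e": "hypertension",
    "f": "hyperlipidemia",
    "g": "T2D",
}

#: The eight key clinical factors, two per basic metabolic disease.
KEY_FACTORS = ("BMI", "WaistCir", "FPG", "OGTT_2hPG", "SBP", "DBP", "TG", "HDL")

#: Basic metabolic disease -> its two defining clinical factors.
#: OB = obesity, HG = hyperglycemia, HT = hypertension, HP = hyperlipidemia.
DEFAULT_KEY_FACTOR_MAP = {
    "obesity": ("BMI", "WaistCir"),
    "hyperglycemia": ("FPG", "OGTT_2hPG"),
    "hypertension": ("SBP", "DBP"),
    "hyperlipidemia": ("TG", "HDL"),
}


def _check_unique(values: Sequence, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class OmicsMatrix:
    """One omics layer: molecule x sample abundances.

    Parameters
    ----------
    layer
        One of ``metabolite``, ``protein``, ``peptide``.
    data
        DataFrame with molecules as rows and samples as columns.  Missing
        measurements are encoded as 0; values must be finite and >= 0.
    annotations
        Optional ``molecule_id -> source_protein_id`` map (peptides only).
    """

    layer: str
    data: pd.DataFrame
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        _check_unique(self.data.index, f"molecule ids in layer {self.layer}")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite abundance in layer {self.layer}")
        if (values < 0).any():
            raise ValueError(f"negative abundance in layer {self.layer}")
        self.data = self.data.astype(float)

    @property
    def molecule_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def reorder_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy with columns in the given order (all must exist)."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from {self.layer} matrix: {missing}")
        return OmicsMatrix(self.layer, self.data.loc[:, list(sample_ids)].copy(),
                           self.annotations)


@dataclass
class ClinicalTable:
    """Sample x clinical-factor numeric table.

    Must contain the eight key factors (BMI and waist circumference in
    kg/m^2 and cm; fasting and 2 h post-load glucose in mmol/L; systolic and
    diastolic blood pressure in mmHg; triglycerides and HDL cholesterol in
    mmol/L).  Any number of extra factors (LDL, ApoB, insulin measures,
    liver enzymes, HOMA indices, ...) may be present and are preserved.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids in clinical table")
        missing = [f for f in KEY_FACTORS if f not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table lacks key factors: {missing}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def factors(self) -> pd.Index:
        return self.data.columns

    def key_factors(self) -> pd.DataFrame:
        return self.data.loc[:, list(KEY_FACTORS)]


@dataclass
class CohortDesign:
    """Sample -> original disease label, plus ground truth for simulations.

    ``disease`` maps every sample to one of the seven single-letter codes in
    :data:`DISEASES`.  Synthetic cohorts additionally carry ``true_group``
    (the planted latent group of each sample) and ``planted`` (named blocks
    of molecules that carry the planted group signal).
    """

    disease: pd.Series
    true_group: pd.Series | None = None
    planted: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.disease.index, "sample ids in design")
        bad = sorted(set(self.disease) - set(DISEASES))
        if bad:
            raise ValueError(f"unknown disease labels {bad}; expected {sorted(DISEASES)}")
        self.disease = self.disease.astype(str)

    @property
    def sample_ids(self) -> pd.Index:
        return self.disease.index

    def group_sizes(self) -> pd.Series:
        return self.disease.value_counts().sort_index()

    def samples_of(self, disease: str) -> pd.Index:
        if disease not in set(self.disease):
            raise KeyError(f"disease {disease!r} absent from design")
        return self.disease.index[self.disease == disease]


@dataclass
class PathwayDB:
    """Pathway id -> name, category and member molecule identifiers.

    Members may be metabolite ids and/or protein (gene) ids; a molecule may
    belong to many pathways.  Peptides are never direct members — they enter
    pathway analyses through their source proteins.
    """

    pathways: dict[str, dict]

    def __post_init__(self) -> None:
        for pid, entry in self.pathways.items():
            members = entry.get("members", [])
            if len(members) == 0:
                raise ValueError(f"pathway {pid!r} has no members")
            entry["members"] = list(dict.fromkeys(members))
            entry.setdefault("name", pid)
            entry.setdefault("category", "uncategorized")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def members(self, pathway_id: str) -> list[str]:
        return self.pathways[pathway_id]["members"]


class KeyFactorMap(dict):
    """Disease -> (factor1, factor2) map used for molecule selection.

    Exactly four basic diseases, two factors each (eight factors total).
    """

    def __init__(self, mapping: Mapping[str, tuple[str, str]] | None = None):
        mapping = dict(mapping or DEFAULT_KEY_FACTOR_MAP)
        if len(mapping) != 4:
            raise ValueError("key-factor map must cover exactly 4 diseases")
        factors = [f for pair in mapping.values() for f in pair]
        if any(len(pair) != 2 for pair in mapping.values()) or len(set(factors)) != 8:
            raise ValueError("key-factor map must assign 2 distinct factors per disease "
                             "(8 factors total)")
        super().__init__(mapping)


def homa1(fpg, fpi):
    """Homeostasis model assessment (original formulas).

    Parameters
    ----------
    fpg
        Fasting plasma glucose in mmol/L (scalar or array).
    fpi
        Fasting plasma insulin in uU/mL (scalar or array).

    Returns
    -------
    (ir, beta)
        Insulin-resistance index ``fpg * fpi / 22.5`` and beta-cell function
        ``20 * fpi / (fpg - 3.5)`` in percent.  ``beta`` is NaN (with a
        warning) wherever ``fpg <= 3.5``, the pole of the formula.
    """
    fpg = np.asarray(fpg, dtype=float)
    fpi = np.asarray(fpi, dtype=float)
    ir = fpg * fpi / 22.5
    undefined = fpg <= 3.5
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(undefined, np.nan, 20.0 * fpi / (fpg - 3.5))
    if np.any(undefined):
        warnings.warn(
            f"HOMA1 %B undefined for {int(np.sum(undefined))} sample(s) with "
            "FPG <= 3.5 mmol/L; set to NaN", stacklevel=2)
    if ir.ndim == 0:
        return float(ir), float(beta)
    return ir, beta
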