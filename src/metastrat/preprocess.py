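"""Preprocessing of omics matrices: sparsity filtering and row normalization.

Two row-wise normalizations are used downstream, each paired with a
specific analysis:

* min-max scaling ``(x - min) / (max - min)`` for the differential
  analysis, mapping every retained row onto [0, 1];
* z-scoring ``(x - mean) / sd`` for the clustering analyses, giving every
  retained row mean 0 and (sample) standard deviation 1.

Rows in which more than half of the samples are zero are removed first;
zeros that encode missing values participate in the row statistics, exactly
as in the raw matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """A row-normalized omics layer plus provenance of dropped rows."""

    layer: str
    data: pd.DataFrame
    mode: str  # "minmax" | "zscore"
    dropped_sparse: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def molecule_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


def filter_sparse_rows(matrix: OmicsMatrix) -> OmicsMatrix:
    """Remove rows whose zero count exceeds half the samples.

    A row with more than ``n_samples / 2`` zeros is dropped (at n = 49 a row
    with 25 zeros goes, one with 24 stays).  Raises if nothing survives.
    """
    n = matrix.n_samples
    zeros = (matrix.data == 0).sum(axis=1)
    keep = zeros <= n / 2
    dropped = matrix.data.index[~keep].tolist()
    if dropped:
        logger.info("filter_sparse_rows[%s]: dropped %d/%d rows: %s%s",
                    matrix.layer, len(dropped), len(keep), dropped[:5],
                    "..." if len(dropped) > 5 else "")
    if not keep.any():
        raise ValueError(f"all rows of {matrix.layer} matrix are >50% zero")
    out = OmicsMatrix(matrix.layer, matrix.data.loc[keep].copy(), matrix.annotations)
    out.dropped_sparse = dropped  # type: ignore[attr-defined]
    return out


def _drop_constant(df: pd.DataFrame, layer: str) -> tuple[pd.DataFrame, list[str]]:
    spread = df.max(axis=1) - df.min(axis=1)
    constant = df.index[spread == 0].tolist()
    if constant:
        logger.warning("%s: dropped %d constant row(s) (no contrast): %s%s",
                       layer, len(constant), constant[:5],
                       "..." if len(constant) > 5 else "")
    return df.loc[spread > 0], constant


def minmax_rows(matrix: OmicsMatrix) -> NormalizedMatrix:
    """Min-max scale each row onto [0, 1]; constant rows are dropped."""
    df, constant = _drop_constant(matrix.data, matrix.layer)
    lo = df.min(axis=1)
    hi = df.max(axis=1)
    scaled = df.sub(lo, axis=0).div(hi - lo, axis=0)
    return NormalizedMatrix(
        layer=matrix.layer, data=scaled, mode="minmax",
        dropped_sparse=list(getattr(matrix, "dropped_sparse", [])),
        dropped_constant=constant)


def zscore_rows(matrix: OmicsMatrix) -> NormalizedMatrix:
    """Standardize each row to mean 0, sample SD 1; constant rows are dropped."""
    df, constant = _drop_constant(matrix.data, matrix.layer)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)  # sample SD (n-1)
    z = df.sub(mean, axis=0).div(sd, axis=0)
    return NormalizedMatrix(
        layer=matrix.layer, data=z, mode="zscore",
        dropped_sparse=list(getattr(matrix, "dropped_sparse", [])),
        dropped_constant=constant)


def preprocess_layer(matrix: OmicsMatrix, mode: str) -> NormalizedMatrix:
    """Sparsity-filter then normalize one layer (``mode`` minmax or zscore)."""
    filtered = filter_sparse_rows(matrix)
    if mode == "minmax":
        return minmax_rows(filtered)
    if mode == "zscore":
        return zscore_rows(filtered)
    raise ValueError(f"unknown normalization mode {mode!r}")


def preprocess_all(matrices: dict[str, OmicsMatrix], mode: str
                   ) -> dict[str, NormalizedMatrix]:
    return {layer: preprocess_layer(m, mode) for layer, m in matrices.items()}


def as_normalized_frame(norm: NormalizedMatrix) -> pd.DataFrame:
    df = norm.data.copy()
    if not np.all(np.isfinite(df.to_numpy())):
        raise AssertionError("normalized matrix contains non-finite values")
    return df
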