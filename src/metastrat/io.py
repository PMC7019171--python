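"""Readers and writers for the plain-text formats the pipeline consumes.

Omics layers are tab-separated (rows = molecules, first column = molecule
id, header = sample ids); the clinical table and cohort design are CSV;
pathway databases are GMT; peptide annotations are a two-column TSV.
Missing abundance cells — empty, ``NA`` or ``NaN`` — are read as 0, the
single canonical sparse encoding used throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import KEY_FACTORS, CohortDesign, ClinicalTable, OmicsMatrix, PathwayDB

#: Cell contents treated as missing (mapped to 0) in omics matrices.
MISSING_TOKENS = ("", "NA", "NaN", "nan")


def read_omics_matrix(path: str | Path, layer: str,
                      annotations: dict[str, str] | None = None) -> OmicsMatrix:
    """Read a molecule x sample TSV into an :class:`OmicsMatrix`.

    Empty/NA cells become 0.  Duplicate molecule or sample ids and
    non-numeric cells are hard errors naming the offending row/column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated molecule ids {dups[:10]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids {dups[:10]}")
    data = raw.replace(list(MISSING_TOKENS), "0")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = numeric.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ValueError(
            f"{path}: non-numeric value {raw.loc[row, col]!r} at "
            f"row {row!r}, column {col!r}")
    return OmicsMatrix(layer=layer, data=numeric, annotations=annotations)


def write_omics_matrix(matrix: OmicsMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="molecule_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read the sample x factor CSV; all 8 key factors must be present."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    missing = [f for f in KEY_FACTORS if f not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table lacks key factors {missing}")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_cohort_design(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    true_group = df["true_group"].astype(str) if "true_group" in df.columns else None
    return CohortDesign(disease=df["disease"].astype(str), true_group=true_group)


def write_cohort_design(design: CohortDesign, path: str | Path) -> None:
    df = pd.DataFrame({"disease": design.disease})
    if design.true_group is not None:
        df["true_group"] = design.true_group
    df.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path, category_from_description: bool = True) -> PathwayDB:
    """Read a GMT file: one set per line, ``id<TAB>description<TAB>members...``.

    The description field, when of the form ``category|name``, populates the
    pathway category; otherwise it becomes the pathway name.
    """
    pathways: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line[:80]!r}")
        pid, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if pid in pathways:
            raise ValueError(f"{path}: duplicated pathway id {pid!r}")
        category, name = "uncategorized", desc or pid
        if category_from_description and "|" in desc:
            category, name = desc.split("|", 1)
        pathways[pid] = {"name": name, "category": category, "members": members}
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    lines = []
    for pid, entry in db:
        desc = f"{entry['category']}|{entry['name']}"
        lines.append("\t".join([pid, desc, *entry["members"]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_peptide_annotations(path: str | Path) -> dict[str, str]:
    """Read the two-column ``peptide_id<TAB>source_protein_id`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly 2 columns, got {df.shape[1]}")
    peptide, protein = df.columns
    if df[peptide].duplicated().any():
        dups = df[peptide][df[peptide].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated peptide ids {dups[:10]}")
    return dict(zip(df[peptide], df[protein]))


def write_peptide_annotations(annotations: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"peptide_id": list(annotations), "protein_id": list(annotations.values())}
    ).to_csv(path, sep="\t", index=False)


def align_to_clinical(matrices: dict[str, OmicsMatrix],
                      clinical: ClinicalTable) -> dict[str, OmicsMatrix]:
    """Enforce the clinical table's sample order on every omics matrix.

    Every omics sample must appear in the clinical table; matrices are
    returned with columns in clinical order (restricted to samples present
    in the matrix, which must be all of them).
    """
    order = list(clinical.sample_ids)
    aligned = {}
    for layer, m in matrices.items():
        extra = [s for s in m.sample_ids if s not in clinical.sample_ids]
        if extra:
            raise ValueError(f"{layer} matrix has samples absent from the "
                             f"clinical table: {extra[:10]}")
        aligned[layer] = m.reorder_samples([s for s in order if s in m.sample_ids])
    return aligned


def load_cohort_dir(path: str | Path):
    """Load a cohort directory written by the ``simulate`` stage.

    Expects ``metabolomics.tsv``, ``proteomics.tsv``, ``peptidomics.tsv``,
    ``clinical.csv``, ``design.csv`` and optionally
    ``peptide_annotations.tsv`` and ``pathways.gmt``.
    """
    path = Path(path)
    annotations = None
    ann_path = path / "peptide_annotations.tsv"
    if ann_path.exists():
        annotations = read_peptide_annotations(ann_path)
    matrices = {
        "metabolite": read_omics_matrix(path / "metabolomics.tsv", "metabolite"),
        "protein": read_omics_matrix(path / "proteomics.tsv", "protein"),
        "peptide": read_omics_matrix(path / "peptidomics.tsv", "peptide",
                                     annotations=annotations),
    }
    clinical = read_clinical(path / "clinical.csv")
    matrices = align_to_clinical(matrices, clinical)
    design = read_cohort_design(path / "design.csv")
    db = None
    gmt = path / "pathways.gmt"
    if gmt.exists():
        db = read_gmt(gmt)
    return matrices, clinical, design, db
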