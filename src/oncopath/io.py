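"""Readers and writers for every external file format the pipeline touches.

Supported formats: GCT 1.2 expression matrices (the dialect used by the CCLE
RNA-seq RPKM release), tab-delimited protein quantification matrices,
cell-line annotation tables, GMT pathway gene-set files, drug-target tables,
approved drug/cancer-type tables and mnAUC tables.  All parsers validate
strictly and never reorder features or samples.  Gene symbols are upper-cased
at parse time so that symbol-keyed joins (pathways, drug targets) cannot fail
silently on case mismatches.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LOG2, RPKM, ExpressionMatrix, PathwayDB, normalize_symbol

__all__ = [
    "GctFormatError",
    "read_gct",
    "write_gct",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_drug_targets",
    "write_drug_targets",
    "read_mnauc",
    "write_mnauc",
    "read_approved_pairs",
    "write_approved_pairs",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_feature_metadata",
    "write_feature_metadata",
    "attach_feature_metadata",
    "unannotated_samples",
]

_NA_STRINGS = {"", "NA", "NaN", "nan"}


class GctFormatError(ValueError):
    """Raised when a file violates the GCT 1.2 format contract."""


def read_gct(path: str | Path, scale: str = RPKM) -> ExpressionMatrix:
    """Read a GCT 1.2 expression matrix.

    GCT 1.2 is two header lines (the ``#1.2`` version token, then
    ``<n_rows>\\t<n_cols>``) followed by a table whose first two columns are
    ``Name`` (feature id) and ``Description`` (gene symbol, possibly empty).

    Raises
    ------
    GctFormatError
        On a missing or foreign version token (GCT 1.3 is rejected
        explicitly), a declared/actual dimension mismatch, or duplicate
        feature ids.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise GctFormatError(
                f"{path}: expected GCT version token '#1.2', found {version!r} "
                "(only GCT 1.2 is supported; 1.3 is not)"
            )
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise GctFormatError(f"{path}: malformed dimensions line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise GctFormatError(f"{path}: non-integer dimensions line") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "Name":
            raise GctFormatError(f"{path}: expected column header starting with 'Name'")
        sample_ids = header[2:]
        if len(sample_ids) != n_cols:
            raise GctFormatError(
                f"{path}: header declares {n_cols} samples but {len(sample_ids)} columns found"
            )
        names: list[str] = []
        descriptions: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols + 2:
                raise GctFormatError(
                    f"{path}: row {len(rows) + 1} has {len(fields) - 2} value columns, expected {n_cols}"
                )
            names.append(fields[0])
            descriptions.append(fields[1])
            try:
                rows.append([float(x) for x in fields[2:]])
            except ValueError as exc:
                raise GctFormatError(f"{path}: non-numeric value in row {len(rows) + 1}") from exc
    if len(rows) != n_rows:
        raise GctFormatError(f"{path}: header declares {n_rows} rows but body has {len(rows)}")
    index = pd.Index(names, name="feature_id")
    if not index.is_unique:
        dupes = index[index.duplicated()].unique().tolist()
        raise GctFormatError(f"{path}: duplicate feature ids: {dupes[:5]}")
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=index, columns=sample_ids)
    symbols = pd.Series(descriptions, index=index)
    symbols = symbols.mask(symbols == "")
    return ExpressionMatrix(values=values, scale=scale, gene_symbols=symbols)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as GCT 1.2 (values at 6 significant digits)."""
    path = Path(path)
    symbols = matrix.gene_symbols
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_features}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for fid, row in matrix.values.iterrows():
            desc = ""
            if symbols is not None and pd.notna(symbols.loc[fid]):
                desc = str(symbols.loc[fid])
            vals = "\t".join(_format_value(v) for v in row.to_numpy())
            fh.write(f"{fid}\t{desc}\t{vals}\n")


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "NA"
    return format(float(v), ".6g")


def read_labels(
    path: str | Path,
    id_column: str = "cell_line",
    label_column: str = "cancer_type",
) -> dict[str, str]:
    """Read a cell line -> cancer type annotation table (tab-delimited).

    Rows duplicated with the same label are deduplicated; duplicated ids with
    conflicting labels raise.  Column names are configurable to accommodate
    annotation dialects such as the CCLE cell-line annotation file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} (have {list(df.columns)})")
    labels: dict[str, str] = {}
    for sample, label in zip(df[id_column], df[label_column]):
        if pd.isna(label) or str(label).strip() == "":
            raise ValueError(f"{path}: empty cancer-type label for cell line {sample!r}")
        label = str(label).strip()
        if sample in labels and labels[sample] != label:
            raise ValueError(
                f"{path}: cell line {sample!r} annotated with conflicting labels "
                f"{labels[sample]!r} and {label!r}"
            )
        labels[sample] = label
    return labels


def write_labels(
    labels: dict[str, str],
    path: str | Path,
    id_column: str = "cell_line",
    label_column: str = "cancer_type",
) -> None:
    pd.DataFrame(
        {id_column: list(labels), label_column: list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def unannotated_samples(matrix: ExpressionMatrix, labels: dict[str, str]) -> list[str]:
    """Samples present in the matrix but absent from the annotation table.

    Reported to the caller rather than silently dropped.
    """
    return [s for s in matrix.sample_ids if s not in labels]


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT gene-set file: one pathway per line, tab-separated
    ``name <TAB> description <TAB> gene [<TAB> gene ...]``."""
    gene_sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene "
                    f"({len(fields)} fields found)"
                )
            name = fields[0]
            if name in gene_sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            gene_sets[name] = genes
            descriptions[name] = fields[1]
    return PathwayDB(gene_sets=gene_sets, descriptions=descriptions)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, genes in db.items():
            desc = db.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def read_drug_targets(
    path: str | Path,
    drug_column: str = "drug_id",
    target_column: str = "target_gene",
) -> dict[str, frozenset[str]]:
    """Read a long-format drug -> target-gene table; one (drug, gene) per row.

    Duplicated (drug, gene) rows — e.g. the same interaction annotated by
    both DrugBank and KEGG — are deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (drug_column, target_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, set[str]] = {}
    for drug, gene in zip(df[drug_column], df[target_column]):
        if pd.isna(gene) or str(gene).strip() == "":
            raise ValueError(f"{path}: empty target gene for drug {drug!r}")
        out.setdefault(str(drug), set()).add(normalize_symbol(str(gene)))
    return {d: frozenset(g) for d, g in out.items()}


def write_drug_targets(
    targets: dict[str, frozenset[str]],
    path: str | Path,
    drug_column: str = "drug_id",
    target_column: str = "target_gene",
) -> None:
    rows = [(d, g) for d in targets for g in sorted(targets[d])]
    pd.DataFrame(rows, columns=[drug_column, target_column]).to_csv(path, sep="\t", index=False)


def read_mnauc(
    path: str | Path,
    drug_column: str = "drug_id",
    mnauc_column: str = "mnauc",
) -> dict[str, float]:
    """Read a drug -> mnAUC table (mean normalized AUC; lower = more potent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (drug_column, mnauc_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, float] = {}
    for drug, raw in zip(df[drug_column], df[mnauc_column]):
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric mnAUC {raw!r} for drug {drug!r}") from exc
        if not np.isfinite(value):
            raise ValueError(f"{path}: non-finite mnAUC for drug {drug!r}")
        out[str(drug)] = value
    return out


def write_mnauc(
    mnauc: dict[str, float],
    path: str | Path,
    drug_column: str = "drug_id",
    mnauc_column: str = "mnauc",
) -> None:
    pd.DataFrame(
        {drug_column: list(mnauc), mnauc_column: [format(v, ".6g") for v in mnauc.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_approved_pairs(
    path: str | Path,
    drug_column: str = "drug_id",
    type_column: str = "cancer_type",
) -> set[tuple[str, str]]:
    """Read an approved (drug, cancer type) pair table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (drug_column, type_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {(str(d), str(t)) for d, t in zip(df[drug_column], df[type_column])}


def write_approved_pairs(
    pairs: set[tuple[str, str]],
    path: str | Path,
    drug_column: str = "drug_id",
    type_column: str = "cancer_type",
) -> None:
    rows = sorted(pairs)
    pd.DataFrame(rows, columns=[drug_column, type_column]).to_csv(path, sep="\t", index=False)


def read_protein_matrix(path: str | Path, id_column: str = "protein_id") -> ExpressionMatrix:
    """Read a tab-delimited protein quantification matrix (already log2).

    The first column holds the protein/gene identifier; missing channels may
    be encoded as empty fields or ``NA`` and are stored as NaN (excluded
    pairwise from downstream statistics).  Protein identifiers double as gene
    symbols for pathway joins.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != id_column:
        raise ValueError(f"{path}: expected first column {id_column!r}, found {df.columns[0]!r}")
    index = pd.Index(df.iloc[:, 0].astype(str), name="feature_id")
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    body.index = index
    matrix = ExpressionMatrix(
        values=body,
        scale=LOG2,
        gene_symbols=pd.Series(index, index=index),
    )
    return matrix


def write_protein_matrix(
    matrix: ExpressionMatrix, path: str | Path, id_column: str = "protein_id"
) -> None:
    if matrix.scale != LOG2:
        raise ValueError("protein matrices are log2-scale")
    with open(path, "w") as fh:
        fh.write(id_column + "\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for fid, row in matrix.values.iterrows():
            fh.write(str(fid) + "\t" + "\t".join(_format_value(v) for v in row.to_numpy()) + "\n")


def read_feature_metadata(path: str | Path) -> pd.DataFrame:
    """Read optional feature metadata (feature_id, gene_symbol, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "gene_symbol", "biotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: feature metadata needs columns {sorted(required)}")
    return df.set_index("feature_id")


def write_feature_metadata(matrix: ExpressionMatrix, path: str | Path) -> None:
    sym = matrix.gene_symbols
    bio = matrix.biotypes
    df = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "gene_symbol": "" if sym is None else sym.fillna("").to_numpy(),
            "biotype": "" if bio is None else bio.fillna("").to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def attach_feature_metadata(matrix: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Attach gene symbols/biotypes from a metadata table to a matrix."""
    unknown = meta.index.difference(matrix.feature_ids)
    if len(unknown):
        warnings.warn(f"feature metadata lists {len(unknown)} ids absent from the matrix")
    symbols = meta["gene_symbol"].replace("", np.nan).reindex(matrix.feature_ids)
    biotypes = meta["biotype"].replace("", np.nan).reindex(matrix.feature_ids)
    return ExpressionMatrix(
        values=matrix.values,
        scale=matrix.scale,
        gene_symbols=symbols,
        biotypes=biotypes,
    )
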