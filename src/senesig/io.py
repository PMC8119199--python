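"""Readers and writers for the plain-text formats the pipeline touches.

Single-cell counts use the 10x triplet convention on disk (MatrixMarket
coordinate file with genes as rows, plus row-aligned ``features.tsv`` and
``barcodes.tsv``); in memory everything is cells x genes, so the transpose
happens here and only here. Bulk matrices, contrast tables, cluster labels
and scores are TSV with a header row; floats are serialized with 17
significant digits so a write/read roundtrip is bit-faithful. Gene sets use
standard GMT (name TAB description TAB genes...).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    BulkExpressionMatrix,
    CellCountMatrix,
    ClusterLabels,
    ContrastResult,
    FormatError,
    GeneSet,
    GeneSetCollection,
    GeneSignature,
)

logger = logging.getLogger("senesig")

PathLike = Union[str, Path]

FLOAT_FMT = "%.17g"


def _read_id_column(path: PathLike, what: str) -> list[str]:
    """First tab-separated field of each line (10x features/barcodes dialect)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if not ids:
        raise FormatError(f"empty {what} file: {path}")
    return ids


def read_counts_mtx(
    matrix_path: PathLike,
    features_path: PathLike,
    barcodes_path: PathLike,
) -> CellCountMatrix:
    """Read a 10x-style triplet count matrix into cells x genes orientation.

    The MatrixMarket file stores features (genes) as rows and barcodes as
    columns; the returned matrix is transposed. ``pattern`` matrices are
    rejected; ``real`` entries are accepted but must be integral.
    """
    with open(matrix_path) as fh:
        header = fh.readline()
    if not header.startswith("%%MatrixMarket"):
        raise FormatError(f"{matrix_path}: missing MatrixMarket banner")
    if "pattern" in header:
        raise FormatError(f"{matrix_path}: pattern matrices carry no counts")
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    genes = _read_id_column(features_path, "features")
    barcodes = _read_id_column(barcodes_path, "barcodes")
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"features file lists {len(genes)} genes but matrix header declares {n_genes} rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes file lists {len(barcodes)} barcodes but matrix header declares {n_cells} columns"
        )
    if not np.all(mat == np.floor(mat)):
        raise FormatError(f"{matrix_path}: non-integer count entries")
    return CellCountMatrix(barcodes=barcodes, gene_ids=genes, counts=mat.T.astype(np.int64))


def write_counts_mtx(
    matrix: CellCountMatrix,
    matrix_path: PathLike,
    features_path: PathLike,
    barcodes_path: PathLike,
) -> None:
    """Write counts in the 10x triplet convention (genes as rows)."""
    sp = scipy.sparse.coo_matrix(matrix.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(matrix_path), sp, field="integer")
    Path(features_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.barcodes))


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file (one set per line: name, description, genes)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} lists duplicate genes; deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, description=desc, genes=tuple(unique)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection_or_signatures, path: PathLike) -> None:
    """Write a GeneSetCollection or a list of GeneSignature objects as GMT."""
    lines = []
    items = list(collection_or_signatures)
    for item in items:
        if isinstance(item, GeneSignature):
            desc = f"direction={item.direction}"
            lines.append("\t".join([item.name, desc, *item.genes]))
        else:
            lines.append("\t".join([item.name, item.description, *item.genes]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def signatures_from_collection(collection: GeneSetCollection, direction: str = "up") -> list[GeneSignature]:
    return [
        GeneSignature(name=s.name, genes=s.genes, direction=direction, provenance={"source": "gmt"})
        for s in collection
    ]


def read_bulk_tsv(path: PathLike, groups_path: PathLike, scale: str = "raw_nrpkm") -> BulkExpressionMatrix:
    """Read a genes x samples TSV plus a sample -> group mapping TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated gene ids")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    groups = read_groups_tsv(groups_path)
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise ValueError(f"samples missing from groups file: {missing}")
    return BulkExpressionMatrix(values=values, scale=scale, sample_groups=groups)


def read_groups_tsv(path: PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: groups file needs sample and group columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_bulk_tsv(matrix: BulkExpressionMatrix, path: PathLike, groups_path: Optional[PathLike] = None) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if groups_path is not None:
        out = pd.DataFrame(
            {"sample": matrix.sample_ids, "group": [matrix.sample_groups[s] for s in matrix.sample_ids]}
        )
        out.to_csv(groups_path, sep="\t", index=False)


def write_contrast_tsv(contrast: ContrastResult, path: PathLike) -> None:
    df = contrast.table.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_contrast_tsv(path: PathLike, name: Optional[str] = None, n_treated: int = 2, n_control: int = 2) -> ContrastResult:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContrastResult(
        contrast_name=name or Path(path).stem,
        table=df,
        n_treated=n_treated,
        n_control=n_control,
    )


def read_cluster_labels(path: PathLike) -> ClusterLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels file needs barcode and cluster columns")
    return ClusterLabels(labels=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_cluster_labels(labels: ClusterLabels, path: PathLike) -> None:
    df = pd.DataFrame({"barcode": list(labels.labels), "cluster": list(labels.labels.values())})
    df.to_csv(path, sep="\t", index=False)
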