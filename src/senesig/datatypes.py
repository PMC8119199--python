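"""Domain containers shared across the pipeline.

Expression data live in two worlds: bulk matrices (genes x samples, on an
nRPKM-like normalized scale or log2-transformed) and single-cell matrices
(cells x genes, raw UMI counts or log-normalized). Gene identifiers are
opaque case-sensitive strings throughout; no symbol/Ensembl mapping is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

RAW_NRPKM = "raw_nrpkm"
LOG2 = "log2"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        counts = pd.Series(list(ids)).value_counts()
        dupes = counts[counts > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class BulkExpressionMatrix:
    """Genes x samples expression with per-sample group labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``scale`` is ``"raw_nrpkm"`` (non-negative normalized expression) or
    ``"log2"`` (after the pseudocounted log2 transform).
    """

    values: pd.DataFrame
    scale: str
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.scale not in (RAW_NRPKM, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        _check_unique(list(self.values.index), "gene ids")
        _check_unique(list(self.values.columns), "sample ids")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == RAW_NRPKM and (arr < 0).any():
            raise ValueError("raw_nrpkm values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups[s] == group]


@dataclass
class ContrastResult:
    """Per-gene differential-expression result for one two-group contrast.

    ``table`` is indexed by gene id with columns ``log2_fc``,
    ``mean_log2_expr``, ``p_value`` and ``p_adjusted``.
    """

    contrast_name: str
    table: pd.DataFrame
    n_treated: int
    n_control: int

    REQUIRED = ("log2_fc", "mean_log2_expr", "p_value", "p_adjusted")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"contrast table missing columns {missing}")
        _check_unique(list(self.table.index), "gene ids")
        if self.n_treated < 1 or self.n_control < 1:
            raise ValueError("group sizes must be positive")
        p = self.table["p_value"].to_numpy()
        padj = self.table["p_adjusted"].to_numpy()
        if ((p < 0) | (p > 1)).any() or ((padj < 0) | (padj > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneSignature:
    """Named, ordered, directional gene set with derivation provenance."""

    name: str
    genes: tuple[str, ...]
    direction: str = "up"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        self.genes = tuple(self.genes)
        _check_unique(self.genes, f"genes in signature {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class CellCountMatrix:
    """Cells x genes UMI counts with barcodes and optional subject ids."""

    barcodes: list[str]
    gene_ids: list[str]
    counts: np.ndarray
    subject_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        _check_unique(self.barcodes, "barcodes")
        _check_unique(self.gene_ids, "gene ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.subject_ids is not None and len(self.subject_ids) != len(self.barcodes):
            raise ValueError("subject_ids must align with barcodes")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class LogNormMatrix:
    """Cells x genes log-normalized expression: ln(1 + count / total * scale_factor)."""

    barcodes: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError("values shape does not match barcodes x genes")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if (self.values < 0).any():
            raise ValueError("log-normalized values must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusterLabels:
    """Barcode -> cluster-id assignment (clustering itself happens upstream)."""

    labels: dict[str, str]

    def for_barcodes(self, barcodes: Sequence[str]) -> np.ndarray:
        missing = [b for b in barcodes if b not in self.labels]
        if missing:
            raise ValueError(f"{len(missing)} barcodes lack a cluster label, e.g. {missing[:3]}")
        return np.array([self.labels[b] for b in barcodes])

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(set(self.labels.values()))


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        _check_unique(self.genes, f"genes in set {self.name!r}")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set names")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)
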