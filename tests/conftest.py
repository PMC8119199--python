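import numpy as np
import pandas as pd
import pytest

from senesig.datatypes import (
    BulkExpressionMatrix,
    CellCountMatrix,
    ClusterLabels,
    ContrastResult,
    GeneSignature,
    LogNormMatrix,
)


@pytest.fixture
def toy_bulk() -> BulkExpressionMatrix:
    """3 genes x 6 samples, 3 senescent vs 3 control, raw nRPKM scale."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.gamma(2.0, 5.0, size=(3, 6)),
        index=["GA", "GB", "GC"],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("senescent" if i < 3 else "control") for i in range(6)}
    return BulkExpressionMatrix(values=values, scale="raw_nrpkm", sample_groups=groups)


def make_contrast(records: dict[str, tuple], name: str = "toy") -> ContrastResult:
    """records: gene -> (log2_fc, mean_log2_expr, p_value, p_adjusted)."""
    table = pd.DataFrame.from_dict(
        records, orient="index", columns=["log2_fc", "mean_log2_expr", "p_value", "p_adjusted"]
    )
    return ContrastResult(contrast_name=name, table=table, n_treated=3, n_control=3)


@pytest.fixture
def toy_counts() -> CellCountMatrix:
    """5 cells x 6 genes incl. one mitochondrial gene, constructed for QC edge cases."""
    genes = ["MT-1", "g1", "g2", "g3", "g4", "g5"]
    counts = np.array(
        [
            [1, 10, 10, 10, 10, 10],  # 5 features ex-mito, ~2% mito
            [0, 5, 5, 0, 0, 0],       # 2 features
            [6, 30, 30, 30, 0, 0],    # 6% mito
            [0, 8, 8, 8, 8, 0],       # 4 features, 0% mito
            [2, 20, 20, 20, 20, 20],  # ~2% mito, 6 features
        ]
    )
    return CellCountMatrix(barcodes=[f"c{i}" for i in range(5)], gene_ids=genes, counts=counts)


@pytest.fixture
def toy_lognorm() -> LogNormMatrix:
    """4 cells x 12 genes with simple values for hand-checkable module scores."""
    rng = np.random.default_rng(7)
    values = rng.uniform(0.0, 3.0, size=(4, 12))
    return LogNormMatrix(
        barcodes=[f"c{i}" for i in range(4)],
        gene_ids=[f"g{i}" for i in range(12)],
        values=values,
    )


@pytest.fixture
def two_cluster_labels() -> ClusterLabels:
    return ClusterLabels({f"c{i}": ("A" if i < 5 else "B") for i in range(10)})


def signature(*genes, name="sig", direction="up") -> GeneSignature:
    return GeneSignature(name=name, genes=tuple(genes), direction=direction)
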