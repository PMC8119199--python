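"""Per-cluster marker detection and the three-part marker filter.

Markers are found by a Wilcoxon rank-sum test of each gene in the focal
cluster against all other cells, on log-normalized expression. The filter
keeps genes with an average log fold change of at least 0.8 (natural log)
that are either detected (>= 1 UMI) in at least 50% of the cluster's cells
or detected in no more than 10% of all other cells. Filtered marker tables
convert into signatures for re-scoring by keeping genes above a
natural-scale fold-change threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._ranksum import EXACT_MAX, ranksum_exact, ranksum_normal
from .datatypes import CellCountMatrix, ClusterLabels, GeneSignature, LogNormMatrix
from .diffexp import adjust_pvalues

logger = logging.getLogger("senesig")

MARKER_COLUMNS = ("gene", "cluster", "avg_logfc", "pct_in", "pct_out", "p", "p_adj")


def rank_markers(
    lognorm: LogNormMatrix,
    counts: CellCountMatrix,
    labels: ClusterLabels,
    cluster: str,
) -> pd.DataFrame:
    """Rank-sum marker statistics for one cluster against all other cells.

    Returns one row per gene: ``avg_logfc`` (mean in-cluster minus mean
    out-of-cluster log-normalized expression, natural log), detection
    fractions ``pct_in``/``pct_out`` from raw counts, two-sided rank-sum
    ``p`` (tie-corrected normal approximation; exact enumeration when both
    sides have <= 10 cells) and BH-adjusted ``p_adj``.
    """
    if lognorm.barcodes != counts.barcodes or lognorm.gene_ids != counts.gene_ids:
        raise ValueError("lognorm and counts must share barcodes and gene ids")
    cell_labels = labels.for_barcodes(lognorm.barcodes)
    mask = cell_labels == cluster
    if not mask.any():
        raise ValueError(f"unknown cluster {cluster!r}; available: {sorted(set(cell_labels))}")
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 3:
        raise ValueError(f"cluster {cluster!r} has {n_in} cells (< 3)")
    if n_out == 0:
        raise ValueError("complement is empty; markers are defined against other clusters")

    x = lognorm.values[mask]
    y = lognorm.values[~mask]
    avg_logfc = x.mean(axis=0) - y.mean(axis=0)
    pct_in = (counts.counts[mask] >= 1).mean(axis=0)
    pct_out = (counts.counts[~mask] >= 1).mean(axis=0)

    if n_in <= EXACT_MAX and n_out <= EXACT_MAX:
        p = np.array(
            [ranksum_exact(x[:, j], y[:, j], alternative="two-sided") for j in range(x.shape[1])]
        )
    else:
        p = ranksum_normal(x, y, alternative="two-sided")
    p_adj = adjust_pvalues(p, "bh")
    return pd.DataFrame(
        {
            "gene": lognorm.gene_ids,
            "cluster": cluster,
            "avg_logfc": avg_logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p": p,
            "p_adj": p_adj,
        }
    )


def filter_markers(
    records: pd.DataFrame,
    lfc_min: float = 0.8,
    pct_in_min: float = 0.5,
    pct_out_max: float = 0.10,
    require_both: bool = False,
) -> pd.DataFrame:
    """Apply the marker filter: lfc >= lfc_min and (pct_in >= pct_in_min or pct_out <= pct_out_max).

    ``require_both`` switches the detection disjunction to a conjunction.
    Input order is preserved; output is a subset of the input.
    """
    lfc_ok = records["avg_logfc"] >= lfc_min
    if require_both:
        det_ok = (records["pct_in"] >= pct_in_min) & (records["pct_out"] <= pct_out_max)
    else:
        det_ok = (records["pct_in"] >= pct_in_min) | (records["pct_out"] <= pct_out_max)
    return records[lfc_ok & det_ok].copy()


def markers_to_signature(
    records: pd.DataFrame,
    fc_threshold: float = 1.5,
    name: str = "marker_signature",
) -> GeneSignature:
    """Top marker genes above a natural-scale fold-change threshold, ordered by avg_logfc.

    A gene passes when exp(avg_logfc) > fc_threshold, i.e. avg_logfc >
    ln(fc_threshold).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if records.empty:
        raise ValueError("marker records are empty")
    lfc_cut = np.log(fc_threshold)
    kept = records[records["avg_logfc"] > lfc_cut].sort_values(
        "avg_logfc", ascending=False, kind="stable"
    )
    return GeneSignature(
        name=name,
        genes=tuple(kept["gene"]),
        direction="up",
        provenance={
            "fc_threshold": fc_threshold,
            "source_cluster": records["cluster"].iloc[0] if "cluster" in records else None,
        },
    )
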