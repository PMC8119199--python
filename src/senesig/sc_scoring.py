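"""Single-cell QC, normalization, signature scoring and phase annotation.

The per-cell module score is the mean log-normalized expression of the
signature genes minus the mean of a random control gene set (default 100
genes). A score above zero indicates enrichment for the signature in that
cell. Control genes can be one uniform seeded draw shared by all cells, or
expression-bin-matched to the signature (25 bins on mean expression).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._ranksum import EXACT_MAX, ranksum_exact, ranksum_normal
from .datatypes import CellCountMatrix, ClusterLabels, GeneSignature, LogNormMatrix
from .diffexp import adjust_pvalues

logger = logging.getLogger("senesig")

CTRL_MODES = ("uniform", "binned")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_low_features: int
    n_high_mito: int


def qc_filter(
    counts: CellCountMatrix,
    min_features: int = 500,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> tuple[CellCountMatrix, QCReport]:
    """Keep cells with >= min_features detected genes and <= max_mito_frac mitochondrial counts.

    Detection means at least 1 UMI. If no gene id carries the mitochondrial
    prefix the mitochondrial criterion passes vacuously, with a warning.
    """
    detected = (counts.counts >= 1).sum(axis=1)
    feat_ok = detected >= min_features
    mito_mask = np.array([g.startswith(mito_prefix) for g in counts.gene_ids])
    if not mito_mask.any():
        warnings.warn(
            f"no gene ids start with {mito_prefix!r}; mitochondrial criterion passes vacuously",
            stacklevel=2,
        )
        mito_ok = np.ones(counts.n_cells, dtype=bool)
    else:
        totals = counts.totals.astype(float)
        mito = counts.counts[:, mito_mask].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1.0), 1.0)
        mito_ok = frac <= max_mito_frac
    keep = feat_ok & mito_ok
    report = QCReport(
        n_input=counts.n_cells,
        n_kept=int(keep.sum()),
        n_low_features=int((~feat_ok).sum()),
        n_high_mito=int((feat_ok & ~mito_ok).sum()),
    )
    logger.info(
        "qc_filter: kept %d/%d cells (%d < %d features, %d > %.1f%% mito)",
        report.n_kept, report.n_input, report.n_low_features, min_features,
        report.n_high_mito, 100 * max_mito_frac,
    )
    filtered = CellCountMatrix(
        barcodes=[b for b, k in zip(counts.barcodes, keep) if k],
        gene_ids=list(counts.gene_ids),
        counts=counts.counts[keep],
        subject_ids=(
            [s for s, k in zip(counts.subject_ids, keep) if k] if counts.subject_ids else None
        ),
    )
    return filtered, report


def lognormalize(counts: CellCountMatrix, scale_factor: float = 1e4) -> LogNormMatrix:
    """Library-size normalize to ``scale_factor`` counts per cell, then log1p (natural log)."""
    totals = counts.totals.astype(float)
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        raise ValueError(f"{n_zero} cells have zero total counts; run qc_filter first")
    values = np.log1p(counts.counts / totals[:, None] * scale_factor)
    return LogNormMatrix(
        barcodes=list(counts.barcodes),
        gene_ids=list(counts.gene_ids),
        values=values,
        scale_factor=scale_factor,
    )


@dataclass
class ModuleScoreResult:
    signature_name: str
    scores: pd.Series  # indexed by barcode
    n_control: int
    seed: int
    ctrl_mode: str
    control_genes_used: list[str]
    dropped_signature_genes: list[str] = field(default_factory=list)


def module_score(
    lognorm: LogNormMatrix,
    signature: GeneSignature,
    n_control: int = 100,
    seed: int = 0,
    ctrl_mode: str = "uniform",
    n_bins: int = 25,
) -> ModuleScoreResult:
    """Per-cell signature score: mean signature expression minus mean control expression.

    ``uniform``: one seeded draw of ``n_control`` detected non-signature
    genes, without replacement, shared by every cell. ``binned``: genes are
    cut into ``n_bins`` equal-size bins by mean expression across cells and
    ``n_control`` controls are drawn from the bin of each signature gene
    (with replacement across signature genes); the control mean runs over
    the pooled multiset.
    """
    if ctrl_mode not in CTRL_MODES:
        raise ValueError(f"ctrl_mode must be one of {CTRL_MODES}")
    gene_index = {g: i for i, g in enumerate(lognorm.gene_ids)}
    present = [g for g in signature.genes if g in gene_index]
    dropped = [g for g in signature.genes if g not in gene_index]
    if dropped:
        warnings.warn(
            f"{len(dropped)} of {len(signature.genes)} signature genes absent from matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is present in the matrix")

    values = lognorm.values
    sig_idx = np.array([gene_index[g] for g in present])
    sig_set = set(present)
    detected = values.max(axis=0) > 0
    pool_idx = np.array(
        [i for i, g in enumerate(lognorm.gene_ids) if detected[i] and g not in sig_set]
    )
    rng = np.random.default_rng(seed)

    if ctrl_mode == "uniform":
        if n_control > pool_idx.size:
            raise ValueError(
                f"n_control={n_control} exceeds the {pool_idx.size} detected non-signature genes"
            )
        ctrl_idx = rng.choice(pool_idx, size=n_control, replace=False)
        ctrl_mean = values[:, ctrl_idx].mean(axis=1)
        control_used = [lognorm.gene_ids[i] for i in ctrl_idx]
    else:
        gene_means = values.mean(axis=0)
        order = np.argsort(gene_means, kind="stable")
        bins = np.empty(len(lognorm.gene_ids), dtype=int)
        bins[order] = np.arange(len(order)) * n_bins // len(order)
        bin_pools = {b: pool_idx[bins[pool_idx] == b] for b in range(n_bins)}
        drawn: list[int] = []
        for gi in sig_idx:
            pool = bin_pools.get(int(bins[gi]))
            if pool is None or pool.size == 0:
                pool = pool_idx
            take = min(n_control, pool.size)
            drawn.extend(rng.choice(pool, size=take, replace=False).tolist())
        ctrl_idx = np.array(drawn)
        ctrl_mean = values[:, ctrl_idx].mean(axis=1)
        control_used = [lognorm.gene_ids[i] for i in ctrl_idx]

    scores = values[:, sig_idx].mean(axis=1) - ctrl_mean
    return ModuleScoreResult(
        signature_name=signature.name,
        scores=pd.Series(scores, index=lognorm.barcodes, name=signature.name),
        n_control=n_control,
        seed=seed,
        ctrl_mode=ctrl_mode,
        control_genes_used=control_used,
        dropped_signature_genes=dropped,
    )


@dataclass
class ClusterScoreSummary:
    signature_name: str
    table: pd.DataFrame  # index cluster; columns mean, median, n_cells, p, q
    subject_means: Optional[pd.DataFrame] = None  # subject x cluster mean scores


def score_clusters(
    scores: ModuleScoreResult,
    labels: ClusterLabels,
    subject_ids: Optional[Sequence[str]] = None,
    alternative: str = "greater",
) -> ClusterScoreSummary:
    """Per-cluster score summary with one-sided rank-sum enrichment vs all other cells.

    p-values are BH-adjusted across clusters. Clusters with fewer than 3
    cells get p = NaN with a warning. When both sides of a comparison have
    <= 10 cells the exact permutation null is used.
    """
    barcodes = list(scores.scores.index)
    cell_labels = labels.for_barcodes(barcodes)
    vals = scores.scores.to_numpy()
    clusters = sorted(set(cell_labels))
    rows = []
    for cl in clusters:
        mask = cell_labels == cl
        inside, outside = vals[mask], vals[~mask]
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has {int(mask.sum())} cells (< 3); p set to NaN", stacklevel=2)
            p = np.nan
        elif inside.size <= EXACT_MAX and outside.size <= EXACT_MAX:
            p = ranksum_exact(inside, outside, alternative=alternative)
        else:
            p = float(ranksum_normal(inside[:, None], outside[:, None], alternative=alternative)[0])
        rows.append(
            {
                "cluster": cl,
                "mean": float(inside.mean()),
                "median": float(np.median(inside)),
                "n_cells": int(mask.sum()),
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")
    q = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        q[ok] = adjust_pvalues(table["p"].to_numpy()[ok], "bh")
    table["q"] = q

    subject_means = None
    if subject_ids is not None:
        if len(subject_ids) != len(barcodes):
            raise ValueError("subject_ids must align with scored barcodes")
        df = pd.DataFrame({"subject": list(subject_ids), "cluster": cell_labels, "score": vals})
        subject_means = df.pivot_table(index="subject", columns="cluster", values="score", aggfunc="mean")
    return ClusterScoreSummary(signature_name=scores.signature_name, table=table, subject_means=subject_means)


@dataclass
class PhaseCall:
    table: pd.DataFrame  # index barcode; columns s_score, g2m_score, phase


def cell_cycle_phase(
    lognorm: LogNormMatrix,
    s_genes: GeneSignature,
    g2m_genes: GeneSignature,
    n_control: int = 100,
    seed: int = 0,
    ctrl_mode: str = "uniform",
) -> PhaseCall:
    """Assign G1/S/G2M per cell from S and G2M marker module scores.

    A cell is called S when its S score is the strict maximum and positive,
    G2M analogously; otherwise G1 (neither program detectably active).
    """
    gene_set = set(lognorm.gene_ids)
    for sig, label in ((s_genes, "S"), (g2m_genes, "G2M")):
        if not any(g in gene_set for g in sig.genes):
            raise ValueError(f"no {label} marker gene is present in the matrix")
    child_seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    s_res = module_score(lognorm, s_genes, n_control=n_control, seed=int(child_seeds[0]), ctrl_mode=ctrl_mode)
    g2m_res = module_score(lognorm, g2m_genes, n_control=n_control, seed=int(child_seeds[1]), ctrl_mode=ctrl_mode)
    s = s_res.scores.to_numpy()
    g2m = g2m_res.scores.to_numpy()
    phase = np.where(
        (s > g2m) & (s > 0), "S", np.where((g2m > s) & (g2m > 0), "G2M", "G1")
    )
    table = pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase}, index=lognorm.barcodes
    )
    return PhaseCall(table=table)
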