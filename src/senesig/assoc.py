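"""Anchor-gene co-expression ranking and hypergeometric gene-set overlap.

``top_correlates`` ranks every gene by its (default Spearman) correlation
with an anchor gene across bulk samples — the "top N correlates" view.
``enrich_hypergeometric`` tests the overlap k between a query gene list and
each set of a collection (size K within the universe) with the
hypergeometric upper tail, reporting BH q-values and the k:K overlap label.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BulkExpressionMatrix, GeneSetCollection, GeneSignature
from .diffexp import adjust_pvalues

CORR_METHODS = ("spearman", "pearson")


def top_correlates(
    expr: BulkExpressionMatrix,
    anchor_gene: str,
    k: int = 50,
    method: str = "spearman",
) -> pd.DataFrame:
    """Top-k genes by correlation with the anchor across samples.

    The anchor itself is excluded; ties in rho break lexically on gene id.
    Genes with zero variance get rho = NaN and sort last.
    """
    if method not in CORR_METHODS:
        raise ValueError(f"method must be one of {CORR_METHODS}")
    if anchor_gene not in expr.values.index:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from matrix")
    if len(expr.sample_ids) < 4:
        raise ValueError("need >= 4 samples for a meaningful correlation")
    mat = expr.values.to_numpy(dtype=float)
    if method == "spearman":
        mat = stats.rankdata(mat, axis=1)
    anchor = mat[expr.values.index.get_loc(anchor_gene)]
    if np.std(anchor) == 0:
        raise ValueError(f"anchor gene {anchor_gene!r} is constant; correlation undefined")
    centered = mat - mat.mean(axis=1, keepdims=True)
    a = anchor - anchor.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (a**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, centered @ a / np.where(denom > 0, denom, 1.0), np.nan)
    df = pd.DataFrame({"gene": expr.gene_ids, "rho": rho})
    df = df[df["gene"] != anchor_gene]
    df = df.sort_values(["rho", "gene"], ascending=[False, True], kind="stable", na_position="last")
    df = df.head(k).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def enrich_hypergeometric(
    query: GeneSignature,
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Overlap enrichment of a query gene list against a gene-set collection.

    For each set: k = |set ∩ query|, K = |set ∩ universe|, and
    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size and
    n the in-universe query size. q is BH across all sets; rows sort by
    ascending p (stable). Query genes outside the universe are dropped with
    a warning.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_in = [g for g in query.genes if g in universe_set]
    n_dropped = len(query.genes) - len(query_in)
    if n_dropped:
        warnings.warn(f"{n_dropped} query genes outside the universe were dropped", stacklevel=2)
    n_query = len(query_in)
    n_universe = len(universe_set)
    query_set = set(query_in)
    rows = []
    for gs in collection:
        members = set(gs.genes) & universe_set
        K = len(members)
        k_ov = len(members & query_set)
        p = float(stats.hypergeom.sf(k_ov - 1, n_universe, K, n_query)) if K else 1.0
        rows.append(
            {
                "set_name": gs.name,
                "k": k_ov,
                "K": K,
                "n_query": n_query,
                "N_universe": n_universe,
                "p": min(p, 1.0),
                "k_over_K": f"{k_ov}:{K}",
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = adjust_pvalues(df["p"].to_numpy(), "bh") if len(df) else []
    df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df[["set_name", "k", "K", "n_query", "N_universe", "p", "q", "k_over_K"]]


def default_universe(expr_genes: list[str], collection: GeneSetCollection) -> list[str]:
    """Genes present in the expression matrix that appear in the collection's union."""
    union: set[str] = set()
    for gs in collection:
        union.update(gs.genes)
    return [g for g in expr_genes if g in union]
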