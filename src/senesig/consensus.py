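"""Consensus signature derivation and cross-contrast comparison.

A consensus senescence signature is the thresholded intersection of several
induction contrasts: within each contrast, genes are kept when they show at
least a two-fold change, an adjusted p <= 0.05 and an average log2
expression >= 1.0; the consensus is the set of genes passing in (by
default) every contrast. Cross-contrast agreement is quantified by the
Spearman correlation of log2 fold changes with a Fisher-z 95% CI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import ContrastResult, GeneSignature

UNIVERSE_MODES = ("union_of_significant", "all_genes")


def filter_de(
    contrast: ContrastResult,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    mean_min: float = 1.0,
    direction: str = "up",
) -> GeneSignature:
    """Threshold one contrast into a directional gene signature.

    Keeps genes with |log2 fold change| >= log2(fc_min) in the requested
    direction, adjusted p <= alpha and mean log2 expression >= mean_min.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    t = contrast.table
    log2_min = np.log2(fc_min)
    if direction == "up":
        fc_ok = t["log2_fc"] >= log2_min
    else:
        fc_ok = t["log2_fc"] <= -log2_min
    keep = fc_ok & (t["p_adjusted"] <= alpha) & (t["mean_log2_expr"] >= mean_min)
    genes = tuple(t.index[keep])
    return GeneSignature(
        name=f"{contrast.contrast_name}_{direction}",
        genes=genes,
        direction=direction,
        provenance={
            "fc_min": fc_min,
            "alpha": alpha,
            "mean_min": mean_min,
            "contrasts": [contrast.contrast_name],
            "min_support": 1,
        },
    )


def intersect_signatures(
    signatures: list[GeneSignature],
    min_support: int | None = None,
    name: str = "consensus",
) -> GeneSignature:
    """Genes appearing in at least ``min_support`` signatures (default: all).

    Output order: descending support count, then lexical — deterministic for
    diffing.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures to intersect")
    directions = {s.direction for s in signatures}
    if len(directions) > 1:
        raise ValueError(f"signatures mix directions {sorted(directions)}")
    if min_support is None:
        min_support = len(signatures)
    if not 1 <= min_support <= len(signatures):
        raise ValueError("min_support must be between 1 and the number of signatures")
    support: dict[str, int] = {}
    for sig in signatures:
        for g in sig.genes:
            support[g] = support.get(g, 0) + 1
    kept = [g for g, c in support.items() if c >= min_support]
    kept.sort(key=lambda g: (-support[g], g))
    return GeneSignature(
        name=name,
        genes=tuple(kept),
        direction=signatures[0].direction,
        provenance={
            "contrasts": [s.name for s in signatures],
            "min_support": min_support,
        },
    )


@dataclass
class OverlapReport:
    """Exact inclusion-exclusion partition over 2-4 gene signatures.

    ``region_counts`` maps a tuple of member signature names (the signatures
    a region's genes belong to, and no others) to the region's gene count.
    """

    set_names: list[str]
    region_counts: dict[tuple[str, ...], int]
    union_size: int
    intersection_size: int

    def count(self, *names: str) -> int:
        return self.region_counts.get(tuple(sorted(names)), 0)


def overlap_counts(signatures: list[GeneSignature]) -> OverlapReport:
    """Venn-style exact region counts for 2-4 signatures."""
    if not 2 <= len(signatures) <= 4:
        raise ValueError("overlap_counts handles 2-4 signatures; use intersect_signatures for more")
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")
    members = {s.name: set(s.genes) for s in signatures}
    union = set().union(*members.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(sorted(names), r):
            regions[combo] = 0
    for gene in union:
        key = tuple(sorted(n for n in names if gene in members[n]))
        regions[key] += 1
    inter = set(members[names[0]])
    for n in names[1:]:
        inter &= members[n]
    return OverlapReport(
        set_names=names,
        region_counts=regions,
        union_size=len(union),
        intersection_size=len(inter),
    )


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n_genes: int
    universe_mode: str
    p_value: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rho <= self.ci_high):
            raise ValueError("CI must bracket rho")


def fisher_z_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% CI for a correlation via tanh(atanh(rho) +/- z/sqrt(n-3))."""
    if abs(rho) >= 1.0 - 1e-15 or n <= 3:
        return rho, rho
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(rho)
    half = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def cross_contrast_correlation(
    a: ContrastResult,
    b: ContrastResult,
    universe_mode: str = "union_of_significant",
    fc_min: float = 2.0,
    alpha: float = 0.05,
    mean_min: float = 1.0,
) -> CorrelationResult:
    """Spearman correlation of log2 fold changes between two contrasts.

    ``union_of_significant`` restricts to genes passing the filter_de
    thresholds (either direction) in at least one of the two contrasts;
    ``all_genes`` uses every shared gene.
    """
    if universe_mode not in UNIVERSE_MODES:
        raise ValueError(f"universe_mode must be one of {UNIVERSE_MODES}")
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if universe_mode == "union_of_significant":
        sig: set[str] = set()
        for contrast in (a, b):
            for direction in ("up", "down"):
                sig.update(filter_de(contrast, fc_min, alpha, mean_min, direction).genes)
        universe = [g for g in shared if g in sig]
    else:
        universe = shared
    if len(universe) < 10:
        raise ValueError(
            f"correlation universe has only {len(universe)} genes (< 10) under mode {universe_mode!r}"
        )
    fa = a.table.loc[universe, "log2_fc"].to_numpy()
    fb = b.table.loc[universe, "log2_fc"].to_numpy()
    rho, p = stats.spearmanr(fa, fb)
    rho = float(rho)
    lo, hi = fisher_z_ci(rho, len(universe))
    return CorrelationResult(
        rho=rho, ci_low=lo, ci_high=hi, n_genes=len(universe), universe_mode=universe_mode, p_value=float(p)
    )
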