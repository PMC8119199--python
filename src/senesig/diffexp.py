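"""Two-group differential expression on log2 bulk expression.

The contrast is a per-gene two-sample t on log2(nRPKM + pseudocount), with
optional empirical-Bayes variance moderation in the limma spirit: each
gene's pooled sample variance s_g^2 is shrunk toward a common prior
variance s_0^2,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

where the prior degrees of freedom d0 and s0^2 are method-of-moments
estimates from the empirical distribution of log sample variances (the
digamma/trigamma moment equations of a scaled chi-square model). The
moderated t uses d0 + d_g degrees of freedom, so with many residual degrees
of freedom the moderated and plain t agree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import LOG2, RAW_NRPKM, BulkExpressionMatrix, ContrastResult

logger = logging.getLogger("senesig")

MODERATION_MODES = ("none", "empirical_bayes")
ADJUST_METHODS = ("bonferroni", "bh")


@dataclass
class DEOptions:
    pseudocount: float = 1e-4
    moderation: str = "empirical_bayes"
    adjust_method: str = "bh"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.moderation not in MODERATION_MODES:
            raise ValueError(f"moderation must be one of {MODERATION_MODES}")
        if self.adjust_method not in ADJUST_METHODS:
            raise ValueError(f"adjust_method must be one of {ADJUST_METHODS}")


def log2_transform(matrix: BulkExpressionMatrix, pseudocount: float = 1e-4) -> BulkExpressionMatrix:
    """log2(value + pseudocount) on a raw nRPKM matrix; flips the scale flag."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if matrix.scale != RAW_NRPKM:
        raise ValueError("matrix is already log2-transformed")
    values = np.log2(matrix.values + pseudocount)
    return BulkExpressionMatrix(values=values, scale=LOG2, sample_groups=dict(matrix.sample_groups))


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex target)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Under the scaled chi-square model, z_g = log(s_g^2) has
    E[z] = log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
    and Var[z] = psi'(df/2) + psi'(d0/2); matching the empirical mean and
    variance of z yields the estimates. Returns (inf, exp(mean adjustment))
    when the observed spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward the moment-matched prior."""
    d0, s0_sq = estimate_prior_variance(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    else:
        s2_tilde = (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)
    return s2_tilde, d0, s0_sq


def de_two_group(
    log_expr: BulkExpressionMatrix,
    treated_group: str,
    control_group: str,
    options: DEOptions | None = None,
    contrast_name: str | None = None,
) -> ContrastResult:
    """Per-gene (moderated) two-sample t contrast on a log2 matrix.

    log2_fc = mean(treated) - mean(control); p two-sided from the pooled-
    variance t, with empirical-Bayes shrinkage of the pooled variances when
    ``options.moderation == "empirical_bayes"``. Zero-variance genes follow
    the continuity convention: no difference -> p = 1; a nonzero difference
    with literally zero variance -> p = 0 with a warning.
    """
    options = options or DEOptions()
    if log_expr.scale != LOG2:
        raise ValueError("de_two_group expects a log2-transformed matrix; run log2_transform first")
    groups = set(log_expr.sample_groups.values())
    for g in (treated_group, control_group):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}; available: {sorted(groups)}")
    if treated_group == control_group:
        raise ValueError("treated and control groups must differ")
    treated = log_expr.samples_in_group(treated_group)
    control = log_expr.samples_in_group(control_group)
    n1, n2 = len(treated), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (treated={n1}, control={n2})")

    x = log_expr.values[treated].to_numpy()
    y = log_expr.values[control].to_numpy()
    mean1 = x.mean(axis=1)
    mean2 = y.mean(axis=1)
    log2_fc = mean1 - mean2
    mean_all = np.hstack([x, y]).mean(axis=1)

    df_resid = n1 + n2 - 2
    s2_pooled = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df_resid

    if options.moderation == "empirical_bayes":
        s2_used, d0, _ = squeeze_variances(s2_pooled, df_resid)
        df_total = df_resid + d0
    else:
        s2_used = s2_pooled
        df_total = float(df_resid)

    se = np.sqrt(s2_used * (1.0 / n1 + 1.0 / n2))
    p = np.ones_like(log2_fc)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, log2_fc / np.where(ok, se, 1.0), 0.0)
    if np.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df_total)
    degenerate = ~ok & (log2_fc != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes have zero variance but nonzero difference; p set to 0",
            stacklevel=2,
        )
        p[degenerate] = 0.0
    # zero variance, zero difference stays at p = 1

    p_adj = adjust_pvalues(p, options.adjust_method)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "mean_log2_expr": mean_all,
            "p_value": p,
            "p_adjusted": p_adj,
        },
        index=log_expr.values.index,
    )
    return ContrastResult(
        contrast_name=contrast_name or f"{treated_group}_vs_{control_group}",
        table=table,
        n_treated=n1,
        n_control=n2,
    )
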