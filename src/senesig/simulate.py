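"""Synthetic bulk induction experiments and clustered single-cell counts.

Counts follow a Gamma-Poisson (negative binomial) law with a shared
dispersion, the minimal overdispersed RNA-seq noise model. The bulk
generator emulates several two-group senescence-induction contrasts with a
planted set of shared up-regulated genes (plus optional contrast-private
genes); the single-cell generator emulates a clustered population with one
planted "senescent" cluster — signature genes up, proliferation genes down,
SASP genes up, mostly G1 — and otherwise exchangeable clusters up to a mild
per-cluster profile jitter. Every planted choice is recorded in a
``SimTruth`` so downstream recovery is checkable without real data.

Defaults are desk-scale study conditions: four contrasts at n = 4 per
group, 200 shared induced genes at fold 4, NB dispersion 0.1; 3,000 cells
in 6 clusters with a 100-gene signature at fold 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import BulkExpressionMatrix, CellCountMatrix, ClusterLabels

PHASES = ("G1", "S", "G2M")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ContrastConfig:
    """One simulated induction contrast (senescent vs control cultures)."""

    name: str
    fold_change: float = 4.0
    n_private_induced: int = 50
    induced_genes: Optional[list[str]] = None  # explicit override (includes shared)

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")


@dataclass
class BulkSimConfig:
    n_genes: int = 5000
    n_per_group: int = 4
    contrasts: list[ContrastConfig] = field(
        default_factory=lambda: [
            ContrastConfig("model_A"),
            ContrastConfig("model_B"),
            ContrastConfig("model_C"),
            ContrastConfig("model_D"),
        ]
    )
    n_shared_induced: int = 200
    shared_induced_genes: Optional[list[str]] = None
    baseline_log_mean: float = float(np.log(500.0))
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        names = [c.name for c in self.contrasts]
        if len(set(names)) != len(names):
            raise ValueError("contrast names must be unique")


@dataclass
class SenescentClusterConfig:
    """Planted senescent cluster: signature up, proliferation down, SASP up, G1 arrest."""

    name: str = "senescent"
    n_signature_genes: int = 100
    up_fold: float = 4.0
    n_proliferation_genes: int = 20
    down_fold: float = 0.25
    n_sasp_genes: int = 20
    sasp_fold: float = 4.0
    g1_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.g1_fraction <= 1.0:
            raise ValueError("g1_fraction must lie in [0, 1]")


@dataclass
class ClusterConfig:
    name: str
    proportion: float
    mean_profile_shift: float = 0.1  # sd of per-gene lognormal jitter on the cluster profile


@dataclass
class ScSimConfig:
    n_cells: int = 3000
    n_genes: int = 2000
    clusters: Optional[list[ClusterConfig]] = None  # default: equal split incl. senescent
    senescent: Optional[SenescentClusterConfig] = field(default_factory=SenescentClusterConfig)
    n_s_genes: int = 40
    n_g2m_genes: int = 50
    phase_fold: float = 8.0
    phase_baseline_factor: float = 0.25
    phase_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)  # G1/S/G2M outside senescent
    mito_gene_count: int = 10
    mito_frac: float = 0.03
    depth_log_mean: float = float(np.log(5000.0))
    depth_log_sd: float = 0.25
    baseline_log_sd: float = 0.1
    nb_dispersion: float = 0.1
    n_subjects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.clusters is None:
            n_bg = 5 if self.senescent is not None else 1
            names = [f"C{i + 1}" for i in range(n_bg)]
            total = n_bg + (1 if self.senescent is not None else 0)
            self.clusters = [ClusterConfig(n, 1.0 / total) for n in names]
            if self.senescent is not None:
                self.clusters.append(ClusterConfig(self.senescent.name, 1.0 / total))
        props = sum(c.proportion for c in self.clusters)
        if abs(props - 1.0) > 1e-9:
            raise ValueError(f"cluster proportions sum to {props}, not 1")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")
        if self.senescent is not None and self.senescent.name not in names:
            raise ValueError("senescent cluster name missing from cluster list")
        if abs(sum(self.phase_probs) - 1.0) > 1e-9:
            raise ValueError("phase_probs must sum to 1")


@dataclass
class SimTruth:
    """Ground truth for a simulation: planted gene sets and per-cell assignments."""

    shared_induced: list[str] = field(default_factory=list)
    per_contrast_induced: dict = field(default_factory=dict)
    senescent_cluster: Optional[str] = None
    signature_genes: list[str] = field(default_factory=list)
    proliferation_genes: list[str] = field(default_factory=list)
    sasp_genes: list[str] = field(default_factory=list)
    s_phase_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)
    cell_clusters: dict = field(default_factory=dict)
    cell_phases: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# count machinery


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam)


def _to_nrpkm(counts: np.ndarray) -> np.ndarray:
    """Library-size normalize each sample (column) to reads-per-million.

    All simulated genes share one gene-model length, so the per-kilobase
    term is a constant and is dropped; the result is an nRPKM-like scale
    whose two-group ratios match the true fold changes.
    """
    totals = counts.sum(axis=0, keepdims=True).astype(float)
    return counts / np.maximum(totals, 1.0) * 1e6


# ---------------------------------------------------------------------------
# bulk simulation


def simulate_bulk(config: BulkSimConfig) -> tuple[dict[str, BulkExpressionMatrix], SimTruth]:
    """Simulate one bulk induction experiment per configured contrast.

    Gene-level baseline means are lognormal and shared across contrasts;
    treated samples have their means multiplied by the contrast's fold
    change on its induced genes (shared planted set plus contrast-private
    genes). Counts are negative binomial and are returned on the normalized
    nRPKM-like scale with groups "senescent" and "control".
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    gene_set = set(genes)
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes))

    if config.shared_induced_genes is not None:
        unknown = [g for g in config.shared_induced_genes if g not in gene_set]
        if unknown:
            raise ValueError(f"shared induced set references unknown genes: {unknown[:5]}")
        shared = list(config.shared_induced_genes)
    else:
        shared = rng.choice(genes, size=config.n_shared_induced, replace=False).tolist()

    available = [g for g in genes if g not in set(shared)]
    rng.shuffle(available)
    cursor = 0
    per_contrast: dict[str, list[str]] = {}
    for c in config.contrasts:
        if c.induced_genes is not None:
            unknown = [g for g in c.induced_genes if g not in gene_set]
            if unknown:
                raise ValueError(f"contrast {c.name!r} references unknown genes: {unknown[:5]}")
            if not set(shared) <= set(c.induced_genes):
                raise ValueError(f"contrast {c.name!r} induced set must contain the shared set")
            per_contrast[c.name] = list(c.induced_genes)
        else:
            private = available[cursor : cursor + c.n_private_induced]
            cursor += c.n_private_induced
            per_contrast[c.name] = shared + private

    gene_pos = {g: i for i, g in enumerate(genes)}
    matrices: dict[str, BulkExpressionMatrix] = {}
    n = config.n_per_group
    for c in config.contrasts:
        fold = np.ones(config.n_genes)
        fold[[gene_pos[g] for g in per_contrast[c.name]]] = c.fold_change
        ctrl_mean = np.tile(baseline[:, None], (1, n))
        trt_mean = np.tile((baseline * fold)[:, None], (1, n))
        mean = np.hstack([ctrl_mean, trt_mean])
        counts = _nb_counts(rng, mean, config.nb_dispersion)
        sample_ids = [f"{c.name}_ctrl_{i + 1}" for i in range(n)] + [
            f"{c.name}_sen_{i + 1}" for i in range(n)
        ]
        groups = {s: ("control" if i < n else "senescent") for i, s in enumerate(sample_ids)}
        values = pd.DataFrame(_to_nrpkm(counts), index=genes, columns=sample_ids)
        matrices[c.name] = BulkExpressionMatrix(values=values, scale="raw_nrpkm", sample_groups=groups)

    truth = SimTruth(shared_induced=shared, per_contrast_induced=per_contrast)
    return matrices, truth


# ---------------------------------------------------------------------------
# single-cell simulation


def _sc_gene_names(config: ScSimConfig) -> dict[str, list[str]]:
    sen = config.senescent
    named = {
        "signature": [f"SIG{i + 1:04d}" for i in range(sen.n_signature_genes)] if sen else [],
        "proliferation": [f"PRLF{i + 1:03d}" for i in range(sen.n_proliferation_genes)] if sen else [],
        "sasp": [f"SASP{i + 1:03d}" for i in range(sen.n_sasp_genes)] if sen else [],
        "s_phase": [f"SPH{i + 1:03d}" for i in range(config.n_s_genes)],
        "g2m": [f"G2M{i + 1:03d}" for i in range(config.n_g2m_genes)],
        "mito": [f"MT-{i + 1}" for i in range(config.mito_gene_count)],
    }
    n_special = sum(len(v) for v in named.values())
    if n_special > config.n_genes:
        raise ValueError(
            f"planted gene lists need {n_special} genes but n_genes is {config.n_genes}"
        )
    named["filler"] = [f"G{i + 1:05d}" for i in range(config.n_genes - n_special)]
    all_names = [g for v in named.values() for g in v]
    if len(set(all_names)) != len(all_names):
        raise ValueError("planted gene lists overlap")
    return named


def simulate_sc(config: ScSimConfig) -> tuple[CellCountMatrix, ClusterLabels, SimTruth]:
    """Simulate a clustered single-cell UMI count matrix with planted structure.

    Per-cell depth is lognormal; each cluster has a mildly jittered copy of
    a common lognormal gene profile; the senescent cluster additionally
    multiplies signature/proliferation/SASP gene means by the configured
    folds and draws phase G1 with probability ``g1_fraction``. S and G2M
    cells (any cluster) boost their phase marker genes; phase markers sit
    below baseline elsewhere so their module scores are negative outside
    the active phase. Mitochondrial genes ("MT-" prefix) carry a configured
    share of depth.
    """
    rng = np.random.default_rng(config.seed)
    named = _sc_gene_names(config)
    genes = [g for v in named.values() for g in v]
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    weights = np.exp(rng.normal(0.0, config.baseline_log_sd, n_genes))
    s_idx = np.array([gene_pos[g] for g in named["s_phase"]], dtype=int)
    g2m_idx = np.array([gene_pos[g] for g in named["g2m"]], dtype=int)
    phase_idx = np.concatenate([s_idx, g2m_idx]) if (s_idx.size or g2m_idx.size) else np.array([], dtype=int)
    weights[phase_idx] *= config.phase_baseline_factor
    mito_idx = np.array([gene_pos[g] for g in named["mito"]], dtype=int)
    if mito_idx.size and config.mito_frac > 0:
        non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
        target = config.mito_frac / (1.0 - config.mito_frac) * weights[non_mito].sum()
        weights[mito_idx] = target / mito_idx.size

    cluster_names = [c.name for c in config.clusters]
    proportions = np.array([c.proportion for c in config.clusters])
    profiles = {}
    for c in config.clusters:
        prof = weights.copy()
        if c.mean_profile_shift > 0:
            prof = prof * np.exp(rng.normal(0.0, c.mean_profile_shift, n_genes))
        if config.senescent is not None and c.name == config.senescent.name:
            sen = config.senescent
            prof[[gene_pos[g] for g in named["signature"]]] *= sen.up_fold
            prof[[gene_pos[g] for g in named["proliferation"]]] *= sen.down_fold
            prof[[gene_pos[g] for g in named["sasp"]]] *= sen.sasp_fold
        profiles[c.name] = prof

    cell_cluster = rng.choice(cluster_names, size=config.n_cells, p=proportions)
    phases = np.empty(config.n_cells, dtype=object)
    sen_name = config.senescent.name if config.senescent is not None else None
    for i, cl in enumerate(cell_cluster):
        if cl == sen_name:
            g1 = config.senescent.g1_fraction
            probs = (g1, (1 - g1) / 2.0, (1 - g1) / 2.0)
        else:
            probs = config.phase_probs
        phases[i] = rng.choice(PHASES, p=probs)

    depth = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, config.n_cells))
    counts = np.zeros((config.n_cells, n_genes), dtype=np.int64)
    for cl in cluster_names:
        for ph in PHASES:
            mask = (cell_cluster == cl) & (phases == ph)
            if not mask.any():
                continue
            prof = profiles[cl].copy()
            if ph == "S" and s_idx.size:
                prof[s_idx] *= config.phase_fold
            elif ph == "G2M" and g2m_idx.size:
                prof[g2m_idx] *= config.phase_fold
            p = prof / prof.sum()
            mean = depth[mask][:, None] * p[None, :]
            counts[mask] = _nb_counts(rng, mean, config.nb_dispersion)

    barcodes = [f"cell{i + 1:05d}" for i in range(config.n_cells)]
    subject_ids = (
        [f"subj{(i % config.n_subjects) + 1}" for i in range(config.n_cells)]
        if config.n_subjects > 0
        else None
    )
    matrix = CellCountMatrix(barcodes=barcodes, gene_ids=genes, counts=counts, subject_ids=subject_ids)
    labels = ClusterLabels(labels=dict(zip(barcodes, cell_cluster)))
    truth = SimTruth(
        senescent_cluster=sen_name,
        signature_genes=named["signature"],
        proliferation_genes=named["proliferation"],
        sasp_genes=named["sasp"],
        s_phase_genes=named["s_phase"],
        g2m_genes=named["g2m"],
        cell_clusters=dict(zip(barcodes, cell_cluster)),
        cell_phases=dict(zip(barcodes, phases)),
    )
    return matrix, labels, truth


def null_sc_config(n_cells: int = 1000, n_genes: int = 2000, seed: int = 0) -> ScSimConfig:
    """One homogeneous cluster, no planted effects — a null for score calibration."""
    return ScSimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        clusters=[ClusterConfig("C1", 1.0, mean_profile_shift=0.0)],
        senescent=None,
        n_s_genes=0,
        n_g2m_genes=0,
        seed=seed,
    )
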