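"""Dual-target docking-score selectivity funnel.

Stage 1 keeps compounds that bind the target strongly (docking score strictly
below the target cutoff, default -8.5 kcal/mol); stage 2 keeps, among those,
compounds that bind the off-target weakly (score strictly above the off-target
cutoff, default -5.0 kcal/mol).  Survivors are reduced to ``n`` structurally
representative compounds by seeded k-medoids clustering on standardized
descriptors (medoids are returned, so every representative is an actual
survivor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_data import DescriptorMatrix, DockingScoreTable


@dataclass
class FunnelConfig:
    target_name: str = "glucosidase"
    offtarget_name: str = "amylase"
    target_cutoff: float = -8.5
    offtarget_cutoff: float = -5.0
    n_representatives: int = 20

    def __post_init__(self) -> None:
        if self.target_cutoff >= 0:
            raise ValueError("target_cutoff must be negative (binding energy)")
        if self.n_representatives < 1:
            raise ValueError("n_representatives must be >= 1")


@dataclass
class FunnelReport:
    """Stage counts and per-compound pass/fail provenance.

    ``provenance`` maps compound id -> one of ``target_pass``,
    ``target_fail``, ``missing_target``, ``selective_pass``,
    ``offtarget_fail``, ``missing_offtarget``, ``representative``.
    Counts are non-increasing through stages.
    """

    n_input: int = 0
    n_target_pass: int = 0
    n_selective: int = 0
    n_representatives: int = 0
    provenance: dict[str, str] = field(default_factory=dict)


def filter_target(scores: DockingScoreTable, cfg: FunnelConfig) -> tuple[DockingScoreTable, dict[str, str]]:
    """Keep compounds with target score strictly below the target cutoff.

    A score exactly at the cutoff is excluded ("lower than" is strict).
    Compounds with a missing target score are excluded with provenance
    ``missing_target``.
    """
    if cfg.target_name not in scores.scores.columns:
        raise KeyError(f"target column {cfg.target_name!r} absent from score table")
    col = scores.scores[cfg.target_name]
    prov: dict[str, str] = {}
    keep: list[str] = []
    for cid, s in col.items():
        if pd.isna(s):
            prov[cid] = "missing_target"
        elif s < cfg.target_cutoff:
            prov[cid] = "target_pass"
            keep.append(cid)
        else:
            prov[cid] = "target_fail"
    return DockingScoreTable(scores=scores.scores.loc[keep]), prov


def filter_selectivity(scores: DockingScoreTable, cfg: FunnelConfig) -> tuple[DockingScoreTable, dict[str, str]]:
    """Keep compounds with off-target score strictly above the off-target
    cutoff, i.e. weak off-target binders (selective candidates).
    """
    if cfg.offtarget_name not in scores.scores.columns:
        raise KeyError(f"off-target column {cfg.offtarget_name!r} absent from score table")
    col = scores.scores[cfg.offtarget_name]
    prov: dict[str, str] = {}
    keep: list[str] = []
    for cid, s in col.items():
        if pd.isna(s):
            prov[cid] = "missing_offtarget"
        elif s > cfg.offtarget_cutoff:
            prov[cid] = "selective_pass"
            keep.append(cid)
        else:
            prov[cid] = "offtarget_fail"
    return DockingScoreTable(scores=scores.scores.loc[keep]), prov


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix; returns medoid
    indices (sorted).  Greedy: random init, then alternate assignment and
    within-cluster medoid update until stable."""
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(assign == j)[0]
            if len(members) == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.sort(medoids)


def tanimoto_distance(fp: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto (Jaccard) distance for a binary fingerprint matrix."""
    fp = np.asarray(fp, dtype=float)
    inter = fp @ fp.T
    counts = fp.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return 1.0 - sim


def pick_representatives(
    survivors: DescriptorMatrix,
    n: int = 20,
    seed: int = 0,
    metric: str = "euclidean",
) -> list[str]:
    """Cluster survivors into min(n, |survivors|) groups and return medoids.

    ``metric`` is ``euclidean`` on standardized descriptors, or ``tanimoto``
    when the matrix holds binary fingerprints.  If there are no more survivors
    than requested representatives, all survivors are returned.
    """
    ids = survivors.compound_ids
    if len(ids) <= n:
        return list(ids)
    x = survivors.values.to_numpy(dtype=float)
    if metric == "tanimoto":
        dist = tanimoto_distance(x)
    elif metric == "euclidean":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        sq = (z * z).sum(axis=1)
        dist = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * z @ z.T, 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    medoids = _kmedoids(dist, n, rng)
    return [ids[i] for i in medoids]


def run_funnel(
    scores: DockingScoreTable,
    cfg: FunnelConfig,
    descriptors: DescriptorMatrix | None = None,
    seed: int = 0,
) -> tuple[FunnelReport, list[str]]:
    """Run both filter stages and, if descriptors are given, pick
    representatives among the selective survivors.

    Returns the report and the final compound list (representatives when
    descriptors are supplied, otherwise all selective survivors).
    """
    report = FunnelReport(n_input=len(scores))
    stage1, prov1 = filter_target(scores, cfg)
    report.provenance.update(prov1)
    report.n_target_pass = len(stage1)
    stage2, prov2 = filter_selectivity(stage1, cfg)
    report.provenance.update(prov2)
    report.n_selective = len(stage2)

    selective_ids = stage2.compound_ids
    if descriptors is not None and selective_ids:
        sub = descriptors.subset_rows(selective_ids)
        reps = pick_representatives(sub, n=cfg.n_representatives, seed=seed)
    else:
        reps = list(selective_ids)[: cfg.n_representatives] if descriptors is not None else list(selective_ids)
    for cid in reps:
        report.provenance[cid] = "representative"
    report.n_representatives = len(reps)
    return report, reps
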