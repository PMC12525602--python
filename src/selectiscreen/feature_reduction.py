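"""Variable clustering and representative selection for descriptor matrices.

Correlated descriptors are grouped by agglomerative hierarchical clustering on
the distance 1 - |Pearson r| (average linkage), cut to ``k`` clusters.  Within
each cluster the first principal component of the member submatrix is the
cluster component; for each member variable v,

    R2_own(v)  = squared correlation of v with its own cluster component
    R2_next(v) = max squared correlation of v with any other cluster component
    ratio(v)   = (1 - R2_own) / (1 - R2_next)

and the member with the smallest ratio represents the cluster (ties broken by
lexicographic name).  This is the varclus-style "1 - R^2 ratio" selection.
An optional univariate pre-filter (one-way F statistic between classes, keep
the top m) can be applied before clustering; it is disabled by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chem_data import DescriptorMatrix


@dataclass
class VariableCluster:
    """One cluster of descriptors with its component and selection ratios."""

    cluster_id: int
    members: list[str]
    component_loadings: np.ndarray  # first-PC scores over compounds
    representative: str
    one_minus_r2_ratio_by_member: dict[str, float] = field(default_factory=dict)


@dataclass
class ReductionResult:
    clusters: list[VariableCluster]
    selected_features: list[str]
    dropped_features: dict[str, str] = field(default_factory=dict)  # name -> reason


def drop_degenerate(matrix: DescriptorMatrix, var_tol: float = 1e-12) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Remove columns with variance <= ``var_tol`` (or any non-finite value).

    Returns the reduced matrix and a name -> reason record of removals.

    Raises
    ------
    ValueError
        If every column is degenerate.
    """
    dropped: dict[str, str] = {}
    keep: list[str] = []
    vals = matrix.values
    for col in vals.columns:
        x = vals[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            dropped[col] = "non-finite values"
        elif np.var(x) <= var_tol:
            dropped[col] = "zero variance"
        else:
            keep.append(col)
    if not keep:
        raise ValueError("all descriptor columns are degenerate")
    return matrix.subset_columns(keep), dropped


def prefilter_f_score(matrix: DescriptorMatrix, m: int) -> DescriptorMatrix:
    """Keep the top-``m`` descriptors by one-way F statistic between classes.

    Univariate screen applied before clustering when enabled; requires labels.
    """
    if matrix.labels is None:
        raise ValueError("prefilter requires labels")
    if m >= matrix.n_descriptors:
        return matrix
    from sklearn.feature_selection import f_classif

    f, _ = f_classif(matrix.values.to_numpy(dtype=float), matrix.labels.to_numpy())
    f = np.nan_to_num(f, nan=-np.inf)
    order = np.argsort(-f, kind="stable")[:m]
    cols = [matrix.values.columns[i] for i in sorted(order)]
    return matrix.subset_columns(cols)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _first_pc(x: np.ndarray) -> np.ndarray:
    """First principal-component score vector of a standardized submatrix."""
    if x.shape[1] == 1:
        return x[:, 0]
    # SVD on the centered (already standardized) data
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pc = u[:, 0] * s[0]
    # fix sign: positive correlation with the member mean, for determinism
    ref = x.mean(axis=1)
    if np.dot(pc, ref) < 0:
        pc = -pc
    return pc


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0 if either vector is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def one_minus_r2_ratio(r2_own: float, r2_next: float) -> float:
    """(1 - R2_own)/(1 - R2_next) with the degenerate-denominator guard."""
    num = 1.0 - r2_own
    den = 1.0 - r2_next
    if den <= 0.0:
        return 0.0 if num <= 1e-15 else math.inf
    return num / den


def cluster_variables(matrix: DescriptorMatrix, k: int) -> list[VariableCluster]:
    """Cluster descriptors into ``k`` groups and compute 1-R^2 ratios.

    Columns are standardized before correlation.  With a single cluster the
    "next closest" component does not exist and R2_next is taken as 0.

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of columns or ``k < 1``.
    """
    names = list(matrix.values.columns)
    p = len(names)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available descriptor columns")

    x = _standardize(matrix.values.to_numpy(dtype=float))
    if k == p:
        assignments = np.arange(1, p + 1)
    else:
        corr = np.corrcoef(x, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - np.abs(corr)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        z = linkage(squareform(dist, checks=False), method="average")
        assignments = fcluster(z, t=k, criterion="maxclust")

    # stable cluster ids: order of first appearance in column order
    seen: dict[int, int] = {}
    for a in assignments:
        if a not in seen:
            seen[a] = len(seen) + 1
    ids = np.array([seen[a] for a in assignments])

    components: dict[int, np.ndarray] = {}
    members_by_id: dict[int, list[int]] = {}
    for cid in range(1, ids.max() + 1):
        idx = np.where(ids == cid)[0]
        members_by_id[cid] = list(idx)
        components[cid] = _first_pc(x[:, idx])

    clusters: list[VariableCluster] = []
    for cid in range(1, ids.max() + 1):
        idx = members_by_id[cid]
        ratios: dict[str, float] = {}
        for j in idx:
            r2_own = _r2(x[:, j], components[cid])
            r2_next = 0.0
            for other, comp in components.items():
                if other != cid:
                    r2_next = max(r2_next, _r2(x[:, j], comp))
            ratios[names[j]] = one_minus_r2_ratio(r2_own, r2_next)
        rep = min(ratios, key=lambda n: (ratios[n], n))
        clusters.append(
            VariableCluster(
                cluster_id=cid,
                members=[names[j] for j in idx],
                component_loadings=components[cid],
                representative=rep,
                one_minus_r2_ratio_by_member=ratios,
            )
        )
    return clusters


def select_representatives(clusters: list[VariableCluster]) -> ReductionResult:
    """Collect one representative per cluster (minimal 1-R^2 ratio).

    Representatives are re-derived from the stored ratios so that a caller may
    edit ratios and re-select; ties break by lexicographic name.
    """
    selected: list[str] = []
    for cl in clusters:
        ratios = cl.one_minus_r2_ratio_by_member
        rep = min(ratios, key=lambda n: (ratios[n], n))
        cl.representative = rep
        selected.append(rep)
    return ReductionResult(clusters=clusters, selected_features=selected)


def reduce_matrix(
    matrix: DescriptorMatrix,
    k: int = 30,
    var_tol: float = 1e-12,
    prefilter_m: int = 0,
) -> tuple[DescriptorMatrix, ReductionResult]:
    """Full reduction: drop degenerates, optional F-score pre-filter, cluster
    to ``k`` groups, select one representative per cluster.

    Returns the reduced matrix (columns = representatives, input row order
    preserved) and the :class:`ReductionResult`.
    """
    clean, dropped = drop_degenerate(matrix, var_tol=var_tol)
    if prefilter_m:
        clean = prefilter_f_score(clean, prefilter_m)
    k_eff = min(k, clean.n_descriptors)
    clusters = cluster_variables(clean, k_eff)
    result = select_representatives(clusters)
    result.dropped_features = dropped
    reduced = matrix.subset_columns(result.selected_features)
    return reduced, result
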