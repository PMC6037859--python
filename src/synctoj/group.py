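"""Group-level inference: voxelwise mixed ANOVA and cluster-extent FDR.

Subject-level contrast images enter a split-plot (repeated-measures) ANOVA
with one between-subject factor (group: TOJ-able vs TOJ-unable) and up to
two within-subject factors (task; COA condition).  Classical partitioned
error terms are used: between-group effects are tested against the
subjects-within-group mean square, and each within-subject term (and its
interaction with group) against the corresponding subject-by-factor
interaction mean square.  Unequal group sizes are handled with the
weighted-(cell)-means decomposition.

Clusters are formed on the F map at an auxiliary voxel threshold
(p < 0.0001 by default, 18-connectivity) and assigned p-values from a
permutation null distribution of maximum cluster extent; Benjamini-Hochberg
across the observed clusters then controls the false discovery rate over
clusters at q.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GroupDesign",
    "Cluster",
    "ClusterResult",
    "mixed_anova",
    "form_clusters",
    "permutation_cluster_fdr",
    "cluster_table",
]


@dataclass(frozen=True)
class GroupDesign:
    """Per-subject images for every within-subject cell, plus group labels.

    ``data`` has shape (n_subjects, n_levels_A, n_levels_B, *spatial); use a
    singleton B axis for designs with a single within factor and spatial
    shape ``()`` or ``(1,)`` for purely behavioral tables.
    """

    data: np.ndarray
    groups: np.ndarray                      # (n_subjects,) labels
    within_names: tuple[str, str] = ("task", "coa")
    between_name: str = "group"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim < 3:
            raise ValueError("data must be (n_subjects, n_A, n_B, *spatial)")
        if not np.isfinite(d).all():
            i = np.argwhere(~np.isfinite(d))[0]
            raise ValueError(f"missing/non-finite cell for subject {i[0]}, cell {tuple(i[1:3])}")
        groups = np.asarray(self.groups)
        if groups.shape != (d.shape[0],):
            raise ValueError("one group label per subject required")
        for g in np.unique(groups):
            if (groups == g).sum() < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "groups", groups)

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[3:]


def _parse_term(design: GroupDesign, term: str) -> frozenset[str]:
    parts = frozenset(p.strip() for p in term.replace("*", ":").split(":"))
    valid = {design.between_name, *design.within_names}
    if not parts or not parts <= valid:
        raise ValueError(f"invalid term {term!r}; factors are {sorted(valid)}")
    a_name, b_name = design.within_names
    if design.data.shape[2] == 1 and b_name in parts:
        raise ValueError(f"design has no {b_name!r} factor")
    return parts


def mixed_anova(design: GroupDesign, term: str) -> tuple[np.ndarray, int, int]:
    """Voxelwise F statistic for one term of the split-plot ANOVA.

    ``term`` names the factors joined with ':' (e.g. "task", "group:task",
    "task:coa").  Returns (F map with the design's spatial shape, df1, df2).
    Voxels whose error mean square is zero get F = 0.
    """
    parts = _parse_term(design, term)
    Y = design.data.reshape(design.data.shape[:3] + (-1,))  # (N, a, b, V)
    N, a, b, V = Y.shape
    groups = design.groups
    glabels = np.unique(groups)
    n_groups = len(glabels)
    n_g = np.array([(groups == g).sum() for g in glabels])

    grand = Y.mean(axis=(0, 1, 2))                     # (V,)
    m_s = Y.mean(axis=(1, 2))                          # (N, V)
    m_sj = Y.mean(axis=2)                              # (N, a, V)
    m_sk = Y.mean(axis=1)                              # (N, b, V)
    m_j = Y.mean(axis=(0, 2))                          # (a, V)
    m_k = Y.mean(axis=(0, 1))                          # (b, V)
    m_jk = Y.mean(axis=0)                              # (a, b, V)

    m_gv = np.stack([m_s[groups == g].mean(axis=0) for g in glabels])        # (G, V)
    m_gj = np.stack([m_sj[groups == g].mean(axis=0) for g in glabels])       # (G, a, V)
    m_gk = np.stack([m_sk[groups == g].mean(axis=0) for g in glabels])       # (G, b, V)
    m_gjk = np.stack([Y[groups == g].mean(axis=0) for g in glabels])         # (G, a, b, V)
    gidx = np.searchsorted(glabels, groups)
    w = n_g[:, None]

    # sums of squares (weighted-means decomposition)
    ss_g = a * b * (w * (m_gv - grand) ** 2).sum(axis=0)
    ss_sg = a * b * ((m_s - m_gv[gidx]) ** 2).sum(axis=0)
    ss_a = N * b * ((m_j - grand) ** 2).sum(axis=0)
    ss_ga = b * (w[:, :, None] * (m_gj - m_gv[:, None] - m_j + grand) ** 2).sum(axis=(0, 1))
    ss_asg = b * ((m_sj - m_s[:, None] - m_gj[gidx] + m_gv[gidx][:, None]) ** 2).sum(axis=(0, 1))
    ss_b = N * a * ((m_k - grand) ** 2).sum(axis=0)
    ss_gb = a * (w[:, :, None] * (m_gk - m_gv[:, None] - m_k + grand) ** 2).sum(axis=(0, 1))
    ss_bsg = a * ((m_sk - m_s[:, None] - m_gk[gidx] + m_gv[gidx][:, None]) ** 2).sum(axis=(0, 1))
    ss_ab = N * ((m_jk - m_j[:, None] - m_k[None] + grand) ** 2).sum(axis=(0, 1))
    ss_gab = (
        w[:, :, None, None]
        * (m_gjk - m_gj[:, :, None] - m_gk[:, None] + m_gv[:, None, None]
           - m_jk + m_j[:, None] + m_k[None] - grand) ** 2
    ).sum(axis=(0, 1, 2))
    resid = (
        Y - m_sj[:, :, None] - m_sk[:, None] - m_gjk[gidx]
        + m_s[:, None, None] + m_gj[gidx][:, :, None] + m_gk[gidx][:, None] - m_gv[gidx][:, None, None]
    )
    ss_absg = (resid ** 2).sum(axis=(0, 1, 2))

    df_sg = N - n_groups
    a_name, b_name = design.within_names
    g_name = design.between_name
    table = {
        frozenset({g_name}): (ss_g, n_groups - 1, ss_sg, df_sg),
        frozenset({a_name}): (ss_a, a - 1, ss_asg, (a - 1) * df_sg),
        frozenset({g_name, a_name}): (ss_ga, (n_groups - 1) * (a - 1), ss_asg, (a - 1) * df_sg),
        frozenset({b_name}): (ss_b, b - 1, ss_bsg, (b - 1) * df_sg),
        frozenset({g_name, b_name}): (ss_gb, (n_groups - 1) * (b - 1), ss_bsg, (b - 1) * df_sg),
        frozenset({a_name, b_name}): (ss_ab, (a - 1) * (b - 1), ss_absg, (a - 1) * (b - 1) * df_sg),
        frozenset({g_name, a_name, b_name}): (
            ss_gab, (n_groups - 1) * (a - 1) * (b - 1), ss_absg, (a - 1) * (b - 1) * df_sg
        ),
    }
    ss_t, df1, ss_e, df2 = table[parts]
    if df1 < 1 or df2 < 1:
        raise ValueError(f"term {term!r} has no degrees of freedom in this design")
    ms_t = ss_t / df1
    ms_e = ss_e / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_e > 0, ms_t / ms_e, 0.0)
    return F.reshape(design.spatial_shape), int(df1), int(df2)


# ---------------------------------------------------------------------------
# clusters

@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    peak_coord: tuple[int, ...]
    n_voxels: int
    peak_stat: float
    peak_equiv_z: float
    p_cluster: float | None = None
    q_fdr: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class ClusterResult:
    label_map: np.ndarray
    clusters: tuple[Cluster, ...]
    voxel_p_threshold: float
    connectivity: int
    df1: int
    df2: int


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def form_clusters(
    stat_map: np.ndarray,
    dfs: tuple[int, int],
    voxel_p: float = 1e-4,
    connectivity: int = 18,
) -> ClusterResult:
    """Threshold an F map and label connected suprathreshold clusters.

    The threshold is the upper ``voxel_p`` quantile of F(df1, df2); peaks are
    the maximum-statistic voxels (ties broken by lowest linear index).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.size == 0:
        raise ValueError("empty statistic map")
    df1, df2 = dfs
    thresh = stats.f.isf(voxel_p, df1, df2)
    supra = stat_map > thresh
    label_map, n_clusters = ndimage.label(supra, structure=_structure(connectivity))

    clusters = []
    for cid in range(1, n_clusters + 1):
        voxels = np.flatnonzero(label_map.ravel() == cid)
        vals = stat_map.ravel()[voxels]
        peak_flat = voxels[np.argmax(vals)]  # argmax returns first max: lowest index
        peak_stat = float(stat_map.ravel()[peak_flat])
        p_up = float(stats.f.sf(peak_stat, df1, df2))
        clusters.append(
            Cluster(
                cluster_id=cid,
                peak_coord=tuple(np.unravel_index(peak_flat, stat_map.shape)),
                n_voxels=len(voxels),
                peak_stat=peak_stat,
                peak_equiv_z=float(stats.norm.isf(p_up)),
            )
        )
    return ClusterResult(label_map, tuple(clusters), voxel_p, connectivity, df1, df2)


def _permute_design(design: GroupDesign, parts: frozenset[str], rng) -> GroupDesign:
    """One null resample respecting the term's exchangeability scheme."""
    a_name, b_name = design.within_names
    if design.between_name in parts:
        perm = rng.permutation(len(design.groups))
        return replace(design, groups=design.groups[perm])
    data = design.data.copy()
    N, a, b = data.shape[:3]
    if parts == {a_name, b_name}:
        # restricted: relabel A within every level of B, per subject
        for s in range(N):
            for k in range(b):
                data[s, :, k] = data[s, rng.permutation(a), k]
    elif a_name in parts:
        for s in range(N):
            data[s] = data[s, rng.permutation(a)]
    else:  # b only
        for s in range(N):
            data[s, :, :] = data[s][:, rng.permutation(b)]
    return replace(design, data=data)


def permutation_cluster_fdr(
    design: GroupDesign,
    term: str,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int | None = 0,
    voxel_p: float = 1e-4,
    connectivity: int = 18,
) -> ClusterResult:
    """Cluster-extent inference by permutation with FDR over clusters.

    A null distribution of the maximum cluster extent is built by relabeling
    appropriate to the term (group labels for between terms; within-subject
    cell labels otherwise).  Each observed cluster's p is the proportion of
    null maxima at least as large; Benjamini-Hochberg across the observed
    clusters flags those with q_fdr < q.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    parts = _parse_term(design, term)
    rng = np.random.default_rng(seed)

    F, df1, df2 = mixed_anova(design, term)
    observed = form_clusters(F, (df1, df2), voxel_p, connectivity)

    null_max = np.zeros(n_perm)
    thresh = stats.f.isf(voxel_p, df1, df2)
    struct = _structure(connectivity)
    for i in range(n_perm):
        perm_design = _permute_design(design, parts, rng)
        Fp, _, _ = mixed_anova(perm_design, term)
        labels, n_c = ndimage.label(Fp > thresh, structure=struct)
        if n_c:
            null_max[i] = np.bincount(labels.ravel())[1:].max()

    clusters = []
    for cl in observed.clusters:
        p = float((1 + np.sum(null_max >= cl.n_voxels)) / (1 + n_perm))
        clusters.append(replace(cl, p_cluster=p))
    clusters = _benjamini_hochberg(clusters, q)
    return replace(observed, clusters=tuple(clusters))


def _benjamini_hochberg(clusters: list[Cluster], q: float) -> list[Cluster]:
    if not clusters:
        return clusters
    m = len(clusters)
    order = np.argsort([c.p_cluster for c in clusters])
    qvals = np.empty(m)
    prev = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        rank = m - rank_rev
        prev = min(prev, clusters[idx].p_cluster * m / rank)
        qvals[idx] = prev
    return [
        replace(c, q_fdr=float(qv), significant=bool(qv < q) and q > 0)
        for c, qv in zip(clusters, qvals)
    ]


def cluster_table(result: ClusterResult) -> pd.DataFrame:
    """Cluster report: peak coordinate, extent, statistic, equivalent z,
    cluster p and FDR q, sorted by peak statistic descending."""
    cols = [
        "cluster_id", "peak_x", "peak_y", "peak_z", "n_voxels",
        "peak_stat", "equiv_z", "p_cluster", "q_fdr", "significant",
    ]
    rows = []
    for c in sorted(result.clusters, key=lambda c: -c.peak_stat):
        coord = tuple(c.peak_coord) + (0,) * (3 - len(c.peak_coord))
        rows.append(
            (c.cluster_id, *coord[:3], c.n_voxels, c.peak_stat, c.peak_equiv_z,
             c.p_cluster, c.q_fdr, c.significant)
        )
    return pd.DataFrame(rows, columns=cols)
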