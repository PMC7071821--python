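"""Signed weighted co-expression network construction.

One network per developmental stage: biweight midcorrelation (with outlier
capping), soft-threshold selection against the scale-free topology criterion,
signed adjacency, signed topological overlap, and module detection by
average-linkage clustering of TOM dissimilarity with a dynamic (gap-based)
tree cut followed by eigengene-correlation merging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from . import modstats

log = logging.getLogger(__name__)

__all__ = [
    "bicor",
    "bicor_matrix",
    "pick_soft_threshold",
    "signed_adjacency",
    "signed_tom",
    "detect_modules",
    "Network",
    "ModulePartition",
]

DEFAULT_POWER_GRID = tuple(range(1, 21)) + tuple(range(22, 31, 2))


def _bicor_weights(x: np.ndarray, max_p_outliers: float) -> np.ndarray | None:
    """Tukey biweight transform of one vector: (x - median) * weight,
    normalized to unit length. Returns None when MAD = 0 (caller falls back
    to Pearson for the affected pairs)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    # cap u so that at most max_p_outliers of the points on each side fall
    # outside |u| >= 1 (zero weight)
    if max_p_outliers < 0.5:
        q_low = np.quantile(u, max_p_outliers)
        if q_low < -1.0:
            u = np.where(u < 0, u / (-q_low), u)
        q_high = np.quantile(u, 1.0 - max_p_outliers)
        if q_high > 1.0:
            u = np.where(u > 0, u / q_high, u)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    xt = (x - med) * w
    norm = np.sqrt(np.sum(xt**2))
    if norm == 0:
        return None
    return xt / norm


def _standardized(x: np.ndarray) -> np.ndarray | None:
    xt = x - x.mean()
    norm = np.sqrt(np.sum(xt**2))
    if norm == 0:
        return None
    return xt / norm


def bicor(x: np.ndarray, y: np.ndarray, max_p_outliers: float = 0.05) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete)."""
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 4:
        return np.nan
    xs, ys = x[mask], y[mask]
    xt = _bicor_weights(xs, max_p_outliers)
    yt = _bicor_weights(ys, max_p_outliers)
    if xt is None:
        xt = _standardized(xs)
    if yt is None:
        yt = _standardized(ys)
    if xt is None or yt is None:
        return np.nan
    return float(np.clip(np.dot(xt, yt), -1.0, 1.0))


def bicor_matrix(m: pd.DataFrame, max_p_outliers: float = 0.05) -> pd.DataFrame:
    """Gene x gene biweight midcorrelation matrix.

    Because the biweight transform of each gene depends only on its own
    values, the complete-data case reduces to a single matrix product of
    transformed rows. Genes whose MAD is zero fall back to Pearson (a logged
    warning); pairs with fewer than 4 shared non-missing samples are NaN.
    """
    if m.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    vals = m.to_numpy(float)
    if np.all(np.isfinite(vals)):
        rows = np.empty_like(vals)
        n_fallback = 0
        for i, x in enumerate(vals):
            xt = _bicor_weights(x, max_p_outliers)
            if xt is None:  # MAD = 0: fall back to Pearson for this gene
                xt = _standardized(x)
                n_fallback += 1
                if xt is None:  # constant gene: correlations become 0
                    xt = np.zeros_like(x)
            rows[i] = xt
        if n_fallback:
            log.warning("bicor: %d gene(s) with MAD=0 fell back to Pearson", n_fallback)
        c = np.clip(rows @ rows.T, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        return pd.DataFrame(c, index=m.index, columns=m.index)

    n = m.shape[0]
    c = np.full((n, n), np.nan)
    for i in range(n):
        c[i, i] = 1.0
        for j in range(i + 1, n):
            c[i, j] = c[j, i] = bicor(vals[i], vals[j], max_p_outliers)
    return pd.DataFrame(c, index=m.index, columns=m.index)


def signed_adjacency(c: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2) ** beta; missing
    correlations contribute adjacency 0 (count logged). Diagonal is 1 by
    convention."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    vals = c.to_numpy(float)
    n_missing = int(np.sum(~np.isfinite(vals)))
    if n_missing:
        log.warning("signed_adjacency: %d missing correlations set to adjacency 0", n_missing)
    a = ((1.0 + np.nan_to_num(vals, nan=-1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=c.index, columns=c.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Connectivity is binned into ``n_bins`` equal-width bins on the raw k
    scale (the convention of the reference co-expression tooling); log10 of
    the bin frequency is regressed on log10 of the bin-mean connectivity.
    Returns (signed R^2, slope) with signed R^2 = -sign(slope) * R^2,
    positive for the decreasing degree distributions of scale-free networks.
    """
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = np.sum((np.asarray(ys) - pred) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def recommended_signed_power(n_samples: int) -> int:
    """Default soft power for signed networks when the scale-free criterion
    cannot be met, following the standard sample-size recommendation."""
    if n_samples < 20:
        return 18
    if n_samples < 30:
        return 16
    if n_samples < 40:
        return 14
    return 12


def pick_soft_threshold(
    c: pd.DataFrame,
    candidate_powers=DEFAULT_POWER_GRID,
    target_fit: float = 0.9,
    fallback_power: int | None = None,
    min_median_k: float = 1.0,
) -> tuple[int, pd.DataFrame]:
    """Choose the lowest soft power whose signed scale-free fit reaches
    ``target_fit`` (default 0.9). If none qualifies, return ``fallback_power``
    when given (the sample-size-based signed-network default; small desk-scale
    matrices rarely show scale-free topology), else the best-fit power; either
    way the ``warning`` flag is set in the table.

    Returns (beta, fit table with power, signed R^2, slope, mean/median/max k).
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers or min(candidate_powers) < 1:
        raise ValueError("candidate_powers must be nonempty and positive")
    rows = []
    vals = c.to_numpy(float)
    half = (1.0 + np.nan_to_num(vals, nan=-1.0)) / 2.0
    np.fill_diagonal(half, 0.0)
    for p in candidate_powers:
        a = half**p
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append(
            {
                "power": p,
                "signed_r2": fit,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    # Powers that leave the median node effectively disconnected produce
    # degenerate (often spuriously high) fit indices; exclude them from
    # selection unless nothing else remains.
    eligible = table[table.median_k >= min_median_k]
    if eligible.empty:
        eligible = table
    ok = eligible[eligible.signed_r2 >= target_fit]
    if len(ok):
        beta = int(ok.power.iloc[0])
        table["warning"] = False
    else:
        if fallback_power is not None:
            beta = int(fallback_power)
        else:
            beta = int(eligible.power[eligible.signed_r2.idxmax()])
        table["warning"] = True
        warnings.warn(
            f"no candidate power reached signed R^2 >= {target_fit}; "
            f"using power {beta} (best fit was {eligible.signed_r2.max():.3f})"
        )
    return beta, table


def signed_tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Signed topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu * a_uj over u != i, j and k_i the off-diagonal row sum.
    Diagonal is 1; dissimilarity for clustering is 1 - TOM.
    """
    a = adj.to_numpy(float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must be in [0, 1]")
    k = a.sum(axis=1)
    L = a @ a  # diagonal of a is 0, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Gene -> module label map; label 0 means unassigned (the ME0 set)."""

    labels: pd.Series
    linkage: np.ndarray | None = None
    deep_split: int = 2
    merge_cut_height: float = 0.25
    min_module_size: int = 20

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def genes_in(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class Network:
    """Per-stage network bundle: correlation, chosen power, adjacency, TOM
    and the soft-threshold fit table."""

    correlation: pd.DataFrame
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    fit_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    max_p_outliers: float = 0.05,
    candidate_powers=DEFAULT_POWER_GRID,
    target_fit: float = 0.9,
) -> Network:
    """Convenience chain: bicor -> soft threshold (unless beta given) ->
    signed adjacency -> signed TOM."""
    c = bicor_matrix(expr, max_p_outliers)
    if beta is None:
        beta, table = pick_soft_threshold(c, candidate_powers, target_fit)
    else:
        table = pd.DataFrame()
    adj = signed_adjacency(c, beta)
    tom = signed_tom(adj)
    return Network(correlation=c, beta=beta, adjacency=adj, tom=tom, fit_table=table)


# ---------------------------------------------------------------------------
# Dynamic tree cut (gap-based "tree" variant)

# deepSplit 0..4 mapped to the minimum branch-detachment gap (as a fraction
# of the dendrogram height range) required for a branch to count as a
# module: higher deepSplit = more sensitive = smaller required gap.
_DEEPSPLIT_GAP = {0: 0.20, 1: 0.10, 2: 0.05, 3: 0.025, 4: 0.01}


def _cut_clusters(Z: np.ndarray, n: int, deep_split: int, min_size: int):
    """Gap-based branch decomposition of an average-linkage dendrogram.

    A branch is module-like when it is *detached*: the merge that absorbs it
    into the rest of the tree sits well above the branch's own top merge.
    Within-module merges happen low in co-expression dendrograms while
    unclustered genes accrete in closely spaced merges near the top, so the
    detachment gap (parent height minus branch height, relative to the
    dendrogram height range) separates the two. The tree is decomposed
    recursively into the *deepest* branches of at least ``min_size`` leaves
    whose detachment gap exceeds the deepSplit-mapped threshold; sub-branches
    of one module that qualify separately are rejoined later by the
    eigengene-merge step. Genes outside every qualifying branch are left
    unassigned.
    """
    gap_frac = _DEEPSPLIT_GAP[deep_split]
    heights = Z[:, 2]
    span = float(heights.max() - heights.min()) if n > 1 else 0.0
    members: list[list[int]] = [[i] for i in range(n)]
    node_height = np.zeros(2 * n - 1)
    kids: dict[int, tuple[int, int]] = {}
    parent_h = np.full(2 * n - 1, np.nan)
    for t in range(n - 1):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        members.append(members[a] + members[b])
        node_height[n + t] = Z[t, 2]
        kids[n + t] = (a, b)
        parent_h[a] = parent_h[b] = Z[t, 2]

    if span <= 0:
        return [list(range(n))]
    thresh = gap_frac * span
    root = 2 * n - 2

    def decompose(v: int) -> list[list[int]]:
        if len(members[v]) < min_size or v < n:
            return []
        found: list[list[int]] = []
        if v in kids:
            a, b = kids[v]
            found = decompose(a) + decompose(b)
        if found:
            return found
        # a detached branch; the root itself never qualifies (a module must
        # separate from something)
        if v != root and parent_h[v] - node_height[v] >= thresh:
            return [members[v]]
        return []

    return decompose(root)


def detect_modules(
    tom: pd.DataFrame,
    deep_split: int = 2,
    merge_cut_height: float = 0.25,
    min_module_size: int = 20,
    expr: pd.DataFrame | None = None,
) -> ModulePartition:
    """Cluster 1 - TOM by average linkage, cut dynamically, drop clusters
    smaller than ``min_module_size`` to label 0, then iteratively merge
    modules whose eigengenes are closer than ``merge_cut_height``
    (dissimilarity 1 - cor). Labels are renumbered by decreasing size.

    ``expr`` (genes x samples) is required for the eigengene merge step; when
    omitted the merge step is skipped.
    """
    if tom.empty:
        raise ValueError("empty TOM")
    if deep_split not in _DEEPSPLIT_GAP:
        raise ValueError("deep_split must be in 0..4")
    n = tom.shape[0]
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    Z = sch.linkage(squareform(diss, checks=False), method="average")
    clusters = _cut_clusters(Z, n, deep_split, min_module_size)

    labels = np.zeros(n, int)
    next_label = 1
    for memb in clusters:
        if len(memb) >= min_module_size:
            labels[memb] = next_label
            next_label += 1

    part = ModulePartition(
        labels=pd.Series(labels, index=tom.index, name="module"),
        linkage=Z,
        deep_split=deep_split,
        merge_cut_height=merge_cut_height,
        min_module_size=min_module_size,
    )
    if expr is not None and part.modules:
        part = _merge_close_modules(part, expr, merge_cut_height)
    return _renumber_by_size(part)


def _merge_close_modules(part: ModulePartition, expr: pd.DataFrame, cut: float) -> ModulePartition:
    labels = part.labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig = modstats.module_eigengenes(expr, ModulePartition(labels=labels))
        me = eig.values_frame()
        best, best_cor = None, -np.inf
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                r = np.corrcoef(me.loc[a], me.loc[b])[0, 1]
                if r > best_cor:
                    best_cor, best = r, (a, b)
        if best is None or 1.0 - best_cor >= cut:
            break
        a, b = best
        labels[labels == b] = a
    return ModulePartition(
        labels=labels,
        linkage=part.linkage,
        deep_split=part.deep_split,
        merge_cut_height=part.merge_cut_height,
        min_module_size=part.min_module_size,
    )


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string; branch lengths
    are merge-height differences."""
    labels = list(labels)
    n = len(labels)
    heights = [0.0] * n + [float(h) for h in Z[:, 2]]

    def render(node: int) -> str:
        if node < n:
            return str(labels[node])
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = heights[node]
        return "({}:{:.6g},{}:{:.6g})".format(
            render(a), h - heights[a], render(b), h - heights[b]
        )

    return render(2 * n - 2) + ";"


def _renumber_by_size(part: ModulePartition) -> ModulePartition:
    counts = part.labels[part.labels != 0].value_counts()
    # decreasing size; ties broken by old label for determinism
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return ModulePartition(
        labels=part.labels.map(remap),
        linkage=part.linkage,
        deep_split=part.deep_split,
        merge_cut_height=part.merge_cut_height,
        min_module_size=part.min_module_size,
    )
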