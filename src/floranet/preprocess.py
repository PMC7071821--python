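"""Count-matrix preprocessing: variance-stabilizing transform, quantile
normalization, orthogroup filtering and principal-component confounder
removal.

The pipeline order is fixed: transform -> quantile-normalize -> filter
(missingness judged on the raw matrix, the variance threshold on transformed
values, where the 0.3 cutoff is meaningful) -> optional confounder-PC
regression. Matrices are pandas DataFrames with orthogroups as rows and
samples as columns; missing values are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterSpec",
    "vst_transform",
    "quantile_normalize",
    "filter_orthogroups",
    "remove_confounder_pcs",
]


@dataclass
class FilterSpec:
    max_missing_fraction: float = 0.5
    min_variance: float = 0.3
    require_common_across_stages: bool = True

    def __post_init__(self):
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_variance < 0:
            raise ValueError("min_variance must be >= 0")


def size_factors(m: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The reference profile is the per-row geometric mean over rows with no
    zeros or missing values; each sample's factor is the median ratio of its
    counts to the reference.
    """
    vals = m.to_numpy(float)
    ok = np.all(np.isfinite(vals), axis=1) & np.all(vals > 0, axis=1)
    if not ok.any():
        raise ValueError("no rows without zeros/missing values to build a reference")
    log_ref = np.log(vals[ok]).mean(axis=1)
    ratios = np.log(vals[ok]) - log_ref[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=m.columns, name="size_factor")


def vst_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform stand-in: divide each sample by its
    median-of-ratios size factor, then log2(x + 1).

    Raises if any sample is entirely zero (its size factor is meaningless).
    """
    vals = m.to_numpy(float)
    colsum = np.nansum(vals, axis=0)
    dead = [c for c, s in zip(m.columns, colsum) if s == 0]
    if dead:
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    sf = size_factors(m)
    return np.log2(m.div(sf, axis=1) + 1.0)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the mean distribution of order statistics.

    Ties within a column receive the average of the reference values they
    span. Missing values stay missing and are excluded from rank computation;
    columns with missing entries are mapped through interpolated quantiles of
    the reference distribution.
    """
    if m.shape[1] == 1:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return m.copy()
    if m.isna().all(axis=0).any():
        raise ValueError("fully-missing column")
    vals = m.to_numpy(float)
    n_rows, n_cols = vals.shape
    complete = np.all(np.isfinite(vals), axis=0)

    if complete.all():
        order_stats = np.sort(vals, axis=0)
        ref = order_stats.mean(axis=1)  # mean k-th order statistic
        out = np.empty_like(vals)
        for j in range(n_cols):
            ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
            lo = np.floor(ranks).astype(int)
            hi = np.ceil(ranks).astype(int)
            out[:, j] = 0.5 * (ref[lo] + ref[hi])
        return pd.DataFrame(out, index=m.index, columns=m.columns)

    # Reference built from interpolated quantiles at a common grid.
    grid = (np.arange(n_rows) + 0.5) / n_rows
    ref_cols = []
    for j in range(n_cols):
        x = vals[:, j]
        x = np.sort(x[np.isfinite(x)])
        q = (np.arange(x.size) + 0.5) / x.size
        ref_cols.append(np.interp(grid, q, x))
    ref = np.mean(ref_cols, axis=0)
    out = np.full_like(vals, np.nan)
    for j in range(n_cols):
        x = vals[:, j]
        fin = np.isfinite(x)
        k = fin.sum()
        ranks = pd.Series(x[fin]).rank(method="average").to_numpy()
        q = (ranks - 0.5) / k
        out[fin, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def filter_orthogroups(
    bud: pd.DataFrame,
    d: pd.DataFrame,
    spec: FilterSpec = FilterSpec(),
    bud_raw: pd.DataFrame | None = None,
    d_raw: pd.DataFrame | None = None,
):
    """Remove orthogroups with too many missing values or too little
    expression variance, in either stage.

    ``bud``/``d`` are the (transformed) matrices the variance criterion is
    judged on; ``bud_raw``/``d_raw``, when given, are the raw matrices the
    missingness criterion is judged on (default: same matrices). A row is
    removed when its missing fraction exceeds ``max_missing_fraction`` or its
    variance is strictly below ``min_variance`` in either stage. With
    ``require_common_across_stages`` the surviving row sets are intersected.

    Returns (bud_filtered, d_filtered, report) where report counts removals
    per criterion.
    """
    if not set(bud.index) & set(d.index):
        raise ValueError("stage matrices share no orthogroup ids")
    bud_raw = bud if bud_raw is None else bud_raw
    d_raw = d if d_raw is None else d_raw

    def row_flags(m: pd.DataFrame, raw: pd.DataFrame):
        miss = raw.isna().mean(axis=1) > spec.max_missing_fraction
        var = m.var(axis=1, ddof=1) < spec.min_variance
        return miss, var

    miss_b, var_b = row_flags(bud, bud_raw)
    miss_d, var_d = row_flags(d, d_raw)
    keep_b = bud.index[~(miss_b | var_b)]
    keep_d = d.index[~(miss_d | var_d)]
    report = {
        "removed_missing_bud": int(miss_b.sum()),
        "removed_variance_bud": int(var_b.sum()),
        "removed_missing_d": int(miss_d.sum()),
        "removed_variance_d": int(var_d.sum()),
    }
    if spec.require_common_across_stages:
        common = keep_b.intersection(keep_d)
        report["n_kept"] = len(common)
        return bud.loc[common], d.loc[common], report
    report["n_kept"] = len(keep_b) + len(keep_d)
    return bud.loc[keep_b], d.loc[keep_d], report


def _sample_pcs(m: pd.DataFrame):
    """Sample-space principal components of the row-standardized matrix."""
    vals = m.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    # eigen-decomposition of the samples x samples covariance
    g = z.T @ z / max(z.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    return z, evals[order], evecs[:, order]


def select_n_pcs(m: pd.DataFrame, n_perm: int = 100, quantile: float = 95.0, seed: int = 0) -> int:
    """Permutation (Buja-Eyuboglu-style) parallel analysis: keep components
    whose eigenvalue exceeds the chosen percentile of eigenvalues obtained
    after independently permuting each row."""
    rng = np.random.default_rng(seed)
    _, evals, _ = _sample_pcs(m)
    vals = m.to_numpy(float)
    null = np.empty((n_perm, len(evals)))
    for p in range(n_perm):
        perm = np.array([rng.permutation(row) for row in vals])
        _, ev, _ = _sample_pcs(pd.DataFrame(perm))
        null[p] = ev
    thresh = np.percentile(null, quantile, axis=0)
    k = 0
    for lam, th in zip(evals, thresh):
        if lam > th:
            k += 1
        else:
            break
    return k


def remove_confounder_pcs(m: pd.DataFrame, k: int | str = "auto", seed: int = 0) -> pd.DataFrame:
    """Regress each orthogroup on the top-k sample-space principal components
    and return residuals with the row mean restored.

    k='auto' selects k by the permutation eigenvalue test; k=0 returns the
    input unchanged.
    """
    if k == "auto":
        k = select_n_pcs(m, seed=seed)
    if k >= m.shape[1]:
        raise ValueError("k must be smaller than the number of samples")
    if k == 0:
        return m.copy()
    _, _, evecs = _sample_pcs(m)
    pcs = evecs[:, :k]  # samples x k, orthonormal
    vals = m.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    centered = vals - mu
    resid = centered - (centered @ pcs) @ pcs.T
    return pd.DataFrame(resid + mu, index=m.index, columns=m.columns)
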