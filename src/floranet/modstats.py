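"""Module-level statistics: eigengenes, module membership (kME),
connectivity, hub/periphery calls, and cross-network overlap tests.

The module eigengene is the first principal component of the standardized
expression of a module's genes, oriented to correlate positively with the
module's mean expression profile and scaled to unit variance across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

__all__ = [
    "EigengeneMatrix",
    "module_eigengenes",
    "compute_kme",
    "compute_connectivity",
    "call_hubs_periphery",
    "module_overlap_fisher",
    "set_overlap_fisher",
]


@dataclass
class EigengeneMatrix:
    """Modules x samples eigengene values plus per-module variance explained."""

    values: pd.DataFrame  # index: module label, columns: samples
    var_explained: pd.Series

    def values_frame(self) -> pd.DataFrame:
        return self.values

    def eigengene(self, module: int) -> pd.Series:
        return self.values.loc[module]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene in module")
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, part) -> EigengeneMatrix:
    """First principal component per module.

    expr is genes x samples. For each module the gene rows are standardized
    and the leading right-singular vector is taken, sign-oriented so its
    correlation with the module mean profile is non-negative, then scaled to
    unit variance. Variance explained is s1^2 / sum(s^2).
    """
    rows, ve = {}, {}
    for m in part.modules:
        genes = part.genes_in(m)
        if len(genes) == 0:
            raise ValueError(f"module {m} is empty")
        x = expr.loc[genes].to_numpy(float)
        try:
            z = _standardize_rows(x)
        except ValueError as e:
            raise ValueError(f"module {m}: {e}") from None
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        e = e / e.std(ddof=1)
        rows[m] = e
        ve[m] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(rows, index=expr.columns).T
    values.index.name = "module"
    return EigengeneMatrix(values=values, var_explained=pd.Series(ve, name="var_explained"))


def compute_kme(expr: pd.DataFrame, eig: EigengeneMatrix) -> pd.DataFrame:
    """kME(gene, module) = Pearson correlation of the gene's profile with
    each module eigengene (all modules, not only the gene's own). Constant
    genes get NaN."""
    if list(expr.columns) != list(eig.values.columns):
        raise ValueError("sample sets of expression and eigengenes differ")
    x = expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    e = eig.values.to_numpy(float)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=1, keepdims=True)
    n = x.shape[1]
    kme = z @ ez.T / (n - 1)
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=expr.index, columns=eig.values.index
    )


def compute_connectivity(adj: pd.DataFrame, part) -> pd.DataFrame:
    """Whole-network and intramodular connectivity.

    kTotal is the off-diagonal adjacency row sum; kWithin restricts to the
    gene's own module co-members (including label 0, reported uniformly);
    kOut = kTotal - kWithin.
    """
    if list(adj.index) != list(part.labels.index):
        raise ValueError("adjacency and partition gene sets differ")
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    labels = part.labels.to_numpy()
    k_total = a.sum(axis=1)
    k_within = np.array(
        [a[i, labels == labels[i]].sum() for i in range(len(labels))]
    )
    return pd.DataFrame(
        {
            "module": labels,
            "kTotal": k_total,
            "kWithin": k_within,
            "kOut": k_total - k_within,
        },
        index=adj.index,
    )


def call_hubs_periphery(
    kme: pd.DataFrame,
    conn: pd.DataFrame,
    hub_kme: float = 0.9,
    periphery_fraction: float = 0.10,
) -> pd.DataFrame:
    """Hub and periphery role calls.

    A gene is a hub iff it is assigned to a module (label != 0) and its kME
    to its own module is strictly greater than ``hub_kme``. The periphery is
    the floor(periphery_fraction * N) genes with smallest kTotal over ALL
    genes (ME0 included), ties broken by gene id for stability. The realized
    connectivity cutoff (max periphery kTotal) is attached as ``.attrs``.
    """
    if list(kme.index) != list(conn.index):
        raise ValueError("kME and connectivity tables are not aligned")
    own_kme = pd.Series(np.nan, index=conn.index)
    for m in kme.columns:
        mask = conn["module"] == m
        own_kme[mask] = kme.loc[mask, m]
    is_hub = (conn["module"] != 0) & (own_kme > hub_kme)

    n_periph = int(np.floor(periphery_fraction * len(conn)))
    order = conn.assign(_gene=conn.index).sort_values(["kTotal", "_gene"])
    periph_genes = set(order.index[:n_periph])
    is_periph = conn.index.to_series().isin(periph_genes)
    cutoff = float(order["kTotal"].iloc[n_periph - 1]) if n_periph else np.nan

    out = pd.DataFrame(
        {
            "module": conn["module"],
            "own_kme": own_kme,
            "kTotal": conn["kTotal"],
            "is_hub": is_hub.fillna(False),
            "is_periphery": is_periph,
        },
        index=conn.index,
    )
    out.attrs["hub_kme_threshold"] = hub_kme
    out.attrs["periphery_fraction"] = periphery_fraction
    out.attrs["periphery_cutoff"] = cutoff
    return out


def _fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        sample_or = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        sample_or = (a * d) / (b * c)
    cmle = _cmle_odds_ratio(table, kind="conditional").statistic
    return {
        "in_both": a,
        "a_only": b,
        "b_only": c,
        "neither": d,
        "p": float(p),
        "odds_ratio_sample": float(sample_or),
        "odds_ratio_cmle": float(cmle),
        "neg_log10_p": float(-np.log10(max(p, 1e-300))),
    }


def set_overlap_fisher(set_a, set_b, universe) -> dict:
    """Fisher's exact test for the overlap of two gene sets in a universe.

    Reports the hypergeometric two-sided p, the sample odds ratio (with a 0.5
    Haldane correction when any cell is zero) and the conditional-MLE odds
    ratio."""
    universe = list(universe)
    sa, sb = set(set_a), set(set_b)
    missing = (sa | sb) - set(universe)
    if missing:
        raise ValueError("sets contain genes outside the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(universe) - a - b - c
    return _fisher_2x2(a, b, c, d)


def module_overlap_fisher(part_a, part_b) -> pd.DataFrame:
    """Cross-tabulate two partitions of the same gene universe: for every
    (moduleA, moduleB) pair, the 2x2 overlap table, hypergeometric two-sided
    p, and both odds-ratio conventions. Label 0 is included as a row/column
    so unassigned overlap is visible."""
    if set(part_a.labels.index) != set(part_b.labels.index):
        raise ValueError("partitions must share a gene universe")
    genes = part_a.labels.index
    la = part_a.labels
    lb = part_b.labels.reindex(genes)
    rows = []
    for ma in sorted(set(la)):
        in_a = set(genes[la == ma])
        for mb in sorted(set(lb)):
            in_b = set(genes[lb == mb])
            res = set_overlap_fisher(in_a, in_b, genes)
            res["module_a"] = ma
            res["module_b"] = mb
            rows.append(res)
    out = pd.DataFrame(rows)
    return out[
        [
            "module_a",
            "module_b",
            "in_both",
            "a_only",
            "b_only",
            "neither",
            "p",
            "odds_ratio_sample",
            "odds_ratio_cmle",
            "neg_log10_p",
        ]
    ]
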