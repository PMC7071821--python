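"""Permutation-based module preservation between two stage networks.

For each reference module the observed preservation statistics are computed
in the *test* data and compared with ``n_perm`` random gene sets of the same
size, giving a Z score per statistic:

density statistics
  * mean within-module correlation in the test data
  * proportion of test-data variance explained by the module eigengene
connectivity statistics
  * Spearman correlation of intramodular connectivity between ref and test
  * Pearson correlation of kME between ref and test

Zdensity / Zconnectivity are the medians within each class, Zsummary their
mean. medianRank ranks the observed statistics across modules (including a
"gold" module of randomly selected genes used as a calibration row); lower
rank = better preserved. Zsummary > 10 indicates strong evidence of
preservation, < 2 no evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["preservation_stats", "classify_preservation", "PreservationReport"]

GOLD = "gold"


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: size, observed stats, Z stats, medianRank
    n_perm: int
    gold_size: int


def _corr(x: np.ndarray) -> np.ndarray:
    return np.corrcoef(x)


def _eigengene(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of row-standardized genes x samples block; returns
    (eigengene, proportion of variance explained)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if np.dot(e, z.mean(axis=0)) < 0:
        e = -e
    return e, float(s[0] ** 2 / np.sum(s**2))


def _module_stats(idx: np.ndarray, ref: np.ndarray, test: np.ndarray, beta: int):
    """The four preservation statistics for one gene-index set."""
    rt = test[idx]
    ct = np.corrcoef(rt)
    iu = np.triu_indices(len(idx), k=1)
    mean_cor = float(ct[iu].mean())
    e_t, prop_var = _eigengene(rt)

    rr = ref[idx]
    cr = np.corrcoef(rr)
    a_r = ((1.0 + cr) / 2.0) ** beta
    a_t = ((1.0 + ct) / 2.0) ** beta
    np.fill_diagonal(a_r, 0.0)
    np.fill_diagonal(a_t, 0.0)
    kw_r = a_r.sum(axis=1)
    kw_t = a_t.sum(axis=1)
    cor_kim = sps.spearmanr(kw_r, kw_t).statistic

    e_r, _ = _eigengene(rr)

    def _kme(block, e):
        zb = block - block.mean(axis=1, keepdims=True)
        zb /= np.sqrt((zb**2).sum(axis=1, keepdims=True))
        ez = e - e.mean()
        ez /= np.sqrt((ez**2).sum())
        return zb @ ez

    kme_r = _kme(rr, e_r)
    kme_t = _kme(rt, e_t)
    cor_kme = float(np.corrcoef(kme_r, kme_t)[0, 1])
    return np.array([mean_cor, prop_var, cor_kim, cor_kme])


STAT_NAMES = ["mean_cor", "prop_var", "cor_kIM", "cor_kME"]


def preservation_stats(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    ref_part,
    n_perm: int = 200,
    gold_size: int = 1000,
    seed: int = 0,
    beta: int = 6,
) -> PreservationReport:
    """Compute Zdensity, Zconnectivity, Zsummary and medianRank for every
    reference module evaluated in the test data.

    The permutation null draws random gene sets of the same size from the
    common gene universe. ``gold_size`` genes (capped at half the universe)
    form the gold calibration module. ``beta`` is the soft power used for the
    intramodular-connectivity statistic.
    """
    genes = ref_expr.index.intersection(test_expr.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between reference and test data")
    rng = np.random.default_rng(seed)
    ref = ref_expr.loc[genes].to_numpy(float)
    test = test_expr.loc[genes].to_numpy(float)
    gene_pos = {g: i for i, g in enumerate(genes)}

    gold_size = min(gold_size, len(genes) // 2)
    module_sets: dict[object, np.ndarray] = {}
    for m in ref_part.modules:
        declared = ref_part.genes_in(m)
        if len(declared) > len(genes):
            raise ValueError(f"module {m} larger than the gene universe")
        idx = np.array([gene_pos[g] for g in declared if g in gene_pos])
        if len(idx) < 3:
            continue
        module_sets[m] = idx
    if gold_size >= 3:
        module_sets[GOLD] = rng.choice(len(genes), size=gold_size, replace=False)

    rows = []
    for m, idx in module_sets.items():
        obs = _module_stats(idx, ref, test, beta)
        perm = np.empty((n_perm, 4))
        for p in range(n_perm):
            ridx = rng.choice(len(genes), size=len(idx), replace=False)
            perm[p] = _module_stats(ridx, ref, test, beta)
        mu = perm.mean(axis=0)
        sd = perm.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (obs - mu) / sd
        z[sd == 0] = np.nan
        row = {"module": m, "size": len(idx)}
        row.update({f"obs_{k}": v for k, v in zip(STAT_NAMES, obs)})
        row.update({f"Z_{k}": v for k, v in zip(STAT_NAMES, z)})
        row["Zdensity"] = np.nanmedian([z[0], z[1]])
        row["Zconnectivity"] = np.nanmedian([z[2], z[3]])
        row["Zsummary"] = np.mean([row["Zdensity"], row["Zconnectivity"]])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("module")

    # medianRank: rank each observed statistic across modules (1 = best
    # preserved = largest observed value), take the median of the four ranks.
    ranks = pd.DataFrame(
        {k: table[f"obs_{k}"].rank(ascending=False, method="average") for k in STAT_NAMES}
    )
    table["medianRank"] = ranks.median(axis=1)
    return PreservationReport(table=table, n_perm=n_perm, gold_size=gold_size)


def classify_preservation(report: PreservationReport) -> pd.Series:
    """Label each module: Zsummary > 10 -> preserved, < 2 -> not_preserved,
    otherwise ambiguous (boundaries are strict)."""
    z = report.table["Zsummary"]
    labels = pd.Series("ambiguous", index=z.index, name="preservation")
    labels[z > 10] = "preserved"
    labels[z < 2] = "not_preserved"
    return labels
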