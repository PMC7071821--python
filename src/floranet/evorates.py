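"""Per-orthogroup evolutionary rates and rate-versus-network-position models.

dN/dS (omega) is estimated by Nei-Gojobori (1986) counting with Jukes-Cantor
correction: synonymous and nonsynonymous sites per codon, pathway-averaged
differences per codon pair, proportions corrected by d = -3/4 ln(1 - 4p/3),
and the orthogroup estimate taken as the ratio of the pairwise-mean dN to the
pairwise-mean dS. This is a counting stand-in for a maximum-likelihood
one-ratio codon model; every report states the estimator, and a user-supplied
omega column can replace it for the downstream statistics.

Downstream: the sentinel/validity filter, OLS of log omega on log
connectivity x log expression with case-resampling bootstrap CIs, one-sided
permutation Welch t-tests for hub and periphery rate shifts, and OLS of log
omega on the module syndrome-association factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .synthetic_data import SENSE_CODONS, _AA

__all__ = [
    "ng86_pairwise",
    "ng86_dnds",
    "filter_rates",
    "rates_vs_connectivity_lm",
    "group_rate_permutation_test",
    "syndrome_rate_lm",
    "RateModelResult",
]

ESTIMATOR = "NG86 counting with Jukes-Cantor correction (not ML one-ratio)"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon: each position
    contributes the fraction of its three possible changes that are
    synonymous. Changes to stop codons count as nonsynonymous."""
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _AA[alt] == _AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


_SITES = {c: _codon_sites(c) for c in SENSE_CODONS}


def _pathway_steps(c1: str, c2: str):
    """All substitution pathways between two codons; each pathway is a list
    of (from_codon, to_codon) single-base steps."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in itertools.permutations(diff):
        path, cur, ok = [], c1, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            path.append((cur, nxt))
            cur = nxt
        yield path


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts for a
    codon pair. Pathways passing through stop codons are excluded; if every
    pathway does, all are used."""
    if c1 == c2:
        return 0.0, 0.0
    paths = list(_pathway_steps(c1, c2))
    valid = [
        p for p in paths if all(b not in _STOPS for _, b in p[:-1])
    ] or paths
    syn = nsyn = 0.0
    for p in valid:
        for a, b in p:
            if b in _STOPS or a in _STOPS or _AA.get(a) != _AA.get(b):
                nsyn += 1.0
            else:
                syn += 1.0
    return syn / len(valid), nsyn / len(valid)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(seq1: str, seq2: str) -> tuple[float, float]:
    """NG86 dN and dS for one aligned sequence pair. Codons containing gaps,
    ambiguity characters or stops in either sequence are skipped."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq1) % 3:
        raise ValueError("alignment length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3].upper(), seq2[k : k + 3].upper()
        if c1 not in _SITES or c2 not in _SITES:
            continue  # gap/ambiguity/stop codon: skipped pairwise
        s1, n1 = _SITES[c1]
        s2, n2 = _SITES[c2]
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        return np.nan, np.nan
    return _jc_correct(Nd / N), _jc_correct(Sd / S)


def _check_alignment(alignment: dict[str, str]) -> None:
    for name, seq in alignment.items():
        if len(seq) % 3:
            raise ValueError(f"sequence {name}: length not divisible by 3")
        for k in range(0, len(seq), 3):
            if seq[k : k + 3].upper() in _STOPS:
                raise ValueError(f"internal stop codon in sequence {name}")


def ng86_dnds(alignment: dict[str, str]) -> dict:
    """Orthogroup-level NG86 estimate.

    dN and dS are unweighted means over all sequence pairs; omega is their
    ratio. ``valid`` is False when dS is 0 or any Jukes-Cantor correction is
    undefined (proportion >= 3/4).

    Returns dict with dN, dS, omega, valid, n_pairs, estimator.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    _check_alignment(alignment)
    names = sorted(alignment)
    dns, dss = [], []
    for a, b in itertools.combinations(names, 2):
        dn, ds = ng86_pairwise(alignment[a], alignment[b])
        dns.append(dn)
        dss.append(ds)
    dns, dss = np.array(dns), np.array(dss)
    if np.any(~np.isfinite(dns)) or np.any(~np.isfinite(dss)):
        return {
            "dN": np.nan, "dS": np.nan, "omega": np.nan, "valid": False,
            "n_pairs": len(dns), "estimator": ESTIMATOR,
        }
    dn, ds = float(dns.mean()), float(dss.mean())
    valid = ds > 0
    omega = dn / ds if valid else np.nan
    return {
        "dN": dn, "dS": ds, "omega": omega, "valid": valid,
        "n_pairs": len(dns), "estimator": ESTIMATOR,
    }


def rate_table(alignments: dict[str, dict[str, str]]) -> pd.DataFrame:
    """NG86 estimates for a set of orthogroup alignments, as a RateTable
    skeleton (join connectivity/expression/module columns downstream)."""
    rows = []
    for og, aln in alignments.items():
        res = ng86_dnds(aln)
        res["orthogroup"] = og
        rows.append(res)
    return pd.DataFrame(rows).set_index("orthogroup").drop(columns="estimator")


def filter_rates(table: pd.DataFrame, sentinel: float = 999.0) -> pd.DataFrame:
    """Remove rows whose omega equals the sentinel (the zero-synonymous-
    difference marker), is invalid/missing, or whose omega, connectivity or
    mean expression is non-positive (they enter log-scale models). Removal
    counts are attached as ``.attrs['removed']``."""
    t = table.copy()
    bad_sentinel = t["omega"] == sentinel
    bad_invalid = ~np.isfinite(t["omega"])
    if "valid" in t.columns:
        bad_invalid |= ~t["valid"].astype(bool)
    bad_nonpos = t["omega"] <= 0
    for col in ("kTotal", "mean_expression"):
        if col in t.columns:
            bad_nonpos |= ~(t[col] > 0)
    keep = ~(bad_sentinel | bad_invalid | bad_nonpos)
    out = t[keep]
    out.attrs["removed"] = {
        "sentinel": int(bad_sentinel.sum()),
        "invalid": int((bad_invalid & ~bad_sentinel).sum()),
        "nonpositive": int((bad_nonpos & ~bad_invalid & ~bad_sentinel).sum()),
        "kept": int(keep.sum()),
    }
    return out


@dataclass
class RateModelResult:
    """Estimates and uncertainty for one rate model."""

    params: pd.Series
    conf_int: pd.DataFrame  # columns: low, high (bootstrap percentile)
    f_stat: float = np.nan
    f_df: tuple = ()
    eta_squared: pd.Series = field(default_factory=pd.Series)
    perm_p: float = np.nan
    t_stat: float = np.nan
    t_df: float = np.nan
    cohens_d: float = np.nan
    mean_diff: float = np.nan
    n: int = 0
    meta: dict = field(default_factory=dict)

    def significant(self, term: str) -> bool:
        lo, hi = self.conf_int.loc[term]
        return bool(lo > 0 or hi < 0)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.params})
        out[["ci_low", "ci_high"]] = self.conf_int
        if len(self.eta_squared):
            out["eta_squared"] = self.eta_squared
        return out


def _bootstrap_ci(X: np.ndarray, y: np.ndarray, n_boot: int, rng, names) -> pd.DataFrame:
    """Case-resampling bootstrap percentile CIs for OLS coefficients."""
    if n_boot <= 0:
        return pd.DataFrame(
            {"low": np.nan, "high": np.nan}, index=names
        )
    n = len(y)
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0]
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({"low": lo, "high": hi}, index=names)


def _eta_squared(fit) -> pd.Series:
    anova = sm.stats.anova_lm(fit, typ=2)
    ss = anova["sum_sq"]
    return (ss / ss.sum()).drop("Residual").rename("eta_squared")


def rates_vs_connectivity_lm(
    table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> RateModelResult:
    """OLS of log omega on log connectivity, log mean expression and their
    interaction, with overall F, per-term eta-squared, and case-resampling
    bootstrap CIs. Requires >= 30 filtered rows with positive values."""
    df = pd.DataFrame(
        {
            "log_omega": np.log(table["omega"].to_numpy(float)),
            "log_k": np.log(table["kTotal"].to_numpy(float)),
            "log_expr": np.log(table["mean_expression"].to_numpy(float)),
        }
    )
    if len(df) < 30:
        raise ValueError("need at least 30 rows after filtering")
    fit = smf.ols("log_omega ~ log_k * log_expr", data=df).fit()
    X = np.column_stack(
        [np.ones(len(df)), df.log_k, df.log_expr, df.log_k * df.log_expr]
    )
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    names = ["Intercept", "log_k", "log_expr", "log_k:log_expr"]
    rng = np.random.default_rng(seed)
    ci = _bootstrap_ci(X, df.log_omega.to_numpy(), n_boot, rng, names)
    return RateModelResult(
        params=pd.Series(fit.params.to_numpy(), index=names),
        conf_int=ci,
        f_stat=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        eta_squared=_eta_squared(fit),
        n=len(df),
        meta={"estimator": ESTIMATOR, "n_boot": n_boot},
    )


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df)


def group_rate_permutation_test(
    group: np.ndarray,
    background: np.ndarray,
    alternative: str = "less",
    n_perm: int = 10_000,
    seed: int = 0,
) -> RateModelResult:
    """One-sided permutation Welch t-test on log omega.

    ``alternative='less'`` tests whether the group (e.g. hubs) has lower
    rates than the background; 'greater' the reverse (periphery). The
    permutation p uses the +1 correction: (1 + #{t_perm as-or-more extreme})
    / (1 + n_perm). Cohen's d uses the pooled SD.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    x = np.log(np.asarray(group, float))
    y = np.log(np.asarray(background, float))
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need at least 5 values in each group after log transform")
    t_obs, df = _welch_t(x, y)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    # vectorized permutation Welch t
    count = 0
    batch = max(1, min(n_perm, int(5e6 / n)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[idx]
        g1, g2 = perm[:, :n1], perm[:, n1:]
        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
        t_perm = (m1 - m2) / np.sqrt(v1 / n1 + v2 / (n - n1))
        if alternative == "less":
            count += int(np.sum(t_perm <= t_obs))
        else:
            count += int(np.sum(t_perm >= t_obs))
        done += b
    p = (1.0 + count) / (1.0 + n_perm)

    sp = np.sqrt(
        ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
        / (len(x) + len(y) - 2)
    )
    d = (x.mean() - y.mean()) / sp if sp > 0 else np.nan
    return RateModelResult(
        params=pd.Series({"mean_diff_log": x.mean() - y.mean()}),
        conf_int=pd.DataFrame({"low": [np.nan], "high": [np.nan]}, index=["mean_diff_log"]),
        perm_p=float(p),
        t_stat=t_obs,
        t_df=df,
        cohens_d=float(d),
        mean_diff=float(x.mean() - y.mean()),
        n=len(x) + len(y),
        meta={"alternative": alternative, "n_perm": n_perm, "estimator": ESTIMATOR},
    )


def syndrome_rate_lm(
    table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> RateModelResult:
    """OLS of log omega on the module syndrome-association factor.

    ``table`` needs columns omega and syndrome_association (category per
    orthogroup; 'none' = module not associated with any syndrome, used as the
    reference level)."""
    df = pd.DataFrame(
        {
            "log_omega": np.log(table["omega"].to_numpy(float)),
            "syndrome": pd.Categorical(table["syndrome_association"]),
        }
    )
    levels = list(df.syndrome.cat.categories)
    if len(levels) < 2:
        raise ValueError("need at least two syndrome-association categories")
    if "none" in levels:
        order = ["none"] + [l for l in levels if l != "none"]
        df["syndrome"] = df.syndrome.cat.reorder_categories(order)
    fit = smf.ols("log_omega ~ C(syndrome)", data=df).fit()
    dummies = pd.get_dummies(df.syndrome, drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), dummies])
    names = ["Intercept"] + [
        f"syndrome[{l}]" for l in df.syndrome.cat.categories[1:]
    ]
    rng = np.random.default_rng(seed)
    ci = _bootstrap_ci(X, df.log_omega.to_numpy(), n_boot, rng, names)
    return RateModelResult(
        params=pd.Series(fit.params.to_numpy(), index=names),
        conf_int=ci,
        f_stat=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        eta_squared=_eta_squared(fit),
        n=len(df),
        meta={
            "reference_level": str(df.syndrome.cat.categories[0]),
            "estimator": ESTIMATOR,
            "n_boot": n_boot,
        },
    )
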