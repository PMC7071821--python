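"""Module-trait association under phylogenetic non-independence.

A categorical trait (one-vs-rest binary coding for multi-level traits) is
regressed on a module eigengene at the species level with a probit
(latent-threshold) phylogenetic mixed model:

    z_s = b0 + b1 * eigengene_s + u_s + e_s,     y_s = 1{z_s > 0}
    u ~ Normal(0, sigma2_phylo * C),             e_s ~ Normal(0, 1) (fixed)

where C is the tree's shared-path-length (Brownian) correlation matrix. The
residual variance is fixed at 1 for identification; sigma2_phylo carries an
inverse-gamma(shape, scale) prior (both 0.001 by default, non-informative,
truncated above at a scientifically vacuous bound — see
PhyloMixedModelSpec). Sampling is a collapsed Gibbs scheme with
truncated-normal data augmentation for the liabilities, an independent
grid draw for the variance, and a Metropolis scale move; nothing requires
tuning. Fits are repeated over a set of candidate ultrametric trees to
propagate phylogenetic uncertainty, and posterior samples are pooled across
trees and chains.

A fixed effect is significant when its pooled 95% credible interval excludes
zero. The association label is strong when at least two species that share
the significant trait level have all-replicate eigengene values beyond +/-1,
weak when at most one such species exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "PhyloMixedModelSpec",
    "PhyloProbitModel",
    "PhyloProbitResults",
    "ultrametricize",
    "sample_trees",
    "phylo_correlation_matrix",
    "gelman_rubin",
    "effective_sample_size",
    "convergence_diagnostics",
    "run_multitree_association",
    "classify_trait_association",
]


# ---------------------------------------------------------------------------
# Trees


def ultrametricize(tree: dendropy.Tree) -> dendropy.Tree:
    """Mean-path-length smoothing of a rooted tree with branch lengths.

    Every node's depth is rescaled by (global mean tip depth) / (mean depth
    of the tips under the node), which leaves topology and relative node
    ordering intact and makes all root-to-tip paths equal; the result is then
    normalized to unit depth. A child is never placed above its parent
    (depths are clipped monotonically).
    """
    tree = tree.clone(depth=1)
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree must be rooted and non-trivial")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length or 0.0) <= 0:
            raise ValueError("branch lengths must be positive")

    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (0.0 if parent is None else depth[id(parent)]) + (
            node.edge.length or 0.0
        )

    tip_depth_sum: dict[int, float] = {}
    tip_count: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tip_depth_sum[id(node)] = depth[id(node)]
            tip_count[id(node)] = 1
        else:
            tip_depth_sum[id(node)] = sum(tip_depth_sum[id(c)] for c in node.child_nodes())
            tip_count[id(node)] = sum(tip_count[id(c)] for c in node.child_nodes())

    global_mean = tip_depth_sum[id(tree.seed_node)] / tip_count[id(tree.seed_node)]
    new_depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        subtree_mean = tip_depth_sum[id(node)] / tip_count[id(node)]
        d = depth[id(node)] * global_mean / subtree_mean
        d = max(d, new_depth[id(node.parent_node)] + 1e-12)
        new_depth[id(node)] = d
        node.edge.length = (d - new_depth[id(node.parent_node)]) / global_mean
    return tree


def sample_trees(trees: list[dendropy.Tree], n: int = 50, seed: int = 0) -> list[dendropy.Tree]:
    """Sample n trees without replacement (with replacement, and a warning,
    when fewer than n are available). Deterministic given seed."""
    if not trees:
        raise ValueError("tree list is empty")
    rng = np.random.default_rng(seed)
    if len(trees) >= n:
        idx = rng.choice(len(trees), size=n, replace=False)
    else:
        warnings.warn(
            f"only {len(trees)} trees available; sampling {n} with replacement"
        )
        idx = rng.choice(len(trees), size=n, replace=True)
    return [trees[i] for i in idx]


def phylo_correlation_matrix(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Shared-path-length correlation matrix (depth-normalized): the
    covariance of a unit-rate Brownian motion on the tree, scaled to unit
    diagonal."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in tax]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    depth = float(np.mean([depths[s] for s in species]))
    n = len(species)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tax[species[i]], tax[species[j]])
            C[i, j] = C[j, i] = max(0.0, (depth - d / 2.0) / depth)
    return C


# ---------------------------------------------------------------------------
# Model


@dataclass
class PhyloMixedModelSpec:
    """Sampler settings and priors for the phylogenetic probit model.

    prior_shape/prior_scale parameterize the inverse-gamma prior on the
    phylogenetic variance (non-informative 0.001/0.001 by default); the
    residual variance is fixed (default 1) for identification. Two chains of
    250,000 iterations with 50,000 burn-in are the reference settings.
    """

    prior_shape: float = 0.001
    prior_scale: float = 0.001
    residual_variance: float = 1.0
    chains: int = 2
    iterations: int = 250_000
    burn_in: int = 50_000
    thin: int = 50
    fixed_effect_prior_variance: float = 1e8
    # Upper truncation of the variance prior. The inverse-gamma(0.001, 0.001)
    # prior is nearly flat in log(sigma2), and with a dozen species a
    # threshold likelihood plateaus as sigma2 -> infinity, so the untruncated
    # posterior escapes to astronomically large latent scales. Truncating at
    # 1e3 (liability-scale heritability 0.999) excludes only that degenerate
    # region.
    phylo_var_max: float = 1e3

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PhyloProbitResults:
    """Posterior samples and summaries from a multi-chain probit fit.

    chains_* are lists (one entry per chain) of thinned post-burn-in draws.
    ``chains_intercept`` and ``chains_slope`` hold the fixed effects on the
    *unit-variance latent scale*, b / sqrt(1 + sigma2_phylo): threshold
    models with a free random-effect variance are identified only up to the
    latent scale, and this rescaling is the standard scale-invariant
    parameterization (raw-scale draws are kept in chains_*_raw).
    """

    chains_intercept: list[np.ndarray]
    chains_slope: list[np.ndarray]
    chains_phylo_var: list[np.ndarray]
    spec: PhyloMixedModelSpec
    chains_intercept_raw: list[np.ndarray] = None
    chains_slope_raw: list[np.ndarray] = None

    def pooled(self, param: str = "slope") -> np.ndarray:
        return np.concatenate(getattr(self, f"chains_{param}"))

    def credible_interval(self, param: str = "slope", level: float = 0.95):
        s = self.pooled(param)
        a = (1.0 - level) / 2.0
        return float(np.quantile(s, a)), float(np.quantile(s, 1.0 - a))

    def posterior_mean(self, param: str = "slope") -> float:
        return float(self.pooled(param).mean())

    def significant(self, param: str = "slope", level: float = 0.95) -> bool:
        lo, hi = self.credible_interval(param, level)
        return lo > 0.0 or hi < 0.0

    def diagnostics(self) -> pd.DataFrame:
        rows = {}
        for param in ("intercept", "slope"):
            chains = getattr(self, f"chains_{param}")
            rows[param] = {
                "psrf": gelman_rubin(chains),
                "ess": effective_sample_size(chains),
            }
        return pd.DataFrame(rows).T

    def summary(self) -> pd.DataFrame:
        rows = []
        diag = self.diagnostics()
        for param in ("intercept", "slope"):
            lo, hi = self.credible_interval(param)
            rows.append(
                {
                    "param": param,
                    "post_mean": self.posterior_mean(param),
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": lo > 0 or hi < 0,
                    "psrf": diag.loc[param, "psrf"],
                    "ess": diag.loc[param, "ess"],
                }
            )
        return pd.DataFrame(rows).set_index("param")


class PhyloProbitModel:
    """Phylogenetic probit mixed model for a binary species trait.

    Parameters
    ----------
    trait : per-species 0/1 response (pd.Series indexed by species)
    predictor : per-species eigengene value (same index)
    tree : ultrametric species tree covering all species
    spec : sampler settings (PhyloMixedModelSpec)
    """

    def __init__(self, trait: pd.Series, predictor: pd.Series, tree: dendropy.Tree,
                 spec: PhyloMixedModelSpec | None = None):
        species = list(trait.index)
        if set(species) != set(predictor.index):
            raise ValueError("trait and predictor species sets differ")
        if len(species) < 6:
            raise ValueError("need at least 6 species")
        y = trait.loc[species].to_numpy(float)
        if len(np.unique(y)) < 2:
            raise ValueError("trait is constant across species (non-identifiable)")
        self.species = species
        self.y = y.astype(int)
        self.x = predictor.loc[species].to_numpy(float)
        self.C = phylo_correlation_matrix(tree, species)
        self.spec = spec or PhyloMixedModelSpec()

    def fit(self, seed: int = 0) -> PhyloProbitResults:
        """Collapsed Gibbs sampler.

        The phylogenetic effects are integrated out analytically: the latent
        liabilities are jointly z ~ N(Xb, sigma2*C + rv*I) truncated by the
        observed trait, sampled single-site; the fixed effects get a
        conjugate GLS update against the marginal covariance; sigma2 is
        slice-sampled on the log scale under its inverse-gamma prior.
        Collapsing removes the strong u <-> sigma2 coupling that makes the
        naive data-augmentation sampler mix slowly.
        """
        spec = self.spec
        n = len(self.y)
        X = np.column_stack([np.ones(n), self.x])
        lam, Q = np.linalg.eigh(self.C)
        lam = np.clip(lam, 1e-10, None)
        rv = spec.residual_variance
        v0 = spec.fixed_effect_prior_variance
        a0, b0 = spec.prior_shape, spec.prior_scale
        pos = self.y == 1
        sign = np.where(pos, 1.0, -1.0)

        def precision(s2):
            return Q @ ((1.0 / (s2 * lam + rv))[:, None] * Q.T)

        # conditional of sigma2 given (z, b) is one-dimensional: sample it
        # by inverse-CDF on a fine log-spaced grid (an independent draw each
        # sweep, which mixes across the heavy upper tail far faster than a
        # local random-walk update)
        grid_log = np.linspace(np.log(1e-8), np.log(spec.phylo_var_max), 600)
        grid_s2 = np.exp(grid_log)
        cell = np.diff(grid_log).mean()
        denom_grid = grid_s2[:, None] * lam[None, :] + rv  # (G, n)
        log_det_grid = -0.5 * np.log(denom_grid).sum(axis=1)
        # inverse-gamma prior with the log-scale Jacobian
        log_prior_grid = -(a0 + 1.0) * grid_log - b0 / grid_s2 + grid_log

        def sample_s2(resid, rng):
            r2 = (Q.T @ resid) ** 2
            ll = log_det_grid - 0.5 * (r2[None, :] / denom_grid).sum(axis=1)
            lp = ll + log_prior_grid
            lp -= lp.max()
            w = np.exp(lp)
            cdf = np.cumsum(w)
            idx = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
            idx = min(idx, len(grid_log) - 1)
            return float(np.exp(grid_log[idx] + (rng.random() - 0.5) * cell))

        def log_target(z, b, s2):
            """Unnormalized log posterior of (z, b, s2) with u collapsed;
            the sign constraints on z are handled by the callers."""
            d = s2 * lam + rv
            r = Q.T @ (z - X @ b)
            ll = -0.5 * np.sum(np.log(d) + r**2 / d)
            lpb = -0.5 * np.dot(b, b) / v0
            lps = -(a0 + 1.0) * np.log(s2) - b0 / s2
            return ll + lpb + lps

        ci, cs, cv, ci_raw, cs_raw = [], [], [], [], []
        for chain in range(spec.chains):
            rng = np.random.default_rng([seed, chain])
            b = np.zeros(2)
            s2 = 1.0
            z = sign.copy()
            P = precision(s2)
            keep = {k: [] for k in ("i", "s", "v", "i_raw", "s_raw")}
            for it in range(spec.iterations):
                # latent liabilities: single-site truncated-normal Gibbs
                mu = X @ b
                for s in range(n):
                    v_s = 1.0 / P[s, s]
                    m_s = mu[s] - v_s * (P[s] @ (z - mu) - P[s, s] * (z[s] - mu[s]))
                    sd_s = np.sqrt(v_s)
                    lo = ndtr(-m_s / sd_s)
                    u01 = rng.random()
                    p = lo + u01 * (1.0 - lo) if pos[s] else u01 * lo
                    p = min(max(p, 1e-14), 1.0 - 1e-14)
                    z[s] = m_s + sd_s * ndtri(p)

                # fixed effects: GLS against the marginal covariance
                XtP = X.T @ P
                Vb = np.linalg.inv(XtP @ X + np.eye(2) / v0)
                mb = Vb @ (XtP @ z)
                b = mb + np.linalg.cholesky(Vb) @ rng.standard_normal(2)

                # sigma2: independent griddy-Gibbs draw from its conditional
                s2 = sample_s2(z - X @ b, rng)

                # Metropolis scale move: the posterior has a near-flat ray
                # along (cz, cb, c^2 s2) (the threshold model's latent-scale
                # degeneracy), which single-site updates traverse slowly.
                # A joint multiplicative proposal jumps along the ray; the
                # sign constraints are preserved because c > 0.
                logc = rng.normal(0.0, 1.0)
                c = np.exp(logc)
                s2_new = c * c * s2
                if s2_new <= spec.phylo_var_max:
                    jac = (n + 2 + 2) * logc
                    delta = (
                        log_target(c * z, c * b, s2_new)
                        - log_target(z, b, s2)
                        + jac
                    )
                    if np.log(rng.random()) < delta:
                        z = c * z
                        b = c * b
                        s2 = s2_new
                P = precision(s2)

                if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                    scale = np.sqrt(rv + s2)
                    keep["i"].append(b[0] / scale)
                    keep["s"].append(b[1] / scale)
                    keep["v"].append(s2)
                    keep["i_raw"].append(b[0])
                    keep["s_raw"].append(b[1])
            ci.append(np.array(keep["i"]))
            cs.append(np.array(keep["s"]))
            cv.append(np.array(keep["v"]))
            ci_raw.append(np.array(keep["i_raw"]))
            cs_raw.append(np.array(keep["s_raw"]))
        return PhyloProbitResults(
            chains_intercept=ci,
            chains_slope=cs,
            chains_phylo_var=cv,
            spec=spec,
            chains_intercept_raw=ci_raw,
            chains_slope_raw=cs_raw,
        )


# ---------------------------------------------------------------------------
# Convergence diagnostics


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor:
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B = n * variance of chain means. Requires >= 2 chains of equal length."""
    if len(chains) < 2:
        raise ValueError("PSRF requires at least two chains")
    n = len(chains[0])
    if any(len(c) != n for c in chains):
        raise ValueError("chains must have equal lengths")
    means = np.array([c.mean() for c in chains])
    W = float(np.mean([c.var(ddof=1) for c in chains]))
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def _ess_single(chain: np.ndarray) -> float:
    """Effective sample size by Geyer's initial-positive-sequence rule."""
    n = len(chain)
    x = chain - chain.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    # FFT autocovariance
    m = 1
    while m < 2 * n:
        m <<= 1
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / max(tau, 1.0))


def effective_sample_size(chains: list[np.ndarray]) -> float:
    """Autocorrelation-based ESS, summed over chains."""
    return float(sum(_ess_single(np.asarray(c, float)) for c in chains))


def convergence_diagnostics(chains: list[np.ndarray]):
    """(PSRF, ESS) for one parameter's chains; PSRF is NaN for one chain."""
    ess = effective_sample_size(chains)
    psrf = gelman_rubin(chains) if len(chains) >= 2 else np.nan
    return psrf, ess


# ---------------------------------------------------------------------------
# Multi-tree association and labelling


def species_eigengene_flags(
    eigengene: pd.Series, meta: pd.DataFrame, threshold: float = 1.0
) -> pd.Series:
    """Flag species whose replicates are *all* above +threshold ('high') or
    *all* below -threshold ('low'); otherwise 'none'. The eigengene is
    indexed by sample; meta maps sample -> species."""
    out = {}
    for sp, samples in meta.groupby("species").groups.items():
        vals = eigengene.loc[list(samples)]
        if (vals > threshold).all():
            out[sp] = "high"
        elif (vals < -threshold).all():
            out[sp] = "low"
        else:
            out[sp] = "none"
    return pd.Series(out, name="flag")


def classify_trait_association(
    significant: bool,
    slope_sign: float,
    flags: pd.Series,
    trait_values: pd.Series,
    level: str,
) -> tuple[str, int]:
    """The strong/weak evidence rule.

    Not significant -> 'none'. Significant and >= 2 species sharing the
    significant trait level are flagged (all replicates beyond +/- threshold)
    -> 'strong'; <= 1 such species -> 'weak'. Returns (label, n flagged
    sharing species)."""
    sharing = [sp for sp in trait_values.index if trait_values[sp] == level]
    n_flagged = sum(1 for sp in sharing if flags.get(sp, "none") != "none")
    if not significant:
        return "none", n_flagged
    return ("strong" if n_flagged >= 2 else "weak"), n_flagged


def run_multitree_association(
    eig,
    traits: pd.DataFrame,
    trees: list[dendropy.Tree],
    meta: pd.DataFrame,
    spec: PhyloMixedModelSpec | None = None,
    seed: int = 0,
    flag_threshold: float = 1.0,
    trait_columns: tuple[str, ...] = ("syndrome", "color", "shape", "spur"),
) -> pd.DataFrame:
    """Fit the phylogenetic probit model for every module x trait level,
    pooling posterior samples over trees and chains, and attach the
    strong/weak evidence labels.

    ``eig`` is an EigengeneMatrix over samples; ``meta`` maps samples to
    species. Multi-level traits are decomposed one-vs-rest; levels that are
    constant across species are skipped.
    """
    spec = spec or PhyloMixedModelSpec()
    me = eig.values_frame()
    species_order = list(traits.index)
    for tree in trees:
        labels = {t.label for t in tree.taxon_namespace}
        if not set(species_order) <= labels:
            raise ValueError("a tree does not cover all species")
    sp_of_sample = meta["species"]
    results = []
    for mi, module in enumerate(me.index):
        eg = me.loc[module]
        missing = set(sp_of_sample.loc[eg.index]) ^ set(species_order)
        if missing:
            raise ValueError(f"species mismatch between eigengenes and traits: {missing}")
        x = eg.groupby(sp_of_sample.loc[eg.index]).mean().loc[species_order]
        flags = species_eigengene_flags(eg, meta.loc[eg.index], flag_threshold)
        for trait_idx, trait in enumerate(trait_columns):
            tvals = traits[trait]
            for li, level in enumerate(sorted(tvals.unique())):
                y = (tvals == level).astype(int)
                if y.nunique() < 2:
                    continue
                slope_chains, intercept_chains = [], []
                for ti, tree in enumerate(trees):
                    model = PhyloProbitModel(y, x, tree, spec)
                    fit_seed = int(
                        np.random.default_rng(
                            [seed, mi, trait_idx, li, ti]
                        ).integers(2**31)
                    )
                    res = model.fit(seed=fit_seed)
                    slope_chains.extend(res.chains_slope)
                    intercept_chains.extend(res.chains_intercept)
                slopes = np.concatenate(slope_chains)
                lo, hi = np.quantile(slopes, [0.025, 0.975])
                significant = bool(lo > 0 or hi < 0)
                psrf = gelman_rubin(slope_chains) if len(slope_chains) > 1 else np.nan
                ess = effective_sample_size(slope_chains)
                label, n_flagged = classify_trait_association(
                    significant, float(np.sign(slopes.mean())), flags, tvals, level
                )
                results.append(
                    {
                        "module": module,
                        "trait": trait,
                        "level": level,
                        "post_mean": float(slopes.mean()),
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                        "significant": significant,
                        "direction": "positive" if slopes.mean() > 0 else "negative",
                        "psrf": psrf,
                        "ess": ess,
                        "n_flagged_sharing": n_flagged,
                        "flagged_species": ",".join(
                            sorted(flags.index[flags != "none"])
                        ),
                        "label": label,
                    }
                )
    return pd.DataFrame(results)
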