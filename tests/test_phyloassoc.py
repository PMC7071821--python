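"""Phylogenetic trait association: tree utilities, the probit mixed model,
convergence diagnostics, and the strong/weak evidence classifier."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from floranet import phyloassoc as pa
from floranet import synthetic_data as sd

FAST = pa.PhyloMixedModelSpec(iterations=6000, burn_in=1500, thin=5)


def species_of(tree):
    return [l.taxon.label for l in tree.leaf_node_iter()]


class TestUltrametricize:
    def test_fixed_point_on_ultrametric_tree(self, tree12):
        out = pa.ultrametricize(tree12)
        orig = {l.taxon.label: d for l, d in zip(tree12.leaf_node_iter(), [1.0] * 12)}
        depths = sd._tip_depths(out)
        ref = np.mean(list(depths.values()))
        assert max(abs(d / ref - 1.0) for d in depths.values()) < 1e-9

    def test_output_always_ultrametric(self):
        t = dendropy.Tree.get(data="((a:1.0,b:0.6):0.5,(c:2.0,d:0.9):0.3);",
                              schema="newick")
        out = pa.ultrametricize(t)
        depths = list(sd._tip_depths(out).values())
        assert max(depths) - min(depths) < 1e-9

    def test_three_taxon_caterpillar_hand_case(self):
        # tip depths 1.0, 1.2, 1.4; global mean 1.2. Internal node (a,b) sits
        # at depth 0.7 with subtree tip mean 1.1 -> rescaled depth
        # 0.7 * 1.2 / 1.1; final normalization by the mean depth 1.2.
        t = dendropy.Tree.get(data="((a:0.3,b:0.5):0.7,c:1.4);", schema="newick")
        out = pa.ultrametricize(t)
        depths = sd._tip_depths(out)
        assert all(abs(d - 1.0) < 1e-9 for d in depths.values())
        internal = [n for n in out.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None][0]
        d = internal.edge.length
        assert d == pytest.approx((0.7 * 1.2 / 1.1) / 1.2, abs=1e-9)

    def test_nonpositive_branch_rejected(self):
        t = dendropy.Tree.get(data="((a:1,b:0):1,c:2);", schema="newick")
        with pytest.raises(ValueError):
            pa.ultrametricize(t)


class TestSampleTrees:
    def test_without_replacement_deterministic(self):
        trees = [sd.simulate_phylogeny(5, seed=s) for s in range(100)]
        a = pa.sample_trees(trees, n=50, seed=7)
        b = pa.sample_trees(trees, n=50, seed=7)
        assert [id(t) for t in a] == [id(t) for t in b]
        assert len({id(t) for t in a}) == 50

    def test_with_replacement_fallback_warns(self):
        trees = [sd.simulate_phylogeny(5, seed=s) for s in range(30)]
        with pytest.warns(UserWarning):
            out = pa.sample_trees(trees, n=50, seed=1)
        assert len(out) == 50

    def test_default_n_is_50(self):
        import inspect

        assert inspect.signature(pa.sample_trees).parameters["n"].default == 50

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pa.sample_trees([], n=5)


class TestGelmanRubin:
    def test_identical_chains_hand_case(self):
        # chains {1,2,3},{1,2,3}: W=1, B=0 -> sqrt(2/3)
        chains = [np.array([1.0, 2, 3]), np.array([1.0, 2, 3])]
        assert pa.gelman_rubin(chains) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.standard_normal(5000), rng.standard_normal(5000)]
        assert pa.gelman_rubin(chains) < 1.01

    def test_divergent_chains_large(self):
        chains = [np.zeros(100) + 0.01 * np.arange(100), np.ones(100) * 10]
        assert pa.gelman_rubin(chains) > 2.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            pa.gelman_rubin([np.arange(10.0)])


class TestEffectiveSampleSize:
    def test_iid_reference_band(self):
        rng = np.random.default_rng(1)
        chains = [rng.standard_normal(5000), rng.standard_normal(5000)]
        ess = pa.effective_sample_size(chains)
        assert 4000 <= ess <= 12000

    def test_autocorrelated_chain_shrinks(self):
        rng = np.random.default_rng(2)
        x = np.zeros(5000)
        for i in range(1, 5000):
            x[i] = 0.95 * x[i - 1] + rng.standard_normal()
        ess = pa.effective_sample_size([x])
        assert ess < 1000


class TestPhyloProbitModel:
    def test_planted_effect_recovered(self, tree12, traits12):
        rng = np.random.default_rng(11)
        sp = species_of(tree12)
        y = (traits12.syndrome == traits12.syndrome.mode()[0]).astype(int).loc[sp]
        x = pd.Series(rng.normal(0, 1, 12), index=sp) + 1.5 * y
        res = pa.PhyloProbitModel(y, x, tree12, FAST).fit(seed=3)
        lo, hi = res.credible_interval("slope")
        assert lo > 0

    def test_null_effect_usually_not_significant(self, tree12, traits12):
        # under the null (predictor independent of trait), the nominal-95%
        # significance rate stays near 5%; check over a modest batch
        sp = species_of(tree12)
        y = (traits12.syndrome == traits12.syndrome.mode()[0]).astype(int).loc[sp]
        rng = np.random.default_rng(4)
        short = pa.PhyloMixedModelSpec(iterations=3000, burn_in=800, thin=4)
        hits = 0
        n = 20
        for _ in range(n):
            x = pd.Series(rng.normal(0, 1, 12), index=sp)
            res = pa.PhyloProbitModel(y, x, tree12, short).fit(
                seed=int(rng.integers(2**31))
            )
            hits += res.significant("slope")
        assert hits / n <= 0.2

    def test_deterministic_given_seed(self, tree12, traits12):
        sp = species_of(tree12)
        y = (traits12.syndrome == traits12.syndrome.mode()[0]).astype(int).loc[sp]
        x = pd.Series(np.random.default_rng(5).normal(size=12), index=sp)
        spec = pa.PhyloMixedModelSpec(iterations=2000, burn_in=500, thin=2)
        a = pa.PhyloProbitModel(y, x, tree12, spec).fit(seed=9)
        b = pa.PhyloProbitModel(y, x, tree12, spec).fit(seed=9)
        assert np.array_equal(a.pooled("slope"), b.pooled("slope"))

    def test_constant_trait_rejected(self, tree12):
        sp = species_of(tree12)
        y = pd.Series(1, index=sp)
        x = pd.Series(np.arange(12.0), index=sp)
        with pytest.raises(ValueError):
            pa.PhyloProbitModel(y, x, tree12)

    def test_prior_defaults(self):
        spec = pa.PhyloMixedModelSpec()
        assert spec.prior_shape == 0.001
        assert spec.prior_scale == 0.001
        assert spec.chains == 2
        assert spec.iterations == 250_000
        assert spec.burn_in == 50_000


class TestClassifier:
    @pytest.mark.parametrize(
        "significant,n_flagged,expected",
        [
            (False, 0, "none"),
            (False, 1, "none"),
            (False, 2, "none"),
            (False, 3, "none"),
            (True, 0, "weak"),
            (True, 1, "weak"),
            (True, 2, "strong"),
            (True, 3, "strong"),
        ],
    )
    @pytest.mark.parametrize("direction", [1.0, -1.0])
    def test_exhaustive_rule_table(self, significant, n_flagged, expected, direction):
        species = [f"s{i}" for i in range(6)]
        trait = pd.Series(
            ["hummingbird"] * 4 + ["bee"] * 2, index=species
        )
        flag_state = ["high"] * n_flagged + ["none"] * (4 - n_flagged) + ["none"] * 2
        flags = pd.Series(flag_state, index=species)
        label, n = pa.classify_trait_association(
            significant, direction, flags, trait, "hummingbird"
        )
        assert label == expected
        assert n == n_flagged

    def test_flags_require_all_replicates_beyond_threshold(self):
        samples = [f"s1_r{i}" for i in range(3)] + [f"s2_r{i}" for i in range(3)]
        meta = pd.DataFrame({"species": ["s1"] * 3 + ["s2"] * 3}, index=samples)
        eg = pd.Series([1.2, 1.5, 1.1, 1.2, 0.9, 1.5], index=samples)
        flags = pa.species_eigengene_flags(eg, meta)
        assert flags["s1"] == "high"  # all three replicates > 1
        assert flags["s2"] == "none"  # one replicate at 0.9 breaks the rule

    def test_low_flags(self):
        samples = [f"s1_r{i}" for i in range(2)]
        meta = pd.DataFrame({"species": ["s1", "s1"]}, index=samples)
        assert pa.species_eigengene_flags(
            pd.Series([-1.2, -1.4], index=samples), meta
        )["s1"] == "low"


class TestMultitreeAssociation:
    def test_planted_syndrome_shift_detected(self, tree12, traits12):
        from floranet import modstats as ms
        from floranet import netbuild as nb
        from floranet import preprocess as pp

        plan = sd.ModulePlan(
            modules=[sd.ModuleSpec(30, 0.8,
                                   trait_effects={("syndrome", "hummingbird"): 3.5})],
            n_background=60,
        )
        counts, meta, truth = sd.simulate_expression(
            tree12, traits12, plan, 3, ("Bud",), seed=2
        )
        m = pp.quantile_normalize(pp.vst_transform(counts))
        eig = ms.module_eigengenes(m, nb.ModulePartition(labels=truth))
        trees = [sd.simulate_phylogeny(12, seed=100 + i) for i in range(3)]
        res = pa.run_multitree_association(
            eig, traits12, trees, meta, FAST, seed=5, trait_columns=("syndrome",)
        )
        hum = res[(res.level == "hummingbird")].iloc[0]
        assert hum.significant
        assert hum.direction == "positive"

    def test_tree_missing_species_rejected(self, tree12, traits12):
        from floranet.modstats import EigengeneMatrix

        small = sd.simulate_phylogeny(5, seed=0)
        eig = EigengeneMatrix(
            values=pd.DataFrame(np.zeros((1, 2)), index=[1], columns=["a", "b"]),
            var_explained=pd.Series(dtype=float),
        )
        meta = pd.DataFrame({"species": ["sp01", "sp02"]}, index=["a", "b"])
        with pytest.raises(ValueError):
            pa.run_multitree_association(eig, traits12, [small], meta)
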