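"""NG86 dN/dS estimation and the rate-versus-network-position models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from floranet import evorates as ev
from floranet import synthetic_data as sd


class TestNg86Sites:
    def test_phe_codon_hand_count(self):
        # TTT: only third-position TTC is synonymous -> S = 1/3, N = 8/3
        s, n = ev._codon_sites("TTT")
        assert s == pytest.approx(1.0 / 3.0)
        assert n == pytest.approx(8.0 / 3.0)

    def test_sites_sum_to_three_per_codon(self):
        for codon in sd.SENSE_CODONS:
            s, n = ev._codon_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_fourfold_degenerate_third_position(self):
        # GGG (Gly): all third-position changes synonymous -> S = 1
        s, _ = ev._codon_sites("GGG")
        assert s == pytest.approx(1.0)


class TestNg86Pairwise:
    def test_identical_sequences(self):
        dn, ds = ev.ng86_pairwise("TTTGGG", "TTTGGG")
        assert dn == 0.0 and ds == 0.0

    def test_single_synonymous_difference_raw_counts(self):
        # TTT vs TTC: zero nonsynonymous differences -> dN = 0; the single
        # synonymous difference saturates the JC correction on 1 codon
        dn, ds = ev.ng86_pairwise("TTT", "TTC")
        assert dn == 0.0
        assert np.isnan(ds)

    def test_single_nonsynonymous_difference(self):
        # TTT (Phe) vs GTT (Val): one nonsynonymous difference
        dn, ds = ev.ng86_pairwise("TTTGGGAAACCC", "GTTGGGAAACCC")
        assert ds == 0.0
        assert dn > 0

    def test_symmetric_in_sequence_order(self):
        a = "ATGGCTAAATTTGGGCCC"
        b = "ATGGCGAAATTCGGACCA"
        assert ev.ng86_pairwise(a, b) == ev.ng86_pairwise(b, a)

    def test_pathway_averaging_two_hit_codon(self):
        # TTT -> GTC: pathways TTT->GTT->GTC (nonsyn, syn) and
        # TTT->TTC->GTC (syn, nonsyn): averaged 1 syn + 1 nonsyn
        S = N = Sd = Nd = 0.0
        sd_, nd_ = ev._codon_differences("TTT", "GTC")
        assert sd_ == pytest.approx(1.0)
        assert nd_ == pytest.approx(1.0)

    def test_gap_codons_skipped(self):
        dn, ds = ev.ng86_pairwise("TTTG-GAAA", "TTCGGGAAA")
        dn2, ds2 = ev.ng86_pairwise("TTTAAA", "TTCAAA")
        assert dn == dn2 and (np.isnan(ds) == np.isnan(ds2))

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ev.ng86_pairwise("TTTA", "TTTA")

    def test_internal_stop_rejected_naming_sequence(self):
        with pytest.raises(ValueError, match="seqB"):
            ev.ng86_dnds({"seqA": "TTTAAA", "seqB": "TTTTAA"})


class TestNg86Orthogroup:
    def test_simulated_omega_recovered_within_counting_bias(self, tree12):
        # round-trip against the codon simulator; NG86 with kappa=2 carries a
        # documented downward bias, tolerance 25% averaged over orthogroups
        for omega in (0.2, 0.5, 1.0):
            alns = sd.simulate_codon_alignments(
                tree12, sd.CodonSimSpec(omega=omega, n_codons=300),
                n_orthogroups=12, seed=7,
            )
            est = [ev.ng86_dnds(a)["omega"] for a in alns.values()]
            est = [e for e in est if np.isfinite(e)]
            assert abs(np.mean(est) / omega - 1.0) <= 0.25

    def test_sequence_permutation_invariance(self, tree12):
        alns = sd.simulate_codon_alignments(
            tree12, sd.CodonSimSpec(omega=0.5, n_codons=60), 1, seed=3
        )
        aln = next(iter(alns.values()))
        shuffled = dict(reversed(list(aln.items())))
        assert ev.ng86_dnds(aln)["omega"] == pytest.approx(
            ev.ng86_dnds(shuffled)["omega"], abs=1e-12
        )

    def test_identical_alignment_invalid(self):
        aln = {"a": "TTTGGGAAA", "b": "TTTGGGAAA"}
        res = ev.ng86_dnds(aln)
        assert res["dN"] == 0.0 and res["dS"] == 0.0
        assert not res["valid"]


class TestFilterRates:
    def _table(self, omegas, valid=None, **cols):
        t = pd.DataFrame({"omega": omegas})
        t["valid"] = valid if valid is not None else np.isfinite(t.omega)
        for k, v in cols.items():
            t[k] = v
        return t

    def test_sentinel_and_invalid_removed(self):
        t = self._table([0.5, 999.0, np.nan, 0.2])
        out = ev.filter_rates(t)
        assert list(out.omega) == [0.5, 0.2]
        assert out.attrs["removed"]["sentinel"] == 1

    def test_ten_row_toy_counts(self):
        # 2 sentinels, 1 dS=0 (invalid) -> 7 survive
        omegas = [0.1, 0.2, 999.0, 0.3, 999.0, 0.4, 0.5, 0.6, 0.7, np.nan]
        out = ev.filter_rates(self._table(omegas))
        assert len(out) == 7

    def test_nonpositive_covariates_removed(self):
        t = self._table([0.5, 0.5, 0.5], kTotal=[1.0, 0.0, 2.0],
                        mean_expression=[1.0, 1.0, -1.0])
        out = ev.filter_rates(t)
        assert len(out) == 1


def ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestRatesVsConnectivityLm:
    def _planted(self, n=200, slope=-0.5, seed=0):
        rng = np.random.default_rng(seed)
        logk = rng.normal(1.0, 0.6, n)
        loge = rng.normal(2.0, 0.5, n)
        logw = slope * logk + 0.1 * rng.standard_normal(n) - 1.0
        return pd.DataFrame(
            {"omega": np.exp(logw), "kTotal": np.exp(logk),
             "mean_expression": np.exp(loge)}
        )

    def test_matches_normal_equations_oracle(self):
        t = self._planted(n=40, seed=1)
        res = ev.rates_vs_connectivity_lm(t, n_boot=0, seed=0)
        logw, logk, loge = np.log(t.omega), np.log(t.kTotal), np.log(t.mean_expression)
        X = np.column_stack([np.ones(len(t)), logk, loge, logk * loge])
        beta = ols_normal_equations(X, logw.to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_planted_negative_slope_recovered(self):
        res = ev.rates_vs_connectivity_lm(self._planted(seed=2), n_boot=500, seed=3)
        assert res.params["log_k"] < 0
        lo, hi = res.conf_int.loc["log_k"]
        assert hi < 0

    def test_f_degrees_of_freedom(self):
        res = ev.rates_vs_connectivity_lm(self._planted(n=100, seed=4), n_boot=0)
        assert res.f_df == (3, 96)
        assert np.isfinite(res.f_stat)
        assert res.eta_squared.sum() <= 1.0 + 1e-9

    def test_null_interaction_false_positive_rate(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            n = 200
            t = pd.DataFrame(
                {
                    "omega": np.exp(rng.normal(-1, 0.5, n)),
                    "kTotal": np.exp(rng.normal(1, 0.5, n)),
                    "mean_expression": np.exp(rng.normal(2, 0.5, n)),
                }
            )
            res = ev.rates_vs_connectivity_lm(t, n_boot=200,
                                              seed=int(rng.integers(2**31)))
            hits += res.significant("log_k:log_expr")
        assert hits / n_sim <= 0.10 + 0.07  # nominal 5% with Monte-Carlo slack

    def test_bootstrap_zero_degrades_gracefully(self):
        res = ev.rates_vs_connectivity_lm(self._planted(seed=6), n_boot=0)
        assert res.conf_int.isna().all().all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ev.rates_vs_connectivity_lm(self._planted(n=10, seed=7))


class TestGroupRatePermutationTest:
    def test_cohens_d_hand_case(self):
        # on the log scale: groups {0..4} vs {2..6} -> means 2 vs 4, each
        # variance 2.5, pooled SD sqrt(2.5) -> d = -2 / sqrt(2.5)
        g = np.exp([0.0, 1.0, 2.0, 3.0, 4.0])
        b = np.exp([2.0, 3.0, 4.0, 5.0, 6.0])
        res = ev.group_rate_permutation_test(g, b, "less", n_perm=200, seed=0)
        assert res.cohens_d == pytest.approx(-2.0 / np.sqrt(2.5), abs=1e-12)
        assert res.mean_diff == pytest.approx(-2.0, abs=1e-12)

    def test_identical_groups_null_p(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(0, 1, 100))
        ps = []
        for s in range(20):
            shuffled = rng.permutation(vals)
            res = ev.group_rate_permutation_test(
                shuffled[:50], shuffled[50:], "less", n_perm=500, seed=s
            )
            ps.append(res.perm_p)
        assert np.mean(np.array(ps) >= 0.4) >= 0.5
        assert min(ps) >= 1.0 / 501

    def test_shifted_group_powerful(self):
        rng = np.random.default_rng(2)
        b = np.exp(rng.normal(0, 1, 100))
        g = np.exp(rng.normal(-1.0, 1, 100))
        res = ev.group_rate_permutation_test(g, b, "less", n_perm=2000, seed=3)
        assert res.perm_p <= 0.001

    def test_direction_matters(self):
        rng = np.random.default_rng(3)
        b = np.exp(rng.normal(0, 1, 100))
        g = np.exp(rng.normal(-1.0, 1, 100))
        res = ev.group_rate_permutation_test(g, b, "greater", n_perm=1000, seed=4)
        assert res.perm_p > 0.9

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ev.group_rate_permutation_test([1.0] * 4, [1.0] * 50, "less")


class TestSyndromeRateLm:
    def _table(self, seed=0, bee_shift=0.0, n=500):
        rng = np.random.default_rng(seed)
        assoc = rng.choice(["none", "bee", "hummingbird"], size=n, p=[0.6, 0.2, 0.2])
        logw = rng.normal(-1, 0.4, n)
        logw[assoc == "bee"] += bee_shift
        return pd.DataFrame({"omega": np.exp(logw), "syndrome_association": assoc})

    def test_reference_level_is_none(self):
        res = ev.syndrome_rate_lm(self._table(), n_boot=50, seed=1)
        assert res.meta["reference_level"] == "none"
        assert "syndrome[bee]" in res.params.index

    def test_planted_bee_shift_recovered(self):
        # 20% lower omega for bee-associated modules -> log shift ~ -0.223
        res = ev.syndrome_rate_lm(self._table(seed=2, bee_shift=np.log(0.8)),
                                  n_boot=400, seed=3)
        lo, hi = res.conf_int.loc["syndrome[bee]"]
        assert res.params["syndrome[bee]"] < 0
        assert hi < 0

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        hits, n_sim = 0, 40
        for _ in range(n_sim):
            res = ev.syndrome_rate_lm(self._table(seed=int(rng.integers(2**31))),
                                      n_boot=200, seed=int(rng.integers(2**31)))
            hits += res.significant("syndrome[bee]")
        assert hits / n_sim <= 0.15

    def test_single_category_rejected(self):
        t = pd.DataFrame({"omega": [0.5] * 40, "syndrome_association": ["none"] * 40})
        with pytest.raises(ValueError):
            ev.syndrome_rate_lm(t)
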