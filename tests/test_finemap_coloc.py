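"""Fine-mapping and colocalization: closed-form oracles, simulations, rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from fastproteo import finemap_coloc as fc
from fastproteo import synthetic_data as sd


class TestCisRegion:
    def _variants(self, chrom, positions):
        return pd.DataFrame({"chr": chrom, "pos": positions})

    def test_window_boundary_arithmetic(self):
        v = self._variants("1", [500_001, 499_999, 1_700_000, 1_700_002])
        # gene on chr1 at [1_000_000, 1_200_000] → window [500_000, 1_700_000]
        reg = fc.extract_cis_region("G", "1", 1_000_000, 1_200_000, v)
        assert sorted(reg.variants["pos"]) == [500_001, 1_700_000]

    def test_mhc_variants_excluded_on_chr6_only(self):
        # gene near the MHC edge: window spans the boundary at 34.0 Mb
        v6 = self._variants("6", [33_900_000, 34_000_001])
        reg6 = fc.extract_cis_region("G", "6", 33_900_000, 34_000_000, v6)
        assert list(reg6.variants["pos"]) == [34_000_001]
        v7 = self._variants("7", [30_000_000])
        reg7 = fc.extract_cis_region("G", "7", 29_900_000, 30_000_000, v7)
        assert list(reg7.variants["pos"]) == [30_000_000]

    def test_empty_region_returns_none(self):
        v = self._variants("2", [1])
        assert fc.extract_cis_region("G", "1", 10**6, 10**6, v) is None


class TestSusieRss:
    def test_single_causal_identity_ld(self, rng):
        M = 100
        z = rng.standard_normal(M)
        z[7] = 10.0
        fit = fc.susie_rss(z, np.eye(M), L=5)
        sets = fc.credible_sets(fit, np.eye(M))
        assert len(sets) == 1
        assert sets[0].members == (7,)
        assert fit.pip[7] > 0.95

    def test_null_z_produces_no_credible_sets(self):
        M = 50
        fit = fc.susie_rss(np.zeros(M), np.eye(M), L=3)
        assert fc.credible_sets(fit, np.eye(M)) == []

    def test_two_variant_closed_form_single_effect(self):
        """α at L=1 equals directly normalized single-effect Bayes factors."""
        z = np.array([2.5, 1.0])
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        V = 25.0
        fit = fc.susie_rss(z, R, L=1, prior_variance=V, estimate_prior_variance=False)
        s2 = V / (1 + V)
        lbf = 0.5 * np.log(1 / (1 + V)) + 0.5 * z**2 * s2
        expected = np.exp(lbf - logsumexp(lbf + np.log(0.5)) + np.log(0.5))
        expected /= expected.sum()
        np.testing.assert_allclose(fit.alpha[0], expected, atol=1e-8)

    def test_elbo_monotone_and_alpha_normalized(self, rng):
        for seed in range(3):
            reg = sd.generate_gwas_region("H4", 60, effect_sizes=6.0, seed=seed)
            fit = fc.susie_rss(reg.stats["protein"]["z"].to_numpy(), reg.ld, L=4)
            e = np.array(fit.elbo)
            assert np.all(np.diff(e) >= -1e-6 * np.maximum(1.0, np.abs(e[:-1])))
            np.testing.assert_allclose(fit.alpha.sum(axis=1), 1.0, atol=1e-10)
            assert np.all((fit.pip >= 0) & (fit.pip <= 1))

    def test_non_psd_ld_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues −1, 3
        with pytest.raises(ValueError, match="regularize"):
            fc.susie_rss(np.zeros(2), R, L=1)


class TestCredibleSets:
    def _fit(self, alpha_rows, V=None):
        alpha = np.array(alpha_rows, float)
        L, M = alpha.shape
        return fc.SusieFit(
            L=L, alpha=alpha, mu=np.zeros((L, M)), mu2=np.zeros((L, M)),
            lbf_variable=np.zeros((L, M)), lbf=np.zeros(L),
            V=np.ones(L) if V is None else np.array(V, float),
            elbo=[0.0], converged=True,
        )

    def test_dominant_variant_singleton_purity_one(self):
        fit = self._fit([[0.97, 0.01, 0.01, 0.01]])
        sets = fc.credible_sets(fit, np.eye(4))
        assert sets[0].members == (0,)
        assert sets[0].purity == 1.0

    def test_perfect_ld_pair_in_one_set(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 1.0
        fit = self._fit([[0.5, 0.48, 0.01, 0.01]])
        sets = fc.credible_sets(fit, R)
        assert set(sets[0].members) == {0, 1}
        assert sets[0].purity == pytest.approx(1.0)

    def test_low_purity_cross_block_set_dropped(self):
        R = np.eye(4)  # variants fully independent
        fit = self._fit([[0.5, 0.48, 0.01, 0.01]])
        assert fc.credible_sets(fit, R, min_purity=0.5) == []

    def test_duplicate_sets_deduplicated(self):
        fit = self._fit([[0.97, 0.01, 0.01, 0.01], [0.97, 0.01, 0.01, 0.01]])
        assert len(fc.credible_sets(fit, np.eye(4))) == 1

    def test_inactive_effects_skipped(self):
        fit = self._fit([[0.97, 0.01, 0.01, 0.01]], V=[0.0])
        assert fc.credible_sets(fit, np.eye(4)) == []


class TestSelectL:
    def _fit_with_sets(self, rows, V=None):
        alpha = np.array(rows, float)
        L, M = alpha.shape
        return fc.SusieFit(
            L=L, alpha=alpha, mu=np.zeros((L, M)), mu2=np.zeros((L, M)),
            lbf_variable=np.zeros((L, M)), lbf=np.zeros(L),
            V=np.ones(L) if V is None else np.array(V, float), elbo=[0.0], converged=True,
        )

    def test_correlated_leads_counted_once_tie_to_smallest_L(self):
        M = 6
        R = np.eye(M)
        R[2, 3] = R[3, 2] = 0.95  # leads 2 and 3 are proxies (r² ≈ 0.9)
        e = 0.01
        row = lambda j: [0.95 if i == j else e for i in range(M)]
        fit3 = self._fit_with_sets([row(0), row(2)])           # 2 independent sets
        fit5 = self._fit_with_sets([row(0), row(2), row(3)])   # 3 sets, two correlated
        chosen, sets = fc.select_L({3: fit3, 5: fit5}, R)
        assert chosen is fit3  # both give 2 independent leads; smaller L wins

    def test_all_single_set_chooses_smallest_L(self):
        M = 4
        row = [0.97, 0.01, 0.01, 0.01]
        fits = {L: self._fit_with_sets([row]) for L in (2, 3, 4)}
        chosen, _ = fc.select_L(fits, np.eye(M))
        assert chosen is fits[2]

    def test_two_causal_simulation_recovers_two_sets(self):
        hits = 0
        n_rep = 30
        for s in range(n_rep):
            reg = sd.generate_gwas_region("H3", 100, effect_sizes=6.0, seed=s)
            # one trait with two causal variants: reuse H3's block-separated pair
            lam = np.zeros(100)
            for t, idx in reg.causal_variants.items():
                for j in idx:
                    lam[j] = 6.0
            rng = np.random.default_rng(s)
            chol = np.linalg.cholesky(reg.ld + 1e-10 * np.eye(100))
            z2 = reg.ld @ lam + chol @ rng.standard_normal(100)
            fit, sets = fc.finemap_region(z2, reg.ld, L_range=(2, 6))
            leads = [cs.lead for cs in sets]
            indep = fc._max_independent_leads(sets, reg.ld)
            hits += indep >= 2
        assert hits / n_rep >= 0.80

    def test_all_failed_raises(self):
        with pytest.raises(ValueError):
            fc.select_L({2: None}, np.eye(2))


class TestWakefield:
    def test_zero_prior_variance_gives_null_bf(self):
        assert fc.wakefield_labf(0.4, 0.1, 0.0) == 0.0

    def test_zero_beta_shrinks_below_null(self):
        assert fc.wakefield_labf(0.0, 0.1, 0.04) < 0.0

    def test_formula_oracle(self):
        beta, se, W = 0.5, 0.1, 0.0225
        V = se**2
        z = beta / se
        expected = 0.5 * np.log(V / (V + W)) + z**2 * W / (2 * (V + W))
        assert fc.wakefield_labf(beta, se, W) == pytest.approx(expected, abs=1e-12)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            fc.wakefield_labf(1.0, 0.0, 0.04)


def coloc_enumeration_oracle(l1, l2, p1, p2, p12):
    """Brute-force configuration enumeration of the five hypotheses."""
    M = len(l1)
    s_h1 = sum(p1 * np.exp(l1[j]) for j in range(M))
    s_h2 = sum(p2 * np.exp(l2[k]) for k in range(M))
    s_h3 = sum(p1 * p2 * np.exp(l1[j] + l2[k]) for j, k in itertools.product(range(M), range(M)) if j != k)
    s_h4 = sum(p12 * np.exp(l1[j] + l2[j]) for j in range(M))
    terms = np.array([1.0, s_h1, s_h2, s_h3, s_h4])
    return terms / terms.sum()


class TestColocAbf:
    def _stats(self, betas, ses):
        m = len(betas)
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(m)],
            "beta": betas, "se": ses,
        })

    def test_pp_sums_to_one(self, rng):
        for _ in range(5):
            s1 = self._stats(rng.normal(0, 0.2, 8), np.full(8, 0.05))
            s2 = self._stats(rng.normal(0, 0.2, 8), np.full(8, 0.05))
            res = fc.coloc_abf(s1, s2, aligned=True)
            assert res.pp.sum() == pytest.approx(1.0, abs=1e-10)
            assert (res.pp >= 0).all()

    def test_single_variant_pp3_exactly_zero(self):
        res = fc.coloc_abf(self._stats([0.5], [0.05]), self._stats([0.4], [0.05]), aligned=True)
        assert res.pp[3] == 0.0

    def test_matches_enumeration_oracle_m3(self, rng):
        for _ in range(20):
            s1 = self._stats(rng.normal(0, 0.3, 3), rng.uniform(0.02, 0.1, 3))
            s2 = self._stats(rng.normal(0, 0.3, 3), rng.uniform(0.02, 0.1, 3))
            res = fc.coloc_abf(s1, s2, aligned=True)
            l1 = fc.wakefield_labf(s1["beta"].to_numpy(), s1["se"].to_numpy(), fc.W_QUANT)
            l2 = fc.wakefield_labf(s2["beta"].to_numpy(), s2["se"].to_numpy(), fc.W_QUANT)
            expected = coloc_enumeration_oracle(l1, l2, 1e-4, 1e-4, 5e-6)
            np.testing.assert_allclose(res.pp, expected, atol=1e-10)

    def test_misaligned_panels_rejected(self):
        s1 = self._stats([0.5, 0.1], [0.05, 0.05])
        s2 = self._stats([0.4], [0.05])
        with pytest.raises(ValueError):
            fc.coloc_abf(s1, s2, aligned=True)


class TestColocCrediblePairs:
    def _region_fits(self, scenario, seed, lam=8.0):
        reg = sd.generate_gwas_region(scenario, 100, effect_sizes=lam, seed=seed)
        f1 = fc.susie_rss(reg.stats["protein"]["z"].to_numpy(), reg.ld, L=5)
        f2 = fc.susie_rss(reg.stats["outcome"]["z"].to_numpy(), reg.ld, L=5)
        return reg, f1, f2

    def test_h4_shared_signal_high_pp4(self):
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            reg, f1, f2 = self._region_fits("H4", s)
            pairs = fc.coloc_credible_pairs(f1, f2, reg.ld)
            if pairs and max(p.pp4 for p in pairs) > 0.8:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_h3_distinct_signals_low_pp4_high_pp3(self):
        ok = 0
        n_rep = 40
        for s in range(n_rep):
            reg, f1, f2 = self._region_fits("H3", s)
            pairs = fc.coloc_credible_pairs(f1, f2, reg.ld)
            if not pairs:
                continue
            best = max(pairs, key=lambda p: p.pp4)
            if best.pp4 < 0.2 and best.pp[3] > 0.6:
                ok += 1
        assert ok / n_rep >= 0.80

    def test_no_credible_sets_gives_empty_list(self):
        M = 30
        f_null = fc.susie_rss(np.zeros(M), np.eye(M), L=2)
        f_sig = fc.susie_rss(np.concatenate([[10.0], np.zeros(M - 1)]), np.eye(M), L=2)
        assert fc.coloc_credible_pairs(f_null, f_sig, np.eye(M)) == []


class TestAcceptLink:
    def _coloc(self, pp4, lead):
        pp = np.array([0, 0, 0, 1 - pp4, pp4], float)
        return fc.ColocResult(pp=pp, priors={}, per_variant_h4=np.zeros(4), lead=lead)

    def _sets(self, lead):
        return [fc.CredibleSet(effect=0, members=(lead,), lead=lead, coverage=0.99, purity=1.0)]

    def test_pass_when_lead_is_pqtl_lead(self):
        assert fc.accept_link(self._coloc(0.85, 1), self._sets(1), np.eye(4))

    def test_fail_below_pp4_threshold(self):
        assert not fc.accept_link(self._coloc(0.79, 1), self._sets(1), np.eye(4))

    def test_fail_weak_proxy(self):
        R = np.eye(4)
        R[1, 2] = R[2, 1] = np.sqrt(0.5)  # r² = 0.5 ≤ 0.8
        assert not fc.accept_link(self._coloc(0.95, 2), self._sets(1), R)

    def test_pass_strong_proxy(self):
        R = np.eye(4)
        R[1, 2] = R[2, 1] = 0.95  # r² ≈ 0.9 > 0.8
        assert fc.accept_link(self._coloc(0.95, 2), self._sets(1), R)

    def test_lead_outside_panel_rejected(self):
        with pytest.raises(ValueError):
            fc.accept_link(self._coloc(0.9, 10), self._sets(1), np.eye(4))


class TestNetwork:
    def _edge(self, protein="P", trait="T", bp=0.5, bt=0.3, pp4=0.9, variant="rs1"):
        return fc.ProteinTraitEdge(protein=protein, trait=trait, pp4=pp4,
                                   variant=variant, beta_protein=bp, beta_trait=bt)

    def test_sign_invariant_under_allele_relabeling(self):
        e1 = self._edge(bp=0.5, bt=-0.3)
        e2 = self._edge(bp=-0.5, bt=0.3)  # both betas flipped to the other allele
        assert e1.sign == e2.sign == "discordant"

    def test_cardinality(self):
        links = [
            self._edge("P1", "T1"), self._edge("P1", "T2"), self._edge("P2", "T2"),
        ]
        G = fc.build_network(links)
        assert G.number_of_nodes() == 4
        assert G.number_of_edges() == 3

    def test_duplicate_pair_keeps_highest_pp4(self):
        G = fc.build_network([
            self._edge(pp4=0.85, variant="rs1"), self._edge(pp4=0.95, variant="rs2"),
        ])
        assert G.number_of_edges() == 1
        assert G.edges[("P", "T")]["pp4"] == 0.95
        assert G.edges[("P", "T")]["variant"] == "rs2"

    def test_graphml_and_tsv_written(self, tmp_path):
        G = fc.build_network([self._edge()])
        fc.write_network(G, tmp_path / "net.tsv", tmp_path / "net.graphml")
        df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(df) == 1
        assert (tmp_path / "net.graphml").stat().st_size > 0


class TestAlignAlleles:
    def _frame(self, alleles, betas, eafs=None):
        m = len(betas)
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(m)],
            "effect_allele": [a[0] for a in alleles],
            "other_allele": [a[1] for a in alleles],
            "beta": betas, "se": 0.1, "n": 1000,
            "eaf": eafs if eafs is not None else 0.3,
        })

    def test_swapped_alleles_flip_beta_and_eaf(self):
        s1 = self._frame([("A", "G")], [0.5], [0.3])
        s2 = self._frame([("G", "A")], [0.5], [0.3])
        a1, a2, dropped = fc.align_alleles(s1, s2)
        assert dropped == 0
        assert a2["beta"][0] == pytest.approx(-0.5)
        assert a2["eaf"][0] == pytest.approx(0.7)

    def test_ambiguous_strand_pairs_dropped(self):
        s1 = self._frame([("A", "T"), ("C", "G"), ("A", "C")], [0.1, 0.2, 0.3])
        s2 = self._frame([("A", "T"), ("C", "G"), ("A", "C")], [0.1, 0.2, 0.3])
        a1, a2, dropped = fc.align_alleles(s1, s2)
        assert dropped == 2
        assert list(a1["variant_id"]) == ["v2"]

    def test_strand_flip_resolved(self):
        s1 = self._frame([("A", "G")], [0.5])
        s2 = self._frame([("T", "C")], [0.5])  # complement strand, same orientation
        a1, a2, dropped = fc.align_alleles(s1, s2)
        assert dropped == 0
        assert a2["beta"][0] == pytest.approx(0.5)
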