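import math

import numpy as np
import pytest
from scipy import stats

from codonregimes import (
    GeneticCode,
    MCMCConfig,
    PriorConfig,
    RocSempprModel,
    codon_probabilities,
    deviance,
    dic_from_deviances,
    gene_log_likelihood,
    identify_optimal_codons,
    log_prior,
    rescale_to_AT_reference,
)
from codonregimes.genome_io import CODON_INDEX, CodonCountTable
from codonregimes.roc_semppr import _split_psrf


class TestCodonProbabilities:
    def test_uniform_when_all_zero(self):
        for n in (2, 3, 4, 6):
            p = codon_probabilities(np.zeros(n), np.zeros(n), 1.0)
            np.testing.assert_allclose(p, 1.0 / n)

    def test_phi_zero_depends_only_on_mutation(self, rng):
        dm = rng.normal(size=4)
        de = rng.normal(size=4)
        p0 = codon_probabilities(dm, de, 0.0)
        p_ref = np.exp(-dm) / np.exp(-dm).sum()
        np.testing.assert_allclose(p0, p_ref, atol=1e-12)

    def test_two_codon_closed_form(self):
        # non-reference ΔM = ln 2, Δη = 0: p_nonref = 1/3, p_ref = 2/3
        p = codon_probabilities(np.array([math.log(2.0), 0.0]), np.zeros(2), 1.0)
        assert p[0] == pytest.approx(1.0 / 3.0, abs=1e-15)
        assert p[1] == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_sum_to_one_randomized(self, rng):
        for _ in range(200):
            n = rng.integers(2, 7)
            p = codon_probabilities(
                rng.normal(0, 3, n), rng.normal(0, 1, n), float(rng.uniform(0, 20))
            )
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p > 0)

    def test_invariant_to_common_shift(self, rng):
        dm = rng.normal(size=4)
        de = rng.normal(size=4)
        p1 = codon_probabilities(dm, de, 2.0)
        p2 = codon_probabilities(dm + 5.7, de, 2.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_monotone_in_phi_for_positive_selection(self):
        dm = np.array([0.3, 0.0])
        de = np.array([0.4, 0.0])
        phis = np.linspace(0, 10, 25)
        p_nonref = [codon_probabilities(dm, de, ph)[0] for ph in phis]
        assert np.all(np.diff(p_nonref) < 0)

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            codon_probabilities(np.array([np.nan, 0.0]), np.zeros(2), 1.0)


class TestGeneLogLikelihood:
    def test_zero_counts_zero(self, standard_code):
        assert gene_log_likelihood(
            np.zeros(61), standard_code, np.zeros(61), np.zeros(61), 1.0
        ) == pytest.approx(0.0)

    def test_uniform_two_codon_case(self, standard_code):
        counts = np.zeros(61)
        counts[CODON_INDEX["AAC"]] = 1
        counts[CODON_INDEX["AAT"]] = 1
        ll = gene_log_likelihood(counts, standard_code, np.zeros(61), np.zeros(61), 1.0)
        assert ll == pytest.approx(2 * math.log(0.5))

    def test_brute_force_sum(self, standard_code, rng):
        counts = rng.integers(0, 20, size=61).astype(float)
        dm = rng.normal(0, 1, 61)
        de = rng.normal(0, 0.3, 61)
        phi = 1.7
        expected = 0.0
        for fam in standard_code.multi_codon_families:
            idx = [CODON_INDEX[c] for c in fam.codons]
            p = codon_probabilities(dm[idx], de[idx], phi)
            expected += float(np.sum(counts[idx] * np.log(p)))
        got = gene_log_likelihood(counts, standard_code, dm, de, phi)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_numba_kernel_matches_reference(self, standard_code, rng):
        """Dual route: the compiled likelihood equals the numpy reference."""
        counts = rng.integers(0, 30, size=(5, 61))
        table = CodonCountTable(
            gene_ids=[f"g{i}" for i in range(5)],
            counts=counts + (counts.sum(axis=1, keepdims=True) == 0),
            gc3=np.full(5, 0.5),
        )
        m = RocSempprModel(table)
        dm = rng.normal(0, 1, 61)
        de = rng.normal(0, 0.3, 61)
        # zero out reference codons as the model assumes
        for fam in standard_code.multi_codon_families:
            dm[CODON_INDEX[fam.reference]] = 0.0
            de[CODON_INDEX[fam.reference]] = 0.0
        for fam in standard_code.families:
            if fam.n_codons == 1:
                dm[CODON_INDEX[fam.codons[0]]] = 0.0
                de[CODON_INDEX[fam.codons[0]]] = 0.0
        phi = rng.uniform(0.1, 4.0, 5)
        fast = m.loglike(dm, de, phi)
        slow = sum(
            gene_log_likelihood(table.counts[g], standard_code, dm, de, phi[g])
            for g in range(5)
        )
        assert fast == pytest.approx(slow, rel=1e-10)


class TestVarMutReduction:
    def test_identical_regimes_equal_constmut_likelihood(self, small_two_regime, rng):
        table, _, _ = small_two_regime
        regimes = rng.integers(0, 2, size=table.n_genes)
        m_const = RocSempprModel(table)
        m_var = RocSempprModel(table, regimes=regimes)
        dm = rng.normal(0, 1, 61)
        de = rng.normal(0, 0.3, 61)
        phi = rng.uniform(0.1, 3.0, table.n_genes)
        ll_const = m_const.loglike(dm, de, phi)
        ll_var = m_var.loglike(np.stack([dm, dm]), de, phi)
        assert ll_var == pytest.approx(ll_const, rel=1e-12)


class TestLogPrior:
    def test_invalid_s_phi(self, standard_code):
        assert log_prior(np.zeros(61), np.zeros(61), np.ones(5), -1.0, standard_code) == -np.inf

    def test_scale_move_lowers_prior_not_likelihood(self, standard_code, small_single_regime):
        table, _, _ = small_single_regime
        m = RocSempprModel(table)
        rng = np.random.default_rng(0)
        dm = np.zeros(61)
        de = rng.normal(0, 0.2, 61)
        phi = rng.lognormal(-1.125, 1.5, table.n_genes)
        ll1 = m.loglike(dm, de, phi)
        ll2 = m.loglike(dm, de / 2.0, phi * 2.0)
        assert ll2 == pytest.approx(ll1, rel=1e-10)
        lp1 = log_prior(dm, de, phi, 1.5, standard_code)
        lp2 = log_prior(dm, de / 2.0, phi * 2.0, 1.5, standard_code)
        assert lp2 < lp1  # doubling phi moves it off the E[phi]=1 prior center


class TestDeviance:
    def test_linear_in_counts(self, small_single_regime, rng):
        table, _, truth = small_single_regime
        gc = GeneticCode.from_name("standard")
        phi = truth.per_gene["phi_true"].to_numpy()
        d1 = deviance(table, gc, truth.delta_m[0], truth.delta_eta, phi)
        doubled = CodonCountTable(
            gene_ids=table.gene_ids, counts=table.counts * 2, gc3=table.gc3
        )
        d2 = deviance(doubled, gc, truth.delta_m[0], truth.delta_eta, phi)
        assert d2 == pytest.approx(2 * d1, rel=1e-10)

    def test_equals_minus_two_loglik(self, small_single_regime):
        table, _, truth = small_single_regime
        gc = GeneticCode.from_name("standard")
        phi = truth.per_gene["phi_true"].to_numpy()
        ll = sum(
            gene_log_likelihood(table.counts[g], gc, truth.delta_m[0], truth.delta_eta, phi[g])
            for g in range(table.n_genes)
        )
        d = deviance(table, gc, truth.delta_m[0], truth.delta_eta, phi)
        assert d == pytest.approx(-2 * ll, rel=1e-12)


class TestDic:
    def test_degenerate_trace(self):
        dic, p_d = dic_from_deviances(np.array([10.0, 10.0, 10.0]), 10.0)
        assert p_d == pytest.approx(0.0)
        assert dic == pytest.approx(10.0)

    def test_two_sample_hand_computation(self):
        # D̄ = 12, D(θ̄) = 9 → p_D = 3, DIC = 9 + 2·3 = 15
        dic, p_d = dic_from_deviances(np.array([10.0, 14.0]), 9.0)
        assert p_d == pytest.approx(3.0)
        assert dic == pytest.approx(15.0)

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            dic_from_deviances(np.array([]), 1.0)


class TestRescaleToAT:
    def test_equal_coefficients_rescale_to_zero(self, standard_code):
        de = np.zeros(61)
        de[CODON_INDEX["GCG"]] = 0.25
        de[CODON_INDEX["GCA"]] = 0.25
        out = rescale_to_AT_reference(np.zeros((1, 61)), de, standard_code)
        assert out["delta_eta"][("Ala", "GCG")] == pytest.approx(0.0)

    def test_gcg_minus_gca(self, standard_code):
        de = np.zeros(61)
        de[CODON_INDEX["GCG"]] = 0.4
        de[CODON_INDEX["GCA"]] = 0.1
        out = rescale_to_AT_reference(np.zeros((1, 61)), de, standard_code)
        # positive: GCG disfavored relative to GCA
        assert out["delta_eta"][("Ala", "GCG")] == pytest.approx(0.3)

    def test_gcc_vs_reference_gct(self, standard_code):
        de = np.zeros(61)
        de[CODON_INDEX["GCC"]] = 0.7
        out = rescale_to_AT_reference(np.zeros((1, 61)), de, standard_code)
        # GCT is the family reference (value 0), so GCC stays 0.7
        assert out["delta_eta"][("Ala", "GCC")] == pytest.approx(0.7)

    def test_agy_family_uses_existing_at_member(self, standard_code):
        de = np.zeros(61)
        de[CODON_INDEX["AGC"]] = 0.5
        out = rescale_to_AT_reference(np.zeros((1, 61)), de, standard_code)
        # AGC's partner AGT is the reference: value relative to AGT
        assert out["delta_eta"][("Ser2", "AGC")] == pytest.approx(0.5)


class TestOptimalCodons:
    def test_minimum_delta_eta_wins(self, standard_code):
        de = np.zeros(61)
        de[CODON_INDEX["AAC"]] = -0.5  # Asn: AAC favored over reference AAT (0)
        assert identify_optimal_codons(de, standard_code)["Asn"] == "AAC"
        de[CODON_INDEX["AAC"]] = 0.2
        assert identify_optimal_codons(de, standard_code)["Asn"] == "AAT"

    def test_tie_breaks_alphabetically(self, standard_code):
        opt = identify_optimal_codons(np.zeros(61), standard_code)
        assert opt["Ala"] == "GCA"
        assert opt["Asn"] == "AAC"


class TestSplitPsrf:
    def test_identical_chains_give_one(self, rng):
        x = rng.normal(size=200)
        # identical chains: between-chain variance only from half-splitting
        assert _split_psrf([x, x.copy()]) == pytest.approx(1.0, abs=0.01)
        # degenerate constant trace: exactly 1
        assert _split_psrf([np.full(100, 2.0), np.full(100, 2.0)]) == 1.0

    def test_diverged_chains_give_large_value(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(50, 1, 200)
        assert _split_psrf([a, b]) > 3.0

    def test_matches_arviz_on_toy(self, rng):
        import arviz as az

        chains = [rng.normal(0, 1, 100), rng.normal(0.3, 1.2, 100)]
        ours = _split_psrf(chains)
        # classical (non-rank-normalized) split-Rhat
        ref = az.rhat(np.array(chains), method="split").item()
        assert ours == pytest.approx(ref, abs=0.05)


class TestMCMCConfig:
    def test_zero_retained_samples_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=95, thin=10)

    def test_full_scale_preset(self):
        cfg = MCMCConfig.full_scale(seed=1)
        assert cfg.iterations == 200_000
        assert cfg.burn_in == 50_000
        assert cfg.thin == 10
        assert cfg.n_chains == 2


class TestSmallFits:
    def test_binomial_logit_oracle(self):
        """Single informative 2-codon family with identical genes: posterior
        ΔM + Δη (at mean φ = 1) matches the analytic binomial logit MLE."""
        counts = np.zeros((40, 61), dtype=int)
        counts[:, CODON_INDEX["AAC"]] = 30
        counts[:, CODON_INDEX["AAT"]] = 70
        table = CodonCountTable(
            gene_ids=[f"g{i}" for i in range(40)], counts=counts, gc3=np.full(40, 0.3)
        )
        m = RocSempprModel(table)
        res = m.fit(MCMCConfig(iterations=4000, burn_in=1000, thin=5, n_chains=1, seed=4))
        k = res.free_codons.index("AAC")
        combo = res.stacked("dM")[:, 0, k] + res.stacked("deta")[:, k]
        target = -math.log(30.0 / 70.0)  # ΔM + Δη·1 at the MLE
        assert abs(combo.mean() - target) < 2 * combo.std() + 0.02

    def test_determinism_same_seed(self, small_single_regime):
        table, _, _ = small_single_regime
        cfg = MCMCConfig(iterations=600, burn_in=200, thin=10, n_chains=1, seed=9)
        r1 = RocSempprModel(table).fit(cfg)
        r2 = RocSempprModel(table).fit(cfg)
        np.testing.assert_array_equal(r1.phi_mean, r2.phi_mean)
        np.testing.assert_array_equal(r1.delta_eta_mean, r2.delta_eta_mean)
        assert r1.dic == r2.dic

    def test_phi_mean_pinned_to_one(self, small_single_regime):
        table, _, _ = small_single_regime
        res = RocSempprModel(table).fit(
            MCMCConfig(iterations=800, burn_in=300, thin=10, n_chains=1, seed=2)
        )
        assert res.phi_mean.mean() == pytest.approx(1.0, abs=1e-9)

    def test_unconverged_short_run_flagged(self, small_single_regime):
        table, _, _ = small_single_regime
        res = RocSempprModel(table).fit(
            MCMCConfig(iterations=40, burn_in=10, thin=1, n_chains=2, seed=1, adapt=False)
        )
        conv = res.convergence()
        assert conv["available"]
        # 30 retained samples from dispersed starts cannot look converged
        assert not conv["converged"]

    def test_single_chain_diagnostics_unavailable(self, small_single_regime):
        table, _, _ = small_single_regime
        res = RocSempprModel(table).fit(
            MCMCConfig(iterations=300, burn_in=100, thin=10, n_chains=1, seed=1)
        )
        conv = res.convergence()
        assert not conv["available"]

    def test_summary_runs(self, small_single_regime):
        table, _, _ = small_single_regime
        res = RocSempprModel(table).fit(
            MCMCConfig(iterations=300, burn_in=100, thin=10, n_chains=1, seed=1)
        )
        text = res.summary()
        assert "DIC" in text and "ConstMut" in text
        ptab = res.parameter_table()
        assert {"family", "codon", "regime", "deltaM_mean", "optimal_flag"} <= set(ptab.columns)
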