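"""History-dependence estimators: ML, NSB, BBC, Shuffling and the GLM."""

import numpy as np
import pytest

import histdep as hd
from histdep.embedding import EmbeddedSamples, SymbolCounts
from histdep.entropy import binary_entropy_bits
from histdep.estimators import (REstimate, bbc_estimate, bic, fit_glm,
                                glm_log2_likelihood, shuffle_surrogate,
                                surrogate_correction)


def counts_from_table(table, d):
    """SymbolCounts from {(x, word_tuple): count} with word most-recent-first."""
    xs, codes, ns = [], [], []
    for (x, word), n in table.items():
        code = sum(b << j for j, b in enumerate(word))
        xs.append(x)
        codes.append(code)
        ns.append(n)
    x_arr = np.repeat(xs, ns).astype(np.uint8)
    code_arr = np.repeat(codes, ns).astype(np.int64)
    return SymbolCounts.from_arrays(x_arr, code_arr, d)


def samples_from_arrays(x, bits, dt=0.005):
    d_carrier = max(1, bits.shape[1])  # embedding spec needs >= 1 bin
    emb = hd.make_embedding(dt * d_carrier, d_carrier, 0.0, dt)
    return EmbeddedSamples(x=np.asarray(x, dtype=np.uint8),
                           bits=np.asarray(bits, dtype=np.uint8),
                           emb=emb, medians=np.zeros(bits.shape[1]))


def plugin_mi_oracle(table):
    """Brute-force plugin mutual information / H(X) from a joint table."""
    total = sum(table.values())
    px, pw, pj = {}, {}, {}
    for (x, w), n in table.items():
        pj[(x, w)] = n / total
        px[x] = px.get(x, 0) + n / total
        pw[w] = pw.get(w, 0) + n / total
    mi = sum(p * np.log2(p / (px[x] * pw[w])) for (x, w), p in pj.items() if p > 0)
    return mi / binary_entropy_bits(px.get(1, 0.0))


class TestRml:
    def test_factorized_table_gives_zero(self):
        # past word independent of x: exact product counts
        table = {(x, (w,)): (30 if x else 70) * (4 if w else 6)
                 for x in (0, 1) for w in (0, 1)}
        counts = counts_from_table(table, d=1)
        assert hd.estimate_R_ml(counts).value == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_coupling_gives_one(self):
        counts = counts_from_table({(0, (0,)): 50, (1, (1,)): 50}, d=1)
        assert hd.estimate_R_ml(counts).value == pytest.approx(1.0)

    def test_hand_table_matches_bruteforce_oracle(self):
        table = {(0, (0,)): 40, (0, (1,)): 10, (1, (0,)): 10, (1, (1,)): 40}
        counts = counts_from_table(table, d=1)
        assert hd.estimate_R_ml(counts).value == pytest.approx(plugin_mi_oracle(table))

    def test_zero_spiking_entropy_rejected(self):
        counts = counts_from_table({(0, (0,)): 10, (0, (1,)): 10}, d=1)
        with pytest.raises(ValueError):
            hd.estimate_R_ml(counts)


class TestRnsb:
    def test_consistent_with_ml_when_well_sampled(self):
        table = {(0, (0,)): 4000, (0, (1,)): 1000, (1, (0,)): 1000, (1, (1,)): 4000}
        counts = counts_from_table(table, d=1)
        r_ml = hd.estimate_R_ml(counts).value
        r_nsb = hd.estimate_R_nsb(counts).value
        assert r_nsb == pytest.approx(r_ml, abs=0.01)

    def test_less_positive_bias_than_ml_on_independent_data(self):
        # d = 10 past bits independent of x, N = 1000: truth is R = 0
        rng = np.random.default_rng(5)
        r_ml, r_nsb = [], []
        for _ in range(5):
            x = (rng.random(1000) < 0.3).astype(np.uint8)
            codes = rng.integers(0, 2**10, size=1000).astype(np.int64)
            counts = SymbolCounts.from_arrays(x, codes, d=10)
            r_ml.append(hd.estimate_R_ml(counts).value)
            r_nsb.append(hd.estimate_R_nsb(counts).value)
        # truth is 0: NSB should be closer to zero than the plugin estimate
        assert np.mean(r_ml) > 0
        assert abs(np.mean(r_nsb)) < np.mean(r_ml)


class TestBBC:
    def test_exact_agreement_accepted(self):
        table = {(0, (0,)): 4000, (0, (1,)): 1000, (1, (0,)): 1000, (1, (1,)): 4000}
        counts = counts_from_table(table, d=1)
        est = bbc_estimate(counts, p=0.05)
        assert est.accepted
        assert est.value == hd.estimate_R_nsb(counts).value

    def test_rejection_sets_value_to_zero(self):
        # undersampled high-dimensional data: NSB and ML disagree strongly
        rng = np.random.default_rng(2)
        x = (rng.random(300) < 0.3).astype(np.uint8)
        codes = rng.integers(0, 2**8, size=300).astype(np.int64)
        counts = SymbolCounts.from_arrays(x, codes, d=8)
        r_ml = hd.estimate_R_ml(counts).value
        r_nsb = hd.estimate_R_nsb(counts).value
        assert abs(r_nsb - r_ml) > 0.05 * r_nsb  # premise of the check
        est = bbc_estimate(counts, p=0.05)
        assert not est.accepted and est.value == 0.0

    def test_tolerance_must_be_positive(self):
        counts = counts_from_table({(0, (0,)): 5, (1, (1,)): 5}, d=1)
        with pytest.raises(ValueError):
            bbc_estimate(counts, p=0.0)


class TestShuffling:
    def test_d1_equals_ml_exactly(self):
        rng = np.random.default_rng(3)
        x = (rng.random(500) < 0.2).astype(np.uint8)
        bits = (rng.random((500, 1)) < 0.4).astype(np.uint8)
        samples = samples_from_arrays(x, bits)
        r_sh = hd.estimate_R_shuffling(samples, rng).value
        r_ml = hd.estimate_R_ml(SymbolCounts.from_samples(samples)).value
        assert r_sh == pytest.approx(r_ml, abs=1e-12)

    def test_shuffle_preserves_pairwise_counts(self):
        rng = np.random.default_rng(4)
        x = (rng.random(400) < 0.3).astype(np.uint8)
        bits = (rng.random((400, 3)) < 0.5).astype(np.uint8)
        samples = samples_from_arrays(x, bits)
        shuffled = shuffle_surrogate(samples, rng)
        for x_val in (0, 1):
            mask = x == x_val
            assert np.array_equal(bits[mask].sum(axis=0), shuffled[mask].sum(axis=0))
        assert np.array_equal(samples.x, x)  # class sizes untouched

    def test_shuffled_joint_approaches_product_form(self):
        # within one class, shuffling factorizes the word distribution
        rng = np.random.default_rng(6)
        n = 40_000
        b0 = (rng.random(n) < 0.5).astype(np.uint8)
        bits = np.stack([b0, b0, (rng.random(n) < 0.2).astype(np.uint8)], axis=1)
        x = np.zeros(n, dtype=np.uint8)
        x[:100] = 1
        samples = samples_from_arrays(x, bits)
        shuffled = shuffle_surrogate(samples, rng)
        mask = x == 0
        # empirical P(b0=1, b1=1) under shuffling ~ P(b0=1) P(b1=1) = 0.25
        both = np.mean(shuffled[mask, 0] & shuffled[mask, 1])
        p_prod = shuffled[mask, 0].mean() * shuffled[mask, 1].mean()
        assert both == pytest.approx(p_prod, abs=0.01)

    def test_mean_nonpositive_on_independent_data(self):
        # truth is R = 0; the shuffling estimator is a lower bound so its
        # expectation over seeds must not be positive
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(100):
            x = (rng.random(2000) < 0.2).astype(np.uint8)
            bits = (rng.random((2000, 8)) < 0.3).astype(np.uint8)
            vals.append(hd.estimate_R_shuffling(samples_from_arrays(x, bits), rng).value)
        assert np.mean(vals) <= 0

    def test_never_above_ml(self):
        rng = np.random.default_rng(8)
        x = (rng.random(3000) < 0.2).astype(np.uint8)
        bits = (rng.random((3000, 4)) < 0.4).astype(np.uint8)
        samples = samples_from_arrays(x, bits)
        means_sh = np.mean([hd.estimate_R_shuffling(samples, rng).value
                            for _ in range(20)])
        r_ml = hd.estimate_R_ml(SymbolCounts.from_samples(samples)).value
        assert means_sh <= r_ml + 1e-12

    def test_correction_terms_signs(self):
        rng = np.random.default_rng(9)
        x = (rng.random(1000) < 0.3).astype(np.uint8)
        bits = (rng.random((1000, 5)) < 0.4).astype(np.uint8)
        corr = surrogate_correction(samples_from_arrays(x, bits), rng)
        assert corr.H_ml_sh >= 0 and corr.H_true_sh >= 0 and corr.H_ml_cond >= 0
        assert corr.H_true_sh >= corr.H_ml_sh  # plugin bias is negative


class TestGLM:
    def test_intercept_only_matches_empirical_rate(self):
        rng = np.random.default_rng(10)
        x = (rng.random(5000) < 0.23).astype(np.uint8)
        samples = samples_from_arrays(x, np.zeros((5000, 0), dtype=np.uint8))
        fit = fit_glm(samples)
        p_hat = 1.0 / (1.0 + np.exp(-(fit.mu + np.log(samples.emb.dt))))
        assert p_hat == pytest.approx(x.mean(), rel=1e-6)
        # R_glm = 0 for a memoryless model: L*/N equals -H(X)
        h_glm = -fit.log2_likelihood / fit.N
        assert h_glm == pytest.approx(binary_entropy_bits(x.mean()), rel=1e-9)

    def test_parameter_recovery_on_simulated_glm(self):
        rng = np.random.default_rng(11)
        n, dt = 10**6, 0.005
        mu_true, h_true = -5.0 + np.log(1.0 / dt), np.array([2.0, 1.0])
        bits = (rng.random((n, 2)) < 0.3).astype(np.uint8)
        lam = np.exp(mu_true + bits @ h_true)
        p = lam * dt / (1 + lam * dt)
        x = (rng.random(n) < p).astype(np.uint8)
        fit = fit_glm(samples_from_arrays(x, bits, dt))
        assert fit.mu == pytest.approx(mu_true, abs=0.05)
        assert np.allclose(fit.h, h_true, atol=0.05)
        assert not fit.separated

    def test_eval_likelihood_matches_fit_likelihood_in_sample(self):
        rng = np.random.default_rng(12)
        x = (rng.random(2000) < 0.2).astype(np.uint8)
        bits = (rng.random((2000, 2)) < 0.5).astype(np.uint8)
        samples = samples_from_arrays(x, bits)
        fit = fit_glm(samples)
        assert glm_log2_likelihood(fit, samples) == pytest.approx(
            fit.log2_likelihood, rel=1e-6)

    def test_bic_arithmetic(self):
        assert bic(3, 1024, -3000.0) == pytest.approx(4 * 10 - 2 * (-3000.0))

    def test_memoryless_train_yields_near_zero_R(self):
        rng = np.random.default_rng(13)
        times = np.sort(rng.uniform(0, 300.0, size=int(300 * 4)))
        train = hd.SpikeTrain(np.unique(times), 0.0, 300.0)
        cfg = hd.AnalysisConfig(d_max=3)
        est = hd.estimate_R_glm(train, 0.05, cfg, d_set=[1, 2, 3])
        assert abs(est.value) < 0.01

    def test_separation_reported(self):
        x = np.array([0, 0, 0, 1, 1, 1] * 20, dtype=np.uint8)
        bits = x[:, None].copy()  # perfectly predictive column
        fit = fit_glm(samples_from_arrays(x, bits))
        assert fit.separated


class TestSymbolRelabeling:
    def test_estimates_invariant_under_word_relabeling(self):
        # XOR with a constant is a bijection on past words; every
        # estimator depends on the counts only through their multiset
        rng = np.random.default_rng(14)
        x = (rng.random(4000) < 0.25).astype(np.uint8)
        codes = rng.integers(0, 8, size=4000).astype(np.int64)
        a = SymbolCounts.from_arrays(x, codes, d=3)
        b = SymbolCounts.from_arrays(x, codes ^ 0b101, d=3)
        assert hd.estimate_R_ml(a).value == pytest.approx(
            hd.estimate_R_ml(b).value, rel=1e-12)
        assert hd.estimate_R_nsb(a).value == pytest.approx(
            hd.estimate_R_nsb(b).value, rel=1e-9)
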