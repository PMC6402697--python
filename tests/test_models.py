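"""Topic models: LDA variational Bayes and the correlated variants."""

import numpy as np
import pytest

from mmctm.containers import CountMatrix, SignatureSet
from mmctm.encoding import snv_independent_space
from mmctm.models import (
    ModelConfig,
    fit_independent,
    fit_lda,
    fit_mmctm,
    fit_model,
    infer_theta,
    restart_protocol,
    signature_correlations,
)
from mmctm.simulate import (
    SimulationSpec,
    draw_correlated_probs,
    draw_dirichlet_probs,
    match_signatures,
    simulate_counts,
    synthetic_signatures,
)


def assert_elbo_monotone(trace, rtol=1e-8):
    trace = np.asarray(trace)
    drops = np.diff(trace) < -rtol * np.abs(trace[:-1])
    assert not drops.any(), f"ELBO decreased at iterations {np.where(drops)[0]}"


def assert_rows_stochastic(fit):
    for sig in fit.signatures:
        for lo, hi in sig.feature_slices():
            np.testing.assert_allclose(sig.phi[:, lo:hi].sum(axis=1), 1.0,
                                       atol=1e-8)
    for probs in fit.sample_probs:
        np.testing.assert_allclose(probs.theta.sum(axis=1), 1.0, atol=1e-8)


class TestLda:
    def test_single_signature_degenerate_case(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_lda(counts, K=1, beta=1.0, seed=0)
        np.testing.assert_allclose(fit.sample_probs[0].theta, 1.0)
        # phi is the Dirichlet posterior mean of the aggregate counts
        agg = counts.counts.sum(axis=0).astype(float)
        expected = (agg + 1.0) / (agg + 1.0).sum()
        np.testing.assert_allclose(fit.signatures[0].phi[0], expected, atol=1e-10)

    def test_disjoint_category_blocks_recovered(self, snv_space):
        rng = np.random.default_rng(3)
        phi = np.zeros((2, 96))
        phi[0, :48] = rng.dirichlet(np.ones(48))
        phi[1, 48:] = rng.dirichlet(np.ones(48))
        sigs = SignatureSet(snv_space, phi)
        theta = np.repeat([[1.0, 0.0], [0.0, 1.0]], 10, axis=0)
        counts = np.vstack([rng.multinomial(4000, theta[d] @ phi)
                            for d in range(20)])
        cm = CountMatrix([f"s{d}" for d in range(20)], snv_space, counts)
        fit = fit_lda(cm, K=2, seed=1)
        mr = match_signatures(fit.signatures[0], sigs)
        assert mr.signature_mae.max() < 0.05

    def test_seeded_determinism(self, small_corpus):
        _, _, counts = small_corpus
        f1 = fit_lda(counts, K=3, seed=42, max_iters=30)
        f2 = fit_lda(counts, K=3, seed=42, max_iters=30)
        np.testing.assert_array_equal(f1.signatures[0].phi, f2.signatures[0].phi)
        np.testing.assert_array_equal(f1.sample_probs[0].theta,
                                      f2.sample_probs[0].theta)

    def test_elbo_monotone_and_normalized(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_lda(counts, K=3, seed=5)
        assert_elbo_monotone(fit.elbo_trace)
        assert_rows_stochastic(fit)

    def test_all_zero_counts_rejected(self, snv_space):
        cm = CountMatrix(["a", "b"], snv_space, np.zeros((2, 96), dtype=int))
        with pytest.raises(ValueError):
            fit_lda(cm, K=2)

    def test_matches_sklearn_variational_lda(self, snv_space):
        """Independent oracle: scikit-learn's VB-LDA finds the same topics."""
        from sklearn.decomposition import LatentDirichletAllocation

        rng = np.random.default_rng(7)
        phi = np.zeros((2, 96))
        phi[0, :48] = rng.dirichlet(np.ones(48))
        phi[1, 48:] = rng.dirichlet(np.ones(48))
        theta = rng.dirichlet(np.ones(2), size=40)
        counts = np.vstack([rng.multinomial(3000, theta[d] @ phi)
                            for d in range(40)])
        cm = CountMatrix([f"s{d}" for d in range(40)], snv_space, counts)
        ours = fit_lda(cm, K=2, seed=1).signatures[0].phi
        sk = LatentDirichletAllocation(n_components=2, random_state=1,
                                       max_iter=100).fit(counts)
        theirs = sk.components_ / sk.components_.sum(axis=1, keepdims=True)
        sims = np.abs(ours @ theirs.T) / (
            np.linalg.norm(ours, axis=1)[:, None]
            * np.linalg.norm(theirs, axis=1)[None, :])
        # best match per signature is essentially identical
        assert sims.max(axis=1).min() > 0.98


@pytest.fixture(scope="module")
def correlated_corpus(snv_space, sv_space):
    """Two modalities whose matching signature probabilities are correlated."""
    K = 3
    s1 = synthetic_signatures(K, snv_space, seed=21)
    s2 = synthetic_signatures(K, sv_space, seed=22)
    sigma = np.eye(2 * K)
    for i in range(K):
        sigma[i, K + i] = sigma[K + i, i] = 0.95
    probs = draw_correlated_probs(np.zeros(2 * K), sigma, 150, [K, K],
                                  seed=23, modalities=["SNV", "SV"])
    counts = simulate_counts(SimulationSpec(
        [s1, s2], probs, [np.full(150, 1200), np.full(150, 200)], seed=24))
    return (s1, s2), probs, counts


class TestMmctm:
    def test_elbo_monotone_rows_normalized_sigma_psd(self, correlated_corpus):
        _, _, counts = correlated_corpus
        fit = fit_mmctm(counts, ModelConfig(model="mmctm", k=(3, 3), seed=1,
                                            max_iters=150))
        assert_elbo_monotone(fit.elbo_trace)
        assert_rows_stochastic(fit)
        assert np.linalg.eigvalsh(fit.prior.sigma).min() >= -1e-10
        np.testing.assert_allclose(fit.prior.sigma, fit.prior.sigma.T)

    def test_single_modality_equals_ctm_trajectory(self, small_corpus):
        _, _, counts = small_corpus
        f_ctm = fit_model([counts], ModelConfig(model="ctm", k=(3,), seed=4,
                                                max_iters=40))
        f_mm = fit_model([counts], ModelConfig(model="mmctm", k=(3,), seed=4,
                                               max_iters=40))
        np.testing.assert_array_equal(f_ctm.elbo_trace, f_mm.elbo_trace)
        np.testing.assert_array_equal(f_ctm.signatures[0].phi,
                                      f_mm.signatures[0].phi)

    def test_fixed_covariance_stays_identity(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=2,
                                              fix_covariance_identity=True,
                                              max_iters=60))
        np.testing.assert_array_equal(fit.prior.sigma, np.eye(2))

    def test_correlated_signatures_recovered_with_positive_r(
            self, correlated_corpus):
        (s1, s2), _, counts = correlated_corpus
        fit = restart_protocol(counts, ModelConfig(model="mmctm", k=(3, 3),
                                                   seed=3, n_restarts=5))
        corr = signature_correlations(fit)
        m1 = match_signatures(fit.signatures[0], s1)
        m2 = match_signatures(fit.signatures[1], s2)
        assert m1.signature_mae.max() < 0.05
        assert m2.signature_mae.max() < 0.05
        # generating pairs (i, K+i) were drawn with correlation 0.95
        inv1 = {r: e for e, r in m1.mapping.items()}
        inv2 = {r: e for e, r in m2.mapping.items()}
        fitted_r = [corr[inv1[i], 3 + inv2[i]] for i in range(3)]
        assert min(fitted_r) > 0.8

    def test_mismatched_sample_order_rejected(self, correlated_corpus):
        _, _, counts = correlated_corpus
        flipped = CountMatrix(list(reversed(counts[1].sample_ids)),
                              counts[1].category_space, counts[1].counts[::-1])
        with pytest.raises(ValueError):
            fit_mmctm([counts[0], flipped],
                      ModelConfig(model="mmctm", k=(3, 3)))

    def test_missing_k_rejected(self, correlated_corpus):
        _, _, counts = correlated_corpus
        with pytest.raises(ValueError):
            fit_mmctm(counts, ModelConfig(model="mmctm", k=(3,)))

    def test_seeded_determinism(self, small_corpus):
        _, _, counts = small_corpus
        f1 = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=9,
                                             max_iters=30))
        f2 = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=9,
                                             max_iters=30))
        np.testing.assert_array_equal(f1.signatures[0].phi, f2.signatures[0].phi)
        np.testing.assert_array_equal(f1.prior.sigma, f2.prior.sigma)


class TestIndependentModels:
    def test_k1_recovers_marginal_feature_frequencies(self, toy_reference):
        from mmctm.encoding import SnvCall, build_count_matrix

        space = snv_independent_space()
        calls = [SnvCall("chr1", 2, "C", "T", "s1"),
                 SnvCall("chr1", 6, "C", "G", "s1"),
                 SnvCall("chr1", 10, "C", "A", "s2")]
        cm, _ = build_count_matrix(calls, space, toy_reference)
        fit = fit_independent([cm], ModelConfig(model="ilda", k=(1,), beta=1e-9))
        phi = fit.signatures[0].phi[0]
        for lo, hi in fit.signatures[0].feature_slices():
            marg = cm.counts[:, lo:hi].sum(axis=0).astype(float)
            np.testing.assert_allclose(phi[lo:hi], marg / marg.sum(), atol=1e-6)

    def test_product_over_features_sums_to_one(self, small_corpus):
        """Factorized signature probabilities form a distribution over the
        96 full categories."""
        space = snv_independent_space()
        rng = np.random.default_rng(0)
        phi = np.concatenate([rng.dirichlet(np.ones(a), size=2)
                              for a in (6, 4, 4)], axis=1)
        sigs = SignatureSet(space, phi)
        probs = draw_dirichlet_probs(2, 40, seed=1)
        cm = simulate_counts(SimulationSpec([sigs], [probs],
                                            [np.full(40, 800)], seed=2))[0]
        fit = fit_independent([cm], ModelConfig(model="ictm", k=(2,), seed=3))
        est = fit.signatures[0].phi
        for k in range(2):
            total = sum(
                est[k, s0] * est[k, 6 + f1] * est[k, 10 + f2]
                for s0 in range(6) for f1 in range(4) for f2 in range(4))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_factorized_signatures_recovered(self):
        space = snv_independent_space()
        rng = np.random.default_rng(5)
        phi = np.concatenate([rng.dirichlet(np.full(a, 0.3), size=2)
                              for a in (6, 4, 4)], axis=1)
        sigs = SignatureSet(space, phi)
        probs = draw_dirichlet_probs(2, 80, seed=6)
        cm = simulate_counts(SimulationSpec([sigs], [probs],
                                            [np.full(80, 3000)], seed=7))[0]
        fit = fit_independent([cm], ModelConfig(model="ictm", k=(2,), seed=8))
        mr = match_signatures(fit.signatures[0], sigs)
        assert mr.signature_mae.max() < 0.05

    def test_full_encoding_rejected(self, small_corpus):
        _, _, counts = small_corpus
        with pytest.raises(ValueError):
            fit_independent([counts], ModelConfig(model="ictm", k=(2,)))


class TestInferTheta:
    def test_k1_gives_theta_one(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(1,), seed=0,
                                              max_iters=30))
        thetas = infer_theta(fit, [counts])
        np.testing.assert_allclose(thetas[0].theta, 1.0)

    def test_concentrated_sample_loads_matching_signature(self, small_corpus):
        sigs, _, counts = small_corpus
        fit = restart_protocol([counts], ModelConfig(model="ctm", k=(3,),
                                                     seed=1, n_restarts=5))
        mr = match_signatures(fit.signatures[0], sigs)
        # a new sample built purely from reference signature j's categories
        for j_ref in range(3):
            n = np.round(2000 * sigs.phi[j_ref]).astype(int)
            cm = CountMatrix(["pure"], counts.category_space, n[None, :])
            theta = infer_theta(fit, [cm])[0].theta[0]
            j_est = {r: e for e, r in mr.mapping.items()}[j_ref]
            assert theta.argmax() == j_est

    def test_determinism_and_category_mismatch(self, small_corpus, sv_space):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=2,
                                              max_iters=40))
        t1 = infer_theta(fit, [counts])[0].theta
        t2 = infer_theta(fit, [counts])[0].theta
        np.testing.assert_array_equal(t1, t2)
        bad = CountMatrix(["x"], sv_space, np.ones((1, len(sv_space)), int))
        with pytest.raises(ValueError):
            infer_theta(fit, [bad])

    def test_zero_count_sample_gets_prior_mean_theta(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(3,), seed=3,
                                              max_iters=40))
        cm = CountMatrix(["z"], counts.category_space,
                         np.zeros((1, 96), dtype=int))
        theta = infer_theta(fit, [cm])[0].theta[0]
        mu = fit.prior.mu
        expected = np.exp(mu - mu.max())
        expected /= expected.sum()
        np.testing.assert_allclose(theta, expected, atol=1e-8)


class TestRestartProtocol:
    def test_single_restart_equals_plain_fit(self, small_corpus):
        _, _, counts = small_corpus
        cfg = ModelConfig(model="ctm", k=(2,), seed=6, n_restarts=1)
        f1 = restart_protocol([counts], cfg)
        assert f1.metadata["selected_restart"] == 0
        assert_elbo_monotone(f1.elbo_trace)

    def test_selected_restart_has_best_mean_rank(self, correlated_corpus):
        _, _, counts = correlated_corpus
        cfg = ModelConfig(model="mmctm", k=(3, 3), seed=7, n_restarts=6,
                          max_restart_iters=20)
        fit = restart_protocol(counts, cfg)
        ranks = np.asarray(fit.metadata["restart_mean_ranks"])
        assert ranks[fit.metadata["selected_restart"]] == ranks.min()


class TestSignatureCorrelations:
    def test_affine_copies_give_unit_correlation(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=1,
                                              max_iters=30))
        # theta columns of a 2-signature model are exact affine copies
        corr = signature_correlations(fit)
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_constant_column_flagged_as_zero(self, small_corpus):
        _, _, counts = small_corpus
        fit = fit_model([counts], ModelConfig(model="ctm", k=(2,), seed=1,
                                              max_iters=10))
        theta = fit.sample_probs[0].theta
        theta[:, 0] = 0.5
        theta[:, 1] = 0.5
        corr = signature_correlations(fit)
        assert corr[0, 1] == 0.0
        np.testing.assert_array_equal(np.diag(corr), 1.0)
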