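"""Mean-field variational inference engines.

Two engines live here.  :class:`VariationalLDA` is plain variational Bayes
for latent Dirichlet allocation: the sample-signature distribution theta_d
gets a Dirichlet prior.  :class:`VariationalCTM` implements the correlated
models: a shared latent Gaussian eta_d in R^{Ktot} (Ktot = sum of the
per-modality signature counts) is passed through a per-modality-block
softmax to produce each modality's theta_d, so signature probabilities can
covary within and across modalities.  With a single modality this is
exactly the correlated topic model; with several it is the multi-modal
variant.

The variational family is fully factorized: a diagonal Gaussian
q(eta_d) = N(lambda_d, diag(nu_d^2)), one categorical responsibility vector
per (sample, category) aggregated by count, and a Dirichlet for each
signature.  The intractable E[log sum_k exp eta_k] term is handled with the
standard first-order auxiliary-variable upper bound, one auxiliary
normalizer zeta per sample per modality block; every update is a coordinate
ascent step on the resulting evidence lower bound, so the objective is
non-decreasing across iterations.

Independent-feature variants reuse the same machinery: a modality whose
category space carries a feature decomposition is split into per-feature
count blocks that share the modality's theta block, and each signature
factorizes into per-feature categorical distributions.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

_RIDGE = 1e-6  # diagonal ridge on the M-step covariance estimate
_INIT_GAMMA_HIGH = 101  # random positive integer init for signature Dirichlets


def _feature_blocks(counts) -> list[np.ndarray]:
    """Split a modality count matrix into per-feature blocks (len 1 if full)."""
    X = np.asarray(counts.counts, dtype=float)
    space = counts.category_space
    if space.encoding == "independent":
        edges = np.cumsum((0,) + tuple(space.feature_arity))
        return [X[:, lo:hi] for lo, hi in zip(edges[:-1], edges[1:])]
    return [X]


def _dirichlet_elogp(gamma: np.ndarray, beta: float) -> float:
    """E[log p(phi | beta)] + H(q(phi)) summed over signature rows."""
    V = gamma.shape[1]
    g0 = gamma.sum(axis=1)
    elog = digamma(gamma) - digamma(g0)[:, None]
    elogp = (gammaln(V * beta) - V * gammaln(beta) + (beta - 1.0) * elog.sum(axis=1))
    entropy = (gammaln(gamma).sum(axis=1) - gammaln(g0)
               + (g0 - V) * digamma(g0)
               - ((gamma - 1.0) * digamma(gamma)).sum(axis=1))
    return float(elogp.sum() + entropy.sum())


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    return mat / mat.sum(axis=1, keepdims=True)


class _ModalityData:
    """Per-modality preprocessed counts and variational signature state."""

    def __init__(self, counts, K: int, rng: np.random.Generator):
        self.counts = counts
        self.K = K
        self.X = _feature_blocks(counts)  # list of (D, V_f)
        self.totals = sum(x.sum(axis=1) for x in self.X)  # tokens per sample
        # random positive integer initialization of the signature Dirichlets
        self.gamma = [rng.integers(1, _INIT_GAMMA_HIGH, size=(K, x.shape[1]))
                      .astype(float) for x in self.X]
        self.resp: list[np.ndarray] = []  # (D, K, V_f) responsibilities
        self.S = np.zeros((counts.n_samples, K))  # expected tokens per signature

    def elog_phi(self) -> list[np.ndarray]:
        return [digamma(g) - digamma(g.sum(axis=1))[:, None] for g in self.gamma]

    def phi_hat(self) -> np.ndarray:
        """Posterior-mean signatures, feature blocks concatenated."""
        return np.concatenate([_normalize_rows(g) for g in self.gamma], axis=1)

    def update_resp(self, log_theta_like: np.ndarray) -> None:
        """Responsibilities r_dvk given per-sample signature scores.

        ``log_theta_like`` is (D, K): lambda for the correlated models,
        E[log theta] for LDA.  Also refreshes S and the per-feature
        expected category-signature counts C.
        """
        self.S.fill(0.0)
        self.resp = []
        self.C = []
        for x, elog in zip(self.X, self.elog_phi()):
            logits = log_theta_like[:, :, None] + elog[None, :, :]
            logits -= logsumexp(logits, axis=1, keepdims=True)
            r = np.exp(logits)
            self.resp.append(r)
            self.S += np.einsum("dv,dkv->dk", x, r)
            self.C.append(np.einsum("dv,dkv->kv", x, r))

    def update_gamma(self, beta: float) -> None:
        self.gamma = [beta + c for c in self.C]

    def likelihood_terms(self, beta: float) -> float:
        """ELBO terms E[log p(x|z,phi)] - E[log q(z)] + Dirichlet terms."""
        total = 0.0
        for x, r, c, g in zip(self.X, self.resp, self.C, self.gamma):
            elog = digamma(g) - digamma(g.sum(axis=1))[:, None]
            total += float(np.sum(c * elog))
            with np.errstate(divide="ignore", invalid="ignore"):
                rlogr = np.where(r > 0, r * np.log(r), 0.0)
            total -= float(np.einsum("dv,dkv->", x, rlogr))
            total += _dirichlet_elogp(g, beta)
        return total

    def predictive_ll(self, theta: np.ndarray) -> float:
        """Average per-token log-likelihood under point estimates."""
        total, tokens = 0.0, 0.0
        for x, g in zip(self.X, self.gamma):
            phi = _normalize_rows(g)
            mix = theta @ phi
            mask = x > 0
            total += float(np.sum(x[mask] * np.log(mix[mask])))
            tokens += float(x.sum())
        return total / tokens if tokens > 0 else 0.0


class VariationalLDA:
    """Variational Bayes for (independent-feature) latent Dirichlet allocation."""

    def __init__(self, counts, K: int, alpha: float, beta: float,
                 rng: np.random.Generator):
        if counts.counts.sum() == 0:
            raise ValueError("cannot fit to an all-zero count matrix")
        self.alpha = alpha
        self.beta = beta
        self.mod = _ModalityData(counts, K, rng)
        D = counts.n_samples
        self.a = np.full((D, K), alpha + self.mod.totals[:, None] / K)
        self.elbo_trace: list[float] = []
        self.pred_ll_trace: list[float] = []

    def _elog_theta(self) -> np.ndarray:
        return digamma(self.a) - digamma(self.a.sum(axis=1))[:, None]

    def step(self) -> None:
        self.mod.update_resp(self._elog_theta())
        self.a = self.alpha + self.mod.S
        self.mod.update_gamma(self.beta)
        self.elbo_trace.append(self._elbo())
        self.pred_ll_trace.append(self.mod.predictive_ll(self.theta()))

    def _elbo(self) -> float:
        K = self.mod.K
        elog_t = self._elog_theta()
        a0 = self.a.sum(axis=1)
        # Dirichlet prior + entropy over theta, plus E[log p(z|theta)]
        prior = (gammaln(K * self.alpha) - K * gammaln(self.alpha)
                 + (self.alpha - 1.0) * elog_t.sum(axis=1))
        entropy = (gammaln(self.a).sum(axis=1) - gammaln(a0)
                   + (a0 - K) * digamma(a0)
                   - ((self.a - 1.0) * digamma(self.a)).sum(axis=1))
        total = float(prior.sum() + entropy.sum())
        total += float(np.sum(self.mod.S * elog_t))
        total += self.mod.likelihood_terms(self.beta)
        return total

    def theta(self) -> np.ndarray:
        return self.a / self.a.sum(axis=1, keepdims=True)

    def run(self, tol: float, max_iters: int) -> None:
        prev = None
        for _ in range(max_iters):
            self.step()
            cur = self.pred_ll_trace[-1]
            if prev is not None and abs(cur - prev) <= tol * abs(prev):
                break
            prev = cur

    def infer_theta(self, counts, tol: float = 1e-6, max_iters: int = 500
                    ) -> np.ndarray:
        """Posterior-mean theta for new samples with signatures frozen."""
        new = _ModalityData(counts, self.mod.K, np.random.default_rng(0))
        new.gamma = [g.copy() for g in self.mod.gamma]
        D = counts.n_samples
        a = np.full((D, self.mod.K),
                    self.alpha + new.totals[:, None] / self.mod.K)
        for _ in range(max_iters):
            elog_t = digamma(a) - digamma(a.sum(axis=1))[:, None]
            new.update_resp(elog_t)
            a_new = self.alpha + new.S
            if np.max(np.abs(a_new - a)) <= tol * (1.0 + np.max(np.abs(a))):
                a = a_new
                break
            a = a_new
        return a / a.sum(axis=1, keepdims=True)


class VariationalCTM:
    """Mean-field variational EM for the (multi-modal) correlated topic model."""

    def __init__(self, counts_list, Ks, beta: float, rng: np.random.Generator,
                 fix_covariance_identity: bool = False):
        if len(counts_list) != len(Ks):
            raise ValueError("one signature count K is required per modality")
        ids0 = counts_list[0].sample_ids
        for cm in counts_list[1:]:
            if cm.sample_ids != ids0:
                raise ValueError("count matrices must share sample_ids in the same order")
        if all(cm.counts.sum() == 0 for cm in counts_list):
            raise ValueError("cannot fit to all-zero count matrices")
        self.beta = beta
        self.fix_cov = fix_covariance_identity
        self.mods = [_ModalityData(cm, k, rng) for cm, k in zip(counts_list, Ks)]
        self.D = counts_list[0].n_samples
        edges = np.cumsum([0] + [m.K for m in self.mods])
        self.blocks = [slice(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
        self.Ktot = int(edges[-1])
        self.lam = np.zeros((self.D, self.Ktot))
        self.nu2 = np.ones((self.D, self.Ktot))
        self.mu = np.zeros(self.Ktot)
        self.sigma = np.eye(self.Ktot)
        self.elbo_trace: list[float] = []
        self.pred_ll_trace: list[float] = []

    # -- helpers -----------------------------------------------------------

    def theta(self) -> list[np.ndarray]:
        """Blockwise softmax of the variational posterior means."""
        out = []
        for sl in self.blocks:
            block = self.lam[:, sl]
            e = np.exp(block - block.max(axis=1, keepdims=True))
            out.append(e / e.sum(axis=1, keepdims=True))
        return out

    def _zeta(self) -> np.ndarray:
        """Optimal auxiliary normalizers, one per (sample, modality)."""
        ex = np.exp(self.lam + 0.5 * self.nu2)
        return np.stack([ex[:, sl].sum(axis=1) for sl in self.blocks], axis=1)

    def _totals(self) -> np.ndarray:
        return np.stack([m.totals for m in self.mods], axis=1)  # (D, M)

    # -- coordinate updates ------------------------------------------------

    def _update_responsibilities(self) -> None:
        for m, sl in zip(self.mods, self.blocks):
            m.update_resp(self.lam[:, sl])

    def _update_eta(self, sigma_inv: np.ndarray, zeta: np.ndarray,
                    N: np.ndarray, maxiter: int = 40) -> None:
        """Jointly maximize the bound over (lambda, log nu^2) for all samples.

        The per-sample problems are independent, so a single quasi-Newton
        solve over the stacked variables is used; with zeta fixed the bound
        is concave in (lambda, nu^2).
        """
        D, K = self.D, self.Ktot
        S = np.concatenate([m.S for m in self.mods], axis=1)  # (D, Ktot)
        # per-sample, per-coordinate weight N_dm / zeta_dm expanded to eta space
        w = np.zeros((D, K))
        for j, sl in enumerate(self.blocks):
            with np.errstate(divide="ignore", invalid="ignore"):
                w[:, sl] = np.where(zeta[:, j:j + 1] > 0,
                                    N[:, j:j + 1] / zeta[:, j:j + 1], 0.0)
        diag_sinv = np.diag(sigma_inv)

        def objective(x):
            lam = x[:D * K].reshape(D, K)
            rho = x[D * K:].reshape(D, K)
            nu2 = np.exp(rho)
            diff = lam - self.mu
            quad = 0.5 * np.einsum("dk,kj,dj->", diff, sigma_inv, diff)
            trace = 0.5 * float(np.sum(nu2 * diag_sinv))
            ex = np.exp(lam + 0.5 * nu2)
            bound = float(np.sum(w * ex))
            f = quad + trace - float(np.sum(S * lam)) + bound - 0.5 * float(np.sum(rho))
            g_lam = diff @ sigma_inv - S + w * ex
            g_nu2 = 0.5 * diag_sinv[None, :] + 0.5 * w * ex - 0.5 / nu2
            g_rho = g_nu2 * nu2
            return f, np.concatenate([g_lam.ravel(), g_rho.ravel()])

        x0 = np.concatenate([self.lam.ravel(), np.log(self.nu2).ravel()])
        f0, _ = objective(x0)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        if res.fun <= f0:  # keep the ascent guarantee
            self.lam = res.x[:D * K].reshape(D, K)
            self.nu2 = np.exp(res.x[D * K:].reshape(D, K))

    def _update_prior(self) -> None:
        self.mu = self.lam.mean(axis=0)
        if self.fix_cov:
            self.sigma = np.eye(self.Ktot)
        else:
            diff = self.lam - self.mu
            self.sigma = (diff.T @ diff + np.diag(self.nu2.sum(axis=0))) / self.D
            self.sigma[np.diag_indices_from(self.sigma)] += _RIDGE

    # -- objective ---------------------------------------------------------

    def _elbo(self, zeta: np.ndarray, N: np.ndarray) -> float:
        D, K = self.D, self.Ktot
        chol = cho_factor(self.sigma)
        sigma_inv = cho_solve(chol, np.eye(K))
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        diff = self.lam - self.mu
        gauss = (-0.5 * D * (logdet + K * np.log(2.0 * np.pi))
                 - 0.5 * np.einsum("dk,kj,dj->", diff, sigma_inv, diff)
                 - 0.5 * float(np.sum(self.nu2 * np.diag(sigma_inv))))
        ex = np.exp(self.lam + 0.5 * self.nu2)
        zterm = 0.0
        for j, (m, sl) in enumerate(zip(self.mods, self.blocks)):
            zterm += float(np.sum(m.S * self.lam[:, sl]))
            with np.errstate(divide="ignore", invalid="ignore"):
                per = np.where(
                    N[:, j] > 0,
                    N[:, j] * (np.log(np.where(zeta[:, j] > 0, zeta[:, j], 1.0))
                               + ex[:, sl].sum(axis=1)
                               / np.where(zeta[:, j] > 0, zeta[:, j], 1.0) - 1.0),
                    0.0)
            zterm -= float(per.sum())
        ent_eta = 0.5 * float(np.sum(np.log(2.0 * np.pi * self.nu2) + 1.0))
        like = sum(m.likelihood_terms(self.beta) for m in self.mods)
        return gauss + zterm + ent_eta + like

    def predictive_ll(self) -> list[float]:
        return [m.predictive_ll(t) for m, t in zip(self.mods, self.theta())]

    def _combined_pred_ll(self) -> float:
        tokens = np.array([m.totals.sum() for m in self.mods])
        lls = np.array(self.predictive_ll())
        return float(np.sum(lls * tokens) / tokens.sum())

    # -- main loop ---------------------------------------------------------

    def step(self) -> None:
        N = self._totals()
        self._update_responsibilities()
        for m in self.mods:
            m.update_gamma(self.beta)
        zeta = self._zeta()
        chol = cho_factor(self.sigma)
        sigma_inv = cho_solve(chol, np.eye(self.Ktot))
        self._update_eta(sigma_inv, zeta, N)
        zeta = self._zeta()
        self._update_prior()
        self.elbo_trace.append(self._elbo(zeta, N))
        self.pred_ll_trace.append(self._combined_pred_ll())

    def run(self, tol: float, max_iters: int) -> None:
        prev = self.pred_ll_trace[-1] if self.pred_ll_trace else None
        for _ in range(max_iters):
            self.step()
            cur = self.pred_ll_trace[-1]
            if prev is not None and abs(cur - prev) <= tol * abs(prev):
                break
            prev = cur

    # -- held-out inference ------------------------------------------------

    def infer_eta(self, counts_list, tol: float = 1e-6, max_iters: int = 200
                  ) -> np.ndarray:
        """Variational means for new samples with signatures and prior frozen.

        Only the per-sample updates run; signatures enter through their
        posterior means.  Zero-count samples keep the prior mean.
        """
        mods = []
        for cm, src in zip(counts_list, self.mods):
            m = _ModalityData(cm, src.K, np.random.default_rng(0))
            m.gamma = [g.copy() for g in src.gamma]
            mods.append(m)
        D = counts_list[0].n_samples
        lam = np.tile(self.mu, (D, 1))
        nu2 = np.ones((D, self.Ktot))
        chol = cho_factor(self.sigma)
        sigma_inv = cho_solve(chol, np.eye(self.Ktot))
        N = np.stack([m.totals for m in mods], axis=1)
        saved = self.mods, self.lam, self.nu2, self.D
        try:
            self.mods, self.lam, self.nu2, self.D = mods, lam, nu2, D
            prev = None
            for _ in range(max_iters):
                self._update_responsibilities()
                zeta = self._zeta()
                self._update_eta(sigma_inv, zeta, N)
                cur = float(np.sum(self.lam))
                if prev is not None and abs(cur - prev) <= tol * (1.0 + abs(prev)):
                    break
                prev = cur
            return self.lam.copy()
        finally:
            self.mods, self.lam, self.nu2, self.D = saved
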