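"""Public fitting interface over the variational engines.

``fit_model`` dispatches on :class:`ModelConfig.model`; thin wrappers
(:func:`fit_lda`, :func:`fit_mmctm`, :func:`fit_independent`) cover the
common cases.  The restart protocol runs many short fits from random
initializations, ranks them per modality by training predictive
log-likelihood, and polishes the restart with the best mean rank to full
convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ..containers import CountMatrix, SampleSignatureProbs, SignatureSet
from .config import ModelConfig
from .engine import VariationalCTM, VariationalLDA

__all__ = [
    "MmctmFit",
    "fit_model",
    "fit_lda",
    "fit_mmctm",
    "fit_independent",
    "infer_theta",
    "restart_protocol",
    "signature_correlations",
]


@dataclass
class GaussianPrior:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be square and match mu")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")


@dataclass
class MmctmFit:
    """A fitted topic model: signatures, sample probabilities, prior, trace."""

    config: ModelConfig
    prior: GaussianPrior | None
    signatures: list[SignatureSet]
    sample_probs: list[SampleSignatureProbs]
    elbo_trace: np.ndarray
    training_predictive_ll: list[float]
    metadata: dict = field(default_factory=dict)
    _engine: object | None = field(default=None, repr=False, compare=False)

    @property
    def modalities(self) -> list[str]:
        return [s.category_space.modality for s in self.signatures]

    def theta_concat(self) -> np.ndarray:
        """Sample-signature probabilities concatenated across modalities."""
        return np.concatenate([p.theta for p in self.sample_probs], axis=1)

    def signature_names(self) -> list[str]:
        return [n for s in self.signatures for n in s.names]


def _restart_rng(seed: int, restart: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(restart,)))


def _validate_counts(counts_list: list[CountMatrix], config: ModelConfig) -> None:
    if len(counts_list) != len(config.k):
        raise ValueError(
            f"{len(counts_list)} count matrices but {len(config.k)} signature counts"
        )
    single = config.model in ("lda", "ctm", "ilda", "ictm")
    if single and len(counts_list) != 1:
        raise ValueError(f"model {config.model!r} takes exactly one modality")
    if config.independent:
        for cm in counts_list:
            if cm.category_space.encoding != "independent":
                raise ValueError(
                    "independent-feature models need independent-encoded count matrices"
                )


def _wrap_fit(engine, counts_list, config, metadata) -> MmctmFit:
    signatures, sample_probs = [], []
    if isinstance(engine, VariationalLDA):
        mods, thetas = [engine.mod], [engine.theta()]
        prior = None
        elbo = np.asarray(engine.elbo_trace)
        pred = [engine.pred_ll_trace[-1]]
    else:
        mods, thetas = engine.mods, engine.theta()
        prior = GaussianPrior(engine.mu.copy(), engine.sigma.copy())
        elbo = np.asarray(engine.elbo_trace)
        pred = engine.predictive_ll()
    for cm, mod, theta in zip(counts_list, mods, thetas):
        signatures.append(SignatureSet(cm.category_space, mod.phi_hat()))
        sample_probs.append(SampleSignatureProbs(
            cm.category_space.modality, list(cm.sample_ids), theta,
            signature_names=signatures[-1].names))
    meta = {"bound": "first-order auxiliary normalizer",
            "model": config.model, **metadata}
    zero = [s for cm in counts_list for s in cm.zero_samples()]
    if zero:
        meta["zero_count_samples"] = sorted(set(zero))
    return MmctmFit(config, prior, signatures, sample_probs, elbo,
                    [float(p) for p in pred], meta, _engine=engine)


def fit_model(counts_list: list[CountMatrix], config: ModelConfig,
              rng: np.random.Generator | None = None,
              tol: float | None = None, max_iters: int | None = None) -> MmctmFit:
    """Fit the configured model once from a random initialization."""
    _validate_counts(counts_list, config)
    rng = rng if rng is not None else _restart_rng(config.seed, 0)
    tol = config.tol_final if tol is None else tol
    max_iters = config.max_iters if max_iters is None else max_iters
    if config.model in ("lda", "ilda"):
        engine = VariationalLDA(counts_list[0], config.k[0], config.alpha,
                                config.beta, rng)
    else:
        engine = VariationalCTM(counts_list, config.k, config.beta, rng,
                                config.fix_covariance_identity)
    engine.run(tol=tol, max_iters=max_iters)
    return _wrap_fit(engine, counts_list, config,
                     {"tol": tol, "max_iters": max_iters, "seed": config.seed})


def fit_lda(counts: CountMatrix, K: int, alpha: float = 0.1, beta: float = 1.0,
            seed: int = 0, **kwargs) -> MmctmFit:
    model = "ilda" if counts.category_space.encoding == "independent" else "lda"
    config = ModelConfig(model=model, k=(K,), alpha=alpha, beta=beta,
                         seed=seed, **kwargs)
    return fit_model([counts], config)


def fit_mmctm(counts_list: list[CountMatrix], config: ModelConfig) -> MmctmFit:
    if not config.correlated:
        raise ValueError("fit_mmctm requires a correlated model variant")
    return fit_model(counts_list, config)


def fit_independent(counts_list: list[CountMatrix], config: ModelConfig) -> MmctmFit:
    if not config.independent:
        raise ValueError("fit_independent requires ilda/ictm/immctm")
    return fit_model(counts_list, config)


def infer_theta(fit: MmctmFit, new_counts: list[CountMatrix]
                ) -> list[SampleSignatureProbs]:
    """Estimate sample-signature probabilities for new samples.

    Signatures and (for correlated models) the Gaussian prior are held
    fixed; only the per-sample variational updates run.  Zero-count samples
    receive the prior-mean-induced theta and are flagged in the result.
    """
    if fit._engine is None:
        raise ValueError("fit does not carry a live engine (deserialized fit?)")
    for cm, sig in zip(new_counts, fit.signatures):
        if cm.category_space.labels != sig.category_space.labels:
            raise ValueError("category space of new counts does not match fit")
    engine = fit._engine
    if isinstance(engine, VariationalLDA):
        thetas = [engine.infer_theta(new_counts[0])]
    else:
        lam = engine.infer_eta(new_counts)
        thetas = []
        for sl in engine.blocks:
            block = lam[:, sl]
            e = np.exp(block - block.max(axis=1, keepdims=True))
            thetas.append(e / e.sum(axis=1, keepdims=True))
    out = []
    for cm, sig, theta in zip(new_counts, fit.signatures, thetas):
        probs = SampleSignatureProbs(cm.category_space.modality,
                                     list(cm.sample_ids), theta,
                                     signature_names=sig.names)
        out.append(probs)
    return out


def restart_protocol(counts_list: list[CountMatrix], config: ModelConfig
                     ) -> MmctmFit:
    """Multi-restart fitting with mean-rank selection.

    Runs ``config.n_restarts`` short fits (tolerance ``tol_restart``, at
    most ``max_restart_iters`` iterations each), ranks the restarts within
    each modality by training predictive log-likelihood (rank 1 = best),
    and continues the restart with the lowest mean rank across modalities
    to convergence at ``tol_final``.
    """
    _validate_counts(counts_list, config)
    fits: list[MmctmFit] = []
    for r in range(config.n_restarts):
        fit = fit_model(counts_list, config, rng=_restart_rng(config.seed, r),
                        tol=config.tol_restart, max_iters=config.max_restart_iters)
        fits.append(fit)
    lls = np.array([f.training_predictive_ll for f in fits])  # (R, M)
    ranks = np.column_stack([rankdata(-lls[:, m], method="average")
                             for m in range(lls.shape[1])])
    mean_ranks = ranks.mean(axis=1)
    best = int(np.argmin(mean_ranks))  # ties: lowest restart index
    winner = fits[best]
    engine = winner._engine
    engine.run(tol=config.tol_final, max_iters=config.max_iters)
    final = _wrap_fit(engine, counts_list, config,
                      {"tol": config.tol_final, "seed": config.seed,
                       "n_restarts": config.n_restarts,
                       "selected_restart": best,
                       "restart_mean_ranks": mean_ranks.tolist(),
                       "restart_predictive_ll": lls.tolist()})
    return final


def signature_correlations(fit: MmctmFit) -> np.ndarray:
    """Pearson correlations of per-sample signature probabilities.

    Computed across samples over the concatenated modality blocks, so
    cross-modality signature correlations appear off the block diagonal.
    Constant columns yield zero correlation entries (flagged in metadata).
    """
    theta = fit.theta_concat()
    if theta.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = theta.std(axis=0)
    constant = sd < 1e-12
    corr = np.eye(theta.shape[1])
    ok = ~constant
    if ok.sum() >= 2:
        sub = np.corrcoef(theta[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    if constant.any():
        fit.metadata.setdefault("constant_signature_columns",
                                np.where(constant)[0].tolist())
        for i in np.where(constant)[0]:
            corr[i, :] = corr[:, i] = 0.0
            corr[i, i] = 1.0
    return corr
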