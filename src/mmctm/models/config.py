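"""Model configuration for the topic-model family."""

from __future__ import annotations

from dataclasses import dataclass, field

MODEL_NAMES = ("lda", "ctm", "mmctm", "ilda", "ictm", "immctm")


@dataclass
class ModelConfig:
    """Configuration shared by all topic-model variants.

    Parameters
    ----------
    model:
        One of ``lda``, ``ctm``, ``mmctm`` or their independent-feature
        variants ``ilda``, ``ictm``, ``immctm``.
    k:
        Signature count per modality (one entry per count matrix).
    alpha:
        Symmetric Dirichlet hyperparameter on the sample-signature
        distribution; used by the LDA variants.  Exposed but inert for the
        Gaussian-prior (correlated) models.
    beta:
        Symmetric Dirichlet hyperparameter on the signatures.
    fix_covariance_identity:
        Hold the Gaussian prior covariance at the identity during fitting
        instead of re-estimating it in the M-step.
    tol_restart, tol_final:
        Relative tolerance on the training per-mutation predictive
        log-likelihood used to stop the short restart fits and the final
        fit, respectively.
    max_restart_iters, max_iters:
        Iteration caps for the short restart fits and the final fit.
    n_restarts:
        Number of random restarts in the restart protocol.
    seed:
        Base seed; restart r uses the spawned stream (seed, r).
    """

    model: str = "mmctm"
    k: tuple[int, ...] = (2,)
    alpha: float = 0.1
    beta: float = 1.0
    fix_covariance_identity: bool = False
    tol_restart: float = 1e-4
    tol_final: float = 1e-5
    max_restart_iters: int = 100
    max_iters: int = 2000
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.model = self.model.lower()
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        self.k = tuple(int(x) for x in (self.k if hasattr(self.k, "__iter__") else (self.k,)))
        if any(x < 1 for x in self.k):
            raise ValueError("all signature counts must be >= 1")
        if self.tol_restart <= 0 or self.tol_final <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    @property
    def correlated(self) -> bool:
        return self.model in ("ctm", "mmctm", "ictm", "immctm")

    @property
    def independent(self) -> bool:
        return self.model in ("ilda", "ictm", "immctm")
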