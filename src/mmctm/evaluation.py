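"""Benchmarking machinery for signature-inference methods.

The central metric is the average per-mutation predictive log-likelihood:
test samples are split into observed and hidden mutation sets, sample
signature probabilities theta are estimated from the observed half with
signatures phi frozen, and the hidden half is scored as

    l = sum_d sum_n log( sum_k p(x_nd | phi_k) p(z_nd = k | theta_d) )
        / sum_d N_d ,

i.e. the mean log mixture probability per hidden mutation.  This module
also provides stratified repeated cross-validation plans, per-category
count downsampling, a balanced logistic-regression classifier benchmark,
and signature-number selection by the likelihood-vs-K curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import CountMatrix, SampleSignatureProbs, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "HeldOutSplit",
    "make_cv_plan",
    "split_observed_hidden",
    "predictive_loglik",
    "downsample_counts",
    "classifier_benchmark",
    "select_signature_number",
]

ZERO_FLOOR = 1e-16  # added to mixture probabilities for methods that can emit exact zeros


@dataclass
class CvPlan:
    """Stratified repeated cross-validation assignments."""

    folds: list[list[tuple[list[str], list[str]]]]  # [repeat][fold] -> (train, test)
    n_repeats: int
    n_folds: int
    strata: dict[str, str]
    seed: int

    def iter_splits(self):
        for r, repeat in enumerate(self.folds):
            for f, (train, test) in enumerate(repeat):
                yield r, f, train, test


@dataclass
class HeldOutSplit:
    observed: CountMatrix
    hidden: CountMatrix
    fraction: float
    seed: int
    zero_samples: list[str] = field(default_factory=list)


def make_cv_plan(sample_ids: list[str], strata: list[str], n_folds: int,
                 n_repeats: int, seed: int) -> CvPlan:
    """Build an ``n_repeats x n_folds`` stratified cross-validation plan.

    Within each repeat the test folds partition the samples, preserving
    stratum proportions up to rounding.  Strata smaller than ``n_folds``
    are spread round-robin (scikit-learn's stratified splitter does this
    implicitly) with a warning.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(strata) != len(sample_ids):
        raise ValueError("one stratum label per sample is required")
    ids = np.asarray(sample_ids)
    y = np.asarray(strata)
    counts = pd.Series(y).value_counts()
    small = counts[counts < n_folds]
    if len(small):
        logger.warning("strata smaller than n_folds distributed round-robin: %s",
                       dict(small))
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in ss.generate_state(n_repeats) % (2 ** 31)]
    folds = []
    for rs in repeat_seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        repeat = []
        for train_idx, test_idx in skf.split(ids, y):
            repeat.append((list(ids[train_idx]), list(ids[test_idx])))
        folds.append(repeat)
    return CvPlan(folds, n_repeats, n_folds,
                  dict(zip(sample_ids, strata)), seed)


def split_observed_hidden(counts: CountMatrix, fraction: float = 0.5,
                          seed: int = 0) -> HeldOutSplit:
    """Split each sample's mutations into observed/hidden sets.

    Each mutation token is assigned to the observed set independently with
    probability ``fraction`` (binomial thinning per category), so the two
    halves sum elementwise to the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    observed = rng.binomial(counts.counts.astype(np.int64), fraction)
    hidden = counts.counts - observed
    zero = counts.zero_samples()
    if zero:
        logger.warning("samples with zero mutations in split: %s", zero)
    obs_cm = CountMatrix(list(counts.sample_ids), counts.category_space, observed)
    hid_cm = CountMatrix(list(counts.sample_ids), counts.category_space, hidden)
    return HeldOutSplit(obs_cm, hid_cm, fraction, seed, zero)


def predictive_loglik(signatures: SignatureSet, theta: SampleSignatureProbs,
                      hidden: CountMatrix, floor: bool = False) -> float:
    """Average per-mutation predictive log-likelihood of hidden counts.

    With ``floor=True`` a 1e-16 constant is added to the mixture
    probability before the log, for comparator methods whose normalized
    outputs can be exactly zero.
    """
    phi = signatures.phi
    th = theta.theta
    X = hidden.counts
    if X.shape != (th.shape[0], phi.shape[1]):
        raise ValueError("shapes of signatures, theta and hidden counts disagree")
    total_tokens = X.sum()
    if total_tokens == 0:
        raise ValueError("hidden counts are all zero; likelihood undefined")
    mix = th @ phi
    if floor:
        mix = mix + ZERO_FLOOR
    mask = X > 0
    return float(np.sum(X[mask] * np.log(mix[mask])) / total_tokens)


def downsample_counts(counts: CountMatrix, fraction: float, seed: int = 0,
                      exact: bool = False) -> CountMatrix:
    """Retain a random ``fraction`` of mutations per sample.

    Default is per-category binomial thinning, which selects mutations
    according to their category proportions in expectation.  With
    ``exact=True`` a fixed number ``round(fraction * N_d)`` of tokens is
    drawn per sample without replacement (multivariate hypergeometric).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    X = counts.counts.astype(np.int64)
    if fraction == 1.0:
        kept = X.copy()
    elif fraction == 0.0:
        kept = np.zeros_like(X)
    elif exact:
        kept = np.zeros_like(X)
        for d in range(X.shape[0]):
            n_keep = int(round(fraction * X[d].sum()))
            if n_keep > 0:
                kept[d] = rng.multivariate_hypergeometric(X[d], n_keep)
    else:
        kept = rng.binomial(X, fraction)
    return CountMatrix(list(counts.sample_ids), counts.category_space, kept)


def classifier_benchmark(theta_features: np.ndarray, labels: np.ndarray,
                         n_folds: int = 5, seed: int = 0) -> list[float]:
    """Balanced logistic-regression accuracy over stratified CV folds.

    The majority class is subsampled to the minority class size, then an
    L2-regularized logistic regression (C = 1, up to 10,000 iterations) is
    scored by plain accuracy on each held-out stratified fold.
    """
    X = np.asarray(theta_features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or class_counts.min() < 2:
        raise ValueError("need two classes with >= 2 samples each")
    rng = np.random.default_rng(seed)
    n_min = class_counts.min()
    keep = np.concatenate([
        rng.choice(np.where(y == c)[0], size=n_min, replace=False)
        for c in classes
    ])
    keep.sort()
    Xb, yb = X[keep], y[keep]
    if np.bincount(yb).min() < n_folds:
        raise ValueError("a fold would lack both classes; reduce n_folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    scores = []
    for train_idx, test_idx in skf.split(Xb, yb):
        clf = LogisticRegression(C=1.0, max_iter=10_000)
        clf.fit(Xb[train_idx], yb[train_idx])
        scores.append(float(clf.score(Xb[test_idx], yb[test_idx])))
    return scores


def _half_split_curve(counts_list, K_range, config_factory, seed):
    from .models import fit_model, infer_theta

    rows = []
    splits = [split_observed_hidden(cm, 0.5, seed + 17 * i)
              for i, cm in enumerate(counts_list)]
    for K in K_range:
        config = config_factory(K)
        fit = fit_model([s.observed for s in splits], config)
        thetas = infer_theta(fit, [s.observed for s in splits])
        lls = []
        for sig, th, s in zip(fit.signatures, thetas, splits):
            lls.append(predictive_loglik(sig, th, s.hidden))
        rows.append({"K": K, "mean_ll": float(np.mean(lls)), "se": 0.0})
    return rows


def _cv_curve(counts_list, K_range, config_factory, strata, n_folds,
              n_repeats, seed):
    from .models import fit_model, infer_theta

    sample_ids = counts_list[0].sample_ids
    strata = strata if strata is not None else ["all"] * len(sample_ids)
    plan = make_cv_plan(sample_ids, strata, n_folds, n_repeats, seed)
    idx = {s: i for i, s in enumerate(sample_ids)}
    rows = []
    for K in K_range:
        lls = []
        for r, f, train, test in plan.iter_splits():
            tr = [CountMatrix(train, cm.category_space,
                              cm.counts[[idx[s] for s in train]])
                  for cm in counts_list]
            te = [CountMatrix(test, cm.category_space,
                              cm.counts[[idx[s] for s in test]])
                  for cm in counts_list]
            config = config_factory(K)
            fit = fit_model(tr, config)
            splits = [split_observed_hidden(cm, 0.5, seed + 997 * r + f)
                      for cm in te]
            thetas = infer_theta(fit, [s.observed for s in splits])
            fold_lls = [predictive_loglik(sig, th, s.hidden)
                        for sig, th, s in zip(fit.signatures, thetas, splits)]
            lls.append(float(np.mean(fold_lls)))
        rows.append({"K": K, "mean_ll": float(np.mean(lls)),
                     "se": float(np.std(lls, ddof=1) / np.sqrt(len(lls)))
                     if len(lls) > 1 else 0.0})
    return rows


def select_signature_number(counts_list: list[CountMatrix], K_range,
                            mode: str = "half_split", seed: int = 0,
                            config_factory=None, strata=None,
                            n_folds: int = 5, n_repeats: int = 1
                            ) -> tuple[pd.DataFrame, int]:
    """Likelihood-vs-K curve with an advisory elbow suggestion.

    The suggestion is the smallest K whose successor improves the mean
    held-out log-likelihood by less than one standard error (for the
    half-split mode, by less than ``1e-3`` nats in absolute terms); it is a
    documented heuristic and never binding.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if config_factory is None:
        from .models import ModelConfig

        model = "mmctm" if len(counts_list) > 1 else "ctm"

        def config_factory(K, _model=model):  # noqa: F811
            return ModelConfig(model=_model, k=(K,) * len(counts_list),
                               seed=seed, max_iters=200)

    if mode == "half_split":
        rows = _half_split_curve(counts_list, K_range, config_factory, seed)
    elif mode == "cv_elbow":
        rows = _cv_curve(counts_list, K_range, config_factory, strata,
                         n_folds, n_repeats, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = pd.DataFrame(rows)
    suggested = K_range[-1]
    for i in range(len(K_range) - 1):
        gain = table.mean_ll[i + 1] - table.mean_ll[i]
        threshold = table.se[i + 1] if table.se[i + 1] > 0 else 1e-3
        if gain < threshold:
            suggested = K_range[i]
            break
    logger.info("signature-number curve suggests K=%d (advisory)", suggested)
    return table, int(suggested)
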