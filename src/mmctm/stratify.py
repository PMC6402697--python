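"""Signature-based patient stratification and cluster association tests.

Samples are clustered on standardized (z-scored) joint SNV+SV signature
probabilities with Ward-linkage agglomeration; standardization gives
low-prevalence signatures the same weight as dominant ones.  Cluster
associations are tested cluster-vs-rest: one-sided Welch t-tests for
signature enrichment, two-tailed Fisher exact or Welch tests (optionally on
midranks) for annotations, and a blocked permutation test that preserves
the composition of confounding strata (e.g. receptor status) when
resampling cluster membership:

    p = (1 + #{ |s'| >= |s| }) / (1 + N)

with s the difference in annotation proportion (or mean) between cluster
and rest, and s' the same statistic for each of N resampled clusters drawn
without replacement block by block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact, rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

from .containers import SampleSignatureProbs

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "standardize_probs",
    "cluster_samples",
    "cluster_signature_enrichment",
    "blocked_permutation_test",
    "annotation_association",
    "bh_adjust",
]


@dataclass
class ClusterResult:
    sample_ids: list[str]
    labels: np.ndarray
    linkage: np.ndarray
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids, "cluster": self.labels})

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def standardize_probs(thetas: list[SampleSignatureProbs] | np.ndarray
                      ) -> np.ndarray:
    """Z-score each signature's probabilities across samples (n-1 SD).

    Zero-variance columns map to all-zeros and are flagged with a warning.
    """
    if isinstance(thetas, np.ndarray):
        mat = thetas
    else:
        mat = np.concatenate([t.theta for t in thetas], axis=1)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    flat = sd < 1e-15
    if flat.any():
        logger.warning("zero-variance signature columns set to 0: %s",
                       np.where(flat)[0].tolist())
    z = np.zeros_like(mat, dtype=float)
    ok = ~flat
    z[:, ok] = (mat[:, ok] - mean[ok]) / sd[ok]
    return z


def cluster_samples(z: np.ndarray, sample_ids: list[str] | None = None,
                    min_cluster_size: int = 3, cut: str = "dynamic_hybrid_like",
                    k: int | None = None, height: float | None = None
                    ) -> ClusterResult:
    """Ward-linkage hierarchical clustering with a configurable cut.

    ``dynamic_hybrid_like`` scans the merge heights and cuts at the height
    yielding the most clusters whose sizes are all >= ``min_cluster_size``
    (ties broken toward the lower height); ``fixed_k`` and ``fixed_height``
    are the plain alternatives.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    ids = sample_ids or [f"S{i + 1}" for i in range(z.shape[0])]
    Z = linkage(z, method="ward", metric="euclidean")
    if cut == "fixed_k":
        if k is None:
            raise ValueError("fixed_k cut requires k")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif cut == "fixed_height":
        if height is None:
            raise ValueError("fixed_height cut requires height")
        labels = fcluster(Z, t=height, criterion="distance")
    elif cut == "dynamic_hybrid_like":
        if z.shape[0] < min_cluster_size:
            raise ValueError("fewer samples than min_cluster_size")
        heights = np.unique(Z[:, 2])
        candidates = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2,
                                     [heights[-1] + 1.0]])
        best_labels, best_n, best_h = None, 0, None
        for h in candidates[::-1]:  # scan from the top so ties keep lower heights
            lab = fcluster(Z, t=h, criterion="distance")
            sizes = np.bincount(lab)[1:]
            n_clusters = len(sizes)
            if sizes.min() >= min_cluster_size and n_clusters >= best_n:
                best_labels, best_n, best_h = lab, n_clusters, h
        if best_labels is None:  # no valid cut: everything in one cluster
            best_labels = np.ones(z.shape[0], dtype=int)
            best_h = float(heights[-1] + 1.0)
        labels = best_labels
        height = best_h
    else:
        raise ValueError(f"unknown cut {cut!r}")
    # relabel deterministically by order of first appearance
    order: dict[int, int] = {}
    relabeled = np.array([order.setdefault(l, len(order) + 1) for l in labels])
    return ClusterResult(ids, relabeled, Z,
                         {"metric": "euclidean", "linkage": "ward", "cut": cut,
                          "min_cluster_size": min_cluster_size, "k": k,
                          "height": height})


def cluster_signature_enrichment(theta: np.ndarray, labels: np.ndarray,
                                 signature_names: list[str] | None = None
                                 ) -> pd.DataFrame:
    """Per (cluster, signature) one-sided Welch enrichment tests.

    Tests whether in-cluster signature probabilities exceed those of all
    other samples (unequal-variance t-test, alternative "greater");
    p-values are BH-adjusted across all tests in the table.
    """
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(labels)
    names = signature_names or [f"sig{j + 1}" for j in range(theta.shape[1])]
    rows = []
    for cl in np.unique(labels):
        inside = labels == cl
        if inside.sum() < 2 or (~inside).sum() < 2:
            logger.warning("cluster %s too small for enrichment tests", cl)
            for name in names:
                rows.append({"cluster": cl, "signature": name,
                             "mean_diff": np.nan, "p_value": np.nan,
                             "conf_low": np.nan, "conf_high": np.nan})
            continue
        for j, name in enumerate(names):
            a, b = theta[inside, j], theta[~inside, j]
            res = ttest_ind(a, b, equal_var=False, alternative="greater")
            ci = res.confidence_interval(0.95)
            rows.append({"cluster": cl, "signature": name,
                         "mean_diff": float(a.mean() - b.mean()),
                         "p_value": float(res.pvalue),
                         "conf_low": float(ci.low), "conf_high": float(ci.high)})
    table = pd.DataFrame(rows)
    valid = table.p_value.notna()
    table["q_value"] = np.nan
    if valid.any():
        table.loc[valid, "q_value"] = bh_adjust(table.loc[valid, "p_value"].to_numpy())
    return table


def blocked_permutation_test(member_flags: np.ndarray,
                             annotation: np.ndarray,
                             block_labels: np.ndarray,
                             n_perm: int = 10_000, seed: int = 0,
                             statistic: str = "proportion"
                             ) -> tuple[float, float]:
    """Blocked permutation test for cluster-annotation association.

    ``member_flags`` marks cluster membership; permuted clusters draw, per
    block, the same number of samples as the original cluster has in that
    block (without replacement), preserving the confounder composition.
    ``statistic="proportion"`` uses the difference in annotation proportion
    between cluster and rest (binary annotations); ``"mean"`` uses the
    difference in means (continuous annotations).  Returns (s, p) with the
    two-tailed add-one permutation p-value.
    """
    if statistic not in ("proportion", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    member = np.asarray(member_flags, dtype=bool)
    ann = np.asarray(annotation, dtype=float)
    blocks = np.asarray(block_labels)
    if member.size != ann.size or member.size != blocks.size:
        raise ValueError("member_flags, annotation and block_labels must align")
    m = int(member.sum())
    n = member.size
    if m == 0:
        raise ValueError("cluster is empty")
    total = float(ann.sum())

    def diff(inside_sum: np.ndarray | float):
        inside_mean = inside_sum / m
        if n == m:
            return inside_mean
        return inside_mean - (total - inside_sum) / (n - m)

    rng = np.random.default_rng(seed)
    s = float(diff(float(ann[member].sum())))
    # draw all permuted clusters at once, block by block
    inside_sums = np.zeros(n_perm)
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        need = int(member[idx].sum())
        if need > idx.size:
            raise ValueError(f"block {b!r} smaller than the cluster's count there")
        if need == 0:
            continue
        if need == idx.size:
            inside_sums += float(ann[idx].sum())
            continue
        order = rng.random((n_perm, idx.size)).argsort(axis=1)[:, :need]
        inside_sums += ann[idx][order].sum(axis=1)
    s_perm = diff(inside_sums)
    exceed = int(np.sum(np.abs(s_perm) >= abs(s) - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return s, float(p)


def annotation_association(values: np.ndarray, labels: np.ndarray,
                           test: str = "fisher_2tail") -> pd.DataFrame:
    """Cluster-vs-rest annotation tests.

    ``fisher_2tail`` for binary annotations (two-tailed Fisher exact),
    ``welch_2tail`` for continuous ones, ``welch_on_ranks`` replaces values
    by midranks before the Welch test (robust to extreme outliers, e.g. a
    hypermutated sample).  Degenerate Fisher margins return p = 1 with a
    flag.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    rows = []
    if test == "welch_on_ranks":
        work = rankdata(values.astype(float))
    else:
        work = values.astype(float)
    for cl in np.unique(labels):
        inside = labels == cl
        flagged = False
        if test == "fisher_2tail":
            a = int(np.sum(work[inside] > 0))
            b_ = int(np.sum(work[inside] == 0))
            c = int(np.sum(work[~inside] > 0))
            d = int(np.sum(work[~inside] == 0))
            table = np.array([[a, b_], [c, d]])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                p, stat_val, flagged = 1.0, 0.0, True
            else:
                _, p = fisher_exact(table, alternative="two-sided")
                stat_val = (a / max(a + b_, 1)) - (c / max(c + d, 1))
            lo = hi = np.nan
        elif test in ("welch_2tail", "welch_on_ranks"):
            x, y = work[inside], work[~inside]
            if x.size < 2 or y.size < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0
                                            and x.mean() == y.mean()):
                p, stat_val, flagged = 1.0, 0.0, x.size < 2 or y.size < 2
                lo = hi = np.nan
            else:
                res = ttest_ind(x, y, equal_var=False)
                p = float(res.pvalue)
                stat_val = float(x.mean() - y.mean())
                ci = res.confidence_interval(0.95)
                lo, hi = float(ci.low), float(ci.high)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"cluster": cl, "test": test, "diff": stat_val,
                     "p_value": float(p), "conf_low": lo, "conf_high": hi,
                     "degenerate": flagged})
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
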