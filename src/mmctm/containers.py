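"""Core data containers shared across the package.

Count matrices hold per-sample tallies of categorized mutations; signature
sets and sample-signature probability matrices hold the row-stochastic
outputs of the topic models.  All containers are thin, validated wrappers
around numpy arrays with pandas converters for TSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategorySpace",
    "CountMatrix",
    "SignatureSet",
    "SampleSignatureProbs",
]

_ROW_SUM_TOL = 1e-8


@dataclass(frozen=True)
class CategorySpace:
    """An ordered set of mutation category labels for one modality.

    Parameters
    ----------
    modality:
        Short name of the data modality, e.g. ``"SNV"`` or ``"SV"``.
    labels:
        Ordered, unique category labels.
    encoding:
        ``"full"`` for a joint category grid (e.g. the 96 trinucleotide
        contexts) or ``"independent"`` for a per-feature decomposition.
    feature_arity:
        For independent encodings, the number of values each feature takes
        (e.g. ``(6, 4, 4)`` for substitution type and the two flanks).
    """

    modality: str
    labels: tuple[str, ...]
    encoding: str = "full"
    feature_arity: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("category labels must be unique")
        if self.encoding not in ("full", "independent"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "independent" and sum(self.feature_arity) != len(self.labels):
            raise ValueError("feature_arity must sum to the number of labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class CountMatrix:
    """Sample x category non-negative integer counts for one modality."""

    sample_ids: list[str]
    category_space: CategorySpace
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.sample_ids), len(self.category_space)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.category_space)} categories"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_categories(self) -> int:
        return len(self.category_space)

    def row_totals(self) -> np.ndarray:
        """Mutation totals per sample (the N_d of the predictive likelihood)."""
        return self.counts.sum(axis=1)

    def zero_samples(self) -> list[str]:
        """Samples with no mutations in this modality (retained but flagged)."""
        return [s for s, t in zip(self.sample_ids, self.row_totals()) if t == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.category_space.labels),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "SNV",
                   encoding: str = "full",
                   feature_arity: tuple[int, ...] = ()) -> "CountMatrix":
        space = CategorySpace(modality, tuple(df.columns), encoding, feature_arity)
        return cls(list(df.index.astype(str)), space, df.to_numpy())


def _check_row_stochastic(mat: np.ndarray, name: str) -> None:
    if np.any(mat < 0):
        raise ValueError(f"{name} has negative entries")
    err = np.abs(mat.sum(axis=1) - 1.0)
    if np.any(err > _ROW_SUM_TOL):
        raise ValueError(f"{name} rows must sum to 1 (max deviation {err.max():.3g})")


@dataclass
class SignatureSet:
    """K x V signature-over-category probabilities for one modality.

    For independent encodings ``phi`` concatenates the per-feature
    distributions along the category axis and each feature block is
    separately row-stochastic; ``feature_slices`` gives the blocks.
    """

    category_space: CategorySpace
    phi: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2 or self.phi.shape[1] != len(self.category_space):
            raise ValueError("phi must be K x V with V matching the category space")
        if not self.names:
            self.names = [f"{self.category_space.modality}-{i + 1}"
                          for i in range(self.phi.shape[0])]
        for lo, hi in self.feature_slices():
            _check_row_stochastic(self.phi[:, lo:hi], "phi")

    @property
    def n_signatures(self) -> int:
        return self.phi.shape[0]

    def feature_slices(self) -> list[tuple[int, int]]:
        if self.category_space.encoding == "independent":
            edges = np.cumsum((0,) + tuple(self.category_space.feature_arity))
            return list(zip(edges[:-1], edges[1:]))
        return [(0, len(self.category_space))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=pd.Index(self.names, name="signature"),
                            columns=list(self.category_space.labels))


@dataclass
class SampleSignatureProbs:
    """D x K sample-over-signature probabilities for one modality."""

    modality: str
    sample_ids: list[str]
    theta: np.ndarray
    signature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != len(self.sample_ids):
            raise ValueError("theta must be D x K with D matching sample_ids")
        if not self.signature_names:
            self.signature_names = [f"{self.modality}-{i + 1}"
                                    for i in range(self.theta.shape[1])]
        _check_row_stochastic(self.theta, "theta")

    @property
    def n_signatures(self) -> int:
        return self.theta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta,
                            index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.signature_names)
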