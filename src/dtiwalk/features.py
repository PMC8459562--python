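"""Edge feature construction: fusion, min-max scaling, oversampling.

A (drug, target) pair is represented by fusing the two node embeddings with
one of five operators; concatenation doubles the dimension (d' = 2d), the
others keep d' = d.  Min-max parameters are fitted on training rows only and
applied without clipping to test rows; random oversampling balances training
labels by duplicating minority rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dtiwalk.embedding import EmbeddingTable

#: fusion operators over equal-length drug/target vectors
FUSION_KINDS = ("concatenate", "hadamard", "average", "weighted_l1", "weighted_l2")


def fuse(fd: np.ndarray, ft: np.ndarray, kind: str) -> np.ndarray:
    """Fuse a drug vector and a target vector into one edge vector.

    concatenate -> [fd || ft] (drug first); hadamard -> fd * ft;
    average -> (fd + ft) / 2; weighted_l1 -> |fd - ft|;
    weighted_l2 -> (fd - ft)^2, all elementwise.
    """
    fd = np.asarray(fd, dtype=float)
    ft = np.asarray(ft, dtype=float)
    if fd.shape != ft.shape or fd.ndim != 1:
        raise ValueError(
            f"drug and target vectors must be 1-D of equal length, got "
            f"{fd.shape} and {ft.shape}"
        )
    if kind == "concatenate":
        return np.concatenate([fd, ft])
    if kind == "hadamard":
        return fd * ft
    if kind == "average":
        return (fd + ft) / 2.0
    if kind == "weighted_l1":
        return np.abs(fd - ft)
    if kind == "weighted_l2":
        return (fd - ft) ** 2
    raise ValueError(f"unknown fusion kind {kind!r}; choose from {FUSION_KINDS}")


@dataclass
class EdgeFeatureSet:
    """Fused per-pair feature rows with binary labels."""

    pairs: list[tuple[str, str]]
    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (len(self.pairs) == self.X.shape[0] == len(self.labels)):
            raise ValueError("pairs, X rows and labels must have equal length")
        if not np.isfinite(self.X).all():
            raise ValueError("edge features must be finite")

    def __len__(self) -> int:
        return len(self.pairs)


def build_feature_set(
    emb: EmbeddingTable,
    pairs: list[tuple[str, str]],
    labels,
    kind: str,
) -> EdgeFeatureSet:
    """One fused row per (drug, target) pair, preserving input order."""
    labels = np.asarray(labels)
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels must have equal length")
    d_out = 2 * emb.d if kind == "concatenate" else emb.d
    X = np.empty((len(pairs), d_out))
    for i, (drug, target) in enumerate(pairs):
        if drug not in emb:
            raise KeyError(f"no embedding for drug {drug!r}")
        if target not in emb:
            raise KeyError(f"no embedding for target {target!r}")
        X[i] = fuse(emb[drug], emb[target], kind)
    return EdgeFeatureSet(pairs=list(pairs), X=X, labels=labels)


@dataclass
class NormalizationParams:
    """Per-feature training minima/maxima for min-max scaling."""

    minimum: np.ndarray
    maximum: np.ndarray


def fit_minmax(train: EdgeFeatureSet) -> NormalizationParams:
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty feature set")
    return NormalizationParams(
        minimum=train.X.min(axis=0), maximum=train.X.max(axis=0)
    )


def apply_minmax(
    fs: EdgeFeatureSet, params: NormalizationParams
) -> EdgeFeatureSet:
    """Scale features to (x - min) / (max - min) with training parameters.

    A constant training feature (max == min) maps to 0 everywhere; test
    values outside the training range are not clipped.
    """
    span = params.maximum - params.minimum
    safe = np.where(span == 0, 1.0, span)
    X = (fs.X - params.minimum) / safe
    X[:, span == 0] = 0.0
    return EdgeFeatureSet(pairs=fs.pairs, X=X, labels=fs.labels)


def oversample_minority(train: EdgeFeatureSet, seed: int) -> EdgeFeatureSet:
    """Balance classes by resampling minority rows with replacement.

    Original rows are kept first in their input order; synthesized rows are
    exact copies of minority rows, appended until both classes match the
    majority count.  Training data only.
    """
    labels = train.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires both classes present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return train
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(labels == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(train)), extra])
    return EdgeFeatureSet(
        pairs=[train.pairs[i] for i in idx],
        X=train.X[idx],
        labels=labels[idx],
    )
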