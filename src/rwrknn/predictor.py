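"""Pair feature assembly, balanced negative sampling, and inverse-distance
weighted KNN regression.

Each (circRNA, disease) pair is represented by the concatenation of the
disease's weighted feature row and the circRNA's weighted feature row
(dimension Nd + Nc — 761 on a 661-circRNA / 100-disease dataset). Known
associations are the positive samples; for every circRNA with ``nd`` known
diseases, ``nd`` unassociated diseases are drawn uniformly without
replacement as negatives, so the training set is exactly balanced.

Scoring is KNN regression under the Minkowski metric: the k nearest training
pairs vote with weight 1/distance, so the score is a convex combination of
neighbour labels and always lies in [0, 1]. A test pair coinciding with
training pairs (distance 0) takes the mean label of its zero-distance
neighbours — the limit of inverse-distance weighting. Ties at the k-th
neighbour break by training-sample index, which keeps scores exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import AssociationMatrix
from .propagation import WeightedFeatures

__all__ = [
    "KnnParams",
    "PairSample",
    "build_pair_features",
    "sample_negatives",
    "minkowski_distance",
    "knn_fit_predict",
    "predict_all_pairs",
]


@dataclass(frozen=True)
class KnnParams:
    """Neighbour count k >= 1 and Minkowski exponent p >= 1 (p = 1 is the
    Manhattan metric). Defaults k = 5, p = 1."""

    k: int = 5
    p: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")


@dataclass(frozen=True)
class PairSample:
    """One (circRNA, disease) instance: concatenated feature vector
    [disease part ‖ circRNA part] and binary label."""

    circ_index: int
    disease_index: int
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def build_pair_features(
    wsd: WeightedFeatures,
    wsc: WeightedFeatures,
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[int],
) -> list[PairSample]:
    """One :class:`PairSample` per (circ_index, disease_index) pair, order
    preserved; features are [disease row of WSD ‖ circRNA row of WSC]."""
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels differ in length")
    nc = wsc.values.shape[0]
    nd = wsd.values.shape[0]
    samples = []
    for (ci, di), label in zip(pairs, labels):
        if not (0 <= ci < nc and 0 <= di < nd):
            raise IndexError(f"pair index ({ci}, {di}) out of range ({nc}, {nd})")
        features = np.concatenate([wsd.values[di], wsc.values[ci]])
        samples.append(PairSample(ci, di, features, int(label)))
    return samples


def sample_negatives(
    assoc: AssociationMatrix, rng_seed: int
) -> list[tuple[int, int]]:
    """Balanced negative pairs: for each circRNA (in registry order) with
    ``nd`` positives, draw ``nd`` distinct unassociated diseases uniformly.

    Deterministic given ``rng_seed``; the result never intersects the known
    positives and has exactly as many pairs as there are positives.
    """
    rng = np.random.default_rng(rng_seed)
    negatives: list[tuple[int, int]] = []
    for ci in range(assoc.n_circ):
        row = assoc.values[ci]
        nd_i = int(row.sum())
        if nd_i == 0:
            continue
        candidates = np.nonzero(row == 0)[0]
        if candidates.size < nd_i:
            name = assoc.circ_registry[ci]
            raise ValueError(
                f"circRNA {name!r} has {nd_i} positives but only "
                f"{candidates.size} unassociated diseases to sample from"
            )
        chosen = rng.choice(candidates, size=nd_i, replace=False)
        negatives.extend((ci, int(di)) for di in chosen)
    return negatives


def minkowski_distance(a: np.ndarray, b: np.ndarray, p: int) -> float:
    """(Σ |aᵢ − bᵢ|^p)^(1/p); p = 1 Manhattan, p = 2 Euclidean."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(np.sum(np.abs(a - b) ** p) ** (1.0 / p))


def _neighbor_scores(
    dists: np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Inverse-distance-weighted neighbour vote for each row of a test × train
    distance matrix."""
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    nbr_d = np.take_along_axis(dists, order, axis=1)
    nbr_y = labels[order]
    scores = np.empty(dists.shape[0])
    for i in range(dists.shape[0]):
        d = nbr_d[i]
        y = nbr_y[i]
        zero = d == 0
        if zero.any():
            scores[i] = y[zero].mean()
        else:
            w = 1.0 / d
            scores[i] = float(np.dot(w, y) / w.sum())
    return scores


def knn_fit_predict(
    train: Sequence[PairSample],
    test_features: Sequence[np.ndarray] | np.ndarray,
    params: KnnParams | None = None,
) -> np.ndarray:
    """Score test feature vectors against labelled training samples.

    Each score is Σ wⱼ·labelⱼ / Σ wⱼ over the k nearest training samples with
    wⱼ = 1/dⱼ; exact matches (dⱼ = 0) dominate with their mean label. Output
    values lie in [0, 1].
    """
    params = params or KnnParams()
    if len(train) < params.k:
        raise ValueError(
            f"need at least k={params.k} training samples, got {len(train)}"
        )
    X = np.vstack([s.features for s in train])
    y = np.array([s.label for s in train], dtype=np.float64)
    T = np.vstack([np.asarray(f, dtype=np.float64) for f in test_features])
    if T.shape[1] != X.shape[1]:
        raise ValueError(
            f"test feature dimension {T.shape[1]} != train dimension {X.shape[1]}"
        )
    metric = "cityblock" if params.p == 1 else "minkowski"
    kwargs = {} if params.p == 1 else {"p": params.p}
    dists = cdist(T, X, metric, **kwargs)
    return _neighbor_scores(dists, y, params.k)


def predict_all_pairs(
    wsd: WeightedFeatures,
    wsc: WeightedFeatures,
    train: Sequence[PairSample],
    params: KnnParams | None = None,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Score every (circRNA, disease) pair, including known positives,
    returning an Nc × Nd matrix for candidate ranking."""
    nc = wsc.values.shape[0]
    nd = wsd.values.shape[0]
    pairs = [(ci, di) for ci in range(nc) for di in range(nd)]
    scores = np.empty(len(pairs))
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start : start + chunk_size]
        feats = np.hstack(
            [
                wsd.values[[di for _, di in chunk]],
                wsc.values[[ci for ci, _ in chunk]],
            ]
        )
        scores[start : start + len(chunk)] = knn_fit_predict(train, feats, params)
    return scores.reshape(nc, nd)
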