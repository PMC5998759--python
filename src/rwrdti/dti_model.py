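"""Pair-vector assembly, negative sampling and the cubic-distance kNN.

A drug-target pair is represented by concatenating the drug's fingerprint
block and the protein's descriptor block (1024 + 1287 = 2311 dimensions
with the default feature sets). Training balances the known positive pairs
with an equal number of randomly sampled non-interacting pairs; to make the
evaluation robust to the sampling, several independent replicate negative
sets are drawn and every performance number is reported per replicate.

Classification uses k-nearest neighbors under the Minkowski distance with
exponent 3 ("cubic" distance), which accentuates the per-feature
differences that network weighting creates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .containers import BipartiteDTI, FeatureMatrix

__all__ = [
    "PairDataset",
    "make_pair_vectors",
    "sample_negatives",
    "build_pair_dataset",
    "cubic_distance",
    "CubicKNN",
    "DEFAULT_SCORE_THRESHOLD",
]

#: default decision threshold for turning kNN scores into labels; headline
#: evaluation is threshold-free (AUC), this only affects label output
DEFAULT_SCORE_THRESHOLD = 0.62


@dataclass
class PairDataset:
    """Labeled pair vectors with replicate negative sets.

    ``negative_set_index[i]`` is the replicate a negative row belongs to
    (-1 for positive rows). ``replicate(j)`` views the positives together
    with the j-th negative set, which is what one kNN model trains on.
    """

    pair_ids: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    negative_set_index: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.negative_set_index = np.asarray(self.negative_set_index, dtype=int)
        n = len(self.pair_ids)
        if not (self.X.shape[0] == self.y.shape[0] == self.negative_set_index.shape[0] == n):
            raise ValueError("pair_ids, X, y and negative_set_index must align")
        if np.any((self.y == 1) != (self.negative_set_index == -1)):
            raise ValueError("positives must carry negative_set_index -1")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_negative_sets(self) -> int:
        idx = self.negative_set_index
        return int(idx.max() + 1) if np.any(idx >= 0) else 0

    def replicate(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) of the positives plus the j-th negative set."""
        mask = (self.y == 1) | (self.negative_set_index == j)
        return self.X[mask], self.y[mask]


def make_pair_vectors(
    pairs: Sequence[tuple[str, str]],
    drug_features: FeatureMatrix,
    protein_features: FeatureMatrix,
    strict: bool = True,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Concatenate drug block (first) and protein block per pair.

    In strict mode a pair whose drug or protein lacks a feature row is an
    error (all dropped pairs listed); in lenient mode such pairs are
    skipped with a warning.
    """
    import logging

    kept: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for d, p in pairs:
        if d in drug_features and p in protein_features:
            kept.append((d, p))
            rows.append(
                np.concatenate([drug_features.row(d), protein_features.row(p)])
            )
        else:
            dropped.append((d, p))
    if dropped:
        if strict:
            raise KeyError(
                f"{len(dropped)} pair(s) lack feature rows: {dropped[:10]}"
            )
        logging.getLogger(__name__).warning(
            "skipping %d pair(s) without feature rows", len(dropped)
        )
    width = drug_features.n_features + protein_features.n_features
    X = np.vstack(rows) if rows else np.empty((0, width))
    return kept, X


def sample_negatives(
    dti: BipartiteDTI, n_sets: int, rng_seed: int
) -> list[list[tuple[str, str]]]:
    """Draw ``n_sets`` replicate negative sets, each the size of the
    positive set, uniformly without replacement from the (drug, protein)
    combinations over the observed entities that are not known positives.

    Replicates are sampled independently (they may overlap one another but
    never the positives). Deterministic given ``rng_seed``.
    """
    drugs = dti.drug_ids
    prots = dti.protein_ids
    n_pos = dti.n_pairs
    universe = len(drugs) * len(prots)
    n_nonpos = universe - n_pos
    if n_nonpos < n_pos:
        raise ValueError(
            f"only {n_nonpos} non-positive combinations available but "
            f"{n_pos} negatives per set are required"
        )
    rng = np.random.default_rng(rng_seed)
    n_p = len(prots)
    sets: list[list[tuple[str, str]]] = []
    for _ in range(n_sets):
        chosen: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        while len(ordered) < n_pos:
            draw = rng.integers(0, universe, size=2 * (n_pos - len(ordered)))
            for flat in draw:
                pair = (drugs[flat // n_p], prots[flat % n_p])
                if pair in dti.pairs or pair in chosen:
                    continue
                chosen.add(pair)
                ordered.append(pair)
                if len(ordered) == n_pos:
                    break
        sets.append(ordered)
    return sets


def build_pair_dataset(
    dti: BipartiteDTI,
    drug_features: FeatureMatrix,
    protein_features: FeatureMatrix,
    n_negative_sets: int = 20,
    rng_seed: int = 0,
    strict: bool = True,
) -> PairDataset:
    """Positives plus replicate negative sets as one labeled dataset."""
    pos_pairs = dti.sorted_pairs()
    neg_sets = sample_negatives(dti, n_negative_sets, rng_seed)
    ids, X_parts, y_parts, set_parts = [], [], [], []
    kept, X = make_pair_vectors(pos_pairs, drug_features, protein_features, strict)
    ids += kept
    X_parts.append(X)
    y_parts.append(np.ones(len(kept), dtype=int))
    set_parts.append(np.full(len(kept), -1))
    for j, neg in enumerate(neg_sets):
        kept, X = make_pair_vectors(neg, drug_features, protein_features, strict)
        ids += kept
        X_parts.append(X)
        y_parts.append(np.zeros(len(kept), dtype=int))
        set_parts.append(np.full(len(kept), j))
    return PairDataset(
        ids,
        np.vstack(X_parts),
        np.concatenate(y_parts),
        np.concatenate(set_parts),
    )


def cubic_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Minkowski distance with exponent 3:
    ``d(x, y) = (sum_i |x_i - y_i|^3)^(1/3)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float((np.abs(x - y) ** 3).sum() ** (1.0 / 3.0))


class CubicKNN:
    """k-nearest-neighbor classifier under the cubic distance.

    ``score_samples`` returns, for each query, the fraction of positive
    labels among the k nearest training vectors — a score in [0, 1].
    Nearest-neighbor search is exact (all pairwise distances); ties at the
    k-th neighbor are broken by training-row order via a stable sort, so
    scoring is deterministic.
    """

    def __init__(self, k: int = 10, threshold: float = DEFAULT_SCORE_THRESHOLD):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.threshold = threshold
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CubicKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if self.k > X.shape[0]:
            raise ValueError(
                f"k={self.k} exceeds the training-set size {X.shape[0]}"
            )
        self._X = X
        self._y = y
        return self

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self._X is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"query width {X.shape[1]} != training width {self._X.shape[1]}"
            )
        return X

    def kneighbors(self, X: np.ndarray) -> np.ndarray:
        """Indices of the k nearest training rows per query (row-order tie
        break)."""
        X = self._check_fitted(X)
        D = cdist(X, self._X, metric="minkowski", p=3)
        order = np.argsort(D, axis=1, kind="stable")
        return order[:, : self.k]

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        nn = self.kneighbors(X)
        return self._y[nn].mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) >= self.threshold).astype(int)
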