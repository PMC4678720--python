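"""Class balancing for the extreme positive/candidate imbalance.

With on the order of ten experimentally supported positive windows against a
hundred thousand candidates, the minority class is synthetically oversampled
(SMOTE: new points drawn uniformly along segments between a minority point
and one of its k nearest minority neighbors) and the majority class is
down-sampled without replacement, producing a training set with a fixed
negative:positive ratio of 2.5:1 (12,500 : 5,000 = 17,500 rows at the
reference configuration).

The neighbor count k is clamped to n_minority - 1 when the minority class is
smaller than the requested k; both the requested and effective k are
recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_N_POSITIVE = 5000
DEFAULT_N_NEGATIVE = 12500
DEFAULT_K = 300


def smote_oversample(
    minority: np.ndarray, k: int, n_synthetic: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate *n_synthetic* rows by segment interpolation.

    Each row is x_i + u (x_nn - x_i) with u ~ U(0,1), x_i cycled over the
    minority rows and x_nn drawn uniformly from the k_eff Euclidean nearest
    minority neighbors of x_i (self excluded); k_eff = min(k, n - 1).
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    k_eff = min(k, n - 1)
    if k_eff != k:
        logger.info("SMOTE k clamped from %d to %d (n_minority=%d)", k, k_eff, n)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is self
    neighbors = idx[:, 1:k_eff + 1]
    out = np.empty((n_synthetic, minority.shape[1]), dtype=float)
    for t in range(n_synthetic):
        i = t % n
        j = neighbors[i, rng.integers(k_eff)]
        u = rng.uniform()
        out[t] = minority[i] + u * (minority[j] - minority[i])
    return out


def undersample_majority(
    majority: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of *n* majority rows without replacement."""
    majority = np.asarray(majority)
    if n > majority.shape[0]:
        raise ValueError(
            f"cannot sample {n} rows from {majority.shape[0]} majority rows"
        )
    idx = rng.choice(majority.shape[0], size=n, replace=False)
    return majority[idx]


@dataclass
class BalancedTrainingSet:
    """SMOTE-balanced training matrix with per-row provenance."""

    X: np.ndarray
    y: np.ndarray  # 1 = positive, 0 = negative
    provenance: np.ndarray  # 'original' | 'synthetic' | 'sampled-negative'
    seed: int | None
    k_requested: int
    k_effective: int

    @property
    def ratio(self) -> float:
        return float((self.y == 0).sum() / (self.y == 1).sum())

    def __len__(self) -> int:
        return len(self.y)


def build_training_set(
    X: np.ndarray,
    y: np.ndarray,
    n_pos_out: int = DEFAULT_N_POSITIVE,
    n_neg_out: int = DEFAULT_N_NEGATIVE,
    k: int = DEFAULT_K,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BalancedTrainingSet:
    """Balanced set of exactly *n_pos_out* positives (originals + SMOTE) and
    *n_neg_out* sampled negatives."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    pos = X[y == 1]
    neg = X[y == 0]
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 labeled positives")
    if pos.shape[0] > n_pos_out:
        raise ValueError(
            f"{pos.shape[0]} original positives exceed the requested {n_pos_out}"
        )
    n_synthetic = n_pos_out - pos.shape[0]
    k_eff = min(k, pos.shape[0] - 1)
    synthetic = smote_oversample(pos, k, n_synthetic, rng)
    sampled_neg = undersample_majority(neg, n_neg_out, rng)
    X_out = np.vstack([pos, synthetic, sampled_neg])
    y_out = np.concatenate(
        [np.ones(n_pos_out, dtype=int), np.zeros(n_neg_out, dtype=int)]
    )
    provenance = np.concatenate(
        [
            np.repeat("original", pos.shape[0]),
            np.repeat("synthetic", n_synthetic),
            np.repeat("sampled-negative", n_neg_out),
        ]
    )
    return BalancedTrainingSet(
        X=X_out, y=y_out, provenance=provenance,
        seed=seed, k_requested=k, k_effective=k_eff,
    )
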