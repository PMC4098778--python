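"""From-scratch SMOTE oversampling of the minority (positive) class.

Synthetic minority samples are convex combinations x + u * (x_nn - x) with u
uniform on [0, 1], x a minority sample and x_nn one of its k nearest minority
neighbours under Euclidean distance on the raw feature scale (no
standardization).  Balancing is only ever applied to training folds; the
cross-validation driver flags every synthetic record so it can never leak
into a test partition.

Interpolated binary features (the accessibility bits) are left fractional:
SMOTE operates in the input space, and re-thresholding would be an extra,
undocumented transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import BalanceError, ProtocolError


@dataclass
class BalancePlan:
    """How to rebalance a training fold.

    k_neighbors follows the original SMOTE formulation (k=5); target_ratio is
    the desired minority/majority ratio after augmentation (1.0 = parity,
    supporting the linear kernel the classifier is restricted to).
    """

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0


def smote(
    minority: np.ndarray,
    n_synthetic: int,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate *n_synthetic* interpolated minority samples.

    k is clamped (with a warning) when it is not smaller than the number of
    minority samples.  Output is bit-identical for a fixed generator state.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise BalanceError(
            f"SMOTE needs at least 2 minority samples, got {minority.shape[0]}"
        )
    if n_synthetic <= 0:
        return np.empty((0, minority.shape[1]))
    if rng is None:
        rng = np.random.default_rng(0)
    n_min = minority.shape[0]
    if k_neighbors >= n_min:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= {n_min} minority samples; "
            f"clamped to {n_min - 1}",
            stacklevel=2,
        )
        k_neighbors = n_min - 1
    if k_neighbors < 1:
        raise BalanceError("k_neighbors must be >= 1")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    # column 0 is the point itself; keep the k true neighbours
    neighbour_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
    parents = rng.integers(0, n_min, size=n_synthetic)
    chosen = rng.integers(0, k_neighbors, size=n_synthetic)
    gaps = rng.uniform(0.0, 1.0, size=n_synthetic)
    x = minority[parents]
    x_nn = minority[neighbour_idx[parents, chosen]]
    return x + gaps[:, None] * (x_nn - x)


def balance_training_fold(
    X: np.ndarray,
    y: np.ndarray,
    plan: BalancePlan,
    is_training: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Augment the positive class of a TRAINING fold to plan.target_ratio
    times the negatives.

    Returns ``(X_aug, y_aug, synthetic_mask)`` where the mask flags every
    synthetic row (original rows first, in input order).  Calling this on a
    test fold is a protocol violation and raises.
    """
    if not is_training:
        raise ProtocolError("SMOTE balancing must never be applied to a test fold")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise BalanceError("X and y length mismatch")
    n_pos = int(np.sum(y == +1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise BalanceError("both classes must be present before balancing")
    target_pos = int(round(plan.target_ratio * n_neg))
    n_synth = target_pos - n_pos
    if n_synth <= 0:
        return X, y, np.zeros(X.shape[0], dtype=bool)
    rng = np.random.default_rng(plan.seed)
    synth = smote(X[y == +1], n_synth, k_neighbors=plan.k_neighbors, rng=rng)
    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate([y, np.full(n_synth, +1, dtype=int)])
    mask = np.concatenate(
        [np.zeros(X.shape[0], dtype=bool), np.ones(n_synth, dtype=bool)]
    )
    return X_aug, y_aug, mask
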