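"""Balanced sampling for one binary one-versus-all task.

Random undersampling removes uniformly chosen majority samples; SMOTE adds
synthetic minority samples by interpolating between a minority sample and
one of its k nearest minority neighbours (Euclidean distance in the
feature space current at the time of the call).  Both are deterministic
given the seed.

Synthetic minority samples are tagged in ``provenance`` and may serve as
interpolation bases in later iterations — the minority pool is always the
current one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import SamplingError, ValidationError

__all__ = ["BinaryTask", "random_undersample", "smote_oversample"]

ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class BinaryTask:
    """One one-versus-all sub-problem.

    ``y`` is boolean (True = positive = the target class);
    ``feature_indices`` maps the current columns back to the original
    dataset columns, so iterative feature elimination stays traceable;
    ``provenance`` tags each row as original or SMOTE-synthetic.
    """

    X: np.ndarray
    y: np.ndarray
    positive_class: str
    feature_indices: np.ndarray = None  # type: ignore[assignment]
    provenance: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X rows and y length must match")
        if self.feature_indices is None:
            self.feature_indices = np.arange(self.X.shape[1])
        self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        if len(self.feature_indices) != self.X.shape[1]:
            raise ValidationError("feature_indices must match X columns")
        if self.provenance is None:
            self.provenance = np.full(self.X.shape[0], ORIGINAL, dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if not (self.y.any() and (~self.y).any()):
            raise ValidationError("both label values must be present")

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.y).sum())

    @property
    def majority_size(self) -> int:
        return max(self.n_pos, self.n_neg)

    @property
    def minority_size(self) -> int:
        return min(self.n_pos, self.n_neg)

    def select_features(self, cols) -> "BinaryTask":
        """Restrict to the given current-column positions (order kept)."""
        cols = np.asarray(cols, dtype=int)
        return BinaryTask(
            X=self.X[:, cols],
            y=self.y.copy(),
            positive_class=self.positive_class,
            feature_indices=self.feature_indices[cols],
            provenance=self.provenance.copy(),
        )


def random_undersample(task: BinaryTask, n_remove: int, seed: int) -> BinaryTask:
    """Remove ``n_remove`` majority-class samples uniformly at random.

    Never undershoots balance: ``n_remove`` may not exceed the
    majority/minority gap.  The minority class is untouched.
    """
    if n_remove < 0:
        raise ValidationError("n_remove must be >= 0")
    gap = task.majority_size - task.minority_size
    if n_remove > gap:
        raise ValidationError(
            f"n_remove={n_remove} exceeds the majority/minority gap {gap}"
        )
    if n_remove == 0:
        return task
    majority_is_pos = task.n_pos >= task.n_neg
    majority_idx = np.flatnonzero(task.y == majority_is_pos)
    rng = np.random.default_rng(seed)
    drop = rng.choice(majority_idx, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(len(task.y)), drop)
    return BinaryTask(
        X=task.X[keep],
        y=task.y[keep],
        positive_class=task.positive_class,
        feature_indices=task.feature_indices.copy(),
        provenance=task.provenance[keep],
    )


def smote_oversample(task: BinaryTask, n_new: int, k: int = 5,
                     seed: int = 0) -> BinaryTask:
    """Append ``n_new`` SMOTE-synthetic minority samples.

    Each synthetic sample is x + u * (x_nn - x) with x a minority sample
    chosen round-robin (so per-base counts differ by at most one), x_nn one
    of its k nearest minority neighbours (k capped at minority size - 1),
    and u uniform on [0, 1).  The majority class is untouched.
    """
    if n_new < 0:
        raise ValidationError("n_new must be >= 0")
    if n_new == 0:
        return task
    minority_is_pos = task.n_pos <= task.n_neg
    min_idx = np.flatnonzero(task.y == minority_is_pos)
    n_min = len(min_idx)
    if n_min < 2:
        raise SamplingError(
            f"minority class has {n_min} sample(s); need >= 2 to interpolate"
        )
    k_eff = min(k, n_min - 1)
    pts = task.X[min_idx]
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    # stable argsort: equal distances resolve to the lower minority index
    nn = np.argsort(d, axis=1, kind="stable")[:, :k_eff]

    rng = np.random.default_rng(seed)
    new_rows = np.empty((n_new, task.X.shape[1]))
    for i in range(n_new):
        base = i % n_min
        neighbor = nn[base, rng.integers(k_eff)]
        u = rng.random()
        new_rows[i] = pts[base] + u * (pts[neighbor] - pts[base])
    return BinaryTask(
        X=np.vstack([task.X, new_rows]),
        y=np.concatenate([task.y, np.full(n_new, minority_is_pos, dtype=bool)]),
        positive_class=task.positive_class,
        feature_indices=task.feature_indices.copy(),
        provenance=np.concatenate(
            [task.provenance, np.full(n_new, SYNTHETIC, dtype=object)]
        ),
    )
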