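"""Entropy, mutual information and symmetric uncertainty on discretized vectors.

These are the shared measures behind all three filter selectors.  Expression
values are discretized into equal-width bins (default 10) spanning the
observed range of each feature; class labels are categorical already and
are used as-is.  Logarithms are base 2, so entropies and mutual
informations are in bits; symmetric uncertainty is base-invariant.

Zero-probability cells contribute 0 to every entropy sum (the usual
``p log p -> 0`` limit convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "DiscreteVector",
    "discretize",
    "discretize_matrix",
    "entropy",
    "mutual_information",
    "symmetric_uncertainty",
    "encode_labels",
    "mi_profile",
    "entropy_from_counts",
]


@dataclass(frozen=True)
class DiscreteVector:
    """Integer bin codes for one variable; every code lies in [0, n_bins)."""

    codes: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.size == 0:
            raise ValidationError("empty vector")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if codes.min() < 0 or codes.max() >= self.n_bins:
            raise ValidationError("codes outside [0, n_bins)")

    def __len__(self) -> int:
        return len(self.codes)


def discretize(values, n_bins: int) -> DiscreteVector:
    """Equal-width binning over [min, max].

    The maximum value is assigned to the top bin; a constant vector maps to
    the single bin 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot discretize an empty vector")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if not np.all(np.isfinite(values)):
        raise ValidationError("values must be finite")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return DiscreteVector(np.zeros(values.shape, dtype=np.int64), n_bins)
    codes = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64)
    np.clip(codes, 0, n_bins - 1, out=codes)
    return DiscreteVector(codes, n_bins)


def discretize_matrix(matrix: np.ndarray, n_bins: int) -> np.ndarray:
    """Column-wise equal-width binning; returns an int code matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValidationError("cannot discretize an empty matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValidationError("values must be finite")
    lo = matrix.min(axis=0)
    span = matrix.max(axis=0) - lo
    span[span == 0] = np.inf  # constant columns -> all codes 0
    codes = np.floor((matrix - lo) / span * n_bins).astype(np.int64)
    np.clip(codes, 0, n_bins - 1, out=codes)
    return codes


def encode_labels(labels) -> DiscreteVector:
    """Map categorical labels to integer codes (sorted label order)."""
    labels = np.asarray(labels).astype(str)
    classes, codes = np.unique(labels, return_inverse=True)
    return DiscreteVector(codes.astype(np.int64), int(len(classes)))


def entropy_from_counts(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy(x: DiscreteVector) -> float:
    """Shannon entropy H(x) in bits, from empirical frequencies."""
    return entropy_from_counts(np.bincount(x.codes, minlength=x.n_bins))


def mutual_information(x: DiscreteVector, y: DiscreteVector) -> float:
    """I(x; y) = H(x) + H(y) - H(x, y), in bits.

    Non-negative and symmetric; bounded by min(H(x), H(y)).
    """
    if len(x) != len(y):
        raise ValidationError(
            f"length mismatch: {len(x)} vs {len(y)}"
        )
    joint = np.bincount(x.codes * y.n_bins + y.codes,
                        minlength=x.n_bins * y.n_bins)
    h_xy = entropy_from_counts(joint)
    mi = entropy(x) + entropy(y) - h_xy
    return max(mi, 0.0)  # clip tiny negative float residue


def symmetric_uncertainty(a: DiscreteVector, b: DiscreteVector) -> float:
    """SU(a; b) = 2 I(a;b) / (H(a) + H(b)), in [0, 1]; 0 when both constant."""
    if len(a) != len(b):
        raise ValidationError(
            f"length mismatch: {len(a)} vs {len(b)}"
        )
    denom = entropy(a) + entropy(b)
    if denom == 0.0:
        return 0.0
    return 2.0 * mutual_information(a, b) / denom


# ---------------------------------------------------------------------------
# vectorised helpers used by the filter selectors
# ---------------------------------------------------------------------------

def mi_profile(codes: np.ndarray, y: DiscreteVector, n_bins: int) -> np.ndarray:
    """Mutual information of every column of a code matrix with ``y``.

    ``codes`` is an (n_samples, n_features) int matrix with entries in
    [0, n_bins).  Equivalent to calling :func:`mutual_information` per
    column but computed with one flat bincount per call, which matters when
    scanning thousands of genes.
    """
    n, f = codes.shape
    if n != len(y):
        raise ValidationError("length mismatch between codes and labels")
    ny = y.n_bins
    states = n_bins * ny
    flat = (np.arange(f, dtype=np.int64) * states)[None, :] + codes * ny + y.codes[:, None]
    joint = np.bincount(flat.ravel(), minlength=f * states).reshape(f, n_bins, ny)
    h_y = entropy(y)

    def _h(counts, axis):
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=axis)

    h_xy = _h(joint, axis=(1, 2))
    h_x = _h(joint.sum(axis=2), axis=1)
    return np.maximum(h_x + h_y - h_xy, 0.0)
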