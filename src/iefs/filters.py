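"""Filter feature selection: mutual-information ranking, FCBF, and mRMR.

All three selectors operate on a (matrix, labels) pair describing one
binary one-versus-all task, score features on the discretized data, and
are fully deterministic: ties are always broken toward the lower original
feature index.

* ``rank_by_relevance`` — univariate I(f; c) ranking, top-n.
* ``fcbf_select`` — symmetric-uncertainty ranking with threshold delta and
  pairwise redundancy elimination: a feature f_i is dropped when a
  better-ranked f_j satisfies SU(c; f_j) >= SU(c; f_i) and
  SU(f_i; f_j) >= SU(f_i; c), i.e. f_j predicts the class at least as well
  and f_i resembles f_j more than it resembles the class.
* ``mrmr_select`` — greedy minimum-redundancy maximum-relevance: the m-th
  pick maximises I(f_j; c) - (1/(m-1)) * sum_{f_i selected} I(f_i; f_j)
  over a candidate pool of the ``window`` most relevant features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FilterError, ValidationError
from .infotheory import (
    DiscreteVector,
    discretize_matrix,
    encode_labels,
    entropy,
    entropy_from_counts,
    mi_profile,
)

__all__ = [
    "RankedFeatureList",
    "FeatureSubset",
    "rank_by_relevance",
    "fcbf_select",
    "fcbf_select_n",
    "mrmr_select",
    "subset_relevance",
    "subset_redundancy",
]


@dataclass
class RankedFeatureList:
    """Features ordered by non-increasing score; ties by ascending index."""

    feature_indices: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_indices) != len(self.scores):
            raise ValidationError("indices and scores differ in length")
        if len(set(self.feature_indices.tolist())) != len(self.feature_indices):
            raise ValidationError("ranked indices must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.feature_indices)


@dataclass
class FeatureSubset:
    """Outcome of one selector run; ``short`` marks an under-sized FCBF result."""

    feature_indices: list[int]
    method: str
    params: dict = field(default_factory=dict)
    short: bool = False

    def __post_init__(self) -> None:
        if len(set(self.feature_indices)) != len(self.feature_indices):
            raise ValidationError("selected indices must be unique")

    def __len__(self) -> int:
        return len(self.feature_indices)


def _prepare(matrix, labels, n_bins):
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    codes = discretize_matrix(matrix, n_bins)
    y = labels if isinstance(labels, DiscreteVector) else encode_labels(labels)
    if codes.shape[0] != len(y):
        raise ValidationError("matrix rows and labels differ in length")
    return codes, y


def _ranked_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score, ascending index on ties."""
    return np.lexsort((np.arange(len(scores)), -scores))


def rank_by_relevance(matrix, labels, n: int, n_bins: int = 10) -> RankedFeatureList:
    """Top-n features by mutual information with the class labels."""
    codes, y = _prepare(matrix, labels, n_bins)
    f = codes.shape[1]
    if not 1 <= n <= f:
        raise ValidationError(f"n must be in [1, {f}], got {n}")
    scores = mi_profile(codes, y, n_bins)
    order = _ranked_order(scores)[:n]
    return RankedFeatureList(order, scores[order])


def _su_profile(codes, other_codes, other_n_bins, col_entropies, other_entropy, n_bins):
    """SU of every column of ``codes`` against one discrete vector."""
    mi = mi_profile(codes, DiscreteVector(other_codes, other_n_bins), n_bins)
    denom = col_entropies + other_entropy
    out = np.zeros_like(mi)
    nz = denom > 0
    out[nz] = 2.0 * mi[nz] / denom[nz]
    return out


def fcbf_select(matrix, labels, delta: float = 0.0, n_bins: int = 10) -> FeatureSubset:
    """Fast correlation-based filter with threshold ``delta``.

    Features below ``delta`` in SU(c; f) are dropped, then the ranked list
    is walked in decreasing order removing every later feature dominated
    by a retained one (both redundancy inequalities).  Survivors are
    returned in rank order.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    codes, y = _prepare(matrix, labels, n_bins)
    f = codes.shape[1]
    col_h = np.array([
        entropy_from_counts(np.bincount(codes[:, j], minlength=n_bins))
        for j in range(f)
    ])
    h_y = entropy(y)
    su_c = _su_profile(codes, y.codes, y.n_bins, col_h, h_y, n_bins)

    order = _ranked_order(su_c)
    order = order[su_c[order] >= delta]
    if order.size == 0:
        raise FilterError(
            f"no feature reaches delta={delta}; max observed SU = {su_c.max():.6g}"
        )
    alive = np.ones(len(order), dtype=bool)
    for pos in range(len(order)):
        if not alive[pos]:
            continue
        j = order[pos]
        rest = order[pos + 1:]
        rest_alive = alive[pos + 1:]
        if rest.size == 0 or not rest_alive.any():
            continue
        cand = rest[rest_alive]
        # SU of each remaining candidate against the retained feature f_j
        su_ij = _su_profile(codes[:, cand], codes[:, j], n_bins,
                            col_h[cand], col_h[j], n_bins)
        dominated = (su_c[j] >= su_c[cand]) & (su_ij >= su_c[cand])
        rest_alive[rest_alive.nonzero()[0][dominated]] = False
    survivors = order[alive]
    return FeatureSubset(
        feature_indices=survivors.tolist(),
        method="fcbf",
        params={"delta": delta, "su": su_c[survivors].tolist()},
    )


def fcbf_select_n(matrix, labels, n: int, n_bins: int = 10) -> FeatureSubset:
    """FCBF tuned to return as close to ``n`` features as achievable.

    The threshold delta only acts through the grid of observed SU(c; f)
    values, and any feature dominating f_i outranks f_i, so the survivor
    set at threshold delta equals the delta=0 survivor set restricted to
    SU >= delta.  The largest achievable survivor count not exceeding
    ``n`` is therefore found by cutting the delta=0 survivors at an SU
    value boundary.  If even delta=0 yields fewer than ``n`` survivors the
    short set is returned with ``short=True``.
    """
    matrix = np.asarray(matrix, dtype=float)
    f = matrix.shape[1]
    if not 1 <= n <= f:
        raise ValidationError(f"n must be in [1, {f}], got {n}")
    base = fcbf_select(matrix, labels, delta=0.0, n_bins=n_bins)
    su = np.asarray(base.params["su"])
    if len(base) <= n:
        return FeatureSubset(base.feature_indices, "fcbf",
                             params={"delta": 0.0, "requested": n},
                             short=len(base) < n)
    # survivors come in non-increasing SU order; a threshold keeps a prefix
    # ending at a strict SU drop, so the achievable counts are the prefix
    # lengths at SU boundaries — take the largest one not exceeding n
    cut = n
    while cut > 0 and cut < len(su) and su[cut - 1] == su[cut]:
        cut -= 1
    if cut == 0:
        # the whole top group is tied; no threshold yields <= n survivors,
        # so fall back to the first n by the documented index tie rule
        cut = n
        delta = float(su[0])
    else:
        delta = float(su[cut - 1])
    kept = base.feature_indices[:cut]
    return FeatureSubset(kept, "fcbf",
                         params={"delta": delta, "requested": n},
                         short=len(kept) < n)


def mrmr_select(matrix, labels, n: int, window: int = 50,
                n_bins: int = 10) -> FeatureSubset:
    """Greedy mRMR selection over a relevance-windowed candidate pool.

    The pool holds the ``window`` features most relevant to the class
    (the linear forward search restriction); the first pick maximises
    relevance, each later pick maximises relevance minus mean mutual
    information with the already-selected set.  Selection order is
    preserved in the result.
    """
    codes, y = _prepare(matrix, labels, n_bins)
    f = codes.shape[1]
    if window < 1:
        raise ValidationError("window must be >= 1")
    pool_size = min(window, f)
    if not 1 <= n <= pool_size:
        raise ValidationError(
            f"n must be in [1, pool size {pool_size}], got {n}"
        )
    rel_all = mi_profile(codes, y, n_bins)
    pool = _ranked_order(rel_all)[:pool_size]
    rel = rel_all[pool]

    selected: list[int] = []
    selected_mask = np.zeros(pool_size, dtype=bool)
    red_sum = np.zeros(pool_size)
    for m in range(1, n + 1):
        if m == 1:
            crit = rel.copy()
        else:
            crit = rel - red_sum / (m - 1)
        crit[selected_mask] = -np.inf
        # ties -> lowest original feature index
        best_pos = min(np.flatnonzero(crit == crit.max()), key=lambda p: pool[p])
        selected.append(int(pool[best_pos]))
        selected_mask[best_pos] = True
        if m < n:
            mi_new = mi_profile(
                codes[:, pool],
                DiscreteVector(codes[:, pool[best_pos]], n_bins),
                n_bins,
            )
            red_sum += mi_new
    return FeatureSubset(selected, "mrmr",
                         params={"window": window, "requested": n})


def subset_relevance(matrix, labels, subset, n_bins: int = 10) -> float:
    """Mean mutual information between subset features and the class,
    D(S, c) = (1/|S|) * sum_{f in S} I(f; c)."""
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be non-empty")
    codes, y = _prepare(matrix, labels, n_bins)
    return float(mi_profile(codes[:, subset], y, n_bins).mean())


def subset_redundancy(matrix, subset, n_bins: int = 10) -> float:
    """Set-level redundancy diagnostic,
    R(S) = (1/|S|^2) * sum_{f_i, f_j in S} I(f_i; f_j) (all ordered pairs,
    self-pairs included)."""
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be non-empty")
    codes = discretize_matrix(np.asarray(matrix, dtype=float)[:, subset], n_bins)
    k = codes.shape[1]
    total = 0.0
    for i in range(k):
        total += mi_profile(codes, DiscreteVector(codes[:, i], n_bins), n_bins).sum()
    return total / (k * k)
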