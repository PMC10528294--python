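"""Sample distance covariance and distance correlation for univariate data.

The distance correlation (dCor) of Székely, Rizzo and Bakirov is a measure
of dependence between random vectors that is zero if and only if the vectors
are independent, and lies in [0, 1].  Its population form is a weighted
L2 distance between the joint characteristic function and the product of the
marginal characteristic functions; the sample version used here is the
standard biased V-statistic built from double-centered pairwise-distance
matrices:

    A_jk = a_jk - abar_j. - abar_.k + abar_..        (a_jk = |x_j - x_k|)
    dCov2_n(x, y) = n^-2 sum_jk A_jk B_jk
    dCor_n(x, y)  = sqrt(dCov2_n) / (dVar2_n(x) dVar2_n(y))^(1/4)

Only univariate samples are supported: the screening application computes
dCor between the response and one feature column at a time.  Complexity is
O(n^2) time and memory per pair, which is ample for the sample sizes the
screening method targets (hundreds of observations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceStats",
    "distance_matrix",
    "double_center",
    "distance_stats",
    "dcor",
    "dcor_profile",
]


@dataclass(frozen=True)
class DistanceStats:
    """Squared sample distance covariance/variances and the resulting dCor.

    ``dcor`` is 0 by convention whenever either sample is constant (zero
    distance variance), so degenerate features screen out silently.
    """

    dcov2: float
    dvar2_x: float
    dvar2_y: float
    dcor: float


def _as_sample(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise InvalidInputError(f"{name} needs at least 2 observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def distance_matrix(x) -> np.ndarray:
    """Pairwise absolute-difference matrix of a univariate sample.

    Entry (j, k) is ``|x_j - x_k|``; symmetric with zero diagonal.
    """
    arr = _as_sample(x)
    return np.abs(arr[:, None] - arr[None, :])


def double_center(d) -> np.ndarray:
    """Double-center a distance matrix so every row and column sums to zero.

    Subtracts row means and column means and adds back the grand mean.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {d.shape}")
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def _stats_from_centered(A: np.ndarray, B: np.ndarray) -> DistanceStats:
    n = A.shape[0]
    inv_n2 = 1.0 / (n * n)
    dcov2 = float(np.multiply(A, B).sum() * inv_n2)
    dvar2_x = float(np.multiply(A, A).sum() * inv_n2)
    dvar2_y = float(np.multiply(B, B).sum() * inv_n2)
    # tiny negative values can arise from cancellation; dCov^2 is nonnegative
    dcov2 = max(dcov2, 0.0)
    denom = dvar2_x * dvar2_y
    if denom <= 0.0:
        r = 0.0
    else:
        r = float(np.sqrt(dcov2) / denom**0.25)
        r = min(max(r, 0.0), 1.0)
    return DistanceStats(dcov2=dcov2, dvar2_x=dvar2_x, dvar2_y=dvar2_y, dcor=r)


def distance_stats(x, y) -> DistanceStats:
    """Squared distance covariance, distance variances and dCor of two samples.

    Uses the biased V-statistic estimator (double-centered distance
    products); a constant sample yields ``dcor = 0`` by the degenerate
    convention rather than an error.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if xa.size != ya.size:
        raise InvalidInputError(
            f"samples must have equal length, got {xa.size} and {ya.size}"
        )
    A = double_center(distance_matrix(xa))
    B = double_center(distance_matrix(ya))
    return _stats_from_centered(A, B)


def dcor(x, y) -> float:
    """Sample distance correlation of two univariate samples (in [0, 1])."""
    return distance_stats(x, y).dcor


def dcor_profile(X, y, feature_ids=None):
    """Distance correlation of every feature column against the response.

    Parameters
    ----------
    X : (n, p) array-like
        Feature matrix.
    y : (n,) array-like
        Response vector.
    feature_ids : sequence, optional
        Identifiers for the columns (defaults to 0-based indices).

    Returns
    -------
    CorrelationProfile
        Scores in [0, 1], method tag ``"DC"``.  Constant columns score 0
        and are reported in a warning log.

    Notes
    -----
    The centered distance matrix of ``y`` is computed once and reused for
    every column, so the cost is one O(n^2) pass per feature.
    """
    from .screening import CorrelationProfile  # local import: avoid cycle

    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2:
        raise InvalidInputError(f"X must be 2-dimensional, got shape {Xa.shape}")
    ya = _as_sample(y, "y")
    if Xa.shape[0] != ya.size:
        raise InvalidInputError(
            f"X has {Xa.shape[0]} rows but y has {ya.size} entries"
        )
    if not np.all(np.isfinite(Xa)):
        raise InvalidInputError("X contains non-finite values")
    p = Xa.shape[1]
    if p < 1:
        raise InvalidInputError("X must have at least one column")

    B = double_center(distance_matrix(ya))
    scores = np.empty(p)
    constant: list[int] = []
    for j in range(p):
        col = Xa[:, j]
        if np.ptp(col) == 0.0:
            scores[j] = 0.0
            constant.append(j)
            continue
        A = double_center(np.abs(col[:, None] - col[None, :]))
        scores[j] = _stats_from_centered(A, B).dcor
    if constant:
        logger.warning(
            "dcor_profile: %d constant feature column(s) scored 0: %s",
            len(constant),
            constant[:10],
        )
    return CorrelationProfile(method="DC", scores=scores, feature_ids=feature_ids)
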