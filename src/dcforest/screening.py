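"""Filter-style feature screening: rank features by a dependence score and
keep those at or above a threshold.

Two scores are supported: distance correlation (``DC``, computed in
:mod:`dcforest.dcor`) and the absolute Pearson correlation baseline (``CC``).
Selection is inclusive (score >= threshold).  A single selection call with an
empty result raises :class:`~dcforest.exceptions.NoFeaturesSurviveError`;
a threshold sweep records empty markers instead and keeps going, because
sweeps deliberately probe thresholds past the viable range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dcor import dcor_profile  # noqa: F401  (re-exported convenience)
from .exceptions import InvalidInputError, NoFeaturesSurviveError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "FilterResult",
    "pearson_profile",
    "dcor_profile",
    "select_features",
    "sweep_thresholds",
]


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-feature dependence scores against the response.

    ``method`` is ``"DC"`` (distance correlation) or ``"CC"`` (absolute
    Pearson).  Scores lie in [0, 1] either way.
    """

    method: str
    scores: np.ndarray
    feature_ids: Sequence = None

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size < 1:
            raise InvalidInputError("scores must be a non-empty 1-d vector")
        if np.any(scores < -1e-12) or np.any(scores > 1 + 1e-12):
            raise InvalidInputError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", np.clip(scores, 0.0, 1.0))
        ids = self.feature_ids
        if ids is None:
            ids = tuple(range(scores.size))
        else:
            ids = tuple(ids)
            if len(ids) != scores.size:
                raise InvalidInputError(
                    f"{len(ids)} feature ids for {scores.size} scores"
                )
        object.__setattr__(self, "feature_ids", ids)

    @property
    def n_features(self) -> int:
        return self.scores.size

    def ranking(self) -> list:
        """Feature ids by decreasing score; ties broken by ascending index."""
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        return [self.feature_ids[i] for i in order]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of thresholding a :class:`CorrelationProfile`.

    ``selected`` lists the surviving feature ids in the profile's column
    order; ``ranking`` is the full score ordering.  ``selected_indices``
    gives the surviving 0-based column positions for slicing a matrix.
    """

    threshold: float
    selected: tuple
    selected_indices: tuple
    ranking: tuple
    scores: np.ndarray = field(repr=False)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def is_empty(self) -> bool:
        return len(self.selected) == 0


def pearson_profile(X, y, feature_ids=None) -> CorrelationProfile:
    """Absolute Pearson correlation of every feature column with the response.

    Constant columns (zero variance) score 0 with a logged warning, mirroring
    the degenerate convention of the distance-correlation profile.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.ndim != 2 or ya.ndim != 1 or Xa.shape[0] != ya.size:
        raise InvalidInputError(
            f"X {getattr(Xa, 'shape', None)} and y {ya.shape} are not conformable"
        )
    if ya.size < 3:
        raise InvalidInputError("need at least 3 observations for a Pearson profile")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
        raise InvalidInputError("inputs contain non-finite values")

    yc = ya - ya.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = Xa - Xa.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    degenerate = (sx == 0.0) | (sy == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / (sx * sy)
    r[degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "pearson_profile: %d constant column(s) scored 0", int(degenerate.sum())
        )
    return CorrelationProfile(
        method="CC", scores=np.clip(r, 0.0, 1.0), feature_ids=feature_ids
    )


def _filter(profile: CorrelationProfile, threshold: float) -> FilterResult:
    keep = np.flatnonzero(profile.scores >= threshold)
    return FilterResult(
        threshold=float(threshold),
        selected=tuple(profile.feature_ids[i] for i in keep),
        selected_indices=tuple(int(i) for i in keep),
        ranking=tuple(profile.ranking()),
        scores=profile.scores,
    )


def select_features(profile: CorrelationProfile, threshold: float) -> FilterResult:
    """Keep every feature whose score is >= ``threshold`` (inclusive).

    Raises
    ------
    NoFeaturesSurviveError
        If the selection is empty — no forest could be grown downstream.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError(f"threshold must be in [0, 1], got {threshold}")
    result = _filter(profile, threshold)
    if result.is_empty:
        raise NoFeaturesSurviveError(threshold, float(profile.scores.max()))
    return result


def sweep_thresholds(
    profile: CorrelationProfile, thresholds
) -> list[FilterResult]:
    """Apply an ascending grid of thresholds to one profile.

    Unlike :func:`select_features`, thresholds that empty the selection do
    not abort the sweep: they yield a :class:`FilterResult` with
    ``is_empty`` set, so downstream tables can record them as NA.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("thresholds must be a non-empty 1-d vector")
    if np.any(t < 0) or np.any(t > 1):
        raise InvalidInputError("thresholds must lie in [0, 1]")
    if np.any(np.diff(t) < 0):
        raise InvalidInputError("thresholds must be sorted ascending")
    results = []
    for ti in t:
        res = _filter(profile, float(ti))
        if res.is_empty:
            logger.info(
                "sweep: threshold %.3g empties the %s selection (max score %.4g)",
                ti,
                profile.method,
                float(profile.scores.max()),
            )
        results.append(res)
    return results
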