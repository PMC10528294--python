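"""Breiman random-forest regression on a (possibly filtered) feature set.

The tree ensemble itself is scikit-learn's ``RandomForestRegressor``
(bootstrap resamples, random feature subset per split).  Everything layered
on top is specific to the screening workflow:

* ``mtry`` is resolved from the *reduced* feature count p* (the forest is
  grown on the filtered design), as ``max(1, floor(mtry_fraction * p*))``;
* out-of-bag (OOB) bookkeeping reconstructs each tree's bootstrap sample
  from its integer ``random_state`` the same way scikit-learn draws it, so
  per-tree OOB membership is available for importance estimation;
* the permutation variable importance is the ratio

      VI_j = E[(fhat(..., Xtilde_j, ...) - fhat(..., X_j, ...))^2]
             / E[(Y - fhat(..., Xtilde_j, ...))^2]

  with both expectations taken over the out-of-bag predictions and
  ``Xtilde_j`` a random permutation of column j.  Note the denominator is
  the *post-permutation* squared error — this normalization is implemented
  exactly as defined, even though most software divides by nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .exceptions import InvalidInputError, NoFeaturesSurviveError

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "FittedForest",
    "ImportanceReport",
    "fit_forest",
    "predict_mse",
    "permutation_importance",
]


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the regression forest.

    Defaults follow the de-facto standard for Breiman-style regression
    forests: 500 trees, mtry = floor(p*/3), minimum terminal-node size 5,
    bootstrap samples of size n.
    """

    n_trees: int = 500
    mtry_fraction: float = 1.0 / 3.0
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise InvalidInputError("n_trees must be >= 1")
        if not 0.0 < self.mtry_fraction <= 1.0:
            raise InvalidInputError("mtry_fraction must be in (0, 1]")
        if self.min_node_size < 1:
            raise InvalidInputError("min_node_size must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        return max(1, floor(self.mtry_fraction * p))


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature permutation importance estimates VI_j.

    Entries are NaN where no out-of-bag prediction was available.
    """

    vi: np.ndarray
    feature_ids: tuple
    n_permutations: int


@dataclass
class FittedForest:
    """A trained forest plus the bookkeeping needed for OOB estimates."""

    model: RandomForestRegressor
    feature_ids: tuple
    config: ForestConfig
    n_train: int
    _oob_masks: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def p_star(self) -> int:
        return len(self.feature_ids)

    def _check_columns(self, X) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim != 2 or Xa.shape[1] != self.p_star:
            raise InvalidInputError(
                f"expected {self.p_star} feature columns, got shape {Xa.shape}"
            )
        return Xa

    def predict(self, X) -> np.ndarray:
        return self.model.predict(self._check_columns(X))

    def oob_masks(self) -> np.ndarray:
        """Boolean (n_trees, n_train) matrix: True where a row is out of bag.

        Reconstructs each tree's bootstrap indices from its integer
        ``random_state`` exactly as scikit-learn draws them (n draws with
        replacement from range(n)).
        """
        if self._oob_masks is None:
            n = self.n_train
            masks = np.ones((len(self.model.estimators_), n), dtype=bool)
            for t, tree in enumerate(self.model.estimators_):
                idx = np.random.RandomState(tree.random_state).randint(0, n, n)
                masks[t, idx] = False
            self._oob_masks = masks
        return self._oob_masks

    def oob_predict(self, X) -> np.ndarray:
        """Per-row predictions averaged over the trees for which the row is
        out of bag.  ``X`` must be row-aligned with the training data.
        Rows in no tree's OOB set come back NaN.
        """
        Xa = self._check_columns(X)
        if Xa.shape[0] != self.n_train:
            raise InvalidInputError(
                "oob_predict needs a matrix row-aligned with the training data"
            )
        masks = self.oob_masks()
        total = np.zeros(self.n_train)
        count = np.zeros(self.n_train)
        for t, tree in enumerate(self.model.estimators_):
            oob = masks[t]
            if not oob.any():
                continue
            total[oob] += tree.predict(Xa[oob])
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            out = total / count
        out[count == 0] = np.nan
        return out


def fit_forest(X, y, cfg: ForestConfig, feature_ids: Sequence = None) -> FittedForest:
    """Grow a regression forest on the (already filtered) training matrix.

    ``feature_ids`` records which original columns the matrix holds; the
    fitted model only accepts matrices with exactly those columns.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.ndim != 2:
        raise InvalidInputError(f"X must be 2-dimensional, got shape {Xa.shape}")
    n, p = Xa.shape
    if p == 0:
        raise NoFeaturesSurviveError(threshold=float("nan"), max_score=float("nan"))
    if n < 5:
        raise InvalidInputError(f"need at least 5 training rows, got {n}")
    if ya.shape != (n,):
        raise InvalidInputError("y must be a vector matching the rows of X")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(range(p))
    if len(ids) != p:
        raise InvalidInputError(f"{len(ids)} feature ids for {p} columns")

    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolved_mtry(p),
        min_samples_leaf=cfg.min_node_size,
        bootstrap=True,
        random_state=int(cfg.seed),
        n_jobs=1,
    )
    model.fit(Xa, ya)
    return FittedForest(model=model, feature_ids=ids, config=cfg, n_train=n)


def predict_mse(model: FittedForest, X_test, y_test) -> float:
    """Mean squared prediction error on held-out data."""
    yhat = model.predict(X_test)
    ya = np.asarray(y_test, dtype=float)
    if ya.shape != yhat.shape:
        raise InvalidInputError("y_test does not match the number of test rows")
    return float(np.mean((ya - yhat) ** 2))


def permutation_importance(
    model: FittedForest,
    X,
    y,
    n_permutations: int = 1,
    seed: int = 0,
) -> ImportanceReport:
    """Out-of-bag permutation importance VI_j for every trained-on feature.

    For each feature j and each of ``n_permutations`` independent
    permutations, column j of the training matrix is shuffled, OOB
    predictions are recomputed, and the ratio

        mean_i (fhat_perm(i) - fhat(i))^2 / mean_i (y_i - fhat_perm(i))^2

    is taken over rows with OOB coverage; the VI_j estimate is the average
    of the ratio over permutations.  A feature the trees never split on
    leaves predictions unchanged, so its numerator — and VI — is zero.
    """
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    Xa = model._check_columns(X)
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != model.n_train or ya.shape != (model.n_train,):
        raise InvalidInputError("X, y must be the training data, row-aligned")

    rng = np.random.default_rng(seed)
    base = model.oob_predict(Xa)
    covered = ~np.isnan(base)
    if not covered.any():
        logger.warning("permutation_importance: no OOB coverage at all")
        return ImportanceReport(
            vi=np.full(model.p_star, np.nan),
            feature_ids=model.feature_ids,
            n_permutations=n_permutations,
        )

    vi = np.zeros(model.p_star)
    for j in range(model.p_star):
        ratios = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = Xa.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_pred = model.oob_predict(Xp)
            num = np.mean((perm_pred[covered] - base[covered]) ** 2)
            den = np.mean((ya[covered] - perm_pred[covered]) ** 2)
            ratios[r] = num / den if den > 0 else 0.0
        vi[j] = ratios.mean()
    return ImportanceReport(
        vi=vi, feature_ids=model.feature_ids, n_permutations=n_permutations
    )
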