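"""Seeded synthetic data for the screening benchmark designs.

Four design distributions ("settings") and three response surfaces
("models") are provided:

* Setting 1 — multivariate normal, AR(1) covariance Sigma_ij = rho^|i-j|
  (rho typically 0.5 or 0.8);
* Setting 2 — the AR(1) covariance plus 0.2 on every off-diagonal entry
  (rho = 0.5 nominally; any rho is accepted if the matrix stays positive
  definite);
* Setting 3 — AR(1) again, used with rho = 0.8 and the nonlinear Model 2;
* Setting 4 — independent Unif[0, 1] entries.

Responses (errors are always i.i.d. N(0, 1)):

* Model 1 (linear):     y = 5 X1 + X2 + X3 + X4 + eps
* Model 2 (nonlinear):  y = X1^2 + X20 + X33^3 + X55^2 + eps
* Model 3 (nonlinear):  y = 100 (X1 - 0.5)^2 (X2 - 0.25)_+ + eps,
  the benchmark hinge function on the uniform cube; (.)_+ is the
  positive part.

All randomness flows through ``numpy.random.SeedSequence`` sub-streams
derived from one master seed: the design and noise draws of the training
and test splits are independent, so changing ``n_test`` never perturbs the
training data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidConfigurationError, InvalidInputError

__all__ = [
    "SimulationSetting",
    "Dataset",
    "ar1_covariance",
    "setting2_covariance",
    "draw_design",
    "response",
    "generate",
    "MODEL_SIGNAL_FEATURES",
]

# 0-based column indices carrying signal, per response model
MODEL_SIGNAL_FEATURES = {1: (0, 1, 2, 3), 2: (0, 19, 32, 54), 3: (0, 1)}

_MIN_P = {1: 4, 2: 55, 3: 2}


@dataclass(frozen=True)
class SimulationSetting:
    """Fully determines a synthetic dataset distribution (plus its seed).

    ``rho`` is ignored for setting 4 (uniform design).  The canonical
    pairings are (model 1, settings 1-2), (model 2, setting 3) and
    (model 3, setting 4), but any combination is accepted for exploration.
    """

    model: int
    setting: int
    p: int
    rho: Optional[float] = None
    n_train: int = 200
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.model not in (1, 2, 3):
            raise InvalidConfigurationError(f"unknown model {self.model}")
        if self.setting not in (1, 2, 3, 4):
            raise InvalidConfigurationError(f"unknown setting {self.setting}")
        if self.p < _MIN_P[self.model]:
            raise InvalidConfigurationError(
                f"model {self.model} needs p >= {_MIN_P[self.model]}, got {self.p}"
            )
        if self.setting != 4:
            if self.rho is None:
                raise InvalidConfigurationError(
                    f"setting {self.setting} requires rho"
                )
            if not abs(self.rho) < 1:
                raise InvalidConfigurationError(f"|rho| must be < 1, got {self.rho}")
        if self.n_train < 1 or self.n_test < 1:
            raise InvalidConfigurationError("sample sizes must be positive")

    def with_seed(self, seed: int) -> "SimulationSetting":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Dataset:
    """One split (train or test) of a generated dataset."""

    X: np.ndarray
    y: np.ndarray
    setting: SimulationSetting
    split: str  # {"train", "test"}

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """AR(1) covariance matrix: entry (i, j) = rho^|i-j|, unit diagonal.

    Positive definite for every |rho| < 1.
    """
    if p < 1:
        raise InvalidInputError("p must be >= 1")
    if not abs(rho) < 1:
        raise InvalidInputError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def setting2_covariance(p: int, rho: float = 0.5) -> np.ndarray:
    """AR(1) covariance plus a constant 0.2 on every off-diagonal entry.

    Verified positive definite before use (it is at the nominal rho = 0.5;
    other rho values may break it, in which case an error names the
    offending smallest eigenvalue).
    """
    sigma = ar1_covariance(p, rho) + 0.2 * (1 - np.eye(p))
    _assert_pd(sigma, f"setting-2 covariance (p={p}, rho={rho})")
    return sigma


def _assert_pd(sigma: np.ndarray, label: str) -> None:
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        lam = float(np.linalg.eigvalsh(sigma)[0])
        raise InvalidConfigurationError(
            f"{label} is not positive definite (smallest eigenvalue {lam:.3e})"
        ) from None


def _covariance_for(setting: SimulationSetting) -> Optional[np.ndarray]:
    if setting.setting in (1, 3):
        return ar1_covariance(setting.p, setting.rho)
    if setting.setting == 2:
        return setting2_covariance(setting.p, setting.rho)
    return None  # setting 4: uniform, no covariance


def draw_design(setting: SimulationSetting, n: int, rng=None) -> np.ndarray:
    """Draw an (n, p) design matrix from the setting's distribution.

    Settings 1-3 use a Cholesky factor of the covariance (computed once per
    call); setting 4 fills the matrix with independent Unif[0, 1] entries.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(setting.seed if rng is None else rng)
    if setting.setting == 4:
        return rng.random((n, setting.p))
    sigma = _covariance_for(setting)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise InvalidConfigurationError(f"covariance factorization failed: {exc}")
    return rng.standard_normal((n, setting.p)) @ chol.T


def response(model: int, X, noise_seed=None) -> np.ndarray:
    """Evaluate a response surface on a design matrix and add N(0,1) noise.

    ``noise_seed`` may be anything ``numpy.random.default_rng`` accepts
    (including an existing Generator); ``None`` draws unseeded noise.  The
    noiseless regression function is exposed separately as :func:`surface`.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2:
        raise InvalidInputError(f"X must be 2-dimensional, got shape {Xa.shape}")
    if not np.all(np.isfinite(Xa)):
        raise InvalidInputError("X contains non-finite values")
    if Xa.shape[1] < _MIN_P[model]:
        raise InvalidConfigurationError(
            f"model {model} needs p >= {_MIN_P[model]}, got {Xa.shape[1]}"
        )
    rng = np.random.default_rng(noise_seed)
    return surface(model, Xa) + rng.standard_normal(Xa.shape[0])


def surface(model: int, X) -> np.ndarray:
    """The noiseless regression function f(x) of each model."""
    Xa = np.asarray(X, dtype=float)
    if model == 1:
        return 5 * Xa[:, 0] + Xa[:, 1] + Xa[:, 2] + Xa[:, 3]
    if model == 2:
        return Xa[:, 0] ** 2 + Xa[:, 19] + Xa[:, 32] ** 3 + Xa[:, 54] ** 2
    if model == 3:
        return 100.0 * (Xa[:, 0] - 0.5) ** 2 * np.maximum(Xa[:, 1] - 0.25, 0.0)
    raise InvalidConfigurationError(f"unknown model {model}")


def generate(setting: SimulationSetting) -> tuple[Dataset, Dataset]:
    """Draw seeded, independent train and test splits of one setting.

    Four independent sub-streams (train design, train noise, test design,
    test noise) are spawned from the master seed, so the two splits share
    no randomness.
    """
    ss = np.random.SeedSequence(setting.seed)
    design_tr, noise_tr, design_te, noise_te = ss.spawn(4)
    X_train = draw_design(setting, setting.n_train, np.random.default_rng(design_tr))
    y_train = response(setting.model, X_train, noise_tr)
    X_test = draw_design(setting, setting.n_test, np.random.default_rng(design_te))
    y_test = response(setting.model, X_test, noise_te)
    return (
        Dataset(X=X_train, y=y_train, setting=setting, split="train"),
        Dataset(X=X_test, y=y_test, setting=setting, split="test"),
    )
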