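"""Smoothed linear cursor velocity decoder.

The decoder maps a normalized neural feature vector ``f_t`` to a 2-D cursor
velocity through a linear decoding matrix with exponential temporal
smoothing,

    v_t = alpha * v_{t-1} + (1 - alpha) * beta * D f_t,

followed by a nonlinear speed adjustment that preserves direction while
remapping speed through s(|v|) = r * (|v| / r)**p — slow movements become
slower and fast movements faster, with ``r`` the crossover speed and
``p >= 1`` the adjustment strength (``p = 1`` is the identity).

Training relabels calibration data with intention estimation (the user is
assumed to always intend motion toward the cued target) and fits ``D`` by
ridge regression; after fitting, ``D`` is rescaled so the mean predicted
speed over the training set is 1, which makes the speed gain ``beta``
interpretable in screen heights per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CursorVelocityDecoder",
    "VelocityState",
    "speed_adjust",
    "estimate_intent",
    "build_intent_dataset",
]


@dataclass
class VelocityState:
    """Velocity carried between bins by the smoothing recursion."""

    v_prev: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def reset(self) -> None:
        self.v_prev = np.zeros(2)


def speed_adjust(v: np.ndarray, r: float, p: float) -> np.ndarray:
    """Nonlinear speed adjustment: direction preserved, speed s(|v|)=r(|v|/r)^p.

    Speeds below the crossover ``r`` are slowed, speeds above are sped up
    (for p > 1); zero velocity maps to zero.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if p < 1:
        raise ValueError("p must be >= 1")
    v = np.asarray(v, dtype=float)
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return np.zeros_like(v)
    return v * (r * (speed / r) ** p / speed)


def estimate_intent(
    cursor_pos: np.ndarray,
    target_pos: np.ndarray,
    mode: str = "unit_vector",
    near_radius: float = 0.06,
) -> tuple[np.ndarray, bool]:
    """Intention-estimation label for one time bin.

    ``unit_vector`` mode assumes constant intended speed: the label is the
    unit vector toward the target, and bins with the cursor within
    ``near_radius`` of the target are excluded from regression.
    ``position_error`` mode assumes intended speed scales with distance: the
    label is the raw displacement ``target - cursor`` and every bin is
    included.

    Returns ``(intended_velocity, include_flag)``.
    """
    cursor_pos = np.asarray(cursor_pos, float)
    target_pos = np.asarray(target_pos, float)
    err = target_pos - cursor_pos
    if mode == "position_error":
        return err, True
    if mode != "unit_vector":
        raise ValueError(f"unknown intention mode {mode!r}")
    dist = float(np.linalg.norm(err))
    if dist < near_radius or dist == 0.0:
        return np.zeros(2), False
    return err / dist, True


def build_intent_dataset(
    features: np.ndarray,
    cursor_pos: np.ndarray,
    target_pos: np.ndarray,
    mode: str = "unit_vector",
    near_radius: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intention labels over a stream; returns (X, y) of included bins."""
    features = np.asarray(features, float)
    err = np.asarray(target_pos, float) - np.asarray(cursor_pos, float)
    dist = np.linalg.norm(err, axis=1)
    if mode == "position_error":
        return features, err
    include = dist >= near_radius
    y = np.zeros_like(err)
    y[include] = err[include] / dist[include, None]
    return features[include], y[include]


class CursorVelocityDecoder(RegressorMixin, BaseEstimator):
    """Linear velocity decoder with temporal smoothing and speed adjustment.

    Parameters
    ----------
    alpha : float in [0, 1)
        Smoothing weight on the previous bin's velocity.  Higher is smoother
        but slower to change direction.
    beta : float > 0
        Speed gain in screen heights per second (applies at inference only).
    r : float > 0
        Crossover speed (screen heights/s) of the nonlinear speed adjustment.
    p : float >= 1
        Speed-adjustment exponent; 1 disables the adjustment.
    ridge : float
        L2 penalty of the training regression.  Features are z-scored, so
        this is on the scale of the (unit-variance) features.
    normalize_gain : bool
        Rescale the decoding matrix after fitting so the mean predicted
        speed over the training bins is 1 (``beta`` then carries the units).

    Attributes
    ----------
    coef_ : ndarray of shape (2, n_features)
        Decoding matrix ``D``.
    intercept_ : ndarray of shape (2,)
        Bias term (z-scored features keep it near zero, but click- or
        speech-locked baseline shifts make it worth fitting).
    """

    def __init__(
        self,
        alpha: float = 0.9,
        beta: float = 0.2,
        r: float = 1.0,
        p: float = 1.0,
        ridge: float = 1e-3,
        normalize_gain: bool = True,
    ):
        self.alpha = alpha
        self.beta = beta
        self.r = r
        self.p = p
        self.ridge = ridge
        self.normalize_gain = normalize_gain

    def _validate_params_(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.r <= 0 or self.p < 1:
            raise ValueError("require r > 0 and p >= 1")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CursorVelocityDecoder":
        """Fit the decoding matrix to (features, intended velocity) samples."""
        self._validate_params_()
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or y.shape != (X.shape[0], 2):
            raise ValueError("X must be (n, F) and y (n, 2)")
        if X.shape[0] < 2 or np.allclose(X, X[0]):
            raise ValueError("degenerate design: need >= 2 distinct samples")
        model = Ridge(alpha=self.ridge)
        model.fit(X, y)
        coef = model.coef_
        intercept = model.intercept_
        if self.normalize_gain:
            pred = X @ coef.T + intercept
            mean_speed = float(np.mean(np.linalg.norm(pred, axis=1)))
            if mean_speed > 0:
                coef = coef / mean_speed
                intercept = intercept / mean_speed
        self.coef_ = coef
        self.intercept_ = np.asarray(intercept, float)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw per-bin velocity predictions ``D f + b`` (no smoothing, no beta)."""
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return X @ self.coef_.T + self.intercept_

    def decode_step(self, state: VelocityState, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One bin of the closed-loop decode.

        Applies the smoothing recursion then the speed adjustment; updates
        ``state`` in place.  Returns ``(v_t, o_t)`` — the smoothed velocity
        and the speed-adjusted output actually applied to the cursor.
        """
        f = np.asarray(f, float).ravel()
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite feature vector")
        pred = self.predict(f[None, :])[0]
        v_t = self.alpha * state.v_prev + (1.0 - self.alpha) * self.beta * pred
        state.v_prev = v_t
        o_t = speed_adjust(v_t, self.r, self.p) if self.p != 1.0 else v_t
        return v_t, o_t

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "params": self.get_params(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CursorVelocityDecoder":
        obj = cls(**d["params"])
        obj.coef_ = np.asarray(d["coef"], float)
        obj.intercept_ = np.asarray(d["intercept"], float)
        obj.n_features_in_ = obj.coef_.shape[1]
        return obj
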