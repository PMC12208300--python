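"""Linear click classifier with temporal smoothing and cooldown.

Each 10 ms feature bin is scored by a two-class linear model (no-click vs
click).  A click is only *emitted* once a fraction ``T`` of the predicted
classes inside a sliding window of width ``L`` are 'click', and a cooldown
``C`` after each emitted click suppresses further output; both rules guard
against errant clicks from bin-level decoding noise.  Defaults follow the
operating point used online: T = 0.8, L = 70 ms, C = 1.0 s.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .features import BIN_S

__all__ = [
    "ClickClassifier",
    "ClickSmoother",
    "ClickEvent",
    "label_click_bins",
    "smooth_clicks",
]

NO_CLICK, CLICK = 0, 1
IGNORED = -1


@dataclass
class ClickEvent:
    """An emitted click, with the cursor/target relation at emission time."""

    bin_index: int
    on_target: bool | None = None


class ClickClassifier(ClassifierMixin, BaseEstimator):
    """Two-class linear click decoder (logistic regression).

    Scores are turned into class probabilities by the logistic (softmax)
    transform; a literal sum-to-one normalization of the raw scores is
    available via ``probability_mode='sum'`` for comparison but is not
    recommended (it is ill-defined for non-positive score sums).  Ties
    predict no-click.

    Attributes
    ----------
    coef_ : ndarray of shape (2, n_features)
        Decoding matrix with one row of scores per class (no-click, click);
        antisymmetric parametrization of the underlying binary fit.
    intercept_ : ndarray of shape (2,)
    """

    def __init__(self, C: float = 1.0, max_iter: int = 500, probability_mode: str = "softmax"):
        self.C = C
        self.max_iter = max_iter
        self.probability_mode = probability_mode

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClickClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        classes = np.unique(y)
        if not np.all(np.isin(classes, [NO_CLICK, CLICK])):
            raise ValueError("labels must be 0 (no-click) or 1 (click)")
        if classes.size < 2:
            raise ValueError("single-class data: cannot fit click classifier")
        model = LogisticRegression(C=self.C, max_iter=self.max_iter)
        model.fit(X, y)
        w = model.coef_[0]
        b = float(model.intercept_[0])
        self.coef_ = np.vstack([-w / 2.0, w / 2.0])
        self.intercept_ = np.array([-b / 2.0, b / 2.0])
        self.classes_ = np.array([NO_CLICK, CLICK])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, float))
        scores = X @ self.coef_.T + self.intercept_
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite classifier scores")
        return scores

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        if self.probability_mode == "sum":
            total = scores.sum(axis=1, keepdims=True)
            safe = np.abs(total) > 1e-12
            proba = np.full_like(scores, 0.5)
            np.divide(scores, total, out=proba, where=safe)
            return proba
        z = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class per bin; exact ties resolve to no-click."""
        proba = self.predict_proba(X)
        return (proba[:, CLICK] > proba[:, NO_CLICK]).astype(int)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "params": self.get_params(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClickClassifier":
        obj = cls(**d["params"])
        obj.coef_ = np.asarray(d["coef"], float)
        obj.intercept_ = np.asarray(d["intercept"], float)
        obj.classes_ = np.array([NO_CLICK, CLICK])
        obj.n_features_in_ = obj.coef_.shape[1]
        return obj


class ClickSmoother:
    """Temporal smoothing and cooldown over a stream of per-bin predictions.

    A click is emitted at the first bin where at least ``ceil(T * w)`` of the
    last ``w = L / bin`` predictions are 'click' and no click was emitted in
    the preceding ``C`` seconds.  After an emission the window is cleared, so
    the requirement re-arms from scratch.
    """

    def __init__(self, T: float = 0.8, L_ms: float = 70.0, C_s: float = 1.0, bin_s: float = BIN_S):
        if not 0 < T <= 1:
            raise ValueError("T must be in (0, 1]")
        w = L_ms / (bin_s * 1000.0)
        if w < 1 or abs(w - round(w)) > 1e-9:
            raise ValueError("L must be a positive multiple of the bin width")
        if C_s < 0:
            raise ValueError("C must be nonnegative")
        self.T = T
        self.L_ms = L_ms
        self.C_s = C_s
        self.bin_s = bin_s
        self.w = int(round(w))
        self.needed = math.ceil(T * self.w)
        self.cooldown_bins = int(round(C_s / bin_s))
        self.reset()

    def reset(self) -> None:
        self._window: deque[int] = deque(maxlen=self.w)
        self._last_click_bin: int | None = None

    def step(self, predicted_class: int, bin_index: int) -> bool:
        """Feed one bin's prediction; return True iff a click is emitted."""
        self._window.append(int(predicted_class))
        if (
            self._last_click_bin is not None
            and bin_index - self._last_click_bin < self.cooldown_bins
        ):
            return False
        if sum(self._window) >= self.needed:
            self._last_click_bin = bin_index
            self._window.clear()
            return True
        return False


def smooth_clicks(
    predictions: np.ndarray,
    T: float = 0.8,
    L_ms: float = 70.0,
    C_s: float = 1.0,
    bin_s: float = BIN_S,
    on_target: np.ndarray | None = None,
) -> list[ClickEvent]:
    """Run the smoother over a whole prediction stream; return emitted events."""
    sm = ClickSmoother(T, L_ms, C_s, bin_s)
    events = []
    for i, c in enumerate(np.asarray(predictions, int)):
        if sm.step(c, i):
            events.append(
                ClickEvent(i, bool(on_target[i]) if on_target is not None else None)
            )
    return events


def label_click_bins(
    on_target: np.ndarray,
    bin_s: float = BIN_S,
    window_start_s: float = 0.5,
    window_end_s: float = 1.0,
    min_stay_s: float = 0.5,
) -> np.ndarray:
    """Training labels for the click classifier from on-target telemetry.

    For each contiguous on-target episode lasting at least ``min_stay_s``,
    bins whose offset from entry falls in ``[window_start_s, window_end_s)``
    are labeled click (1); the episode's remaining on-target bins are
    ignored (-1).  On-target bins of shorter episodes are also ignored, and
    every off-target bin is labeled no-click (0).
    """
    on_target = np.asarray(on_target, bool)
    labels = np.where(on_target, IGNORED, NO_CLICK)
    n = len(on_target)
    start_b = int(round(window_start_s / bin_s))
    end_b = int(round(window_end_s / bin_s))
    min_b = int(round(min_stay_s / bin_s))
    i = 0
    while i < n:
        if on_target[i]:
            j = i
            while j < n and on_target[j]:
                j += 1
            if j - i >= min_b:
                labels[i + start_b : min(i + end_b, j)] = CLICK
            i = j
        else:
            i += 1
    return labels
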