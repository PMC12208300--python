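"""Neural feature extraction and preprocessing.

Turns multichannel broadband voltage into the two per-electrode features the
decoding stack consumes — threshold-crossing counts and spike band power
(SBP) — computed in 1 ms frames, aggregated into 10 ms bins, and normalized
(z-score, clip, electrode exclusion, noise gating) by a scikit-learn style
transformer.

Feature vector layout
---------------------
A population of ``E`` electrodes yields a ``2E``-dimensional feature vector
per bin: components ``[0, E)`` are threshold-crossing counts, components
``[E, 2E)`` are spike band power.  All downstream decoders use this layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: frames (1 ms) aggregated into one decoding bin (10 ms)
FRAMES_PER_BIN = 10
#: decoding bin width in seconds
BIN_S = 0.01

__all__ = [
    "RawVoltageBlock",
    "BinnedFeatures",
    "FeatureNormalizer",
    "bandpass_filter",
    "linear_regression_reference",
    "extract_frames",
    "bin_frames",
    "stack_features",
    "split_features",
    "feature_indices_for_electrodes",
]


@dataclass
class RawVoltageBlock:
    """A block of broadband voltage from a multi-array recording.

    Parameters
    ----------
    samples : ndarray of shape (n_electrodes, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.  Must be at least 10 kHz so the spike band
        (250–5000 Hz) is representable.
    array_ids : ndarray of shape (n_electrodes,)
        Array label per electrode (e.g. ``"d6v"``).  Electrodes of one array
        are referenced together.
    """

    samples: np.ndarray
    fs: float
    array_ids: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.array_ids = np.asarray(self.array_ids)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (electrodes x time)")
        if self.array_ids.shape[0] != self.samples.shape[0]:
            raise ValueError("array_ids length must match electrode count")
        if self.fs < 10_000:
            raise ValueError("sampling rate must be >= 10 kHz")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage block contains non-finite samples")
        if self.samples.shape[1] < 1:
            raise ValueError("empty voltage block")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]


@dataclass
class BinnedFeatures:
    """Binned neural features at 10 ms resolution.

    ``crossings[t, e]`` is the number of 1 ms frames within bin ``t`` in
    which electrode ``e``'s filtered voltage reached its threshold (an
    integer in ``[0, 10]``); ``sbp[t, e]`` is the mean squared filtered
    voltage (µV²) over the bin.
    """

    crossings: np.ndarray
    sbp: np.ndarray
    bin_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.crossings = np.asarray(self.crossings)
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.crossings.shape != self.sbp.shape:
            raise ValueError("crossings and sbp must have the same shape")
        if np.any(self.crossings < 0) or np.any(self.sbp < 0):
            raise ValueError("features must be nonnegative")
        if self.bin_index is None:
            self.bin_index = np.arange(self.crossings.shape[0])

    @property
    def n_bins(self) -> int:
        return self.crossings.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.crossings.shape[1]

    def vectors(self) -> np.ndarray:
        """Return the (n_bins, 2E) stacked feature matrix."""
        return stack_features(self.crossings, self.sbp)


def stack_features(crossings: np.ndarray, sbp: np.ndarray) -> np.ndarray:
    """Stack crossings and SBP into the canonical (n, 2E) feature layout."""
    return np.concatenate([np.asarray(crossings, float), np.asarray(sbp, float)], axis=-1)


def split_features(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`stack_features`."""
    X = np.asarray(X)
    n_e = X.shape[-1] // 2
    return X[..., :n_e], X[..., n_e:]


def feature_indices_for_electrodes(electrodes: np.ndarray, n_electrodes: int) -> np.ndarray:
    """Column indices (into a 2E-wide feature matrix) of the given electrodes.

    Returns the crossing columns followed by the SBP columns, preserving the
    canonical layout for the sub-population.
    """
    electrodes = np.asarray(electrodes, dtype=int)
    return np.concatenate([electrodes, electrodes + n_electrodes])


# ---------------------------------------------------------------------------
# Voltage-domain operations
# ---------------------------------------------------------------------------

def bandpass_filter(
    samples: np.ndarray,
    fs: float,
    low_hz: float = 250.0,
    high_hz: float = 5000.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth bandpass to the spike band.

    The upper edge is capped below Nyquist so reduced sampling rates (down
    to 10 kHz) remain usable; offline blocks are filtered zero-phase.
    """
    nyq = fs / 2.0
    high = min(high_hz, 0.99 * nyq)
    sos = _signal.butter(order, [low_hz, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        # pad ~3 cycles of the low edge so block-boundary transients settle
        padlen = int(min(np.asarray(samples).shape[-1] - 1, 3 * fs / low_hz))
        return _signal.sosfiltfilt(sos, samples, axis=-1, padlen=padlen)
    return _signal.sosfilt(sos, samples, axis=-1)


def linear_regression_reference(block: RawVoltageBlock) -> RawVoltageBlock:
    """Remove common noise by within-array linear regression referencing.

    For each electrode, the least-squares prediction of its signal from the
    other electrodes of the *same* array is subtracted.  Arrays are
    referenced independently.  If the predictor set for an electrode is
    rank-deficient, that electrode falls back to mean-across-array
    subtraction (logged).
    """
    out = np.empty_like(block.samples)
    for arr in np.unique(block.array_ids):
        idx = np.flatnonzero(block.array_ids == arr)
        if idx.size < 2:
            raise ValueError(f"array {arr!r} has fewer than 2 electrodes")
        sig = block.samples[idx]  # (m, T)
        for j, e in enumerate(idx):
            others = np.delete(sig, j, axis=0)
            A = others.T  # (T, m-1)
            y = sig[j]
            if np.linalg.matrix_rank(A) < min(A.shape):
                logger.warning(
                    "rank-deficient predictors for electrode %d; using mean-across-array reference", e
                )
                out[e] = y - others.mean(axis=0)
                continue
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            out[e] = y - A @ coef
    return RawVoltageBlock(out, block.fs, block.array_ids)


def extract_frames(
    block: RawVoltageBlock,
    threshold_multiplier: float = -4.5,
    prefiltered: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute 1 ms threshold-crossing and spike-band-power frames.

    Each electrode's threshold is ``threshold_multiplier`` times the RMS of
    its *filtered* signal over the block (the multiplier is negative, so the
    threshold sits below zero).  A crossing is registered in a 1 ms frame iff
    the filtered signal reaches (falls to or below) the threshold within that
    frame; SBP is the mean squared filtered voltage over the frame.

    Returns ``(crossings, sbp)`` arrays of shape (n_frames, n_electrodes);
    a trailing partial frame is dropped.
    """
    if threshold_multiplier >= 0:
        raise ValueError("threshold_multiplier must be negative")
    filt = block.samples if prefiltered else bandpass_filter(block.samples, block.fs)
    spf = int(round(block.fs * 0.001))  # samples per 1 ms frame
    n_frames = filt.shape[1] // spf
    if n_frames < 1:
        raise ValueError("block shorter than one 1 ms frame")
    filt = filt[:, : n_frames * spf]
    rms = np.sqrt(np.mean(filt**2, axis=1, keepdims=True))
    thresh = threshold_multiplier * rms  # (E, 1), negative
    framed = filt.reshape(filt.shape[0], n_frames, spf)
    # a silent electrode (RMS 0) has no threshold to reach
    crossings = ((framed.min(axis=2) <= thresh) & (rms > 0)).astype(int).T  # (n_frames, E)
    sbp = np.mean(framed**2, axis=2).T
    return crossings, sbp


def bin_frames(crossings: np.ndarray, sbp: np.ndarray) -> BinnedFeatures:
    """Aggregate 1 ms frames into 10 ms bins (sum crossings, average SBP).

    A trailing group of fewer than 10 frames is dropped and logged.
    """
    crossings = np.asarray(crossings)
    sbp = np.asarray(sbp, dtype=float)
    n_frames = crossings.shape[0]
    n_bins = n_frames // FRAMES_PER_BIN
    dropped = n_frames - n_bins * FRAMES_PER_BIN
    if dropped:
        logger.info("bin_frames: dropping %d trailing frame(s)", dropped)
    n_e = crossings.shape[1]
    c = crossings[: n_bins * FRAMES_PER_BIN].reshape(n_bins, FRAMES_PER_BIN, n_e)
    p = sbp[: n_bins * FRAMES_PER_BIN].reshape(n_bins, FRAMES_PER_BIN, n_e)
    return BinnedFeatures(c.sum(axis=1), p.mean(axis=1))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class FeatureNormalizer(TransformerMixin, BaseEstimator):
    """Z-score, clip and gate binned neural features.

    Fitting estimates the per-feature mean and standard deviation from the
    current training set and builds the electrode exclusion mask: electrodes
    whose mean crossing rate is below ``min_rate_hz`` during training, or
    whose features have zero variance, are excluded from both training and
    inference.  Transforming z-scores the retained features, clips them to
    ``[-clip, +clip]``, and applies a causal noise gate: if at least 4 of the
    last 5 raw bins on an electrode show a firing rate >= 500 Hz (5 or more
    crossings per 10 ms bin) or SBP >= 25 000 µV², both of that electrode's
    features are replaced by their training means (z = 0) for that bin.  The
    gate is inactive until 5 bins of history exist.

    Parameters
    ----------
    min_rate_hz : float, default 5.0
        Mean-firing-rate exclusion threshold.
    clip : float, default 5.0
        Clip bound in z-units.
    noise_rate_hz : float, default 500.0
        Per-bin firing-rate noise threshold.
    noise_sbp : float, default 25000.0
        Per-bin SBP noise threshold (µV²).
    bin_s : float, default 0.01
        Bin width in seconds (sets the rate conversion).
    min_bins : int, default 100
        Minimum training bins required to fit.
    """

    def __init__(
        self,
        min_rate_hz: float = 5.0,
        clip: float = 5.0,
        noise_rate_hz: float = 500.0,
        noise_sbp: float = 25_000.0,
        bin_s: float = BIN_S,
        min_bins: int = 100,
    ):
        self.min_rate_hz = min_rate_hz
        self.clip = clip
        self.noise_rate_hz = noise_rate_hz
        self.noise_sbp = noise_sbp
        self.bin_s = bin_s
        self.min_bins = min_bins

    def fit(self, X: np.ndarray, y=None) -> "FeatureNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n_bins, 2*n_electrodes)")
        if X.shape[0] < self.min_bins:
            raise ValueError(f"need >= {self.min_bins} training bins, got {X.shape[0]}")
        n_e = X.shape[1] // 2
        crossings = X[:, :n_e]
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        rate_hz = crossings.mean(axis=0) / self.bin_s
        excluded = rate_hz < self.min_rate_hz
        # zero-variance features keep a unit-std surrogate: their z-score is 0
        # at every training value, so they carry no information but no NaNs
        if excluded.all():
            raise ValueError("all electrodes excluded; population carries no usable signal")
        self.n_electrodes_ = n_e
        self.mean_ = mean
        self.std_ = std
        self.excluded_ = excluded
        self.retained_electrodes_ = np.flatnonzero(~excluded)
        self.retained_features_ = feature_indices_for_electrodes(self.retained_electrodes_, n_e)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray, history: np.ndarray | None = None) -> np.ndarray:
        """Normalize a contiguous stream of raw bins.

        ``X`` is (n_bins, 2E) raw features in stream order.  ``history`` may
        supply up to 5 raw bins preceding ``X`` so the noise gate carries
        across calls; without it, the gate warms up within ``X``.
        Returns (n_bins, 2 * n_retained).
        """
        check_is_fitted(self, "mean_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, expected {self.n_features_in_}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        n_e = self.n_electrodes_
        if history is not None and len(history):
            full = np.vstack([np.atleast_2d(history)[-5:], X])
            offset = full.shape[0] - X.shape[0]
        else:
            full, offset = X, 0
        hot = (full[:, :n_e] >= self.noise_rate_hz * self.bin_s) | (
            full[:, n_e:] >= self.noise_sbp
        )  # (n, E) bins that look like noise
        noisy = np.zeros_like(hot)
        n = full.shape[0]
        if n >= 5:  # gate needs 5 bins of history (including the current bin)
            cs = np.cumsum(hot, axis=0, dtype=int)
            win = cs[4:].copy()
            win[1:] -= cs[:-5]
            noisy[4:] = win >= 4
        noisy = noisy[offset:]
        std = np.where(self.std_ == 0, 1.0, self.std_)
        Z = (X - self.mean_) / std
        np.clip(Z, -self.clip, self.clip, out=Z)
        # mean substitution: both features of a noisy electrode -> z = 0
        noisy2 = np.concatenate([noisy, noisy], axis=1)
        Z[noisy2] = 0.0
        return Z[:, self.retained_features_]

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "mean_")
        return {
            "params": self.get_params(),
            "n_electrodes": int(self.n_electrodes_),
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "excluded": self.excluded_.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        obj = cls(**d["params"])
        n_e = d["n_electrodes"]
        obj.n_electrodes_ = n_e
        obj.mean_ = np.asarray(d["mean"], float)
        obj.std_ = np.asarray(d["std"], float)
        obj.excluded_ = np.asarray(d["excluded"], bool)
        obj.retained_electrodes_ = np.flatnonzero(~obj.excluded_)
        obj.retained_features_ = feature_indices_for_electrodes(obj.retained_electrodes_, n_e)
        obj.n_features_in_ = 2 * n_e
        return obj

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "FeatureNormalizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
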