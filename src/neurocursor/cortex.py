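"""Synthetic neural population and simulated user.

Generates 10 ms binned feature streams with the statistical structure the
decoding stack assumes, so the closed loop runs without real recordings:

* Poisson threshold-crossing counts with rectified cosine directional
  tuning — unit rate ``max(0, b + d * (pd . dir) + g_click * click +
  g_speech * speaking)`` — and spike band power generated as a noisy affine
  function of the same rate, so both feature families carry information.
* Four 64-electrode arrays with heterogeneous directional information
  (dorsal 6v strong, area 4 moderate, ventral 6v weak, 55b essentially
  untuned) and click modulation present on every array, emulating the
  spatial structure seen in ventral-precentral-gyrus recordings.
* Optional speech-locked modulation on a subset of units (overlapping the
  directionally tuned ones) to model interference from speaking.

A :class:`SimulatedUser` converts task state into a movement/click/speech
intent with a reaction delay, a stop radius around the target, and a hold
delay before click intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .features import BIN_S, stack_features

__all__ = [
    "ARRAY_NAMES",
    "PopulationSpec",
    "SyntheticPopulation",
    "UserIntent",
    "SimulatedUser",
    "synthetic_voltage_block",
]

#: array labels: mid-precentral 55b, dorsal/ventral premotor 6v, primary motor 4
ARRAY_NAMES = ("55b", "d6v", "v6v", "4")

DEFAULT_DIRECTION_MULT = {"d6v": 1.0, "4": 0.5, "v6v": 0.2, "55b": 0.02}


@dataclass
class PopulationSpec:
    """Generative parameters of the synthetic population.

    Per-unit baselines and directional depths are drawn uniformly from the
    given ranges; directional depth is scaled per array by
    ``direction_mult`` to plant the array heterogeneity.  Click gains are
    planted on a random ``click_frac`` of units per array with equal
    strength across arrays; speech gains likewise on ``speech_frac`` of
    units (disabled by default).
    """

    n_per_array: int = 64
    arrays: tuple[str, ...] = ARRAY_NAMES
    direction_mult: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTION_MULT))
    baseline_hz: tuple[float, float] = (8.0, 40.0)
    depth_hz: tuple[float, float] = (10.0, 30.0)
    click_gain_hz: tuple[float, float] = (15.0, 40.0)
    click_frac: float = 0.3
    # strong speech-locked modulation: when enabled, the decoded perturbation
    # while speaking is on the order of a full-speed movement command
    speech_gain_hz: tuple[float, float] = (40.0, 100.0)
    speech_frac: float = 0.0
    sbp_base: float = 40.0
    sbp_per_count: float = 120.0
    sbp_noise: float = 25.0
    seed: int = 0

    @property
    def n_electrodes(self) -> int:
        return self.n_per_array * len(self.arrays)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["arrays"] = list(self.arrays)
        d["baseline_hz"] = list(self.baseline_hz)
        d["depth_hz"] = list(self.depth_hz)
        d["click_gain_hz"] = list(self.click_gain_hz)
        d["speech_gain_hz"] = list(self.speech_gain_hz)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("arrays", "baseline_hz", "depth_hz", "click_gain_hz", "speech_gain_hz"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class UserIntent:
    """What the simulated user is trying to do in one bin.

    ``speech_vec`` is a unit vector in a 2-D articulator space identifying
    the word being spoken; speech-tuned units respond through a rectified
    cosine against their own articulatory preferred direction, so different
    words perturb different neural dimensions.
    """

    direction: np.ndarray = field(default_factory=lambda: np.zeros(2))
    click: bool = False
    speaking: bool = False
    speech_vec: np.ndarray | None = None


class SyntheticPopulation:
    """A population of cosine-tuned Poisson units across four arrays."""

    def __init__(self, spec: PopulationSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        n = spec.n_electrodes
        self.baseline = rng.uniform(*spec.baseline_hz, size=n)
        theta = rng.uniform(0, 2 * np.pi, size=n)
        self.pd = np.column_stack([np.cos(theta), np.sin(theta)])
        self.array_ids = np.repeat(list(spec.arrays), spec.n_per_array)
        mult = np.array([spec.direction_mult.get(a, 1.0) for a in self.array_ids])
        self.depth = rng.uniform(*spec.depth_hz, size=n) * mult
        self.click_gain = np.zeros(n)
        self.speech_gain = np.zeros(n)
        for a in spec.arrays:
            idx = np.flatnonzero(self.array_ids == a)
            k = int(round(spec.click_frac * idx.size))
            chosen = rng.choice(idx, size=k, replace=False)
            self.click_gain[chosen] = rng.uniform(*spec.click_gain_hz, size=k)
        speech_theta = rng.uniform(0, 2 * np.pi, size=n)
        self.speech_pd = np.column_stack([np.cos(speech_theta), np.sin(speech_theta)])
        if spec.speech_frac > 0:
            # speech modulation preferentially lands on directionally tuned units,
            # so speaking perturbs the same dimensions the cursor decoder reads out
            order = np.argsort(-self.depth)
            k = int(round(spec.speech_frac * n))
            chosen = order[:k]
            self.speech_gain[chosen] = rng.uniform(*spec.speech_gain_hz, size=k)
        self.sbp_coupling = spec.sbp_per_count * rng.uniform(0.7, 1.3, size=n)

    @property
    def n_electrodes(self) -> int:
        return self.spec.n_electrodes

    def electrodes_of(self, arrays) -> np.ndarray:
        """Electrode indices belonging to the given array label(s)."""
        if isinstance(arrays, str):
            arrays = [arrays]
        return np.flatnonzero(np.isin(self.array_ids, list(arrays)))

    def rates(self, intent: UserIntent) -> np.ndarray:
        lam = (
            self.baseline
            + self.depth * (self.pd @ np.asarray(intent.direction, float))
            + self.click_gain * float(intent.click)
        )
        if intent.speaking:
            if intent.speech_vec is None:
                lam = lam + self.speech_gain
            else:
                # signed cosine drive, like the directional term: words can
                # raise or suppress a unit's rate around baseline
                lam = lam + self.speech_gain * (
                    self.speech_pd @ np.asarray(intent.speech_vec, float)
                )
        return np.maximum(lam, 0.0)

    def generate_bin(self, intent: UserIntent, rng: np.random.Generator) -> np.ndarray:
        """One 10 ms bin of raw features, shape (2E,): counts then SBP."""
        lam = self.rates(intent)
        counts = np.minimum(rng.poisson(lam * BIN_S), 10)
        sbp = (
            self.spec.sbp_base
            + self.sbp_coupling * counts
            + rng.gamma(2.0, self.spec.sbp_noise, size=lam.size)
        )
        return stack_features(counts.astype(float), sbp)

    def generate_stream(
        self, intents: list[UserIntent], rng: np.random.Generator
    ) -> np.ndarray:
        return np.array([self.generate_bin(i, rng) for i in intents])


def synthetic_voltage_block(
    n_electrodes: int = 8,
    duration_s: float = 0.2,
    fs: float = 30_000.0,
    spike_rate_hz: float = 40.0,
    noise_uv: float = 10.0,
    seed: int = 0,
):
    """Small synthetic broadband block for exercising the voltage path.

    Band-limited Gaussian noise plus biphasic spike waveforms at Poisson
    times.  Returns a :class:`~neurocursor.features.RawVoltageBlock` with all
    electrodes assigned round-robin to the four standard arrays.
    """
    from .features import RawVoltageBlock, bandpass_filter

    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    noise = bandpass_filter(rng.normal(0, noise_uv, size=(n_electrodes, n)), fs)
    # biphasic spike template ~1 ms long
    t = np.arange(int(fs * 0.001))
    templ = -np.sin(np.pi * t / t.size) * np.exp(-3 * t / t.size)
    templ = templ / np.abs(templ).max()
    rms = np.sqrt(np.mean(noise**2, axis=1))
    for e in range(n_electrodes):
        n_spikes = rng.poisson(spike_rate_hz * duration_s)
        starts = rng.integers(0, n - t.size, size=n_spikes)
        amp = 6.0 * rms[e]
        for s in starts:
            noise[e, s : s + t.size] += amp * templ
    array_ids = np.array([ARRAY_NAMES[e % 4] for e in range(n_electrodes)])
    return RawVoltageBlock(noise, fs, array_ids)


class SimulatedUser:
    """Turns task state into a movement / click / speech intent.

    After ``reaction_s`` from each go cue (or target change) the user
    intends the unit direction toward the target; within ``stop_radius`` of
    the target the direction intent is zero, and in click tasks a click
    intent is raised once the cursor has been on the target for
    ``click_hold_s``.  A speak event sets the speaking flag for
    ``speak_duration_s``.
    """

    def __init__(
        self,
        reaction_s: float = 0.2,
        stop_radius: float = 0.06,
        click_hold_s: float = 0.3,
        speak_duration_s: float = 1.0,
    ):
        self.reaction_s = reaction_s
        self.stop_radius = stop_radius
        self.click_hold_s = click_hold_s
        self.speak_duration_s = speak_duration_s
        self._speaking_until = -np.inf
        self._speech_vec: np.ndarray | None = None

    def start_speaking(self, t: float, speech_vec: np.ndarray | None = None) -> None:
        self._speaking_until = t + self.speak_duration_s
        self._speech_vec = speech_vec

    def intent(
        self,
        t: float,
        cursor_pos: np.ndarray,
        target_pos: np.ndarray | None,
        go_time: float,
        on_target_since: float | None,
        wants_click: bool = False,
    ) -> UserIntent:
        speaking = t < self._speaking_until
        vec = self._speech_vec if speaking else None
        if target_pos is None or t < go_time + self.reaction_s:
            return UserIntent(np.zeros(2), False, speaking, vec)
        err = np.asarray(target_pos, float) - np.asarray(cursor_pos, float)
        dist = float(np.linalg.norm(err))
        if dist <= self.stop_radius:
            click = (
                wants_click
                and on_target_since is not None
                and t - on_target_since >= self.click_hold_s
            )
            return UserIntent(np.zeros(2), click, speaking, vec)
        return UserIntent(err / dist, False, speaking, vec)
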