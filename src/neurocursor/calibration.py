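"""Performance-gated rapid decoder calibration with assist fading.

A calibration run starts fully computer-assisted ('open loop': the cursor
drives itself to each cued target) while decoders retrain in the background
every few seconds on all data collected so far.  The background decoder is
applied to every incoming bin; the angle between its predicted velocity and
the cursor-to-target direction (chance 90°) is averaged over a recency-
weighted 20 s sliding window.  Once that average drops below 80° the
computer assist fades linearly, reaching zero ('closed loop', user-only
control) at 60°.  Assist never increases within a run.

Click calibration runs in parallel: with click assist on, the computer
registers a click after the cursor sits on the target for 1.5 s, while the
click decoder is evaluated in shadow; once, in a sliding window of 8
trials, at least 7 cued targets would have been clicked with at most 4
off-target clicks, click assist turns off for the rest of the session.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .click import ClickClassifier, ClickSmoother, label_click_bins
from .cortex import SimulatedUser, SyntheticPopulation
from .cursor import CursorVelocityDecoder, VelocityState, build_intent_dataset
from .features import BIN_S, FeatureNormalizer
from .session import Telemetry
from .tasks import Radial8Config, Radial8Task

__all__ = [
    "AssistState",
    "RollingErrorTracker",
    "CalibrationConfig",
    "CalibrationResult",
    "angular_error",
    "update_velocity_assist",
    "blend_assisted_velocity",
    "evaluate_click_assist",
    "run_calibration",
]


def angular_error(predicted_v, cursor_pos, target_pos) -> float:
    """Angle in degrees between a predicted velocity and the cursor-to-target
    direction; in [0, 180], with 90 the chance level for random directions.
    Raises if either vector is zero (callers skip those samples)."""
    v = np.asarray(predicted_v, float)
    d = np.asarray(target_pos, float) - np.asarray(cursor_pos, float)
    nv, nd = np.linalg.norm(v), np.linalg.norm(d)
    if nv == 0 or nd == 0:
        raise ValueError("zero vector: angular error undefined")
    c = float(np.clip(np.dot(v, d) / (nv * nd), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclass
class AssistState:
    """Velocity- and click-assist levels during calibration."""

    velocity_assist: float = 1.0
    click_assist: bool = True

    @property
    def phase(self) -> str:
        if self.velocity_assist >= 1.0:
            return "open_loop"
        if self.velocity_assist <= 0.0:
            return "closed_loop"
        return "transition"


class RollingErrorTracker:
    """Recency-weighted mean of angular errors over a sliding time window.

    Samples older than ``window_s`` are dropped; remaining samples get
    exponential weights with the configured half-life, so recent decoder
    performance dominates the average.
    """

    def __init__(self, window_s: float = 20.0, half_life_s: float = 5.0):
        self.window_s = window_s
        self.half_life_s = half_life_s
        self._t: deque[float] = deque()
        self._err: deque[float] = deque()

    def add(self, t: float, error_deg: float) -> None:
        self._t.append(t)
        self._err.append(float(error_deg))
        self._trim(t)

    def _trim(self, now: float) -> None:
        while self._t and now - self._t[0] > self.window_s:
            self._t.popleft()
            self._err.popleft()

    def __len__(self) -> int:
        return len(self._t)

    def weighted_mean(self, now: float) -> float:
        self._trim(now)
        if not self._t:
            raise ValueError("no samples in window")
        ages = now - np.asarray(self._t)
        w = np.exp2(-ages / self.half_life_s)
        return float(np.average(np.asarray(self._err), weights=w))


def update_velocity_assist(
    tracker_mean_deg: float,
    state: AssistState,
    full_assist_deg: float = 80.0,
    no_assist_deg: float = 60.0,
) -> AssistState:
    """Lower velocity assist according to the rolling angular error.

    The error maps linearly onto an assist level (1 at ``full_assist_deg``
    and above, 0 at ``no_assist_deg`` and below); the new level is the
    minimum of that and the previous level, so assist only ever decreases.
    """
    span = full_assist_deg - no_assist_deg
    mapped = float(np.clip((tracker_mean_deg - no_assist_deg) / span, 0.0, 1.0))
    state.velocity_assist = min(state.velocity_assist, mapped)
    return state


def blend_assisted_velocity(
    decoded_v, cursor_pos, target_pos, assist_level: float, assist_speed: float
) -> np.ndarray:
    """Weighted sum of the decoded velocity and a pull straight to the target."""
    if not 0.0 <= assist_level <= 1.0:
        raise ValueError("assist_level must be in [0, 1]")
    decoded_v = np.asarray(decoded_v, float)
    err = np.asarray(target_pos, float) - np.asarray(cursor_pos, float)
    dist = float(np.linalg.norm(err))
    pull = err / dist * assist_speed if dist > 0 else np.zeros(2)
    return (1.0 - assist_level) * decoded_v + assist_level * pull


def evaluate_click_assist(
    recent_trials: list[tuple[bool, int]], window: int = 8, min_hits: int = 7, max_off: int = 4
) -> bool:
    """Whether click assist should turn off, from shadow-decoded trials.

    ``recent_trials`` holds ``(target_clicked, n_off_target_clicks)`` per
    completed trial; the rule looks at the last ``window`` of them.  Returns
    True (assist off) when at least ``min_hits`` cued targets would have
    been clicked and the total off-target clicks is at most ``max_off``.
    """
    if len(recent_trials) < window:
        return False
    recent = recent_trials[-window:]
    hits = sum(1 for clicked, _ in recent if clicked)
    off = sum(n for _, n in recent)
    return hits >= min_hits and off <= max_off


# ---------------------------------------------------------------------------
# Calibration session
# ---------------------------------------------------------------------------

@dataclass
class CalibrationConfig:
    """Configuration of a Radial8 calibration run."""

    block_s: float = 180.0
    n_blocks: int = 1
    radial8: Radial8Config = field(
        default_factory=lambda: Radial8Config(selection="click")
    )
    # decoder parameters
    alpha: float = 0.9
    beta: float = 0.2
    r: float = 1.0
    p: float = 1.0
    ridge: float = 1e-3
    intent_mode: str = "unit_vector"  # unit_vector | position_error
    near_radius: float | None = None  # default: target radius
    # click decoder parameters
    click_enabled: bool = True
    T: float = 0.8
    L_ms: float = 70.0
    C_s: float = 1.0
    auto_click_dwell_s: float = 1.5
    # assist schedule
    full_assist_deg: float = 80.0
    no_assist_deg: float = 60.0
    tracker_window_s: float = 20.0
    tracker_half_life_s: float = 5.0
    eval_every_s: float = 1.0
    retrain_every_s: float = 2.5
    assist_speed: float | None = None  # default: beta
    min_train_bins: int = 100
    imagery: str = "right_hand_mouse"


@dataclass
class CalibrationResult:
    telemetry: Telemetry
    normalizer: FeatureNormalizer | None
    cursor_decoder: CursorVelocityDecoder | None
    click_decoder: ClickClassifier | None
    assist_zero_time: float | None
    first_closed_loop_success: float | None
    n_retrains: int
    final_assist: float
    click_assist_off_time: float | None


def run_calibration(
    config: CalibrationConfig,
    population: SyntheticPopulation,
    user: SimulatedUser | None = None,
    rng: np.random.Generator | None = None,
) -> CalibrationResult:
    """Run Radial8 calibration blocks end-to-end against a synthetic cortex.

    Orchestrates the full loop: synthetic feature generation, background
    retraining of both decoders every ``retrain_every_s`` on all data so far
    (normalization statistics are refit with each retraining), rolling
    angular-error evaluation every ``eval_every_s``, graded velocity-assist
    reduction, the binary click-assist rule, and hot decoder swaps
    mid-movement.  Returns the trained decoders and full telemetry.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(0)
    near_radius = cfg.near_radius if cfg.near_radius is not None else cfg.radial8.target_radius
    assist_speed = cfg.assist_speed if cfg.assist_speed is not None else cfg.beta
    if user is None:
        user = SimulatedUser(stop_radius=cfg.radial8.target_radius)

    task = Radial8Task(cfg.radial8, rng)
    n_bins = int(round(cfg.block_s * cfg.n_blocks / BIN_S))
    n_e = population.n_electrodes
    tel = Telemetry.allocate(n_bins, n_e, meta={
        "kind": "radial8_calibration",
        "array_ids": list(map(str, population.array_ids)),
        "bin_s": BIN_S,
        "imagery": cfg.imagery,
    })

    norm: FeatureNormalizer | None = None
    cdec: CursorVelocityDecoder | None = None
    kdec: ClickClassifier | None = None
    vstate = VelocityState()
    smoother = ClickSmoother(cfg.T, cfg.L_ms, cfg.C_s)
    tracker = RollingErrorTracker(cfg.tracker_window_s, cfg.tracker_half_life_s)
    assist = AssistState()

    pos = np.array([0.5, 0.5])
    raw_hist: deque[np.ndarray] = deque(maxlen=5)
    eval_bins = max(1, int(round(cfg.eval_every_s / BIN_S)))
    retrain_bins = max(1, int(round(cfg.retrain_every_s / BIN_S)))
    n_retrains = 0
    assist_zero_time = None
    click_off_time = None
    first_cl_success = None
    shadow_results: list[tuple[bool, int]] = []
    trial_shadow_hit = False
    trial_shadow_off = 0
    trial_min_assist = assist.velocity_assist

    for k in range(n_bins):
        t = k * BIN_S
        target = task.target_pos
        go_time = task.go_time

        intent = user.intent(
            t, pos, target, go_time, task.on_target_since, wants_click=task.wants_click
        )
        raw = population.generate_bin(intent, rng)

        pred = None
        o_t = np.zeros(2)
        v_t = np.zeros(2)
        f = None
        if norm is not None and cdec is not None:
            f = norm.transform(raw[None, :], history=np.array(raw_hist) if raw_hist else None)[0]
            pred = cdec.predict(f[None, :])[0]
            v_t, o_t = cdec.decode_step(vstate, f)
        raw_hist.append(raw)

        # rolling angular-error sample (skipped near the target, where the
        # toward-target direction is ill-conditioned and intent is to stop)
        if pred is not None:
            dist = float(np.linalg.norm(target - pos))
            if dist >= near_radius and np.linalg.norm(pred) > 0:
                tracker.add(t, angular_error(pred, pos, target))

        vel = blend_assisted_velocity(o_t, pos, target, assist.velocity_assist, assist_speed)
        pos = np.clip(pos + vel * BIN_S, 0.0, 1.0)

        on_target = task.on_target(pos)

        # click path: auto-click under click assist; decoded clicks once off.
        # The decoded stream also runs in shadow while assist is on, feeding
        # the assist-off rule.
        click_pred = -1
        shadow_emit = False
        if cfg.click_enabled and kdec is not None and f is not None:
            click_pred = int(kdec.predict(f[None, :])[0])
            shadow_emit = smoother.step(click_pred, k)
            if shadow_emit:
                if on_target:
                    trial_shadow_hit = True
                else:
                    trial_shadow_off += 1
        if cfg.click_enabled and assist.click_assist:
            since = task.on_target_since
            emit = (
                since is not None
                and t - since >= cfg.auto_click_dwell_s
                and task.wants_click
            )
        else:
            emit = shadow_emit

        completed = task.step(t, pos, emit)

        tel.record(
            k, t=t, raw=raw, cursor=pos, target=target, target_id=task.target_id,
            on_target=on_target, pred=pred, v=v_t, o=vel,
            assist=assist.velocity_assist, click_pred=click_pred,
            click_emitted=emit, trial_id=task._trial_count - 1, go_active=True,
        )

        trial_min_assist = min(trial_min_assist, assist.velocity_assist)
        if completed is not None:
            tel.trials.append(completed)
            if cfg.click_enabled:
                shadow_results.append((trial_shadow_hit, trial_shadow_off))
                if assist.click_assist and evaluate_click_assist(shadow_results):
                    assist.click_assist = False
                    click_off_time = t
                    tel.events.append({"t": t, "kind": "click_assist_off"})
            if (
                first_cl_success is None
                and completed.outcome == "success"
                and trial_min_assist <= 0.0
            ):
                first_cl_success = t
            trial_shadow_hit = False
            trial_shadow_off = 0
            trial_min_assist = assist.velocity_assist

        # periodic assist evaluation
        if (k + 1) % eval_bins == 0 and len(tracker):
            m = tracker.weighted_mean(t)
            prev = assist.velocity_assist
            update_velocity_assist(m, assist, cfg.full_assist_deg, cfg.no_assist_deg)
            if assist.velocity_assist <= 0.0 and prev > 0.0:
                assist_zero_time = t
                tel.events.append({"t": t, "kind": "closed_loop_reached"})

        # background retraining on all pooled data so far
        if (k + 1) % retrain_bins == 0 and k + 1 >= cfg.min_train_bins:
            raw_all = tel.raw_features[: k + 1]
            try:
                new_norm = FeatureNormalizer(min_bins=cfg.min_train_bins).fit(raw_all)
            except ValueError:
                continue
            F = new_norm.transform(raw_all)
            X, y = build_intent_dataset(
                F,
                tel.cursor_pos[: k + 1],
                tel.target_pos[: k + 1],
                mode=cfg.intent_mode,
                near_radius=near_radius,
            )
            if X.shape[0] >= 2:
                try:
                    new_cdec = CursorVelocityDecoder(
                        alpha=cfg.alpha, beta=cfg.beta, r=cfg.r, p=cfg.p, ridge=cfg.ridge
                    ).fit(X, y)
                except ValueError:
                    new_cdec = None
                if new_cdec is not None:
                    norm, cdec = new_norm, new_cdec
                    n_retrains += 1
                    tel.events.append({"t": t, "kind": "decoder_update"})
                    if cfg.click_enabled:
                        labels = label_click_bins(tel.on_target[: k + 1])
                        mask = labels >= 0
                        if mask.any() and np.unique(labels[mask]).size == 2:
                            kdec = ClickClassifier().fit(F[mask], labels[mask])

    tel.trim(n_bins)
    return CalibrationResult(
        telemetry=tel,
        normalizer=norm,
        cursor_decoder=cdec,
        click_decoder=kdec,
        assist_zero_time=assist_zero_time,
        first_closed_loop_success=first_cl_success,
        n_retrains=n_retrains,
        final_assist=assist.velocity_assist,
        click_assist_off_time=click_off_time,
    )
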