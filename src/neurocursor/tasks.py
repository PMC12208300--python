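"""Behavioral task state machines.

Three tasks drive calibration and evaluation:

* **Radial8** — center-out-and-back target acquisition on a ring of eight
  targets plus a center target; selection by continuous dwell or by click;
  10 s trial limit; no intertrial gap (the next cue is immediate).
* **Grid** — an N x N grid of square targets (6 x 6 or 14 x 14) for bitrate
  evaluation; any enabled cell can be selected (correct or not); a thin
  border around the grid and 1 px gaps between cells absorb clicks without
  selecting; the cell the cursor starts a trial on is disabled for 2 s or
  until the cursor leaves it.
* **Speech-and-cursor** — the Radial8 layout with word prompts and auditory
  beeps interleaved, producing the four conditions (verbal/control block x
  beep/no-beep trial) used to quantify speech interference.

Coordinates live in the unit square (screen heights), origin bottom-left.
All tasks expose the same stepping interface: ``step(t, cursor_pos, click)``
advances one bin and returns a completed :class:`TrialRecord` or ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Radial8Config",
    "GridConfig",
    "SpeechTaskConfig",
    "TrialRecord",
    "Radial8Task",
    "GridTask",
    "SpeechCursorTask",
    "radial8_sequence",
    "radial8_positions",
]

CENTER = np.array([0.5, 0.5])

DEFAULT_WORDS = (
    "kite", "shoe", "maze", "drum", "fern", "clock", "gem", "pond", "vast", "ripe",
)


@dataclass
class TrialRecord:
    trial_id: int
    target_id: int
    target_pos: tuple[float, float]
    t_start: float
    t_go: float
    t_end: float = float("nan")
    outcome: str = ""  # success | wrong_target | timeout
    acquisition_time: float = float("nan")
    events: list = field(default_factory=list)
    condition: dict = field(default_factory=dict)

    def add_event(self, t: float, kind: str, **extra) -> None:
        self.events.append({"t": round(float(t), 6), "kind": kind, **extra})


@dataclass
class Radial8Config:
    ring_radius: float = 0.35
    target_radius: float = 0.06
    cursor_radius: float = 0.02
    dwell_s: float = 0.8
    timeout_s: float = 10.0
    selection: str = "dwell"  # dwell | click


@dataclass
class GridConfig:
    n: int = 6
    border_px: float = 43.0
    gap_px: float = 1.0
    px_per_screen_height: float = 1080.0
    cursor_radius: float = 0.02
    timeout_s: float = 10.0
    start_disable_s: float = 2.0


@dataclass
class SpeechTaskConfig:
    ring_radius: float = 0.35
    target_radius: float = 0.06
    cursor_radius: float = 0.02
    dwell_s: float = 1.5
    timeout_s: float = 10.0
    delay_range_s: tuple[float, float] = (1.3, 1.7)
    beep_move_window_s: tuple[float, float] = (0.3, 2.0)
    beep_dwell_delay_s: float = 0.1
    intertrial_s: float = 1.0
    block_type: str = "verbal"  # verbal | control
    beep_prob: float = 0.5
    speak_reaction_s: float = 0.3
    words: tuple[str, ...] = DEFAULT_WORDS


def radial8_positions(ring_radius: float = 0.35) -> np.ndarray:
    """Positions of the 9 targets: index 0 is center, 1..8 the ring at 45°."""
    angles = np.deg2rad(np.arange(8) * 45.0)
    outer = CENTER + ring_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([CENTER, outer])


def radial8_sequence(rng: np.random.Generator) -> Iterator[int]:
    """Infinite center-out-and-back cue order.

    Alternates outer target and center; each consecutive run of eight outer
    cues is a random permutation of all eight.
    """
    while True:
        for k in rng.permutation(8):
            yield int(k) + 1
            yield 0


class Radial8Task:
    """Center-out-and-back target acquisition."""

    def __init__(self, config: Radial8Config, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.positions = radial8_positions(config.ring_radius)
        self._seq = radial8_sequence(rng)
        self._trial_count = 0
        self._trial: TrialRecord | None = None
        self._on_target_since: float | None = None
        self._begin_trial(0.0)

    # -- state the loop reads ------------------------------------------------

    @property
    def go_active(self) -> bool:
        return True

    @property
    def go_time(self) -> float:
        return self._trial.t_go if self._trial else float("inf")

    @property
    def target_id(self) -> int:
        return self._trial.target_id if self._trial else -1

    @property
    def target_pos(self) -> np.ndarray:
        return np.asarray(self._trial.target_pos)

    @property
    def on_target_since(self) -> float | None:
        return self._on_target_since

    @property
    def wants_click(self) -> bool:
        return self.config.selection == "click"

    def on_target(self, pos: np.ndarray, target_id: int | None = None) -> bool:
        tid = self.target_id if target_id is None else target_id
        d = np.linalg.norm(np.asarray(pos, float) - self.positions[tid])
        return d <= self.config.target_radius + self.config.cursor_radius

    # -- stepping ------------------------------------------------------------

    def _begin_trial(self, t: float) -> None:
        tid = next(self._seq)
        self._trial = TrialRecord(
            trial_id=self._trial_count,
            target_id=tid,
            target_pos=tuple(self.positions[tid]),
            t_start=t,
            t_go=t,  # no delay period: cue is the go cue
        )
        self._trial.add_event(t, "go_cue", target=tid)
        self._trial_count += 1
        self._on_target_since = None

    def step(self, t: float, cursor_pos: np.ndarray, click: bool = False) -> TrialRecord | None:
        trial = self._trial
        cfg = self.config
        on = self.on_target(cursor_pos)
        if on and self._on_target_since is None:
            self._on_target_since = t
            trial.add_event(t, "target_enter")
        elif not on and self._on_target_since is not None:
            self._on_target_since = None
            trial.add_event(t, "target_exit")

        outcome = None
        if click:
            trial.add_event(t, "click", on_target=on)
            if cfg.selection == "click" and on:
                outcome = "success"
        if (
            cfg.selection == "dwell"
            and self._on_target_since is not None
            and t - self._on_target_since >= cfg.dwell_s
        ):
            outcome = "success"
        if outcome is None and t - trial.t_go >= cfg.timeout_s:
            outcome = "timeout"
        if outcome is None:
            return None

        trial.t_end = t
        trial.outcome = outcome
        trial.acquisition_time = t - trial.t_go
        trial.add_event(t, "selection" if outcome == "success" else "timeout")
        self._trial = None
        self._begin_trial(t)  # next cue is immediate
        return trial


class GridTask:
    """Grid target selection for bitrate evaluation."""

    def __init__(self, config: GridConfig, rng: np.random.Generator, start_pos=CENTER):
        self.config = config
        self.rng = rng
        sh = config.px_per_screen_height
        self.border = config.border_px / sh
        self.gap = config.gap_px / sh
        self.grid_lo = self.border
        self.grid_size = 1.0 - 2 * self.border
        self.cell = self.grid_size / config.n
        self._trial_count = 0
        self._trial: TrialRecord | None = None
        self._cursor = np.asarray(start_pos, float)
        self._start_cell: int | None = None
        self._left_start = False
        self._on_target_since: float | None = None
        self._begin_trial(0.0)

    @property
    def go_active(self) -> bool:
        return True

    @property
    def go_time(self) -> float:
        return self._trial.t_go if self._trial else float("inf")

    @property
    def target_id(self) -> int:
        return self._trial.target_id if self._trial else -1

    @property
    def target_pos(self) -> np.ndarray:
        """Center of the cued cell."""
        return self.cell_center(self.target_id)

    @property
    def on_target_since(self) -> float | None:
        return self._on_target_since

    wants_click = True

    def cell_center(self, cell_id: int) -> np.ndarray:
        i, j = divmod(cell_id, self.config.n)
        return np.array(
            [
                self.grid_lo + (j + 0.5) * self.cell,
                self.grid_lo + (i + 0.5) * self.cell,
            ]
        )

    def cell_at(self, pos: np.ndarray) -> int | None:
        """Cell under a point, or None in the border or a gap.

        Cells are half-open ``[left, right) x [bottom, top)``, with the last
        ``gap`` of each cell's extent belonging to the inter-cell gap.
        """
        x, y = float(pos[0]), float(pos[1])
        fx = (x - self.grid_lo) / self.cell
        fy = (y - self.grid_lo) / self.cell
        if not (0 <= fx < self.config.n and 0 <= fy < self.config.n):
            return None
        j, i = int(fx), int(fy)
        # fractional offset inside the cell, in screen heights
        ox = (fx - j) * self.cell
        oy = (fy - i) * self.cell
        if ox >= self.cell - self.gap or oy >= self.cell - self.gap:
            return None  # in a gap
        return i * self.config.n + j

    def on_target(self, pos: np.ndarray) -> bool:
        return self.cell_at(pos) == self.target_id

    def _begin_trial(self, t: float) -> None:
        tid = int(self.rng.integers(0, self.config.n**2))
        self._trial = TrialRecord(
            trial_id=self._trial_count,
            target_id=tid,
            target_pos=tuple(self.cell_center(tid)),
            t_start=t,
            t_go=t,
        )
        self._trial.add_event(t, "go_cue", target=tid)
        self._trial_count += 1
        self._start_cell = self.cell_at(self._cursor)
        self._left_start = False
        self._on_target_since = None

    def step(self, t: float, cursor_pos: np.ndarray, click: bool = False) -> TrialRecord | None:
        self._cursor = np.asarray(cursor_pos, float)
        trial = self._trial
        cfg = self.config
        here = self.cell_at(self._cursor)
        if self._start_cell is not None and here != self._start_cell:
            self._left_start = True
        on = here == trial.target_id
        if on and self._on_target_since is None:
            self._on_target_since = t
            trial.add_event(t, "target_enter")
        elif not on and self._on_target_since is not None:
            self._on_target_since = None
            trial.add_event(t, "target_exit")

        outcome = None
        if click:
            if here is None:
                trial.add_event(t, "click", cell=None, selected=False)
            else:
                disabled = (
                    here == self._start_cell
                    and not self._left_start
                    and t - trial.t_start < cfg.start_disable_s
                )
                trial.add_event(t, "click", cell=here, selected=not disabled)
                if not disabled:
                    outcome = "success" if here == trial.target_id else "wrong_target"
        if outcome is None and t - trial.t_go >= cfg.timeout_s:
            outcome = "timeout"
        if outcome is None:
            return None

        trial.t_end = t
        trial.outcome = outcome
        trial.acquisition_time = t - trial.t_go
        trial.add_event(t, "success_sound" if outcome == "success" else "failure_sound")
        self._trial = None
        self._begin_trial(t)  # cursor position carries over
        return trial


class SpeechCursorTask:
    """Radial8 dwell task with interleaved word prompts and speech go cues.

    Trial sequence: target + word presentation -> randomized delay
    (1.3–1.7 s) -> cursor go cue -> move/dwell (1.5 s dwell) -> 1.0 s
    intertrial.  On beep trials a single beep is scheduled either during the
    move period (0.3–2.0 s after the go cue) or 0.1 s after first target
    entry, whichever comes first; in verbal blocks a speak event follows the
    beep after the configured reaction latency.
    """

    def __init__(self, config: SpeechTaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.positions = radial8_positions(config.ring_radius)
        self._seq = radial8_sequence(rng)
        self._trial_count = 0
        self._trial: TrialRecord | None = None
        self._phase = "intertrial"  # presentation | move | intertrial
        self._phase_until = 0.0
        self._on_target_since: float | None = None
        self._beep_t: float | None = None
        self._beeped = False
        self._speak_t: float | None = None
        self._pending: list[TrialRecord] = []

    @property
    def go_active(self) -> bool:
        return self._phase == "move"

    @property
    def go_time(self) -> float:
        if self._trial is None or self._phase != "move":
            return float("inf")
        return self._trial.t_go

    @property
    def target_id(self) -> int:
        return self._trial.target_id if self._trial else -1

    @property
    def target_pos(self) -> np.ndarray | None:
        if self._trial is None or self._phase != "move":
            return None
        return np.asarray(self._trial.target_pos)

    @property
    def on_target_since(self) -> float | None:
        return self._on_target_since

    wants_click = False

    def on_target(self, pos: np.ndarray) -> bool:
        if self._trial is None:
            return False
        d = np.linalg.norm(np.asarray(pos, float) - np.asarray(self._trial.target_pos))
        return d <= self.config.target_radius + self.config.cursor_radius

    def pop_speak_events(self, t: float) -> bool:
        """True once, at the bin where a scheduled speak event fires."""
        if self._speak_t is not None and t >= self._speak_t:
            self._speak_t = None
            return True
        return False

    def _begin_trial(self, t: float) -> None:
        cfg = self.config
        tid = next(self._seq)
        beep = bool(self.rng.random() < cfg.beep_prob)
        word = str(self.rng.choice(list(cfg.words)))
        self._trial = TrialRecord(
            trial_id=self._trial_count,
            target_id=tid,
            target_pos=tuple(self.positions[tid]),
            t_start=t,
            t_go=float("nan"),
            condition={"block_type": cfg.block_type, "beep": beep, "word": word},
        )
        self._trial.add_event(t, "target_presentation", target=tid)
        self._trial.add_event(t, "word_presentation", word=word)
        self._trial_count += 1
        self._phase = "presentation"
        self._phase_until = t + self.rng.uniform(*cfg.delay_range_s)
        self._on_target_since = None
        self._beeped = False
        self._beep_t = None
        self._entered_once = False

    def _do_beep(self, t: float) -> None:
        self._beeped = True
        self._trial.add_event(t, "beep")
        if self.config.block_type == "verbal":
            self._speak_t = t + self.config.speak_reaction_s

    def step(self, t: float, cursor_pos: np.ndarray, click: bool = False) -> TrialRecord | None:
        cfg = self.config
        if self._trial is None and self._phase == "intertrial" and t >= self._phase_until:
            self._begin_trial(t)
        if self._trial is None:
            return None
        trial = self._trial

        if self._phase == "presentation":
            if t >= self._phase_until:
                self._phase = "move"
                trial.t_go = t
                trial.add_event(t, "go_cue")
                if trial.condition["beep"]:
                    self._beep_t = t + self.rng.uniform(*cfg.beep_move_window_s)
            return None

        # move/dwell period
        on = self.on_target(cursor_pos)
        if on and self._on_target_since is None:
            self._on_target_since = t
            trial.add_event(t, "target_enter")
            if trial.condition["beep"] and not self._beeped and not self._entered_once:
                # beep lands in the dwell period instead of the scheduled move time
                self._beep_t = min(self._beep_t, t + cfg.beep_dwell_delay_s)
            self._entered_once = True
        elif not on and self._on_target_since is not None:
            self._on_target_since = None
            trial.add_event(t, "target_exit")
        if self._beep_t is not None and not self._beeped and t >= self._beep_t:
            self._do_beep(t)

        outcome = None
        if self._on_target_since is not None and t - self._on_target_since >= cfg.dwell_s:
            outcome = "success"
        elif t - trial.t_go >= cfg.timeout_s:
            outcome = "timeout"
        if outcome is None:
            return None

        trial.t_end = t
        trial.outcome = outcome
        trial.acquisition_time = t - trial.t_go
        trial.add_event(t, "selection" if outcome == "success" else "timeout")
        self._trial = None
        self._phase = "intertrial"
        self._phase_until = t + cfg.intertrial_s
        return trial
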