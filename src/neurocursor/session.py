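"""Closed-loop session engine and telemetry container.

:class:`Telemetry` holds the full per-bin record of a simulated session —
raw binned features, cursor and target state, decoder outputs, assist
levels, click predictions and trial records — and round-trips to disk
(JSONL for per-bin scalars and trials, HDF5 or CSV for the feature stream).

:func:`run_fixed_session` drives a task with *fixed* decoders (no assist,
no retraining): the evaluation and speech-and-cursor sessions.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import BIN_S
from .tasks import TrialRecord

__all__ = ["Telemetry", "run_fixed_session", "trials_dataframe"]


def _json_default(obj):
    """Serialize numpy scalars/arrays that leak into event payloads."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class Telemetry:
    """Per-bin telemetry of one simulated session."""

    t: np.ndarray
    raw_features: np.ndarray
    cursor_pos: np.ndarray
    target_pos: np.ndarray
    target_id: np.ndarray
    on_target: np.ndarray
    pred_v: np.ndarray
    v: np.ndarray
    o: np.ndarray
    assist: np.ndarray
    click_pred: np.ndarray
    click_emitted: np.ndarray
    trial_id: np.ndarray
    go_active: np.ndarray
    trials: list[TrialRecord] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @classmethod
    def allocate(cls, n_bins: int, n_electrodes: int, meta: dict | None = None) -> "Telemetry":
        return cls(
            t=np.zeros(n_bins),
            raw_features=np.zeros((n_bins, 2 * n_electrodes)),
            cursor_pos=np.zeros((n_bins, 2)),
            target_pos=np.full((n_bins, 2), np.nan),
            target_id=np.full(n_bins, -1, dtype=int),
            on_target=np.zeros(n_bins, dtype=bool),
            pred_v=np.full((n_bins, 2), np.nan),
            v=np.zeros((n_bins, 2)),
            o=np.zeros((n_bins, 2)),
            assist=np.zeros(n_bins),
            click_pred=np.full(n_bins, -1, dtype=int),
            click_emitted=np.zeros(n_bins, dtype=bool),
            trial_id=np.full(n_bins, -1, dtype=int),
            go_active=np.zeros(n_bins, dtype=bool),
            meta=dict(meta or {}),
        )

    def record(
        self, k, *, t, raw, cursor, target, target_id, on_target, pred, v, o,
        assist, click_pred, click_emitted, trial_id, go_active,
    ) -> None:
        self.t[k] = t
        self.raw_features[k] = raw
        self.cursor_pos[k] = cursor
        if target is not None:
            self.target_pos[k] = target
        self.target_id[k] = target_id
        self.on_target[k] = on_target
        if pred is not None:
            self.pred_v[k] = pred
        self.v[k] = v
        self.o[k] = o
        self.assist[k] = assist
        self.click_pred[k] = click_pred
        self.click_emitted[k] = click_emitted
        self.trial_id[k] = trial_id
        self.go_active[k] = go_active

    def trim(self, n: int) -> None:
        for name in (
            "t", "raw_features", "cursor_pos", "target_pos", "target_id",
            "on_target", "pred_v", "v", "o", "assist", "click_pred",
            "click_emitted", "trial_id", "go_active",
        ):
            setattr(self, name, getattr(self, name)[:n])

    @property
    def n_bins(self) -> int:
        return self.t.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.raw_features.shape[1] // 2

    @property
    def array_ids(self) -> np.ndarray:
        return np.asarray(self.meta["array_ids"])

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.meta.get("bin_s", BIN_S)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Write the session to a directory (JSONL bins/trials + HDF5 features)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "bins.jsonl", "w") as fh:
            for k in range(self.n_bins):
                row = {
                    "t": round(float(self.t[k]), 6),
                    "cursor": [float(x) for x in self.cursor_pos[k]],
                    "target": None
                    if np.isnan(self.target_pos[k, 0])
                    else [float(x) for x in self.target_pos[k]],
                    "target_id": int(self.target_id[k]),
                    "on_target": bool(self.on_target[k]),
                    "pred_v": None
                    if np.isnan(self.pred_v[k, 0])
                    else [float(x) for x in self.pred_v[k]],
                    "v": [float(x) for x in self.v[k]],
                    "o": [float(x) for x in self.o[k]],
                    "assist": float(self.assist[k]),
                    "click_pred": int(self.click_pred[k]),
                    "click_emitted": bool(self.click_emitted[k]),
                    "trial_id": int(self.trial_id[k]),
                    "go_active": bool(self.go_active[k]),
                }
                fh.write(json.dumps(row, default=_json_default) + "\n")
        with open(d / "trials.jsonl", "w") as fh:
            for tr in self.trials:
                fh.write(json.dumps(trial_to_dict(tr), default=_json_default) + "\n")
        with open(d / "meta.json", "w") as fh:
            json.dump({"meta": self.meta, "events": self.events}, fh, indent=1, default=_json_default)
        import h5py

        with h5py.File(d / "features.h5", "w") as h5:
            h5.create_dataset("raw_features", data=self.raw_features, compression="gzip")
            h5.attrs["n_electrodes"] = self.n_electrodes

    @classmethod
    def load(cls, directory) -> "Telemetry":
        d = Path(directory)
        with open(d / "meta.json") as fh:
            header = json.load(fh)
        import h5py

        with h5py.File(d / "features.h5", "r") as h5:
            raw = h5["raw_features"][:]
        rows = [json.loads(line) for line in open(d / "bins.jsonl")]
        n = len(rows)
        tel = cls.allocate(n, raw.shape[1] // 2, meta=header["meta"])
        tel.events = header["events"]
        tel.raw_features = raw
        for k, row in enumerate(rows):
            tel.t[k] = row["t"]
            tel.cursor_pos[k] = row["cursor"]
            if row["target"] is not None:
                tel.target_pos[k] = row["target"]
            tel.target_id[k] = row["target_id"]
            tel.on_target[k] = row["on_target"]
            if row["pred_v"] is not None:
                tel.pred_v[k] = row["pred_v"]
            tel.v[k] = row["v"]
            tel.o[k] = row["o"]
            tel.assist[k] = row["assist"]
            tel.click_pred[k] = row["click_pred"]
            tel.click_emitted[k] = row["click_emitted"]
            tel.trial_id[k] = row["trial_id"]
            tel.go_active[k] = row["go_active"]
        trials = []
        for line in open(d / "trials.jsonl"):
            trials.append(trial_from_dict(json.loads(line)))
        tel.trials = trials
        return tel

    def write_features_csv(self, path) -> None:
        """Long-format CSV of the feature stream: bin_index, electrode, crossings, sbp."""
        import pandas as pd

        n_e = self.n_electrodes
        bins, elecs = np.meshgrid(np.arange(self.n_bins), np.arange(n_e), indexing="ij")
        pd.DataFrame(
            {
                "bin_index": bins.ravel(),
                "electrode": elecs.ravel(),
                "crossings": self.raw_features[:, :n_e].astype(int).ravel(),
                "sbp": self.raw_features[:, n_e:].ravel(),
            }
        ).to_csv(path, index=False)


def trial_to_dict(tr: TrialRecord) -> dict:
    return {
        "trial_id": tr.trial_id,
        "target_id": tr.target_id,
        "target_pos": [float(x) for x in tr.target_pos],
        "t_start": tr.t_start,
        "t_go": tr.t_go,
        "t_end": tr.t_end,
        "outcome": tr.outcome,
        "acquisition_time": tr.acquisition_time,
        "events": tr.events,
        "condition": tr.condition,
    }


def trial_from_dict(d: dict) -> TrialRecord:
    return TrialRecord(
        trial_id=d["trial_id"],
        target_id=d["target_id"],
        target_pos=tuple(d["target_pos"]),
        t_start=d["t_start"],
        t_go=d["t_go"],
        t_end=d["t_end"],
        outcome=d["outcome"],
        acquisition_time=d["acquisition_time"],
        events=d["events"],
        condition=d["condition"],
    )


def trials_dataframe(trials: list[TrialRecord]):
    """Flatten trial records (with condition columns) into a DataFrame."""
    import pandas as pd

    rows = []
    for tr in trials:
        row = {
            "trial_id": tr.trial_id,
            "target_id": tr.target_id,
            "outcome": tr.outcome,
            "acquisition_time": tr.acquisition_time,
            "t_go": tr.t_go,
            "t_end": tr.t_end,
        }
        row.update(tr.condition)
        rows.append(row)
    return pd.DataFrame(rows)


def run_fixed_session(
    task,
    population,
    user,
    normalizer,
    cursor_decoder,
    click_decoder=None,
    duration_s: float = 180.0,
    rng: np.random.Generator | None = None,
    start_pos=(0.5, 0.5),
    meta: dict | None = None,
    smoother_T: float = 0.8,
    smoother_L_ms: float = 70.0,
    smoother_C_s: float = 1.0,
) -> Telemetry:
    """Run one block under full neural control with fixed decoders.

    The cursor is driven only by the decoded (smoothed, speed-adjusted)
    velocity; clicks, if a click decoder is given, come from the smoothed
    click stream.  Speech tasks' speak events set the simulated user's
    speaking flag.  Returns the block telemetry.
    """
    from .click import ClickSmoother
    from .cursor import VelocityState

    rng = rng if rng is not None else np.random.default_rng(0)
    n_bins = int(round(duration_s / BIN_S))
    n_e = population.n_electrodes
    base_meta = {
        "kind": "fixed_session",
        "array_ids": list(map(str, population.array_ids)),
        "bin_s": BIN_S,
    }
    base_meta.update(meta or {})
    tel = Telemetry.allocate(n_bins, n_e, meta=base_meta)

    vstate = VelocityState()
    smoother = ClickSmoother(T=smoother_T, L_ms=smoother_L_ms, C_s=smoother_C_s)
    pos = np.asarray(start_pos, float).copy()
    raw_hist: deque[np.ndarray] = deque(maxlen=5)

    for k in range(n_bins):
        t = k * BIN_S
        target = task.target_pos
        intent = user.intent(
            t, pos, target, task.go_time, task.on_target_since,
            wants_click=task.wants_click,
        )
        raw = population.generate_bin(intent, rng)
        f = normalizer.transform(raw[None, :], history=np.array(raw_hist) if raw_hist else None)[0]
        raw_hist.append(raw)
        pred = cursor_decoder.predict(f[None, :])[0]
        v_t, o_t = cursor_decoder.decode_step(vstate, f)
        pos = np.clip(pos + o_t * BIN_S, 0.0, 1.0)
        on = task.on_target(pos)

        click_pred = -1
        emit = False
        if click_decoder is not None:
            click_pred = int(click_decoder.predict(f[None, :])[0])
            emit = smoother.step(click_pred, k)

        completed = task.step(t, pos, emit)
        tel.record(
            k, t=t, raw=raw, cursor=pos, target=target,
            target_id=task.target_id, on_target=on, pred=pred, v=v_t, o=o_t,
            assist=0.0, click_pred=click_pred, click_emitted=emit,
            trial_id=getattr(task, "_trial_count", 0) - 1, go_active=task.go_active,
        )
        if completed is not None:
            tel.trials.append(completed)
        if hasattr(task, "pop_speak_events") and task.pop_speak_events(t):
            theta = rng.uniform(0, 2 * np.pi)  # the word's articulatory pattern
            user.start_speaking(t, np.array([np.cos(theta), np.sin(theta)]))
            tel.events.append({"t": t, "kind": "speak"})

    tel.trim(n_bins)
    return tel
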