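"""Task geometry, cue sequencing, selection and timing rules."""

import numpy as np
import pytest

from neurocursor.tasks import (
    GridConfig,
    GridTask,
    Radial8Config,
    Radial8Task,
    SpeechCursorTask,
    SpeechTaskConfig,
    radial8_positions,
    radial8_sequence,
)

BIN = 0.01


def drive(task, path):
    """Step a task along a scripted list of (cursor_pos, click) bins."""
    completed = []
    for k, (pos, click) in enumerate(path):
        tr = task.step(k * BIN, np.asarray(pos, float), click)
        if tr is not None:
            completed.append(tr)
    return completed


class TestRadial8Sequence:
    def test_alternation_and_permutation(self):
        rng = np.random.default_rng(0)
        seq = radial8_sequence(rng)
        first16 = [next(seq) for _ in range(16)]
        assert first16[1::2] == [0] * 8  # every other cue is the center
        assert sorted(first16[0::2]) == list(range(1, 9))

    def test_consecutive_blocks_are_independent_permutations(self):
        rng = np.random.default_rng(1)
        seq = radial8_sequence(rng)
        blocks = [[next(seq) for _ in range(16)][0::2] for _ in range(6)]
        assert all(sorted(b) == list(range(1, 9)) for b in blocks)
        assert len({tuple(b) for b in blocks}) > 1

    def test_same_seed_reproduces(self):
        a = radial8_sequence(np.random.default_rng(7))
        b = radial8_sequence(np.random.default_rng(7))
        assert [next(a) for _ in range(40)] == [next(b) for _ in range(40)]


class TestRadial8Task:
    def test_dwell_success(self):
        cfg = Radial8Config(dwell_s=0.8, selection="dwell")
        task = Radial8Task(cfg, np.random.default_rng(2))
        tgt = task.target_pos
        path = [(tgt, False)] * 82
        completed = drive(task, path)
        assert len(completed) == 1
        assert completed[0].outcome == "success"
        assert completed[0].acquisition_time == pytest.approx(0.8, abs=0.02)

    def test_exit_resets_dwell_clock(self):
        cfg = Radial8Config(dwell_s=0.8, selection="dwell")
        task = Radial8Task(cfg, np.random.default_rng(3))
        tgt = task.target_pos
        away = tgt + np.array([0.3, 0.0])
        path = [(tgt, False)] * 79 + [(away, False)] + [(tgt, False)] * 79
        completed = drive(task, path)
        assert completed == []  # neither stay reached 0.8 s continuously

    def test_timeout_after_ten_seconds(self):
        cfg = Radial8Config(selection="dwell")
        task = Radial8Task(cfg, np.random.default_rng(4))
        far = np.array([0.01, 0.01])
        completed = drive(task, [(far, False)] * 1001)
        assert len(completed) == 1
        assert completed[0].outcome == "timeout"

    def test_click_selection(self):
        cfg = Radial8Config(selection="click")
        task = Radial8Task(cfg, np.random.default_rng(5))
        tgt = task.target_pos
        completed = drive(task, [(tgt, False)] * 10 + [(tgt, True)])
        assert len(completed) == 1 and completed[0].outcome == "success"

    def test_off_target_click_ignored(self):
        cfg = Radial8Config(selection="click")
        task = Radial8Task(cfg, np.random.default_rng(6))
        far = np.array([0.05, 0.05])
        completed = drive(task, [(far, True)] * 20)
        assert completed == []

    def test_perfect_mover_bound(self):
        """A straight-line mover at constant speed succeeds every trial in
        under distance/speed + dwell (+ a bin of slack)."""
        cfg = Radial8Config(dwell_s=0.8, selection="dwell")
        task = Radial8Task(cfg, np.random.default_rng(7))
        speed = 0.5
        pos = np.array([0.5, 0.5])
        t = 0.0
        for _ in range(40):
            tgt = task.target_pos
            dist0 = np.linalg.norm(tgt - pos)
            start = t
            while True:
                err = tgt - pos
                d = np.linalg.norm(err)
                if d > 1e-9:
                    pos = pos + err / d * min(speed * BIN, d)
                tr = task.step(t, pos, False)
                t += BIN
                if tr is not None:
                    assert tr.outcome == "success"
                    assert t - start < dist0 / speed + cfg.dwell_s + 3 * BIN
                    break

    def test_outcomes_partition_trials(self):
        rng = np.random.default_rng(8)
        cfg = Radial8Config(selection="dwell")
        task = Radial8Task(cfg, rng)
        pos = np.array([0.5, 0.5])
        completed = []
        for k in range(3000):
            pos = np.clip(pos + rng.normal(0, 0.02, 2), 0, 1)
            tr = task.step(k * BIN, pos, False)
            if tr is not None:
                completed.append(tr)
        assert len(completed) > 0
        assert all(tr.outcome in ("success", "wrong_target", "timeout") for tr in completed)


class TestGeometry:
    def test_ring_positions(self):
        pos = radial8_positions(0.35)
        assert np.allclose(pos[0], [0.5, 0.5])
        d = np.linalg.norm(pos[1:] - pos[0], axis=1)
        assert np.allclose(d, 0.35)

    def test_grid_cells_tile_exactly(self):
        task = GridTask(GridConfig(n=6), np.random.default_rng(9))
        centers = [task.cell_center(i) for i in range(36)]
        ids = [task.cell_at(c) for c in centers]
        assert ids == list(range(36))


class TestGridTask:
    def _task(self, seed=10, n=6):
        return GridTask(GridConfig(n=n), np.random.default_rng(seed))

    def test_click_on_cued_cell_succeeds(self):
        task = self._task()
        tgt = task.target_pos
        completed = drive(task, [(tgt, False)] * 5 + [(tgt, True)])
        assert len(completed) == 1
        assert completed[0].outcome == "success"

    def test_click_on_other_cell_is_wrong_target(self):
        task = self._task(11)
        other = (task.target_id + 1) % 36
        pos = task.cell_center(other)
        # move off the start cell first so it cannot be the disabled one
        completed = drive(task, [(pos, False)] * 5 + [(pos, True)])
        if task.cell_at(np.array([0.5, 0.5])) == other:
            pytest.skip("start cell coincides with clicked cell")
        assert len(completed) == 1
        assert completed[0].outcome == "wrong_target"

    def test_border_click_does_not_select(self):
        task = self._task(12)
        border = np.array([0.01, 0.5])  # inside the 43 px frame
        completed = drive(task, [(border, True)] * 10)
        assert completed == []

    def test_gap_click_does_not_select(self):
        task = self._task(13)
        # a point in the vertical gap between cells 0 and 1
        x = task.grid_lo + task.cell - task.gap / 2
        pos = np.array([x, task.grid_lo + task.cell / 2])
        assert task.cell_at(pos) is None
        completed = drive(task, [(pos, True)] * 5)
        assert completed == []

    def test_start_cell_disabled_then_reenabled(self):
        task = self._task(14)
        start = task.cell_at(np.array([0.5, 0.5]))
        assert start is not None
        pos = task.cell_center(start)
        # click at 1.0 s without having left: no selection
        path = [(pos, False)] * 99 + [(pos, True)]
        assert drive(task, path) == []
        # same click at 2.5 s (> 2.0 s disable window): selects
        task2 = self._task(14)
        start2 = task2.cell_at(np.array([0.5, 0.5]))
        pos2 = task2.cell_center(start2)
        path2 = [(pos2, False)] * 250 + [(pos2, True)]
        completed = drive(task2, path2)
        assert len(completed) == 1

    def test_leaving_start_cell_reenables_it(self):
        task = self._task(15)
        start = task.cell_at(np.array([0.5, 0.5]))
        outside = np.array([0.01, 0.01])
        pos = task.cell_center(start)
        path = [(pos, False)] * 5 + [(outside, False)] * 5 + [(pos, False)] * 5 + [(pos, True)]
        completed = drive(task, path)
        assert len(completed) == 1


class TestSpeechTask:
    def _run_block(self, block_type, seed, duration_s=60.0, perfect=True):
        cfg = SpeechTaskConfig(block_type=block_type)
        rng = np.random.default_rng(seed)
        task = SpeechCursorTask(cfg, rng)
        pos = np.array([0.5, 0.5])
        speaks = []
        for k in range(int(duration_s / BIN)):
            t = k * BIN
            tgt = task.target_pos
            if perfect and tgt is not None:
                err = tgt - pos
                d = np.linalg.norm(err)
                if d > 1e-9:
                    pos = pos + err / d * min(0.5 * BIN, d)
            task.step(t, pos, False)
            if task.pop_speak_events(t):
                speaks.append(t)
        return task, speaks

    def test_verbal_beep_trials_emit_beep_then_speak(self):
        task, speaks = self._run_block("verbal", 16)
        trials = []  # collect completed trials again via a fresh run with records
        cfg = SpeechTaskConfig(block_type="verbal")
        rng = np.random.default_rng(16)
        task = SpeechCursorTask(cfg, rng)
        pos = np.array([0.5, 0.5])
        done = []
        n_speak = 0
        for k in range(6000):
            t = k * BIN
            tgt = task.target_pos
            if tgt is not None:
                err = tgt - pos
                d = np.linalg.norm(err)
                if d > 1e-9:
                    pos = pos + err / d * min(0.5 * BIN, d)
            tr = task.step(t, pos, False)
            if tr is not None:
                done.append(tr)
            if task.pop_speak_events(t):
                n_speak += 1
        beep_trials = [tr for tr in done if tr.condition["beep"]]
        nobeep_trials = [tr for tr in done if not tr.condition["beep"]]
        assert beep_trials and nobeep_trials
        for tr in beep_trials:
            kinds = [e["kind"] for e in tr.events]
            assert "beep" in kinds
        for tr in nobeep_trials:
            kinds = [e["kind"] for e in tr.events]
            assert "beep" not in kinds
        assert n_speak == len(beep_trials)

    def test_control_block_never_speaks(self):
        _, speaks = self._run_block("control", 17)
        assert speaks == []

    def test_delay_period_within_stated_range(self):
        cfg = SpeechTaskConfig()
        rng = np.random.default_rng(18)
        task = SpeechCursorTask(cfg, rng)
        pos = np.array([0.5, 0.5])
        done = []
        for k in range(6000):
            t = k * BIN
            tgt = task.target_pos
            if tgt is not None:
                err = tgt - pos
                d = np.linalg.norm(err)
                if d > 1e-9:
                    pos = pos + err / d * min(0.5 * BIN, d)
            tr = task.step(t, pos, False)
            if tr is not None:
                done.append(tr)
        assert done
        for tr in done:
            delay = tr.t_go - tr.t_start
            assert 1.3 - BIN <= delay <= 1.7 + BIN
            assert tr.acquisition_time <= 10.0 + BIN

    def test_beep_times_respect_windows(self):
        cfg = SpeechTaskConfig(block_type="control", beep_prob=1.0)
        rng = np.random.default_rng(19)
        task = SpeechCursorTask(cfg, rng)
        pos = np.array([0.5, 0.5])
        done = []
        for k in range(12000):
            t = k * BIN
            tgt = task.target_pos
            if tgt is not None:
                err = tgt - pos
                d = np.linalg.norm(err)
                if d > 1e-9:
                    pos = pos + err / d * min(0.3 * BIN, d)
            tr = task.step(t, pos, False)
            if tr is not None:
                done.append(tr)
        assert done
        for tr in done:
            beeps = [e["t"] for e in tr.events if e["kind"] == "beep"]
            assert len(beeps) == 1
            entry = [e["t"] for e in tr.events if e["kind"] == "target_enter"]
            lo = tr.t_go + 0.3
            if entry:
                assert beeps[0] <= max(entry[0] + 0.1, lo) + BIN
            assert beeps[0] >= tr.t_go + 0.3 - BIN or (
                entry and beeps[0] >= entry[0] + 0.1 - BIN
            )
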