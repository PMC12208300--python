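"""Performance metrics and offline analyses.

Implements the standardized grid-task bitrate, selection accounting,
acquisition-time comparisons across speech conditions (rank-sum tests with
Bonferroni correction), and the two per-array ablation analyses: velocity
decoding evaluated by average angular error per trial, and click decoding
evaluated by cross-validated classification of 100 ms windows taken just
before each click (110–10 ms before trial end = click, 800–700 ms before =
non-click).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .calibration import angular_error
from .cursor import CursorVelocityDecoder, build_intent_dataset
from .features import FeatureNormalizer, feature_indices_for_electrodes
from .session import Telemetry

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSummary",
    "AblationResult",
    "bitrate",
    "block_summary",
    "acquisition_time_comparison",
    "bootstrap_ci",
    "default_array_subsets",
    "velocity_ablation",
    "click_window_ablation",
]

CHANCE_ANGULAR_ERROR = 90.0


@dataclass
class BlockSummary:
    n_grid: int
    correct: int
    wrong: int
    timeouts: int
    duration_s: float
    bitrate_bps: float


@dataclass
class AblationResult:
    label: str
    metric: str  # angular_error_deg | click_accuracy
    value: float
    ci_low: float
    ci_high: float
    n: int
    p_vs_chance: float
    p_vs_all: float
    significant_vs_chance: bool
    significant_vs_all: bool


def bitrate(n_grid: int, correct: int, wrong: int, duration_s: float) -> float:
    """Standardized grid-selection throughput in bits/s.

    B = log2(N - 1) * max(correct - wrong, 0) / duration, for an N-target
    grid: each selection conveys log2(N - 1) bits and wrong selections must
    be undone, floored at zero.
    """
    if n_grid < 2:
        raise ValueError("bitrate needs at least 2 targets")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return float(np.log2(n_grid - 1) * max(correct - wrong, 0) / duration_s)


def block_summary(trials, n: int, duration_s: float) -> BlockSummary:
    """Summarize one grid block's trials; ``n`` is the grid side length."""
    correct = sum(1 for tr in trials if tr.outcome == "success")
    wrong = sum(1 for tr in trials if tr.outcome == "wrong_target")
    timeouts = sum(1 for tr in trials if tr.outcome == "timeout")
    return BlockSummary(
        n_grid=n * n,
        correct=correct,
        wrong=wrong,
        timeouts=timeouts,
        duration_s=duration_s,
        bitrate_bps=bitrate(n * n, correct, wrong, duration_s),
    )


def acquisition_time_comparison(
    df: pd.DataFrame,
    condition_col: str = "condition",
    time_col: str = "acquisition_time",
    min_trials: int = 5,
) -> dict:
    """Per-condition medians plus all pairwise rank-sum tests.

    P-values are Bonferroni-corrected by the number of pairwise comparisons.
    Conditions with fewer than ``min_trials`` trials are excluded (logged).
    Returns ``{"medians": {...}, "n": {...}, "pairwise": {(a, b): p}}``.
    """
    groups = {}
    for cond, sub in df.groupby(condition_col):
        vals = sub[time_col].dropna().to_numpy()
        if vals.size < min_trials:
            logger.warning("condition %r has %d trials; excluded", cond, vals.size)
            continue
        groups[cond] = vals
    if len(groups) < 2:
        raise ValueError("need at least two conditions with enough trials")
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        stat = stats.ranksums(groups[a], groups[b])
        pairwise[(a, b)] = min(1.0, stat.pvalue * m)
    return {
        "medians": {c: float(np.median(v)) for c, v in groups.items()},
        "n": {c: int(v.size) for c, v in groups.items()},
        "pairwise": pairwise,
        "n_comparisons": m,
    }


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (seeded, reproducible)."""
    values = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def default_array_subsets(arrays=("55b", "d6v", "v6v", "4")) -> dict[str, list[str]]:
    """Single-array, leave-one-array-out, and all-array electrode subsets."""
    subsets: dict[str, list[str]] = {}
    for a in arrays:
        subsets[a] = [a]
    for a in arrays:
        subsets[f"excl_{a}"] = [b for b in arrays if b != a]
    subsets["all"] = list(arrays)
    return subsets


def _subset_columns(array_ids: np.ndarray, members: list[str]) -> np.ndarray:
    electrodes = np.flatnonzero(np.isin(array_ids, members))
    return feature_indices_for_electrodes(electrodes, array_ids.size)


def _per_trial_angular_errors(
    tel: Telemetry,
    pred: np.ndarray,
    near_radius: float,
) -> np.ndarray:
    """Mean angular error per trial over move-period bins away from the target."""
    dist = np.linalg.norm(tel.target_pos - tel.cursor_pos, axis=1)
    speed = np.linalg.norm(pred, axis=1)
    usable = tel.go_active & (dist >= near_radius) & (speed > 0) & np.isfinite(dist)
    errors = []
    for tid in np.unique(tel.trial_id[tel.trial_id >= 0]):
        mask = usable & (tel.trial_id == tid)
        if not mask.any():
            continue
        errs = [
            angular_error(pred[i], tel.cursor_pos[i], tel.target_pos[i])
            for i in np.flatnonzero(mask)
        ]
        errors.append(float(np.mean(errs)))
    return np.asarray(errors)


def velocity_ablation(
    calib_tel: Telemetry,
    eval_tel: Telemetry,
    subsets: dict[str, list[str]] | None = None,
    near_radius: float = 0.06,
    intent_mode: str = "unit_vector",
    alpha_sig: float = 0.01,
    seed: int = 0,
    n_boot: int = 10_000,
) -> list[AblationResult]:
    """Per-array contribution to velocity decoding.

    For each electrode subset, a decoder is trained on the calibration
    telemetry restricted to that subset and replayed over the evaluation
    telemetry; the statistic is the mean over trials of the per-trial mean
    angular error.  Significance vs 90° chance (one-sample t) and vs the
    all-array decoder (two-sample t) is Bonferroni-corrected within each
    family of comparisons.
    """
    subsets = subsets or default_array_subsets(
        tuple(dict.fromkeys(calib_tel.array_ids))
    )
    array_ids = calib_tel.array_ids
    per_subset: dict[str, np.ndarray] = {}
    for label, members in subsets.items():
        cols = _subset_columns(array_ids, members)
        if cols.size == 0:
            logger.warning("subset %r has no electrodes; skipped", label)
            continue
        raw_train = calib_tel.raw_features[:, cols]
        try:
            norm = FeatureNormalizer().fit(raw_train)
        except ValueError:
            logger.warning("subset %r: no retained electrodes; skipped", label)
            continue
        F = norm.transform(raw_train)
        X, y = build_intent_dataset(
            F, calib_tel.cursor_pos, calib_tel.target_pos,
            mode=intent_mode, near_radius=near_radius,
        )
        dec = CursorVelocityDecoder().fit(X, y)
        F_eval = norm.transform(eval_tel.raw_features[:, cols])
        pred = dec.predict(F_eval)
        per_subset[label] = _per_trial_angular_errors(eval_tel, pred, near_radius)

    if "all" not in per_subset:
        raise ValueError("ablation requires an 'all' subset for reference")
    n_chance = len(per_subset)
    n_vs_all = max(1, len(per_subset) - 1)
    results = []
    for i, (label, errs) in enumerate(per_subset.items()):
        lo, hi = bootstrap_ci(errs, n_boot=n_boot, seed=seed + i)
        p_chance = min(1.0, stats.ttest_1samp(errs, CHANCE_ANGULAR_ERROR).pvalue * n_chance)
        if label == "all":
            p_all = 1.0
        else:
            p_all = min(
                1.0, stats.ttest_ind(errs, per_subset["all"]).pvalue * n_vs_all
            )
        results.append(
            AblationResult(
                label=label,
                metric="angular_error_deg",
                value=float(np.mean(errs)),
                ci_low=lo,
                ci_high=hi,
                n=errs.size,
                p_vs_chance=p_chance,
                p_vs_all=p_all,
                significant_vs_chance=p_chance < alpha_sig,
                significant_vs_all=p_all < alpha_sig,
            )
        )
    return results


def _click_windows(
    tel: Telemetry,
    click_window_s: tuple[float, float] = (-0.110, -0.010),
    nonclick_window_s: tuple[float, float] = (-0.800, -0.700),
) -> tuple[np.ndarray, np.ndarray]:
    """100 ms window features and labels from click-terminated trials.

    Windows are located by time relative to each trial's end; features are
    the mean of each raw feature over the window's bins.
    """
    X_rows, y_rows = [], []
    for tr in tel.trials:
        if tr.outcome not in ("success", "wrong_target"):
            continue
        for (a, b), label in ((click_window_s, 1), (nonclick_window_s, 0)):
            i0 = int(np.searchsorted(tel.t, tr.t_end + a))
            i1 = int(np.searchsorted(tel.t, tr.t_end + b))
            if i1 <= i0 or i0 < 0:
                continue
            X_rows.append(tel.raw_features[i0:i1].mean(axis=0))
            y_rows.append(label)
    return np.asarray(X_rows), np.asarray(y_rows)


def click_window_ablation(
    eval_tel: Telemetry,
    subsets: dict[str, list[str]] | None = None,
    n_folds: int = 5,
    alpha_sig: float = 0.01,
    seed: int = 0,
    n_boot: int = 10_000,
    min_trials: int = 20,
) -> list[AblationResult]:
    """Per-array click information, from windows flanking online clicks.

    Each click-terminated trial contributes one 'click' window (110–10 ms
    before trial end) and one 'non-click' window (800–700 ms before end);
    features are window means.  A logistic regression is scored by
    stratified cross-validation per electrode subset; chance is 0.5.
    """
    subsets = subsets or default_array_subsets(
        tuple(dict.fromkeys(eval_tel.array_ids))
    )
    X_all, y = _click_windows(eval_tel)
    n_trials = int(np.sum(y == 1))
    if n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} click-terminated trials, got {n_trials}")
    array_ids = eval_tel.array_ids
    correctness: dict[str, np.ndarray] = {}
    for label, members in subsets.items():
        cols = _subset_columns(array_ids, members)
        if cols.size == 0:
            logger.warning("subset %r has no electrodes; skipped", label)
            continue
        model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=500))
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(model, X_all[:, cols], y, cv=cv)
        correctness[label] = (pred == y).astype(float)

    if "all" not in correctness:
        raise ValueError("ablation requires an 'all' subset for reference")
    n_chance = len(correctness)
    n_vs_all = max(1, len(correctness) - 1)
    results = []
    for i, (label, corr) in enumerate(correctness.items()):
        lo, hi = bootstrap_ci(corr, n_boot=n_boot, seed=seed + i)
        p_chance = min(1.0, stats.ttest_1samp(corr, 0.5).pvalue * n_chance)
        if label == "all":
            p_all = 1.0
        else:
            p_all = min(1.0, stats.ttest_ind(corr, correctness["all"]).pvalue * n_vs_all)
        results.append(
            AblationResult(
                label=label,
                metric="click_accuracy",
                value=float(np.mean(corr)),
                ci_low=lo,
                ci_high=hi,
                n=corr.size,
                p_vs_chance=p_chance,
                p_vs_all=p_all,
                significant_vs_chance=p_chance < alpha_sig,
                significant_vs_all=p_all < alpha_sig,
            )
        )
    return results


def ablation_dataframe(results: list[AblationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
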