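"""Named decoder-parameter presets by post-implant session day.

``beta`` and ``r`` are in screen heights per second; ``alpha`` and ``p``
are unitless.  Sessions without a stated speed gain predate decoding-matrix
normalization, so their presets carry ``beta = None`` (callers fall back to
the package default).  ``p = 1`` disables the nonlinear speed adjustment,
in which case ``r`` is irrelevant.
"""

from __future__ import annotations

TABLE1_PRESETS: dict[str, dict] = {
    # first-ever usage: dwell selection, position-error intention estimation
    "day-39": {
        "alpha": 0.9,
        "beta": None,
        "r": 1.0,
        "p": 1.0,
        "intent_mode": "position_error",
        "selection": "dwell",
        "dwell_s": 0.8,
        "click_enabled": False,
    },
    "day-171": {
        "alpha": 0.9,
        "beta": 0.2,
        "r": 1.0,
        "p": 1.0,
        "intent_mode": "unit_vector",
        "selection": "click",
        "click_enabled": True,
    },
    # simultaneous speech and cursor session (dwell selection, 1.0 s dwell)
    "day-202": {
        "alpha": 0.9,
        "beta": 0.2,
        "r": 1.0,
        "p": 1.0,
        "intent_mode": "unit_vector",
        "selection": "dwell",
        "dwell_s": 1.0,
        "click_enabled": False,
        "speech_beta": 0.15,
    },
    "day-233": {
        "alpha": 0.93,
        "beta": 0.16,
        "r": 1.0,
        "p": 1.0,
        "intent_mode": "unit_vector",
        "selection": "click",
        "click_enabled": True,
        "grid_overrides": {"alpha": 0.9, "beta": 0.2},
    },
    "day-339": {
        "alpha": 0.93,
        "beta": 0.22,
        "r": 0.4,
        "p": 1.4,
        "intent_mode": "unit_vector",
        "selection": "click",
        "click_enabled": True,
    },
    "day-468": {
        "alpha": 0.92,
        "beta": 0.13,
        "r": 0.05,
        "p": 1.5,
        "intent_mode": "unit_vector",
        "selection": "click",
        "click_enabled": True,
    },
}


def get_preset(name: str) -> dict:
    try:
        return dict(TABLE1_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(TABLE1_PRESETS)}"
        ) from None
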