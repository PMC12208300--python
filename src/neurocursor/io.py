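"""Decoder bundles, run manifests, and config loading."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .click import ClickClassifier
from .cortex import PopulationSpec
from .cursor import CursorVelocityDecoder
from .features import FeatureNormalizer

__all__ = [
    "save_bundle",
    "load_bundle",
    "write_manifest",
    "load_config",
    "sha256_file",
]


def save_bundle(
    path,
    normalizer: FeatureNormalizer,
    cursor_decoder: CursorVelocityDecoder,
    click_decoder: ClickClassifier | None = None,
    population_spec: PopulationSpec | None = None,
    meta: dict | None = None,
) -> None:
    """Persist a decoder checkpoint (normalization stats + both decoding
    matrices + the generating population spec) as one JSON file."""
    bundle = {
        "schema": "neurocursor-bundle-1",
        "normalizer": normalizer.to_dict(),
        "cursor_decoder": cursor_decoder.to_dict(),
        "click_decoder": click_decoder.to_dict() if click_decoder is not None else None,
        "population_spec": _spec_to_dict(population_spec) if population_spec else None,
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_bundle(path) -> dict:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("schema") != "neurocursor-bundle-1":
        raise ValueError(f"unrecognized bundle schema in {path}")
    out = {
        "normalizer": FeatureNormalizer.from_dict(bundle["normalizer"]),
        "cursor_decoder": CursorVelocityDecoder.from_dict(bundle["cursor_decoder"]),
        "click_decoder": (
            ClickClassifier.from_dict(bundle["click_decoder"])
            if bundle["click_decoder"] is not None
            else None
        ),
        "population_spec": (
            _spec_from_dict(bundle["population_spec"])
            if bundle["population_spec"]
            else None
        ),
        "meta": bundle.get("meta", {}),
    }
    return out


def _spec_to_dict(spec: PopulationSpec) -> dict:
    d = dict(spec.__dict__)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _spec_from_dict(d: dict) -> PopulationSpec:
    d = dict(d)
    for k in ("arrays", "baseline_hz", "depth_hz", "click_gain_hz", "speech_gain_hz"):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return PopulationSpec(**d)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, outputs: list[str]) -> None:
    """Record everything needed to reproduce a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "neurocursor",
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": {
            name: sha256_file(out_dir / name)
            for name in outputs
            if (out_dir / name).is_file()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
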