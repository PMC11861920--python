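"""YAML configuration loading for the CLI.

A config file may carry three sections, each mapping directly onto the
corresponding parameter dataclass::

    segmentation:            # -> SegmentationParams
      min_area_px: 400
      max_eccentricity: 0.95
    densitometry:
      tau: 0.07              # overrides the stain default
      sigma: 2.0
      radius: 5
    rules:                   # -> PatternRules
      f_min: 0.02
      td_min_fraction: 0.75

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .head_segmentation import SegmentationParams
from .pattern_classification import PatternRules


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None) -> dict:
    """Parse a YAML config into parameter objects (missing file -> defaults)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    dens = dict(raw.get("densitometry", {}))
    allowed_dens = {"tau", "sigma", "radius", "K"}
    unknown = set(dens) - allowed_dens
    if unknown:
        raise ValueError(f"unknown keys in 'densitometry' config: {sorted(unknown)}")
    return {
        "segmentation": _build(
            SegmentationParams, dict(raw.get("segmentation", {})), "segmentation"
        ),
        "rules": _build(PatternRules, dict(raw.get("rules", {})), "rules"),
        "densitometry": dens,
    }
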