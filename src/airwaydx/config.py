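"""YAML configuration for fuzzy breakpoints and diagnostic thresholds.

Layout::

    fuzzy:
      r_high_lo: 150
      r_high_hi: 155
      ...
    criteria:
      r5_pct_min: 150
      asthma_ratio_max: 0.8
      ...

Every key defaults to the built-in value; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .criteria import CriteriaThresholds
from .fuzzy import FuzzyBreakpoints


@dataclass(frozen=True)
class Config:
    fuzzy: FuzzyBreakpoints
    criteria: CriteriaThresholds


def load_config(path=None) -> Config:
    """Load a YAML config; a missing path yields all defaults."""
    if path is None:
        return Config(fuzzy=FuzzyBreakpoints(), criteria=CriteriaThresholds())
    with open(Path(path), "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - {"fuzzy", "criteria"}
    if unknown:
        raise ValueError(f"unknown top-level config section(s): {sorted(unknown)}")
    return Config(
        fuzzy=FuzzyBreakpoints.from_dict(raw.get("fuzzy") or {}),
        criteria=CriteriaThresholds.from_dict(raw.get("criteria") or {}),
    )
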