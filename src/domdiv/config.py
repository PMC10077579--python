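"""YAML configuration loading for the assignment and survey configs."""

from __future__ import annotations

from typing import Any, Mapping

import yaml

from .formulas import AssignmentConfig
from .peaklists import PeaklistFormat
from .simulate import SurveyConfig

__all__ = ["load_config", "assignment_config", "survey_config", "peaklist_format"]


def load_config(path) -> dict[str, Any]:
    """Load a structured configuration file (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return dict(cfg)


def _build(cls, section: Mapping[str, Any] | None):
    section = dict(section or {})
    if "ranges" in section:  # YAML lists -> tuples for element ranges
        section["ranges"] = {el: tuple(v) for el, v in section["ranges"].items()}
    for key in ("hc_bounds", "mass_window", "mass_range"):
        if key in section:
            section[key] = tuple(section[key])
    return cls(**section)


def assignment_config(cfg: Mapping[str, Any]) -> AssignmentConfig:
    """Build an :class:`AssignmentConfig` from the ``assignment`` section."""
    return _build(AssignmentConfig, cfg.get("assignment"))


def survey_config(cfg: Mapping[str, Any]) -> SurveyConfig:
    """Build a :class:`SurveyConfig` from the ``survey`` section."""
    return _build(SurveyConfig, cfg.get("survey"))


def peaklist_format(cfg: Mapping[str, Any]) -> PeaklistFormat:
    """Build a :class:`PeaklistFormat` from the ``peaklist`` section."""
    return _build(PeaklistFormat, cfg.get("peaklist"))
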