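"""Threshold configuration for differential calling.

Two quantification regimes are supported for PTM sites: label-free
(fold-change cutoffs 1.3 / 0.77) and TMT reporter-ion quantification
(1.2 / 0.833 — looser because isobaric labelling compresses observed
ratios toward 1), both gated by a replicate-ratio coefficient of
variation below ``cv_max``.  Metabolite calling uses either the
VIP >= 1 & |log2FC| >= 1 criterion or a plain ratio criterion
(>= 1.5 / <= 0.67), plus the rescue-reversal thresholds for the
three-group design.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ThresholdConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariant."""


_MODE_DEFAULTS: dict[str, dict[str, float]] = {
    "label_free": {"fc_up": 1.3, "fc_down": 0.77, "cv_max": 0.1},
    "tmt": {"fc_up": 1.2, "fc_down": 0.833, "cv_max": 0.1},
    "metabolite": {
        "fc_up": 1.5,
        "fc_down": 0.67,
        "vip_min": 1.0,
        "abs_log2fc_min": 1.0,
        "rescue_up": 1.5,
        "rescue_down": 0.67,
    },
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs used by the differential-calling operations.

    Parameters
    ----------
    fc_up, fc_down
        Fold-change cutoffs for up/down calls.  Strict inequalities for
        PTM sites, non-strict for the metabolite ratio criterion.
    cv_max
        Upper bound on the replicate-ratio coefficient of variation
        (PTM regimes only); a site is callable only when CV < cv_max.
    vip_min, abs_log2fc_min
        VIP-criterion cutoffs for metabolites (non-strict ``>=``).
    rescue_up, rescue_down
        Reversal thresholds for the rescue-group vs stress-group ratio
        in the three-group analysis.
    mode
        One of ``label_free``, ``tmt``, ``metabolite``.
    """

    fc_up: float = 1.3
    fc_down: float = 0.77
    cv_max: float = 0.1
    vip_min: float = 1.0
    abs_log2fc_min: float = 1.0
    rescue_up: float = 1.5
    rescue_down: float = 0.67
    mode: str = "label_free"

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEFAULTS:
            raise ConfigurationError(
                f"mode must be one of {sorted(_MODE_DEFAULTS)}, got {self.mode!r}"
            )
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ConfigurationError(
                f"need fc_down < 1 < fc_up, got ({self.fc_down}, {self.fc_up})"
            )
        if not (0 < self.rescue_down < 1 < self.rescue_up):
            raise ConfigurationError(
                "need rescue_down < 1 < rescue_up, got "
                f"({self.rescue_down}, {self.rescue_up})"
            )
        if self.cv_max <= 0:
            raise ConfigurationError(f"cv_max must be positive, got {self.cv_max}")
        if self.vip_min < 0 or self.abs_log2fc_min < 0:
            raise ConfigurationError("vip_min and abs_log2fc_min must be >= 0")

    @classmethod
    def for_mode(cls, mode: str, **overrides: float) -> "ThresholdConfig":
        """Build the default configuration for a quantification regime."""
        if mode not in _MODE_DEFAULTS:
            raise ConfigurationError(
                f"mode must be one of {sorted(_MODE_DEFAULTS)}, got {mode!r}"
            )
        params: dict[str, Any] = dict(_MODE_DEFAULTS[mode])
        params.update(overrides)
        return cls(mode=mode, **params)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: float) -> "ThresholdConfig":
        """Read a flat ``key: value`` text config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        mode = raw.pop("mode", "label_free")
        return cls.for_mode(mode, **raw)

    def with_overrides(self, **overrides: float) -> "ThresholdConfig":
        return replace(self, **overrides)

    def summary(self) -> str:
        """One-line rendering used in output-file headers."""
        return (
            f"mode={self.mode} fc_up={self.fc_up:g} fc_down={self.fc_down:g} "
            f"cv_max={self.cv_max:g} vip_min={self.vip_min:g} "
            f"abs_log2fc_min={self.abs_log2fc_min:g} "
            f"rescue_up={self.rescue_up:g} rescue_down={self.rescue_down:g}"
        )
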