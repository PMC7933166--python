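"""Vital-sign noise removal: flag implausible per-minute records.

Three configurable screens are evaluated per channel against the incoming
validity flags, and their flags are unioned:

1. plausibility bounds — values outside [min, max] for the channel;
2. jump rule — a minute-to-minute change between two adjacent valid minutes
   exceeding ``max_abs_jump`` invalidates both endpoints of the jump;
3. flatline rule — a run of >= ``flatline_minutes`` exactly-identical values
   is treated as sensor dropout and invalidated.

Evaluating every screen against the same input validity (rather than
chaining them) keeps the operation monotone — loosening any rule can only
shrink the invalid set — and idempotent.  Records are invalidated, never
deleted, so the admission-anchored minute grid (and with it the 90% presence
rule) stays intact.

The study these defaults stand in for removed noise with per-variable rules
that are not public; the bounds below are standard monitor-artifact screens
and are deliberately overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import PHYSIOLOGIC_BOUNDS, Cohort, Patient, VitalChannelSeries
from .errors import ConfigurationError

#: Default maximum credible minute-to-minute change, channel units per minute.
DEFAULT_MAX_ABS_JUMP = {
    "pulse_rate": 40.0,
    "sbp": 50.0,
    "dbp": 35.0,
    "resp_rate": 20.0,
    "spo2": 15.0,
}

DEFAULT_FLATLINE_MINUTES = 5


@dataclass(frozen=True)
class NoiseRuleSet:
    """Per-channel plausibility bounds, jump limits, and the flatline length."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PHYSIOLOGIC_BOUNDS))
    max_abs_jump: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_ABS_JUMP))
    flatline_minutes: int = DEFAULT_FLATLINE_MINUTES

    def __post_init__(self):
        for ch, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
                raise ConfigurationError(
                    f"bounds for {ch!r} must satisfy min < max, got ({lo}, {hi})")
        for ch, j in self.max_abs_jump.items():
            if not math.isfinite(j) or j <= 0:
                raise ConfigurationError(f"max_abs_jump for {ch!r} must be > 0, got {j}")
        if self.flatline_minutes < 2:
            raise ConfigurationError(
                f"flatline_minutes must be >= 2, got {self.flatline_minutes}")

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseRuleSet":
        kwargs = {}
        if "bounds" in d:
            kwargs["bounds"] = {ch: tuple(v) for ch, v in d["bounds"].items()}
        if "max_abs_jump" in d:
            kwargs["max_abs_jump"] = {ch: float(v) for ch, v in d["max_abs_jump"].items()}
        if "flatline_minutes" in d:
            kwargs["flatline_minutes"] = int(d["flatline_minutes"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "NoiseRuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("noise_rules", data))


def _flatline_mask(values: np.ndarray, run_length: int) -> np.ndarray:
    """True for every minute inside a run of >= run_length identical values."""
    n = values.size
    mask = np.zeros(n, dtype=bool)
    if n < run_length:
        return mask
    # NaN never equals anything, so missing minutes break runs
    same = np.zeros(n, dtype=bool)
    same[1:] = values[1:] == values[:-1]
    start = 0
    for i in range(1, n + 1):
        if i == n or not same[i]:
            if i - start >= run_length:
                mask[start:i] = True
            start = i
    return mask


def remove_noise(series: VitalChannelSeries, rules: NoiseRuleSet) -> VitalChannelSeries:
    """Return a copy of ``series`` with implausible minutes flagged invalid.

    Values are untouched; only the valid flags change.  Applying the
    operation twice gives the same result as applying it once.
    """
    if series.channel not in rules.bounds or series.channel not in rules.max_abs_jump:
        raise ConfigurationError(f"no noise rules configured for channel {series.channel!r}")
    out = series.copy()
    values, valid = out.values, out.valid
    n = values.size
    flagged = np.zeros(n, dtype=bool)

    lo, hi = rules.bounds[series.channel]
    with np.errstate(invalid="ignore"):
        flagged |= valid & ~((values >= lo) & (values <= hi))

    if n >= 2:
        pair_ok = valid[1:] & valid[:-1]
        with np.errstate(invalid="ignore"):
            jump = np.abs(np.diff(values)) > rules.max_abs_jump[series.channel]
        bad_pair = pair_ok & jump
        flagged[1:] |= bad_pair
        flagged[:-1] |= bad_pair

    flagged |= valid & _flatline_mask(values, rules.flatline_minutes)

    out.valid = valid & ~flagged
    return out


def preprocess_cohort(cohort: Cohort, rules: NoiseRuleSet | None = None) -> Cohort:
    """Apply :func:`remove_noise` to every channel of every patient."""
    rules = rules or NoiseRuleSet()
    patients = []
    for p in cohort.patients:
        patients.append(Patient(
            id=p.id, sex=p.sex, age_group=p.age_group,
            admission_time=p.admission_time, stay_minutes=p.stay_minutes,
            channels={ch: remove_noise(s, rules) for ch, s in p.channels.items()},
            assessments=p.assessments, latent_pain=p.latent_pain,
            corruption=p.corruption,
        ))
    return Cohort(config=cohort.config, patients=patients)
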