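"""Fluctuation-feature engineering: slicing, integration, leveling, assignment.

One labeled feature vector is produced per CPOT assessment that passes every
gate:

* slicing — the 60 minutes ending at the evaluation time, ``(t-60, t]`` on the
  half-open minute convention, are extracted per predictor channel;
* presence rule — a window is usable only if >= 90% of its minutes are valid
  (54 of 60); windows with exactly 54 valid minutes are included;
* fluctuation integration — rising (sum of positive minute-to-minute
  increments) and falling (sum of magnitudes of negative increments) are
  accumulated over consecutive valid pairs only; their sum is the window's
  total variation;
* leveling — each integral is min-max normalized against the range of the 60
  rolling baseline integrals from hour 1-2 after ICU admission, cancelling
  between-patient differences in scale; values outside the baseline range map
  outside [0, 1] (no clipping — out-of-range variability is the signal);
* assignment — sex, age group, and the most recent RASS within 3 hours are
  attached, and the label is CPOT >= 3.

Predictors are the four channels systolic/diastolic pressure, pulse rate and
respiratory rate; SpO2 is never a predictor.  Every excluded assessment is
logged with its reason so that dataset rows + exclusions = total assessments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, PREDICTOR_CHANNELS, SEXES, AssessmentEvent, Cohort, VitalChannelSeries
from .errors import (
    BaselineUnavailableError,
    DegenerateBaselineError,
    RassUnavailableError,
    WindowUnavailableError,
)
from .preprocessing import NoiseRuleSet, preprocess_cohort

WINDOW_MINUTES = 60
PRESENCE_THRESHOLD = 0.90
BASELINE_FIRST_END = 60      # first baseline window ends 1 h after admission
BASELINE_RECORDS = 60        # one rolling integral per minute of hour 1-2
RASS_LOOKBACK_MINUTES = 180
LEVEL_EPSILON = 1e-9

#: Fixed feature order of the assembled design matrix.
FEATURE_COLUMNS = [
    "sbp_rising", "sbp_falling",
    "dbp_rising", "dbp_falling",
    "pulse_rate_rising", "pulse_rate_falling",
    "resp_rate_rising", "resp_rate_falling",
    "sex", "age_group", "rass",
]

#: Ordinal encodings: sex {female: 0, male: 1}; age group {20-44: 0,
#: 45-64: 1, 65+: 2}; RASS is used as its signed integer value.
SEX_CODES = {s: i for i, s in enumerate(SEXES)}
AGE_CODES = {g: i for i, g in enumerate(AGE_GROUPS)}

EXCLUSION_REASONS = (
    "window_unavailable", "low_presence", "baseline_unavailable",
    "degenerate_baseline", "no_recent_rass",
)


@dataclass
class Window:
    """Channel values and validity for the 60 minutes ending at eval_time."""

    channel: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if self.values.size != WINDOW_MINUTES or self.valid.size != WINDOW_MINUTES:
            raise ValueError("a window holds exactly 60 minute slots")

    @property
    def presence(self) -> float:
        return float(np.mean(self.valid))


@dataclass(frozen=True)
class FluctuationSummary:
    rising: float       # channel units, >= 0
    falling: float      # channel units, >= 0
    presence: float     # fraction of valid minutes in the window

    @property
    def total(self) -> float:
        """Total variation of the valid sub-series."""
        return self.rising + self.falling


@dataclass(frozen=True)
class BaselineStats:
    """Range of the rolling baseline fluctuation integrals for one channel."""

    channel: str
    minimum: float
    maximum: float

    def __post_init__(self):
        if self.minimum > self.maximum:
            raise ValueError("baseline minimum must not exceed maximum")


def slice_window(series: VitalChannelSeries, eval_time: int) -> Window:
    """Extract minutes ``(eval_time - 60, eval_time]`` as a 60-slot window.

    Minutes outside the recorded grid appear as invalid slots.  Evaluation
    times earlier than minute 60 have no full window and raise.
    """
    if eval_time < WINDOW_MINUTES:
        raise WindowUnavailableError(
            f"eval_time {eval_time} precedes the first full one-hour window")
    start = eval_time - WINDOW_MINUTES + 1          # inclusive
    values = np.full(WINDOW_MINUTES, np.nan)
    valid = np.zeros(WINDOW_MINUTES, dtype=bool)
    n = len(series)
    src_lo = max(start, 0)
    src_hi = min(eval_time + 1, n)
    if src_hi > src_lo:
        dst_lo = src_lo - start
        dst_hi = dst_lo + (src_hi - src_lo)
        values[dst_lo:dst_hi] = series.values[src_lo:src_hi]
        valid[dst_lo:dst_hi] = series.valid[src_lo:src_hi]
    return Window(series.channel, values, valid)


def fluctuation_integrals(window: Window) -> FluctuationSummary:
    """Rising/falling fluctuation integrals over consecutive valid pairs.

    Pairs spanning an invalid minute are skipped.  The presence fraction is
    reported regardless; the caller enforces the 90% threshold.
    """
    v = window.values
    ok = window.valid[1:] & window.valid[:-1]
    with np.errstate(invalid="ignore"):
        d = np.diff(v)
    d = np.where(ok, d, 0.0)
    rising = float(np.sum(np.maximum(d, 0.0)))
    falling = float(np.sum(np.maximum(-d, 0.0)))
    return FluctuationSummary(rising=rising, falling=falling, presence=window.presence)


def baseline_minmax(series: VitalChannelSeries, admission: int = 0,
                    mode: str = "rolling_window") -> BaselineStats:
    """Per-patient baseline fluctuation range from hour 1-2 after admission.

    ``rolling_window`` (default): for each of the 60 minutes m in
    [admission+60, admission+120), the total fluctuation integral
    (rising + falling) of the trailing one-hour window ending at m is
    computed; the min and max of these 60 records are returned.  Every one of
    the 60 windows must itself satisfy the 90% presence rule.

    ``per_minute_diff``: the 60 records are the absolute minute-to-minute
    differences at those minutes; at least 54 of the 60 (90%) must be
    computable from valid pairs.
    """
    first = admission + BASELINE_FIRST_END
    last = first + BASELINE_RECORDS            # exclusive
    if len(series) < last:
        raise BaselineUnavailableError(
            f"series of length {len(series)} does not cover the baseline "
            f"hour (needs minutes {admission}..{last - 1})")
    if mode == "rolling_window":
        records = []
        for m in range(first, last):
            w = slice_window(series, m)
            if w.presence < PRESENCE_THRESHOLD:
                raise BaselineUnavailableError(
                    f"baseline window ending at minute {m} has presence "
                    f"{w.presence:.2f} < {PRESENCE_THRESHOLD}")
            records.append(fluctuation_integrals(w).total)
        records = np.asarray(records)
    elif mode == "per_minute_diff":
        v, ok = series.values, series.valid
        pair_ok = ok[first:last] & ok[first - 1:last - 1]
        with np.errstate(invalid="ignore"):
            diffs = np.abs(v[first:last] - v[first - 1:last - 1])
        if np.mean(pair_ok) < PRESENCE_THRESHOLD:
            raise BaselineUnavailableError(
                "fewer than 90% of baseline minute-to-minute differences are computable")
        records = diffs[pair_ok]
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return BaselineStats(channel=series.channel,
                         minimum=float(records.min()), maximum=float(records.max()))


def level(value: float, stats: BaselineStats) -> float:
    """Min-max normalize a fluctuation integral against the baseline range.

    Values outside the baseline range map outside [0, 1]; no clipping.
    """
    span = stats.maximum - stats.minimum
    if span < LEVEL_EPSILON:
        raise DegenerateBaselineError(
            f"baseline range for {stats.channel!r} is degenerate "
            f"(max - min = {span:.3e} < {LEVEL_EPSILON})")
    return (value - stats.minimum) / span


def recent_rass(assessments: list[AssessmentEvent], eval_time: int) -> int:
    """RASS of the latest assessment within 3 h of (and including) eval_time.

    Ties on identical timestamps are broken by the latest insertion order.
    """
    best = None
    for a in assessments:
        if eval_time - RASS_LOOKBACK_MINUTES <= a.time <= eval_time:
            if best is None or a.time >= best.time:
                best = a
    if best is None:
        raise RassUnavailableError(
            f"no RASS assessment within {RASS_LOOKBACK_MINUTES} minutes of minute {eval_time}")
    return best.rass


@dataclass
class LabeledDataset:
    """Design matrix (one row per retained assessment) plus the exclusion log."""

    frame: pd.DataFrame          # patient_id, eval_time, FEATURE_COLUMNS, label
    exclusions: pd.DataFrame     # patient_id, eval_time, reason

    @property
    def feature_names(self) -> list[str]:
        return list(FEATURE_COLUMNS)

    @property
    def X(self) -> np.ndarray:
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def exclusion_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in EXCLUSION_REASONS}
        for r, c in self.exclusions["reason"].value_counts().items():
            counts[str(r)] = int(c)
        return counts

    def prevalence(self) -> float:
        """Fraction of retained assessments labeled positive."""
        return float(self.frame["label"].mean()) if len(self.frame) else float("nan")

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the dataset CSV and a JSON sidecar of exclusion counts."""
        import json

        self.frame.to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump({"n_rows": len(self.frame),
                           "exclusions": self.exclusion_counts()},
                          fh, indent=2, sort_keys=True)
                fh.write("\n")

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        frame = pd.read_csv(path)
        empty = pd.DataFrame(columns=["patient_id", "eval_time", "reason"])
        return cls(frame=frame, exclusions=empty)


def build_dataset(cohort: Cohort, rules: NoiseRuleSet | None = None,
                  baseline_mode: str = "rolling_window") -> LabeledDataset:
    """Assemble one labeled feature vector per CPOT assessment.

    When ``rules`` is given, noise removal is applied first; pass ``None``
    for a cohort that has already been preprocessed.  Gates are checked in
    the order: baseline availability (per patient), degenerate baseline (per
    patient), window availability, presence, recent RASS; the first failing
    gate is logged as the exclusion reason.
    """
    if rules is not None:
        cohort = preprocess_cohort(cohort, rules)

    rows: list[dict] = []
    excluded: list[tuple[str, int, str]] = []

    for p in cohort.patients:
        baselines: dict[str, BaselineStats] = {}
        patient_reason = None
        for ch in PREDICTOR_CHANNELS:
            try:
                stats = baseline_minmax(p.channels[ch], p.admission_time, baseline_mode)
            except BaselineUnavailableError:
                patient_reason = "baseline_unavailable"
                break
            if stats.maximum - stats.minimum < LEVEL_EPSILON:
                patient_reason = "degenerate_baseline"
                break
            baselines[ch] = stats
        if patient_reason is not None:
            excluded.extend((p.id, a.time, patient_reason) for a in p.assessments)
            continue

        for a in p.assessments:
            try:
                feats: dict[str, float] = {}
                for ch in PREDICTOR_CHANNELS:
                    w = slice_window(p.channels[ch], a.time)
                    if w.presence < PRESENCE_THRESHOLD:
                        excluded.append((p.id, a.time, "low_presence"))
                        raise _Skip
                    fl = fluctuation_integrals(w)
                    feats[f"{ch}_rising"] = level(fl.rising, baselines[ch])
                    feats[f"{ch}_falling"] = level(fl.falling, baselines[ch])
                rass = recent_rass(p.assessments, a.time)
            except WindowUnavailableError:
                excluded.append((p.id, a.time, "window_unavailable"))
                continue
            except RassUnavailableError:
                excluded.append((p.id, a.time, "no_recent_rass"))
                continue
            except DegenerateBaselineError:
                excluded.append((p.id, a.time, "degenerate_baseline"))
                continue
            except _Skip:
                continue
            rows.append({
                "patient_id": p.id, "eval_time": a.time, **feats,
                "sex": SEX_CODES[p.sex], "age_group": AGE_CODES[p.age_group],
                "rass": a.rass, "label": int(a.cpot >= 3),
            })

    columns = ["patient_id", "eval_time", *FEATURE_COLUMNS, "label"]
    frame = pd.DataFrame(rows, columns=columns)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "eval_time", "reason"])
    return LabeledDataset(frame=frame, exclusions=exclusions)


class _Skip(Exception):
    """Internal control flow: assessment already logged as excluded."""
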