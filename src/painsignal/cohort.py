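"""Seeded synthetic ICU cohort generation.

Emulates the data model of an ICU pain-tracking study: per-minute vital signs
(pulse rate, systolic/diastolic arterial pressure, respiratory rate, SpO2),
CPOT/RASS/CAM-ICU assessment events performed every 8 hours plus extra
assessments when obvious pain occurs, and a latent per-minute pain intensity
that drives both the CPOT score and a transient perturbation of the vitals.

The generator is a pure function of (config, seed): identical inputs yield
byte-identical cohorts.  Latent pain, the injected artifact masks, and the
assessment schedule provide ground truth for every downstream test.

Mechanism
---------
Each vital channel is an AR(1) deviation process around a per-patient mean,
with per-patient innovation s.d. and autocorrelation drawn from physiologically
plausible ranges.  Sedation (RASS <= -1) scales the innovation s.d. by 0.7 per
sedation step.  A pain episode ramps a latent intensity up over ~5 minutes,
holds a plateau, then decays with a 30-minute half-life; while an episode is
active the minute-to-minute innovations are multiplied by
(1 + pain_effect_size) and an additive level bump proportional to
pain_effect_size * latent intensity is applied.  With pain_effect_size = 0 the
vitals are, by construction, independent of the pain labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.signal import lfilter

from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Channel conventions (shared minute grid: integer minutes since admission)
# ---------------------------------------------------------------------------

CHANNELS = ("pulse_rate", "sbp", "dbp", "resp_rate", "spo2")

#: Channels used as predictors downstream (SpO2 is generated but never a
#: predictor).  Order is fixed: systolic, diastolic, pulse, respiratory rate.
PREDICTOR_CHANNELS = ("sbp", "dbp", "pulse_rate", "resp_rate")

#: Hard physiologic plausibility bounds per channel (channel units).  Injected
#: artifact spikes land strictly outside these; the default noise-removal
#: rules use the same bounds.
PHYSIOLOGIC_BOUNDS = {
    "pulse_rate": (20.0, 250.0),
    "sbp": (30.0, 300.0),
    "dbp": (15.0, 200.0),
    "resp_rate": (2.0, 60.0),
    "spo2": (50.0, 100.0),
}

# Per-patient baseline parameter ranges: (mean low, mean high), (sd low, sd high)
_MEAN_RANGE = {
    "pulse_rate": (60.0, 100.0),
    "sbp": (100.0, 145.0),
    "dbp": (55.0, 85.0),
    "resp_rate": (12.0, 22.0),
    "spo2": (94.0, 99.0),
}
_SD_RANGE = {
    "pulse_rate": (0.5, 2.0),
    "sbp": (0.8, 2.5),
    "dbp": (0.5, 1.8),
    "resp_rate": (0.3, 1.0),
    "spo2": (0.1, 0.4),
}
_PHI_RANGE = (0.90, 0.97)

#: Additive level shift per unit latent intensity per unit pain_effect_size.
_PAIN_BUMP = {
    "pulse_rate": 10.0,
    "sbp": 15.0,
    "dbp": 8.0,
    "resp_rate": 4.0,
    "spo2": -1.5,
}

AGE_GROUPS = ("20-44", "45-64", "65+")
SEXES = ("female", "male")
_AGE_PROBS = (0.20, 0.30, 0.50)   # cohort median age ~65 -> half in 65+
_MALE_PROB = 0.58
_DELIRIUM_PROB = 0.217

# Assessment cadence: every 8 h starting 4 h after admission, leaving the
# baseline hour (minutes 60-120) and a settling period pain-free.
_ASSESS_INTERVAL = 480
_FIRST_ASSESS = 240
_MIN_ASSESSMENTS = 5
_EPISODE_EARLIEST_ONSET = 180
_EPISODE_LATEST_MARGIN = 45     # onset must leave room for the extra assessment

_RAMP_MINUTES = 5.0
_DECAY_HALF_LIFE = 30.0
_ACTIVE_THRESHOLD = 0.05
_SEDATION_SD_FACTOR = 0.7


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    pain_episode_rate is in episodes per patient-day (applied outside the
    3-hour admission settling window); its default is calibrated so that the
    default configuration yields a fraction of CPOT >= 3 assessments within
    one percentage point of ``pain_prevalence_target``.
    """

    n_patients: int = 100
    stay_hours_range: tuple[float, float] = (48.0, 96.0)
    pain_episode_rate: float = 0.098
    pain_effect_size: float = 1.0
    pain_prevalence_target: float = 0.033
    sedation_mix: tuple[float, float, float] = (0.428, 0.083, 0.489)
    artifact_rate: float = 0.004
    missing_rate: float = 0.01
    cpot_noise_sd: float = 0.6
    sedation_cpot_attenuation: float = 0.96
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be a non-negative integer, got {self.n_patients!r}")
        lo, hi = self.stay_hours_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo <= 0 or hi < lo:
            raise ConfigurationError(f"stay_hours_range must satisfy 0 < min <= max, got {self.stay_hours_range!r}")
        for name in ("pain_episode_rate", "pain_effect_size", "cpot_noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("pain_prevalence_target", "artifact_rate", "missing_rate",
                     "sedation_cpot_attenuation"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.sedation_mix) != 3 or any(p < 0 for p in self.sedation_mix):
            raise ConfigurationError(f"sedation_mix needs 3 non-negative proportions, got {self.sedation_mix!r}")
        if not math.isclose(sum(self.sedation_mix), 1.0, abs_tol=1e-6):
            raise ConfigurationError("sedation_mix proportions must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("stay_hours_range", "sedation_mix"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "cohort" in data:
            data = data["cohort"]
        return cls.from_dict(data)


@dataclass
class VitalChannelSeries:
    """One per-minute physiological channel on the admission-anchored grid."""

    channel: str
    values: np.ndarray          # float, NaN where the minute is absent
    valid: np.ndarray           # bool, same length

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have equal length")

    def __len__(self) -> int:
        return self.values.size

    def copy(self) -> "VitalChannelSeries":
        return VitalChannelSeries(self.channel, self.values.copy(), self.valid.copy())


@dataclass(frozen=True)
class AssessmentEvent:
    """A timestamped CPOT/RASS/CAM-ICU bedside assessment."""

    time: int                   # minute offset from admission
    cpot: int                   # 0..8
    rass: int                   # -5..+4
    cam_icu: str                # positive | negative | unassessable

    def __post_init__(self):
        if not 0 <= self.cpot <= 8:
            raise ValueError(f"CPOT must lie in [0, 8], got {self.cpot}")
        if not -5 <= self.rass <= 4:
            raise ValueError(f"RASS must lie in [-5, +4], got {self.rass}")


@dataclass
class Patient:
    id: str
    sex: str
    age_group: str
    admission_time: int                     # minute 0 reference
    stay_minutes: int
    channels: dict[str, VitalChannelSeries]
    assessments: list[AssessmentEvent]
    latent_pain: np.ndarray | None = None   # per-minute intensity in [0,1]
    corruption: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[Patient]

    @property
    def n_assessments(self) -> int:
        return sum(len(p.assessments) for p in self.patients)

    def pain_prevalence(self) -> float:
        """Fraction of assessments with CPOT >= 3 (NaN for an empty cohort)."""
        total = self.n_assessments
        if total == 0:
            return float("nan")
        pos = sum(1 for p in self.patients for a in p.assessments if a.cpot >= 3)
        return pos / total


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def derive_cpot(latent_intensity: float, observation_noise_sd: float,
                rng: np.random.Generator) -> int:
    """Map a latent pain intensity in [0, 1] to an observed CPOT score.

    The expected score rises linearly (0 -> 0, 1 -> 8); Gaussian observation
    noise models inter-rater variation; the result is rounded and clamped to
    the 9-level scale.
    """
    if not 0.0 <= latent_intensity <= 1.0:
        raise ValueError(f"latent_intensity must lie in [0, 1], got {latent_intensity!r}")
    raw = 8.0 * latent_intensity
    if observation_noise_sd > 0:
        raw += observation_noise_sd * rng.standard_normal()
    return int(np.clip(np.rint(raw), 0, 8))


def inject_artifacts(series: VitalChannelSeries, artifact_rate: float,
                     missing_rate: float, rng: np.random.Generator,
                     ) -> tuple[VitalChannelSeries, np.ndarray]:
    """Corrupt a clean series with sensor spikes and dropped minutes.

    Spikes are pushed strictly beyond the channel's physiologic plausibility
    bounds; missing minutes become NaN with valid=False.  Returns the
    corrupted series and the ground-truth corruption mask (True where the
    minute was altered or dropped).
    """
    if not (0.0 <= artifact_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ConfigurationError("artifact_rate and missing_rate must lie in [0, 1]")
    n = len(series)
    out = series.copy()
    mask = np.zeros(n, dtype=bool)
    if n == 0 or (artifact_rate == 0.0 and missing_rate == 0.0):
        return out, mask

    lo, hi = PHYSIOLOGIC_BOUNDS[series.channel]
    span = hi - lo
    spike = rng.random(n) < artifact_rate
    missing = rng.random(n) < missing_rate

    # spikes: beyond either bound by 5-50% of the plausible span
    offsets = rng.uniform(0.05 * span, 0.50 * span, size=n)
    high_side = rng.random(n) < 0.5
    spiked_values = np.where(high_side, hi + offsets, lo - offsets)
    if series.channel == "spo2":
        # saturation cannot exceed 100%; spikes only go low
        spiked_values = lo - offsets
    out.values[spike] = spiked_values[spike]

    out.values[missing] = np.nan
    out.valid[missing] = False
    mask = spike | missing
    return out, mask


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------

def _draw_rass_base(rng: np.random.Generator, mix) -> int:
    stratum = rng.choice(3, p=np.asarray(mix, dtype=float) / sum(mix))
    if stratum == 0:
        return 0
    if stratum == 1:
        return int(rng.choice([1, 2, 3, 4], p=[0.60, 0.25, 0.10, 0.05]))
    return int(rng.choice([-1, -2, -3, -4, -5], p=[0.30, 0.25, 0.20, 0.15, 0.10]))


def _episode_profile(stay: int, episodes, out: np.ndarray) -> None:
    """Accumulate (max-combine) episode intensity profiles into ``out``."""
    t_all = np.arange(stay, dtype=float)
    for onset, peak, duration in episodes:
        hi = min(stay, int(onset + _RAMP_MINUTES + duration + 8 * _DECAY_HALF_LIFE))
        lo = int(onset)
        t = t_all[lo:hi] - onset
        shape = np.empty_like(t)
        ramp = t < _RAMP_MINUTES
        plateau = (t >= _RAMP_MINUTES) & (t < _RAMP_MINUTES + duration)
        decay = t >= _RAMP_MINUTES + duration
        shape[ramp] = t[ramp] / _RAMP_MINUTES
        shape[plateau] = 1.0
        shape[decay] = 2.0 ** (-(t[decay] - _RAMP_MINUTES - duration) / _DECAY_HALF_LIFE)
        np.maximum(out[lo:hi], peak * shape, out=out[lo:hi])


def _simulate_patient(cfg: CohortConfig, index: int,
                      seed_seq: np.random.SeedSequence) -> Patient:
    rng = np.random.default_rng(seed_seq)
    lo_h, hi_h = cfg.stay_hours_range
    stay = int(rng.integers(int(lo_h * 60), int(hi_h * 60) + 1))
    sex = SEXES[1] if rng.random() < _MALE_PROB else SEXES[0]
    age_group = AGE_GROUPS[rng.choice(3, p=_AGE_PROBS)]
    rass_base = _draw_rass_base(rng, cfg.sedation_mix)
    sed_factor = _SEDATION_SD_FACTOR ** max(0, -rass_base)

    # --- pain episodes -----------------------------------------------------
    onset_lo = _EPISODE_EARLIEST_ONSET
    onset_hi = stay - _EPISODE_LATEST_MARGIN
    episodes: list[tuple[float, float, float]] = []
    if onset_hi > onset_lo and cfg.pain_episode_rate > 0:
        lam = cfg.pain_episode_rate * (onset_hi - onset_lo) / 1440.0
        n_epi = int(rng.poisson(lam))
        onsets = np.sort(rng.uniform(onset_lo, onset_hi, size=n_epi))
        # peak floor keeps episode-triggered assessments near-certainly
        # CPOT-positive in every sedation stratum, preserving the null
        # structure (labels independent of RASS when pain_effect_size = 0)
        peaks = rng.uniform(0.65, 1.0, size=n_epi)
        durations = rng.uniform(20.0, 60.0, size=n_epi)
        episodes = list(zip(onsets, peaks, durations))

    latent = np.zeros(stay)
    _episode_profile(stay, episodes, latent)
    active = latent > _ACTIVE_THRESHOLD

    # --- vital channels ----------------------------------------------------
    channels: dict[str, VitalChannelSeries] = {}
    corruption: dict[str, np.ndarray] = {}
    pain_gain = np.where(active, 1.0 + cfg.pain_effect_size, 1.0)
    for ch in CHANNELS:
        mu = rng.uniform(*_MEAN_RANGE[ch])
        sigma = rng.uniform(*_SD_RANGE[ch])
        phi = rng.uniform(*_PHI_RANGE)
        eps = rng.standard_normal(stay)
        dev = lfilter([1.0], [1.0, -phi], sigma * sed_factor * pain_gain * eps)
        values = mu + dev + cfg.pain_effect_size * _PAIN_BUMP[ch] * latent
        if ch == "spo2":
            np.clip(values, None, 100.0, out=values)
        series = VitalChannelSeries(ch, values, np.ones(stay, dtype=bool))
        series, mask = inject_artifacts(series, cfg.artifact_rate, cfg.missing_rate, rng)
        channels[ch] = series
        corruption[ch] = mask

    # --- assessment schedule ----------------------------------------------
    sched = np.arange(float(_FIRST_ASSESS), float(stay), float(_ASSESS_INTERVAL))
    if sched.size < _MIN_ASSESSMENTS:
        # inclusion criterion: every patient is assessed at least five times
        first = min(float(_FIRST_ASSESS), 0.25 * stay)
        sched = np.unique(np.rint(np.linspace(first, stay - 1, _MIN_ASSESSMENTS)))
    times = [int(round(t)) for t in sched]
    for onset, _, duration in episodes:
        extra = onset + rng.uniform(_RAMP_MINUTES, min(25.0, _RAMP_MINUTES + duration))
        extra = int(round(min(extra, stay - 1)))
        times.append(extra)

    assessments: list[AssessmentEvent] = []
    for t in sorted(times):
        jitter = int(rng.choice([-1, 0, 1], p=[0.10, 0.80, 0.10]))
        rass_t = int(np.clip(rass_base + jitter, -5, 4))
        attenuation = cfg.sedation_cpot_attenuation ** max(0, -rass_t)
        intensity = float(latent[t]) * attenuation
        cpot = derive_cpot(intensity, cfg.cpot_noise_sd, rng)
        if rass_t <= -4:
            cam = "unassessable"
        else:
            cam = "positive" if rng.random() < _DELIRIUM_PROB else "negative"
        assessments.append(AssessmentEvent(time=t, cpot=cpot, rass=rass_t, cam_icu=cam))

    return Patient(
        id=f"P{index:05d}",
        sex=sex,
        age_group=age_group,
        admission_time=0,
        stay_minutes=stay,
        channels=channels,
        assessments=assessments,
        latent_pain=latent,
        corruption=corruption,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a synthetic cohort; a pure function of (config, seed)."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)
    patients = [_simulate_patient(config, i, children[i])
                for i in range(config.n_patients)]
    return Cohort(config=config, patients=patients)


# ---------------------------------------------------------------------------
# Serialization (CSV tables, UTF-8, RFC-4180 via pandas)
# ---------------------------------------------------------------------------

_ADMISSION_EPOCH = "2017-01-01T00:00:00"


def save_cohort(cohort: Cohort, outdir) -> None:
    """Write patients.csv, vitals.csv, assessments.csv and (synthetic cohorts
    only) ground_truth.csv under ``outdir``."""
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    epoch = pd.Timestamp(_ADMISSION_EPOCH)
    pats = pd.DataFrame({
        "id": [p.id for p in cohort.patients],
        "sex": [p.sex for p in cohort.patients],
        "age_group": [p.age_group for p in cohort.patients],
        "admission_iso8601": [(epoch + pd.Timedelta(hours=6 * i)).isoformat()
                              for i in range(len(cohort.patients))],
        "stay_minutes": [p.stay_minutes for p in cohort.patients],
    })
    pats.to_csv(os.path.join(outdir, "patients.csv"), index=False)

    vit_frames = []
    for p in cohort.patients:
        minutes = np.arange(p.stay_minutes)
        for ch in CHANNELS:
            s = p.channels[ch]
            vit_frames.append(pd.DataFrame({
                "patient_id": p.id, "minute": minutes,
                "channel": ch, "value": np.round(s.values, 2),
            }))
    vitals = (pd.concat(vit_frames, ignore_index=True) if vit_frames
              else pd.DataFrame(columns=["patient_id", "minute", "channel", "value"]))
    vitals.to_csv(os.path.join(outdir, "vitals.csv"), index=False)

    rows = [(p.id, a.time, a.cpot, a.rass, a.cam_icu)
            for p in cohort.patients for a in p.assessments]
    pd.DataFrame(rows, columns=["patient_id", "minute", "cpot", "rass", "cam_icu"]) \
        .to_csv(os.path.join(outdir, "assessments.csv"), index=False)

    if all(p.latent_pain is not None for p in cohort.patients):
        gt_frames = [pd.DataFrame({
            "patient_id": p.id,
            "minute": np.arange(p.stay_minutes),
            "latent_pain": np.round(p.latent_pain, 4),
        }) for p in cohort.patients]
        gt = (pd.concat(gt_frames, ignore_index=True) if gt_frames
              else pd.DataFrame(columns=["patient_id", "minute", "latent_pain"]))
        gt.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)


def load_cohort(indir, config: CohortConfig | None = None) -> Cohort:
    """Reconstruct a Cohort from the CSV tables written by :func:`save_cohort`.

    Minutes absent from vitals.csv (or with an empty value) become invalid
    slots on the admission-anchored grid; latent ground truth is loaded when
    ground_truth.csv is present.
    """
    import os

    import pandas as pd

    pats = pd.read_csv(os.path.join(indir, "patients.csv"))
    vitals = pd.read_csv(os.path.join(indir, "vitals.csv"))
    assess = pd.read_csv(os.path.join(indir, "assessments.csv"))
    gt_path = os.path.join(indir, "ground_truth.csv")
    gt = pd.read_csv(gt_path) if os.path.exists(gt_path) else None

    patients = []
    vit_by_pat = dict(tuple(vitals.groupby("patient_id", sort=False))) if len(vitals) else {}
    ass_by_pat = dict(tuple(assess.groupby("patient_id", sort=False))) if len(assess) else {}
    gt_by_pat = dict(tuple(gt.groupby("patient_id", sort=False))) if gt is not None and len(gt) else {}

    for row in pats.itertuples(index=False):
        stay = int(row.stay_minutes)
        channels = {}
        pv = vit_by_pat.get(row.id)
        for ch in CHANNELS:
            values = np.full(stay, np.nan)
            if pv is not None:
                sub = pv[pv["channel"] == ch]
                idx = sub["minute"].to_numpy(dtype=int)
                values[idx] = sub["value"].to_numpy(dtype=float)
            channels[ch] = VitalChannelSeries(ch, values, ~np.isnan(values))
        events = []
        pa = ass_by_pat.get(row.id)
        if pa is not None:
            for a in pa.sort_values("minute", kind="stable").itertuples(index=False):
                events.append(AssessmentEvent(int(a.minute), int(a.cpot),
                                              int(a.rass), str(a.cam_icu)))
        latent = None
        pg = gt_by_pat.get(row.id)
        if pg is not None:
            latent = np.zeros(stay)
            latent[pg["minute"].to_numpy(dtype=int)] = pg["latent_pain"].to_numpy(dtype=float)
        patients.append(Patient(
            id=str(row.id), sex=str(row.sex), age_group=str(row.age_group),
            admission_time=0, stay_minutes=stay, channels=channels,
            assessments=events, latent_pain=latent,
        ))
    return Cohort(config=config or CohortConfig(n_patients=len(patients)), patients=patients)
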