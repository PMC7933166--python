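"""One-command experiment runner: simulate -> preprocess -> featurize ->
evaluate -> report, fully seeded and logged.

A single root seed is fanned out to named sub-streams (cohort, resampling,
splitting) so that individual stages can be re-run in isolation; a run is
reproducible from its persisted config and seed alone.  Each stage boundary
logs row counts (patients simulated, assessments in, excluded, trained on),
and stage failures propagate as :class:`~painsignal.errors.StageError` with
the stage name and a remediation hint.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .cohort import Cohort, CohortConfig, generate_cohort, save_cohort
from .errors import PainsignalError, StageError
from .evaluation import EvaluationReport, ModelSpec, default_model_specs, evaluate
from .features import LabeledDataset, build_dataset
from .preprocessing import NoiseRuleSet, preprocess_cohort
from .resampling import ResampleConfig

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything a run needs: sub-configs, model grids, seeds, and options.

    When ``seed`` is set it overrides the sub-config seeds via deterministic
    fan-out; leave it None to control each stream individually.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise_rules: NoiseRuleSet = field(default_factory=NoiseRuleSet)
    resample: ResampleConfig | None = field(default_factory=ResampleConfig)
    models: list[ModelSpec] = field(default_factory=default_model_specs)
    seed: int | None = None
    n_folds: int = 10
    grid_folds: int = 10
    split_unit: str = "patient"       # "patient" (leakage-free) or "assessment"
    baseline_mode: str = "rolling_window"
    persist_cohort: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs: dict = {}
        if d.get("cohort") is not None:
            kwargs["cohort"] = CohortConfig.from_dict(d["cohort"])
        if d.get("noise_rules") is not None:
            kwargs["noise_rules"] = NoiseRuleSet.from_dict(d["noise_rules"])
        if "resample" in d:
            kwargs["resample"] = (None if d["resample"] is None
                                  else ResampleConfig.from_dict(d["resample"]))
        if d.get("models") is not None:
            kwargs["models"] = [ModelSpec.from_dict(m) for m in d["models"]]
        for key in ("seed", "n_folds", "grid_folds", "split_unit",
                    "baseline_mode", "persist_cohort"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "noise_rules": {
                "bounds": {k: list(v) for k, v in self.noise_rules.bounds.items()},
                "max_abs_jump": dict(self.noise_rules.max_abs_jump),
                "flatline_minutes": self.noise_rules.flatline_minutes,
            },
            "resample": (None if self.resample is None
                         else dataclasses.asdict(self.resample)),
            "models": [{"family": m.family, "grid": m.grid} for m in self.models],
            "seed": self.seed,
            "n_folds": self.n_folds,
            "grid_folds": self.grid_folds,
            "split_unit": self.split_unit,
            "baseline_mode": self.baseline_mode,
            "persist_cohort": self.persist_cohort,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _fan_out_seeds(root_seed: int) -> dict[str, int]:
    """Derive named sub-stream seeds (< 2**31) from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(3)
    return {name: int(s % (2**31))
            for name, s in zip(("cohort", "resample", "split"), state)}


def _resolved(config: ExperimentConfig) -> tuple[ExperimentConfig, int]:
    """Apply root-seed fan-out; returns the concrete config and split seed."""
    if config.seed is None:
        return config, (config.resample.seed if config.resample else 0)
    seeds = _fan_out_seeds(config.seed)
    cohort = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    resample = (dataclasses.replace(config.resample, seed=seeds["resample"])
                if config.resample is not None else None)
    concrete = dataclasses.replace(config, cohort=cohort, resample=resample)
    return concrete, seeds["split"]


def run_experiment(config: ExperimentConfig | None = None,
                   outdir: str | None = None,
                   seed: int | None = None) -> EvaluationReport:
    """Run the full pipeline; persist artifacts under ``outdir`` if given.

    Artifacts: cohort CSVs (patients/vitals/assessments/ground_truth),
    dataset.csv + exclusions.json, report.json, operating_points.csv, and
    run.json (library versions, resolved seeds, config echo).
    """
    config = config or ExperimentConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config, split_seed = _resolved(config)
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    # --- simulate ----------------------------------------------------------
    try:
        cohort = generate_cohort(config.cohort)
    except PainsignalError as e:
        raise StageError("simulate", str(e), "check the cohort configuration") from e
    logger.info("simulate: %d patients, %d assessments",
                len(cohort.patients), cohort.n_assessments)
    if outdir and config.persist_cohort:
        save_cohort(cohort, outdir)

    # --- preprocess --------------------------------------------------------
    try:
        clean = preprocess_cohort(cohort, config.noise_rules)
    except PainsignalError as e:
        raise StageError("preprocess", str(e), "check the noise rules") from e
    logger.info("preprocess: noise rules applied to %d patients", len(clean.patients))

    # --- featurize ---------------------------------------------------------
    try:
        dataset = build_dataset(clean, rules=None, baseline_mode=config.baseline_mode)
    except PainsignalError as e:
        raise StageError("featurize", str(e), "check window/baseline settings") from e
    logger.info("featurize: %d assessments in, %d rows retained, %d excluded",
                clean.n_assessments, len(dataset), len(dataset.exclusions))
    if outdir:
        dataset.to_csv(os.path.join(outdir, "dataset.csv"),
                       os.path.join(outdir, "exclusions.json"))

    # --- evaluate ----------------------------------------------------------
    try:
        report = evaluate(dataset, config.models, config.resample,
                          seed=split_seed, n_folds=config.n_folds,
                          grid_folds=config.grid_folds,
                          split_unit=config.split_unit,
                          exclusions=dataset.exclusion_counts())
    except PainsignalError as e:
        raise StageError(
            "evaluate", str(e),
            "increase n_patients or the pain episode rate so both classes "
            "are populated in every fold") from e
    logger.info("evaluate: best model %s, test AUROC %.3f", report.best_family,
                report.models[report.best_family].test_auroc)

    # --- report ------------------------------------------------------------
    if outdir:
        report.to_json(os.path.join(outdir, "report.json"))
        report.operating_table_frame().to_csv(
            os.path.join(outdir, "operating_points.csv"), index=False)
        _write_run_metadata(config, split_seed, outdir)
    return report


def _write_run_metadata(config: ExperimentConfig, split_seed: int, outdir: str) -> None:
    import sklearn

    meta = {
        "painsignal_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "seeds": {"root": config.seed, "cohort": config.cohort.seed,
                  "resample": (config.resample.seed if config.resample else None),
                  "split": split_seed},
        "config": config.to_dict(),
    }
    with open(os.path.join(outdir, "run.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
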