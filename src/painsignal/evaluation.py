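"""Classifier comparison and ROC operating-point analysis.

Trains random-forest, RBF-SVM and logistic-regression pain classifiers on the
leveled fluctuation features and reports, per model: train/test ROC curves and
AUROCs, an operating-point table at predefined sensitivity/specificity
targets, the optimal point (maximum harmonic mean of sensitivity and
specificity), and — for the random forest — impurity-decrease feature
importances.

Evaluation design: stratified 10-fold cross-validation, i.e. ten random 9:1
train/validation splits; within each training portion a grid search (itself
k-fold cross-validated) selects hyperparameters, oversampling is refit on
training data only, and the held-out fold is scored by the refit model.  The
reported test AUROC is computed on the pooled out-of-fold scores, so every
assessment is scored exactly once out-of-sample; at ~3% positive prevalence
this is what makes the test estimate usable.  A single 9:1 split with the
grid search inside is available as :func:`split_and_crossvalidate`.

Classifier scores are not comparable across folds (each fold fits its own
model, and margins such as an SVM decision function carry fold-specific
offsets), so the reported cross-validated AUROC is the unweighted mean of the
per-fold AUROCs; merging scores before computing a single AUROC mixes
incomparable scales and biases the estimate.  The merged out-of-fold scores
are still used — with probability-scale scores — to draw the test ROC curve
and read off the operating-point table, which needs one curve over all data.

Oversampling is always fit inside the training side of a split — resampling
before splitting would place synthetic near-copies of minority points on both
sides and inflate the apparent AUROC.

ROC conventions: thresholds are the distinct score values, classification is
positive iff score >= threshold, tied scores share one vertex, and the curve
is anchored at (sensitivity 0, specificity 1) and (sensitivity 1,
specificity 0).  AUROC is the trapezoidal area in sensitivity versus
(1 - specificity), which equals the Mann-Whitney statistic
P(score+ > score-) + 0.5 P(tie).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, RocUndefinedError, StratificationError
from .resampling import ResampleConfig, resample

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("random_forest", "svm_rbf", "logistic_regression")

DEFAULT_SENS_TARGETS = (0.6, 0.7, 0.8, 0.9)
DEFAULT_SPEC_TARGETS = (0.6, 0.7, 0.8, 0.9)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def binarize_cpot(score: int) -> int:
    """Binary pain label: CPOT 0-2 is negative, CPOT >= 3 is positive."""
    if not 0 <= score <= 8:
        raise ValueError(f"CPOT score must lie in [0, 8], got {score!r}")
    return int(score >= 3)


def prevalence(n_positive: int, n_total: int) -> float:
    """Positive fraction as a percentage, 100 * n_positive / n_total."""
    if n_total <= 0:
        raise ValueError("prevalence is undefined for an empty population")
    if not 0 <= n_positive <= n_total:
        raise ValueError(f"need 0 <= n_positive <= n_total, got ({n_positive}, {n_total})")
    return 100.0 * n_positive / n_total


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A model family with its hyperparameter grid and (after search) the
    selected point."""

    family: str
    grid: dict[str, list]
    selected: dict | None = None

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError("hyperparameter grid must be non-empty")

    def combinations(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, vals))
                for vals in itertools.product(*(self.grid[k] for k in keys))]

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(family=d["family"], grid={k: list(v) for k, v in d["grid"].items()},
                   selected=d.get("selected"))


def default_model_specs() -> list[ModelSpec]:
    """Default grids: singletons pinned at the study's selected optima.

    SVM C=10, gamma=10, RBF kernel; RF max_depth=14, 17 trees, Gini; LR
    C=1.0, tol=1e-4.  Widen the grids in the experiment config to search.
    """
    return [
        ModelSpec("random_forest",
                  {"max_depth": [14], "n_estimators": [17], "criterion": ["gini"]}),
        ModelSpec("svm_rbf", {"C": [10.0], "gamma": [10.0], "kernel": ["rbf"]}),
        ModelSpec("logistic_regression", {"C": [1.0], "tol": [1e-4]}),
    ]


def _make_estimator(family: str, params: dict, seed: int):
    """Instantiate a model; SVM and LR get in-pipeline standardization (fit
    on training data only), the forest consumes raw features."""
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm_rbf":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed, **params))])
    if family == "logistic_regression":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=2000, **params))])
    raise ConfigurationError(f"unknown model family {family!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Vertices of an empirical ROC curve, one per distinct score plus the
    (sens 0, spec 1) anchor at threshold +inf; ordered by falling threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def vertices(self):
        return zip(self.thresholds, self.sensitivity, self.specificity)


@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC curve: positive iff score >= threshold, ties grouped."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise RocUndefinedError("ROC requires both positive and negative labels")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # one vertex per distinct score: take the last index of each tie block
    last = np.flatnonzero(np.diff(s_sorted) != 0)
    last = np.concatenate([last, [s.size - 1]])
    thresholds = np.concatenate([[np.inf], s_sorted[last]])
    sens = np.concatenate([[0.0], tp[last] / n_pos])
    spec = np.concatenate([[1.0], 1.0 - fp[last] / n_neg])
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def auroc(curve: ROCCurve) -> float:
    """Trapezoidal area under sensitivity versus (1 - specificity)."""
    fpr = 1.0 - curve.specificity
    return float(np.trapezoid(curve.sensitivity, fpr))


def harmonic_mean(sensitivity: float, specificity: float) -> float:
    """2sp/(s+p); 0 by continuity when either argument is 0."""
    if sensitivity <= 0.0 or specificity <= 0.0:
        logger.debug("harmonic_mean: zero argument, returning 0 by continuity")
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


def harmonic_mean_3(sensitivity: float, specificity: float, auroc_value: float) -> float:
    """Three-way harmonic mean of sensitivity, specificity and AUROC.

    Exposed for completeness; the operating-point analysis uses the two-way
    sensitivity/specificity mean.
    """
    vals = (sensitivity, specificity, auroc_value)
    if any(v <= 0.0 for v in vals):
        return 0.0
    return 3.0 / sum(1.0 / v for v in vals)


@dataclass(frozen=True)
class OperatingPointRow:
    condition: str
    point: OperatingPoint
    achieved: bool = True


def operating_point_table(curve: ROCCurve,
                          sens_targets=DEFAULT_SENS_TARGETS,
                          spec_targets=DEFAULT_SPEC_TARGETS) -> list[OperatingPointRow]:
    """Sensitivity/specificity at predefined targets, without interpolation.

    For each sensitivity target the achieved point is the vertex with the
    smallest sensitivity >= target (ties resolved toward higher specificity),
    and symmetrically for specificity targets.  An unreachable target is
    reported at the nearest achievable vertex and flagged.
    """
    verts = list(curve.vertices())
    rows: list[OperatingPointRow] = []

    def pick(axis: int, target: float):
        cands = [v for v in verts if v[axis] >= target]
        other = 2 if axis == 1 else 1
        if cands:
            best = min(cands, key=lambda v: (v[axis], -v[other]))
            return best, True
        best = max(verts, key=lambda v: (v[axis], v[other]))
        return best, False

    for t in sens_targets:
        (thr, sens, spec), ok = pick(1, t)
        rows.append(OperatingPointRow(f"sensitivity>={t}", OperatingPoint(sens, spec, thr), ok))
    for t in spec_targets:
        (thr, sens, spec), ok = pick(2, t)
        rows.append(OperatingPointRow(f"specificity>={t}", OperatingPoint(sens, spec, thr), ok))
    return rows


def optimal_operating_point(curve: ROCCurve) -> OperatingPoint:
    """Vertex maximizing the harmonic mean of sensitivity and specificity;
    ties broken toward higher specificity."""
    best = max(curve.vertices(),
               key=lambda v: (harmonic_mean(v[1], v[2]), v[2]))
    return OperatingPoint(sensitivity=best[1], specificity=best[2], threshold=best[0])


def feature_importance_report(model, feature_names) -> list[tuple[str, float]]:
    """Impurity-decrease importances of a fitted random forest, normalized to
    sum 1 and ranked descending."""
    if not isinstance(model, RandomForestClassifier):
        raise TypeError("feature importances are reported for random forests only")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return [(feature_names[i], float(imp[i])) for i in order]


# ---------------------------------------------------------------------------
# Splitting, grid search, cross-validation
# ---------------------------------------------------------------------------

def _auroc_of(scores, labels) -> float:
    return auroc(roc_curve(scores, labels))


def _check_two_classes(y: np.ndarray, n_folds: int | None = None) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError(
            "the dataset contains a single class; enlarge the cohort (more "
            "patients or a higher pain episode rate) so both labels occur")
    if n_folds is not None and counts.min() < n_folds:
        raise StratificationError(
            f"the rarer class has {counts.min()} rows, fewer than the "
            f"{n_folds} folds requested; enlarge the dataset or reduce the "
            "number of folds")


def _fit_scored(family: str, params: dict, X_tr, y_tr, resample_cfg, seed: int):
    """Oversample the training rows, fit, and return the fitted model."""
    if resample_cfg is not None:
        X_tr, y_tr = resample(X_tr, y_tr, replace(resample_cfg, seed=seed))
    model = _make_estimator(family, params, seed)
    model.fit(X_tr, y_tr)
    return model


def grid_search(X, y, model_spec: ModelSpec, resample_cfg: ResampleConfig | None,
                seed: int, n_folds: int = 10) -> dict:
    """Select hyperparameters by mean cross-validated AUROC on (X, y).

    Oversampling is refit inside each training fold; validation folds are
    never resampled.  A single-point grid is returned directly.
    """
    combos = model_spec.combinations()
    if len(combos) == 1:
        return combos[0]
    _check_two_classes(y, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    best_params, best_score = None, -np.inf
    for params in combos:
        fold_scores = []
        for k, (tr, va) in enumerate(skf.split(X, y)):
            model = _fit_scored(model_spec.family, params, X[tr], y[tr],
                                resample_cfg, seed + k)
            fold_scores.append(_auroc_of(_scores(model, X[va]), y[va]))
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params


@dataclass
class SplitResult:
    """Outcome of one 9:1 split: the selected spec and out-of-sample scores."""

    model_spec: ModelSpec
    model: object
    train_scores: np.ndarray
    train_labels: np.ndarray
    test_scores: np.ndarray
    test_labels: np.ndarray
    test_index: np.ndarray


def split_and_crossvalidate(dataset, model_spec: ModelSpec, seed: int,
                            resample_cfg: ResampleConfig | None = ResampleConfig(),
                            test_size: float = 0.1,
                            grid_folds: int = 10) -> SplitResult:
    """One stratified 9:1 train/test split with grid search on the training
    portion, oversampling inside training folds, and a final refit.

    ``dataset`` is a LabeledDataset or an (X, y) pair.
    """
    X, y = (dataset.X, dataset.y) if hasattr(dataset, "X") else dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    idx = np.arange(y.size)
    tr, te = train_test_split(idx, test_size=test_size, stratify=y,
                              random_state=seed % (2**32), shuffle=True)
    selected = grid_search(X[tr], y[tr], model_spec, resample_cfg, seed, grid_folds)
    model = _fit_scored(model_spec.family, selected, X[tr], y[tr], resample_cfg, seed)
    return SplitResult(
        model_spec=ModelSpec(model_spec.family, model_spec.grid, selected=selected),
        model=model,
        train_scores=_scores(model, X[tr]), train_labels=y[tr],
        test_scores=_scores(model, X[te]), test_labels=y[te],
        test_index=te,
    )


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    family: str
    selected: dict
    train_auroc: float              # mean of per-fold training AUROCs
    test_auroc: float               # mean of per-fold held-out AUROCs
    pooled_test_auroc: float        # AUROC of the merged out-of-fold scores
    fold_test_aurocs: list[float]
    test_curve: ROCCurve
    train_curve: ROCCurve
    operating_points: list[OperatingPointRow]
    optimal_point: OperatingPoint
    optimal_harmonic_mean: float
    feature_importances: list[tuple[str, float]] | None = None


@dataclass
class EvaluationReport:
    models: dict[str, ModelResult]
    best_family: str
    prevalence_percent: float
    n_rows: int
    n_positive: int
    n_folds: int
    seed: int
    resample: dict | None
    exclusions: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _num(x):
            x = float(x)
            return x if np.isfinite(x) else repr(x)

        def _point(p: OperatingPoint) -> dict:
            return {"sensitivity": _num(p.sensitivity),
                    "specificity": _num(p.specificity),
                    "threshold": _num(p.threshold)}

        out = {
            "best_family": self.best_family,
            "prevalence_percent": _num(self.prevalence_percent),
            "n_rows": self.n_rows,
            "n_positive": self.n_positive,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "resample": self.resample,
            "exclusions": self.exclusions,
            "models": {},
        }
        for fam, r in self.models.items():
            out["models"][fam] = {
                "selected": r.selected,
                "train_auroc": _num(r.train_auroc),
                "test_auroc": _num(r.test_auroc),
                "pooled_test_auroc": _num(r.pooled_test_auroc),
                "fold_test_aurocs": [_num(a) for a in r.fold_test_aurocs],
                "operating_points": [
                    {"condition": row.condition, "achieved": row.achieved,
                     **_point(row.point)}
                    for row in r.operating_points],
                "optimal_point": _point(r.optimal_point),
                "optimal_harmonic_mean": _num(r.optimal_harmonic_mean),
                "feature_importances": (
                    [[n, _num(v)] for n, v in r.feature_importances]
                    if r.feature_importances is not None else None),
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def operating_table_frame(self) -> pd.DataFrame:
        """Operating-point table of the best model, one row per condition."""
        r = self.models[self.best_family]
        rows = [(row.condition, row.point.sensitivity, row.point.specificity,
                 row.point.threshold, row.achieved)
                for row in r.operating_points]
        rows.append(("optimal", r.optimal_point.sensitivity,
                     r.optimal_point.specificity, r.optimal_point.threshold, True))
        return pd.DataFrame(rows, columns=["condition", "sensitivity",
                                           "specificity", "threshold", "achieved"])


def evaluate(dataset, model_specs: list[ModelSpec] | None = None,
             resample_cfg: ResampleConfig | None = ResampleConfig(),
             seed: int = 0, n_folds: int = 10, grid_folds: int = 10,
             split_unit: str = "patient",
             exclusions: dict[str, int] | None = None) -> EvaluationReport:
    """Cross-validated comparison of the configured model families.

    Runs stratified ``n_folds``-fold cross-validation (each fold a 9:1 split
    when ``n_folds`` is 10); grid search and oversampling happen inside each
    training portion.  The reported train/test AUROCs are means of the
    per-fold AUROCs; the merged out-of-fold scores provide the test ROC curve
    and the operating-point table.  Feature importances come from a final
    forest refit on the full dataset.

    ``split_unit`` controls whether folds group all assessments of a patient
    together ("patient", the default) or split at the assessment level
    ("assessment").  Repeated assessments of one patient share demographics,
    sedation and the leveling denominators, so assessment-level folds let a
    flexible model recognise the patient across the split and inflate the
    held-out AUROC; grouping by patient removes that leakage.
    """
    model_specs = model_specs if model_specs is not None else default_model_specs()
    X, y = (dataset.X, dataset.y) if hasattr(dataset, "X") else dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y, n_folds)
    feature_names = (dataset.feature_names if hasattr(dataset, "feature_names")
                     else [f"f{i}" for i in range(X.shape[1])])

    groups = None
    if split_unit == "patient" and hasattr(dataset, "frame") and "patient_id" in getattr(dataset, "frame").columns:
        groups = dataset.frame["patient_id"].to_numpy()
    elif split_unit not in ("patient", "assessment"):
        raise ConfigurationError(f"split_unit must be 'patient' or 'assessment', got {split_unit!r}")
    if groups is not None:
        sgkf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                    random_state=seed % (2**32))
        folds = list(sgkf.split(X, y, groups))
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
        folds = list(skf.split(X, y))

    results: dict[str, ModelResult] = {}
    for spec in model_specs:
        pooled_test = np.empty(y.size)
        fold_aurocs: list[float] = []
        train_aurocs: list[float] = []
        train_scores_parts, train_labels_parts = [], []
        selected = None
        for k, (tr, te) in enumerate(folds):
            params = grid_search(X[tr], y[tr], spec, resample_cfg,
                                 seed + 1000 * k, grid_folds)
            if selected is None:
                selected = params
            model = _fit_scored(spec.family, params, X[tr], y[tr],
                                resample_cfg, seed + 1000 * k)
            pooled_test[te] = _scores(model, X[te])
            try:
                fold_aurocs.append(_auroc_of(pooled_test[te], y[te]))
            except RocUndefinedError:
                # grouped stratification cannot always place positives in
                # every fold; such folds contribute scores but no fold AUROC
                logger.warning("%s: fold %d held out a single class; "
                               "skipping its fold AUROC", spec.family, k)
            tr_scores = _scores(model, X[tr])
            train_aurocs.append(_auroc_of(tr_scores, y[tr]))
            train_scores_parts.append(tr_scores)
            train_labels_parts.append(y[tr])

        if not fold_aurocs:
            raise StratificationError(
                "no fold held out both classes; enlarge the dataset or reduce "
                "the number of folds")
        test_curve = roc_curve(pooled_test, y)
        train_curve = roc_curve(np.concatenate(train_scores_parts),
                                np.concatenate(train_labels_parts))
        opt = optimal_operating_point(test_curve)
        importances = None
        if spec.family == "random_forest":
            final = _fit_scored(spec.family, selected, X, y, resample_cfg, seed)
            importances = feature_importance_report(final, feature_names)
        results[spec.family] = ModelResult(
            family=spec.family, selected=selected,
            train_auroc=float(np.mean(train_aurocs)),
            test_auroc=float(np.mean(fold_aurocs)),
            pooled_test_auroc=auroc(test_curve),
            fold_test_aurocs=fold_aurocs,
            test_curve=test_curve, train_curve=train_curve,
            operating_points=operating_point_table(test_curve),
            optimal_point=opt,
            optimal_harmonic_mean=harmonic_mean(opt.sensitivity, opt.specificity),
            feature_importances=importances,
        )
        logger.info("%s: test AUROC %.3f (train %.3f)", spec.family,
                    results[spec.family].test_auroc, results[spec.family].train_auroc)

    best = max(results, key=lambda f: results[f].test_auroc)
    n_pos = int(y.sum())
    return EvaluationReport(
        models=results, best_family=best,
        prevalence_percent=prevalence(n_pos, y.size),
        n_rows=int(y.size), n_positive=n_pos, n_folds=n_folds, seed=seed,
        resample=(None if resample_cfg is None else {
            "method": resample_cfg.method, "k_neighbors": resample_cfg.k_neighbors,
            "balance_ratio": resample_cfg.balance_ratio,
            "standardize": resample_cfg.standardize}),
        exclusions=exclusions or {},
    )
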