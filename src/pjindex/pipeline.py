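"""Risk-model training and evaluation under nested k-fold cross-validation.

The outer loop (stratified k-fold, k ≈ ln(n) by default) estimates
generalisation; the inner loop tunes a small per-family hyperparameter grid
on the outer-training subjects only.  Outer-training folds are balanced to
1:1 by subsampling the majority class; the untouched outer test fold is
scored.  When a ``featurizer`` callback is supplied, the comorbidity feature
set, the group profiles and the per-subject similarity features are rebuilt
from the outer-training subjects of each fold, so no test-fold subject can
influence feature selection.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .emr import Cohort, CohortSpec, EMRTable, build_cohort
from .similarity import IndexKind, cohort_group_profile, featurize_cohort
from .stats import select_feature_set

__all__ = [
    "ModelKind",
    "Subgroup",
    "SUBGROUPS",
    "CVConfig",
    "Metrics",
    "ModelReport",
    "GridCell",
    "fold_count",
    "evaluate",
    "nested_cv_train",
    "enumerate_grid",
    "run_experiment_grid",
]

ModelKind = Literal["LR", "SVC", "RF", "XGB"]
Subgroup = Literal["all", "age_lt65", "age_ge65", "sex_f", "sex_m"]
SUBGROUPS: tuple[Subgroup, ...] = ("all", "age_lt65", "age_ge65", "sex_f", "sex_m")
INDEX_KINDS: tuple[IndexKind, ...] = ("JI", "PJI", "OPJI", "APJI")
MODEL_KINDS: tuple[ModelKind, ...] = ("LR", "SVC", "RF", "XGB")


def fold_count(n: int) -> int:
    """Default number of folds: K ≈ ln(n), rounded (ln(17000) -> 10)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return max(2, int(round(math.log(n))))


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation sizing; k_outer defaults to round(ln(n))."""

    n: int
    d: int = 2
    k_outer: int | None = None
    k_inner: int = 3
    seed: int = 0

    @property
    def outer(self) -> int:
        return self.k_outer if self.k_outer is not None else fold_count(self.n)

    def check(self) -> None:
        if self.n / self.outer <= 3 * self.d:
            warnings.warn(
                f"n/K = {self.n / self.outer:.1f} violates the n/K > 3d rule "
                f"(d={self.d})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Metrics:
    """Held-out classification metrics (all in [0, 1])."""

    model_score: float
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "model_score": self.model_score,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }


def _mean_metrics(per_fold: Sequence[Metrics]) -> Metrics:
    return Metrics(**{k: float(np.mean([m.as_dict()[k] for m in per_fold]))
                      for k in per_fold[0].as_dict()})


@dataclass(frozen=True)
class GridCell:
    code_level: str
    lead_years: int
    index_kind: IndexKind
    model_kind: ModelKind
    subgroup: Subgroup


@dataclass
class ModelReport:
    config: GridCell | None
    metrics: Metrics
    per_fold: list[Metrics]
    best_params: list[dict] = field(default_factory=list)


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    model_score: float | None = None,
    threshold: float = 0.5,
) -> Metrics:
    """Standard binary metrics from risk scores.

    Class metrics threshold the scores at 0.5; AUC is the rank statistic
    (probability a random case outscores a random control).  ``model_score``
    defaults to accuracy; nested CV overrides it with the selected inner
    model's validation accuracy.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / len(y) if len(y) else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    if np.all(s == s[0]):
        warnings.warn("all scores identical; AUC is 0.5 by convention", stacklevel=2)
        auc = 0.5
    elif len(np.unique(y)) < 2:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y, s))
    return Metrics(
        model_score=accuracy if model_score is None else model_score,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        f1=f1,
        auc=auc,
    )


def _estimator_and_grid(kind: ModelKind, seed: int):
    if kind == "LR":
        return (LogisticRegression(max_iter=2000),
                {"C": list(np.logspace(-2, 2, 5))})
    if kind == "SVC":
        return (SVC(kernel="rbf", probability=True, random_state=seed),
                {"C": [0.1, 0.5, 1.0, 5.0, 10.0]})
    if kind == "RF":
        return (RandomForestClassifier(random_state=seed, n_jobs=1),
                {"n_estimators": [100, 300], "max_depth": [None, 8]})
    if kind == "XGB":
        return (XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss"),
                {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]})
    raise ValueError(f"unknown model kind {kind!r}")


def _balance_indices(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class among ``idx`` to a 1:1 ratio."""
    pos = idx[y[idx] == 1]
    neg = idx[y[idx] == 0]
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    out = np.concatenate([pos, neg])
    out.sort()
    return out


def nested_cv_train(
    features: np.ndarray | pd.DataFrame | None,
    labels: Sequence[int],
    model_kind: ModelKind,
    cv: CVConfig,
    featurizer: Callable[[np.ndarray], np.ndarray] | None = None,
    config: GridCell | None = None,
) -> ModelReport:
    """Nested stratified k-fold training of one model family.

    ``featurizer(train_indices)`` — when given — must return the feature
    matrix for *all* subjects computed using only the training subjects
    (feature-set selection and reference profiles), and is invoked once per
    outer fold; otherwise the precomputed ``features`` are used as-is.
    Deterministic given ``cv.seed``.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if features is None and featurizer is None:
        raise ValueError("either features or a featurizer is required")
    cv.check()
    rng = np.random.default_rng(cv.seed)

    outer = StratifiedKFold(n_splits=cv.outer, shuffle=True, random_state=cv.seed)
    per_fold: list[Metrics] = []
    best_params: list[dict] = []
    X_static = None if features is None else np.asarray(features, dtype=float)

    for fold, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(y)), y)):
        X = featurizer(train_idx) if featurizer is not None else X_static
        X = np.asarray(X, dtype=float)
        fit_idx = _balance_indices(train_idx, y, rng)

        est, grid = _estimator_and_grid(model_kind, cv.seed + fold)
        inner = StratifiedKFold(n_splits=cv.k_inner, shuffle=True,
                                random_state=cv.seed + fold)
        search = GridSearchCV(est, grid, cv=inner, scoring="accuracy", n_jobs=1)
        search.fit(X[fit_idx], y[fit_idx])
        scores = search.predict_proba(X[test_idx])[:, 1]
        per_fold.append(
            evaluate(scores, y[test_idx], model_score=float(search.best_score_))
        )
        best_params.append(dict(search.best_params_))

    return ModelReport(config, _mean_metrics(per_fold), per_fold, best_params)


def enumerate_grid(
    code_levels: Sequence[str] = ("single", "group"),
    lead_years: Sequence[int] = (1, 2, 3),
    index_kinds: Sequence[IndexKind] = INDEX_KINDS,
    model_kinds: Sequence[ModelKind] = MODEL_KINDS,
    subgroups: Sequence[Subgroup] = SUBGROUPS,
) -> list[GridCell]:
    """All configuration cells (full default grid: 2*3*4*4*5 = 480)."""
    return [
        GridCell(cl, ly, ik, mk, sg)
        for cl in code_levels
        for ly in lead_years
        for ik in index_kinds
        for mk in model_kinds
        for sg in subgroups
    ]


def _subgroup_mask(cohort: Cohort, subgroup: Subgroup) -> np.ndarray:
    if subgroup == "all":
        return np.ones(len(cohort), dtype=bool)
    age = cohort.age_at_index().to_numpy()
    sex = cohort.subjects["sex"].to_numpy()
    if subgroup == "age_lt65":
        return age < 65
    if subgroup == "age_ge65":
        return age >= 65
    if subgroup == "sex_f":
        return sex == "F"
    if subgroup == "sex_m":
        return sex == "M"
    raise ValueError(f"unknown subgroup {subgroup!r}")


def make_featurizer(
    cohort: Cohort,
    index_kind: IndexKind,
    or_min: float = 2.0,
    prevalence_min: float = 0.01,
    correction: float = 0.5,
    pseudo_count: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Leakage-safe featurizer: feature set and profiles from training rows only."""
    sids = cohort.subjects["subject_id"].to_numpy()

    def featurize(train_idx: np.ndarray) -> np.ndarray:
        train_cohort = cohort.subset(np.isin(np.arange(len(cohort)), train_idx))
        fs = select_feature_set(
            train_cohort, or_min=or_min, prevalence_min=prevalence_min,
            correction=correction, pseudo_count=pseudo_count,
        )
        train_ids = set(sids[train_idx])
        case_prof = cohort_group_profile(cohort, "case", fs, train_ids)
        ctrl_prof = cohort_group_profile(cohort, "control", fs, train_ids)
        feats = featurize_cohort(cohort, fs, case_prof, ctrl_prof, index_kind)
        return feats[["sim_to_case", "sim_to_control"]].to_numpy()

    return featurize


def _cell_seed(base_seed: int, cell: GridCell) -> int:
    tag = f"{cell.code_level}|{cell.lead_years}|{cell.index_kind}|{cell.model_kind}|{cell.subgroup}"
    return (base_seed ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def run_experiment_grid(
    emr: EMRTable,
    grid: Sequence[GridCell] | None = None,
    target_codes: Iterable[str] = ("428",),
    control_ratio: float = 2.5,
    seed: int = 0,
    k_outer: int | None = None,
    k_inner: int = 3,
    or_min: float = 2.0,
    prevalence_min: float = 0.01,
) -> tuple[pd.DataFrame, list[ModelReport]]:
    """Train one model per grid cell and return a tidy metrics table.

    Cohorts are cached per (code_level, lead_years); per cell, the subgroup
    filter is applied and a leakage-safe featurizer drives nested CV.  A
    failing cell is recorded (``error`` column) and the grid continues.
    Seeds fan out deterministically per cell from ``seed``.
    """
    cells = list(grid) if grid is not None else enumerate_grid()
    cohorts: dict[tuple[str, int], Cohort] = {}
    rows: list[dict] = []
    reports: list[ModelReport] = []

    for cell in cells:
        row: dict = {
            "code_level": cell.code_level,
            "lead_years": cell.lead_years,
            "index_kind": cell.index_kind,
            "model_kind": cell.model_kind,
            "subgroup": cell.subgroup,
            "error": "",
        }
        try:
            key = (cell.code_level, cell.lead_years)
            if key not in cohorts:
                spec = CohortSpec(
                    target_codes=frozenset(target_codes),
                    lead_years=cell.lead_years,
                    code_level=cell.code_level,  # type: ignore[arg-type]
                )
                cohorts[key] = build_cohort(
                    emr, spec, control_ratio=control_ratio, seed=seed
                )
            sub = cohorts[key].subset(_subgroup_mask(cohorts[key], cell.subgroup))
            y = (sub.labels == "case").astype(int).to_numpy()
            cv = CVConfig(n=len(sub), d=2, k_outer=k_outer, k_inner=k_inner,
                          seed=_cell_seed(seed, cell))
            report = nested_cv_train(
                None, y, cell.model_kind, cv,
                featurizer=make_featurizer(sub, cell.index_kind,
                                           or_min=or_min,
                                           prevalence_min=prevalence_min),
                config=cell,
            )
            reports.append(report)
            row.update(report.metrics.as_dict())
        except Exception as exc:  # noqa: BLE001 — grid must survive cell failures
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    return pd.DataFrame(rows), reports
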