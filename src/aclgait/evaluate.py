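"""Subject-stratified learning protocol and classification metrics.

The protocol mirrors a small-cohort wearable-sensor study design: the
twelve subjects are randomly split into training (6), validation (2) and
test (4) partitions with equal cohort counts in each; a grid search over
model hyper-parameters and a select-K-best univariate feature selection
(K <= 10) is scored by leave-one-subject-out cross-validation (LOSO-CV)
on the training partition; the tuned model is confirmed on the
validation subjects, training and validation are then merged (8
subjects) and re-tuned via LOSO, and the final model is scored on the
four held-out test subjects.  The whole procedure is repeated over
several random partitions, accumulating per-subject accuracies and
pooling test confusion counts.

The positive class is the post-ACL cohort throughout.  Feature
standardization and feature selection are fitted on training folds only;
held-out subjects are never touched during fitting (leakage guard).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "POSITIVE_CLASS",
    "ConfusionMatrix",
    "SplitPlan",
    "ModelGrid",
    "MetricsReport",
    "default_grids",
    "stratified_split",
    "loso_grid_search",
    "evaluate_protocol",
    "metrics_from_confusion",
    "LeakageError",
]

POSITIVE_CLASS = "acl"
NEGATIVE_CLASS = "healthy"
MODEL_FAMILIES = ("knn", "nb", "svm", "xgb", "mlp", "stacking")


class LeakageError(RuntimeError):
    """A held-out subject's data reached a fitting step."""


@dataclass
class ConfusionMatrix:
    """Pooled binary confusion counts; positive class = post-ACL."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)

    def as_dict(self) -> Dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


def metrics_from_confusion(cm: ConfusionMatrix) -> Dict[str, float]:
    """Sensitivity, specificity, precision, F1, pooled accuracy (all in
    percent) and Cohen's kappa from pooled confusion counts.

    Metrics with a zero denominator are NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else np.nan

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    acc = ratio(cm.tp + cm.tn, cm.total)
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else np.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
        "kappa": float(kappa) if np.isfinite(kappa) else np.nan,
    }


# ----------------------------------------------------------------------
# splits

@dataclass
class SplitPlan:
    """Subject -> partition assignment with equal cohort counts per part."""

    assignment: Dict[str, str]  # subject -> {"train","validation","test"}
    seed: int

    def subjects(self, role: str) -> List[str]:
        return sorted(s for s, r in self.assignment.items() if r == role)


def stratified_split(
    subject_cohorts: Mapping[str, str],
    seed: int,
    counts: Tuple[int, int, int] = (6, 2, 4),
) -> SplitPlan:
    """Randomly assign subjects to train/validation/test, stratified.

    ``counts`` are the total partition sizes; each cohort contributes
    proportionally (and exactly), otherwise the cohorts are not
    stratifiable and an error is raised.
    """
    total = sum(counts)
    if len(subject_cohorts) != total:
        raise ValueError(f"expected {total} subjects, got {len(subject_cohorts)}")
    cohorts: Dict[str, List[str]] = {}
    for subj, coh in subject_cohorts.items():
        cohorts.setdefault(coh, []).append(subj)
    assignment: Dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for coh in sorted(cohorts):
        members = sorted(cohorts[coh])
        n_c = len(members)
        parts = []
        for c in counts:
            if (n_c * c) % total != 0:
                raise ValueError(
                    f"cohort {coh!r} (n={n_c}) not stratifiable into {counts}"
                )
            parts.append(n_c * c // total)
        rng.shuffle(members)
        roles = (["train"] * parts[0] + ["validation"] * parts[1] + ["test"] * parts[2])
        assignment.update(dict(zip(members, roles)))
    return SplitPlan(assignment, seed)


# ----------------------------------------------------------------------
# models and grids

@dataclass
class ModelGrid:
    """Hyper-parameter grid for one model family plus the K-best grid."""

    family: str
    param_grid: Dict[str, List] = field(default_factory=dict)
    k_grid: List[int] = field(default_factory=lambda: list(range(1, 11)))

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.k_grid:
            raise ValueError("empty K grid")
        if max(self.k_grid) > 10:
            raise ValueError("K must not exceed 10 (overfitting guard)")

    def points(self) -> List[Tuple[int, Tuple[Tuple[str, object], ...]]]:
        """Deterministically ordered (k, params) grid points."""
        keys = sorted(self.param_grid)
        combos = [
            tuple(zip(keys, vals))
            for vals in itertools.product(*(self.param_grid[k] for k in keys))
        ] or [()]
        return [
            (k, params)
            for k in sorted(self.k_grid)
            for params in sorted(combos, key=lambda p: repr(p))
        ]


def default_grids() -> Dict[str, ModelGrid]:
    """Documented default grids for the six model families."""
    return {
        "knn": ModelGrid("knn", {"n_neighbors": [1, 3, 5, 7, 9]}),
        "nb": ModelGrid("nb", {}),
        "svm": ModelGrid("svm", {"C": [0.1, 1, 10], "gamma": ["scale", 0.01, 0.1]}),
        "xgb": ModelGrid("xgb", {"max_depth": [2, 3, 4],
                                 "n_estimators": [50, 100, 200],
                                 "learning_rate": [0.05, 0.1, 0.3]}),
        "mlp": ModelGrid("mlp", {"hidden_layer_sizes": [(16,), (32,), (32, 16)],
                                 "alpha": [1e-4, 1e-3]}),
        "stacking": ModelGrid("stacking", {}),
    }


def _base_estimator(family: str, params: Dict, seed: int):
    if family == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **params})
    if family == "nb":
        return GaussianNB(**params)
    if family == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "xgb":
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss",
            **{"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1, **params},
        )
    if family == "mlp":
        return MLPClassifier(random_state=seed, max_iter=800,
                             **{"hidden_layer_sizes": (32,), "alpha": 1e-4, **params})
    if family == "stacking":
        from sklearn.ensemble import StackingClassifier

        base = [(f, _base_estimator(f, {}, seed)) for f in ("knn", "svm", "nb", "xgb", "mlp")]
        return StackingClassifier(base, final_estimator=LogisticRegression(max_iter=1000),
                                  cv=3, n_jobs=1)
    raise ValueError(f"unknown model family {family!r}")


def _safe_f_classif(X, y):
    """One-way F scores with NaN scores demoted (constant features)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, pvals = f_classif(X, y)
    scores = np.where(np.isfinite(scores), scores, 0.0)
    return scores, pvals


def make_pipeline(family: str, params: Dict, k: int, seed: int) -> Pipeline:
    """z-score scaling + select-K-best (one-way F) + classifier."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("select", SelectKBest(_safe_f_classif, k=k)),
        ("model", _base_estimator(family, dict(params), seed)),
    ])


# ----------------------------------------------------------------------
# LOSO machinery

def _check_matrix(X: np.ndarray, feature_names: Sequence[str]) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.nonzero(bad.any(axis=0))[0][0])
        raise ValueError(f"non-finite values in feature {feature_names[j]!r}")


def _encode(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y) == POSITIVE_CLASS).astype(int)


def loso_accuracy(
    X: np.ndarray,
    y01: np.ndarray,
    subjects: np.ndarray,
    family: str,
    params: Dict,
    k: int,
    seed: int,
    forbidden_subjects: Iterable[str] = (),
) -> Dict[str, float]:
    """Per-subject LOSO accuracies (%); fitting never sees the held-out
    subject nor any subject listed in ``forbidden_subjects``."""
    forbidden = set(forbidden_subjects)
    present = set(np.unique(subjects))
    if forbidden & present:
        raise LeakageError(f"held-out subjects present in fitting data: {forbidden & present}")
    out: Dict[str, float] = {}
    for subj in sorted(present):
        mask = subjects == subj
        pipe = make_pipeline(family, params, k, seed)
        pipe.fit(X[~mask], y01[~mask])
        out[subj] = 100.0 * float(np.mean(pipe.predict(X[mask]) == y01[mask]))
    return out


@dataclass
class GridSearchResult:
    family: str
    best_k: int
    best_params: Dict
    mean_accuracy: float
    se_accuracy: float
    per_subject: Dict[str, float]
    n_points: int
    selected_features: List[str]


def loso_grid_search(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    grid: ModelGrid,
    seed: int = 0,
    forbidden_subjects: Iterable[str] = (),
) -> GridSearchResult:
    """Grid search scored by mean per-subject LOSO accuracy.

    Ties are broken towards the smallest K and then the lexicographically
    first hyper-parameter combination, for determinism.  The returned
    selected features come from refitting the selector on the full
    training data at the optimum.
    """
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    _check_matrix(Xa, names)
    y01 = _encode(y)
    subjects = np.asarray(subjects)
    if len(np.unique(subjects)) < 2:
        raise ValueError("need at least two training subjects for LOSO")
    points = grid.points()
    if not points:
        raise ValueError("empty grid")
    best = None
    for k, params in points:
        if k >= Xa.shape[1]:
            k = Xa.shape[1]
        accs = loso_accuracy(Xa, y01, subjects, grid.family, dict(params), k, seed,
                             forbidden_subjects)
        mean = float(np.mean(list(accs.values())))
        if best is None or mean > best[0]:
            best = (mean, k, params, accs)
    mean, k, params, accs = best
    vals = np.array(list(accs.values()))
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0

    pipe = make_pipeline(grid.family, dict(params), k, seed)
    pipe.fit(Xa, y01)
    support = pipe.named_steps["select"].get_support()
    selected = [n for n, s in zip(names, support) if s]
    return GridSearchResult(grid.family, k, dict(params), mean, se, accs,
                            len(points), selected)


# ----------------------------------------------------------------------
# full protocol

@dataclass
class MetricsReport:
    """Aggregated test-set performance of one model family."""

    family: str
    per_subject_accuracy: List[Tuple[str, float]]  # pooled over permutations
    mean_accuracy: float                           # % over players
    se_accuracy: float                             # sd / sqrt(n)
    confusion: ConfusionMatrix                     # pooled over permutations
    metrics: Dict[str, float]                      # derived from the pooled matrix
    validation_accuracy: List[float]
    permutation_seeds: List[int]
    selected_features: List[List[str]]


def _subject_cohorts(meta: pd.DataFrame) -> Dict[str, str]:
    return dict(
        meta.drop_duplicates("subject").set_index("subject")["cohort"]
    )


def evaluate_protocol(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    grid: ModelGrid,
    n_permutations: int = 10,
    seed: int = 0,
    counts: Tuple[int, int, int] = (6, 2, 4),
) -> MetricsReport:
    """Run the full split / tune / confirm / merge / retune / test protocol.

    Parameters
    ----------
    X : DataFrame
        Feature matrix, one row per repetition (finite values only).
    meta : DataFrame
        Per-repetition metadata with ``subject`` and ``cohort`` columns
        aligned with ``X``.
    grid : ModelGrid
        Family and hyper-parameter/K grids searched at both tuning steps.
    n_permutations : int
        Number of random subject partitions to average over.
    seed : int
        Master seed; per-permutation seeds are spawned from it and
        recorded in the report.
    """
    if len(X) != len(meta):
        raise ValueError("X and meta must be aligned")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    _check_matrix(Xa, names)
    subjects = meta["subject"].to_numpy()
    y01 = _encode(meta["cohort"].to_numpy())
    cohorts = _subject_cohorts(meta)

    perm_seeds = [int(s) for s in
                  np.random.SeedSequence(seed).generate_state(n_permutations) % (2**31)]

    pooled_cm = ConfusionMatrix()
    per_subject: List[Tuple[str, float]] = []
    val_accs: List[float] = []
    selected: List[List[str]] = []

    for p_seed in perm_seeds:
        plan = stratified_split(cohorts, p_seed, counts)
        train_s = plan.subjects("train")
        val_s = plan.subjects("validation")
        test_s = plan.subjects("test")

        labels = meta["cohort"].to_numpy()
        tr_mask = np.isin(subjects, train_s)
        res = loso_grid_search(
            X.loc[tr_mask], labels[tr_mask], subjects[tr_mask],
            grid, seed=p_seed, forbidden_subjects=val_s + test_s,
        )
        # confirmation on the validation subjects (does not overturn the optimum)
        pipe = make_pipeline(grid.family, res.best_params, res.best_k, p_seed)
        pipe.fit(Xa[tr_mask], y01[tr_mask])
        va_mask = np.isin(subjects, val_s)
        val_accs.append(100.0 * float(np.mean(pipe.predict(Xa[va_mask]) == y01[va_mask])))

        # merge train+validation (8 subjects) and re-tune via LOSO
        merged_s = train_s + val_s
        mg_mask = np.isin(subjects, merged_s)
        res8 = loso_grid_search(
            X.loc[mg_mask], labels[mg_mask], subjects[mg_mask],
            grid, seed=p_seed, forbidden_subjects=test_s,
        )
        final = make_pipeline(grid.family, res8.best_params, res8.best_k, p_seed)
        if set(np.unique(subjects[mg_mask])) & set(test_s):
            raise LeakageError("test subjects present at final fit")
        final.fit(Xa[mg_mask], y01[mg_mask])
        selected.append(res8.selected_features)

        for subj in test_s:
            m = subjects == subj
            pred = final.predict(Xa[m])
            truth = y01[m]
            per_subject.append((subj, 100.0 * float(np.mean(pred == truth))))
            pooled_cm = pooled_cm + ConfusionMatrix(
                tp=int(np.sum((pred == 1) & (truth == 1))),
                fn=int(np.sum((pred == 0) & (truth == 1))),
                fp=int(np.sum((pred == 1) & (truth == 0))),
                tn=int(np.sum((pred == 0) & (truth == 0))),
            )

    accs = np.array([a for _, a in per_subject])
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return MetricsReport(
        family=grid.family,
        per_subject_accuracy=per_subject,
        mean_accuracy=mean,
        se_accuracy=se,
        confusion=pooled_cm,
        metrics=metrics_from_confusion(pooled_cm),
        validation_accuracy=val_accs,
        permutation_seeds=perm_seeds,
        selected_features=selected,
    )
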