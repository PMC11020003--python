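"""Classifiers, patient-wise stratified cross-validation and metric reporting.

Folds are built at the patient level: every patient's spectra land in exactly
one fold, so no patient contributes to both training and test data. Greedy
packing (patients in descending spectrum count, each placed into the fold
where it least worsens per-class imbalance) approximates stratification;
exact patient-level stratification is a bin-packing problem.

Metrics follow the margin-assessment convention: the tumour class is
positive, sensitivity is tumour recall, specificity normal recall, and AUC is
the trapezoidal area under the ROC curve (equal to the pairwise concordance
probability with ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .io import SpectrumSet
from .specnet import SpecNet, SpecNetConfig

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "CLASSIFIER_KINDS",
    "make_patient_folds",
    "train_classifier",
    "compute_auc",
    "evaluate",
    "cross_validate",
    "design_matrix",
]

POSITIVE_LABEL = "tumour"
CLASSIFIER_KINDS = ("specnet", "rf", "xgb", "lgbm", "mlp", "svm")


@dataclass
class FoldAssignment:
    """Patient-wise fold partition: every patient maps to exactly one fold."""

    fold_of_spectrum: np.ndarray
    patient_to_fold: dict[str, int]
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_spectrum == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_spectrum != fold)


def make_patient_folds(
    patients: Sequence[str] | SpectrumSet,
    labels: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy patient-wise, approximately class-stratified k-fold split.

    Patients are sorted by descending spectrum count (seeded shuffle breaks
    ties) and each is assigned to the fold minimising the resulting sum of
    squared per-class fold counts, which balances both class totals and fold
    sizes.
    """
    if isinstance(patients, SpectrumSet):
        labels = patients.labels
        patients = patients.patient_ids
    patients = np.asarray(patients)
    labels = np.asarray(labels if labels is not None else ["unknown"] * len(patients))
    uniq = np.unique(patients)
    if uniq.size < k:
        raise ValueError(f"need at least k={k} distinct patients, found {uniq.size}")
    classes = np.unique(labels)
    per_patient = {
        p: np.array([np.sum((patients == p) & (labels == c)) for c in classes])
        for p in uniq
    }
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    order.sort(key=lambda p: -per_patient[p].sum())
    fold_counts = np.zeros((k, classes.size))
    patient_to_fold: dict[str, int] = {}
    for p in order:
        costs = [
            np.sum((fold_counts[f] + per_patient[p]) ** 2)
            + np.sum(np.delete(fold_counts, f, axis=0) ** 2)
            for f in range(k)
        ]
        f = int(np.argmin(costs))
        patient_to_fold[str(p)] = f
        fold_counts[f] += per_patient[p]
    fold_of_spectrum = np.array([patient_to_fold[str(p)] for p in patients])
    return FoldAssignment(fold_of_spectrum, patient_to_fold, k)


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    config: SpecNetConfig | dict | None = None,
    seed: int = 0,
):
    """Fit one classifier; the returned handle supports ``predict_proba``.

    ``kind`` is one of ``specnet | rf | xgb | lgbm | mlp | svm``; baselines
    use library defaults with the given seed, SpecNet takes a
    :class:`SpecNetConfig`. Deterministic given (kind, data, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if kind == "specnet":
        if config is None:
            config = SpecNetConfig(n1=X.shape[1], seed=seed)
        elif isinstance(config, dict):
            config = SpecNetConfig(**{"n1": X.shape[1], "seed": seed, **config})
        return SpecNet(config).fit(X, y)
    if kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif kind == "xgb":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss"
        )
    elif kind == "lgbm":
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    elif kind == "mlp":
        from sklearn.neural_network import MLPClassifier

        model = MLPClassifier(random_state=seed, max_iter=500)
    elif kind == "svm":
        from sklearn.svm import SVC

        model = SVC(kernel="linear", probability=True, random_state=seed)
    else:
        raise ValueError(
            f"unknown classifier kind {kind!r}; known kinds: "
            + ", ".join(CLASSIFIER_KINDS)
        )
    return model.fit(X, y)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half. Needs both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: test labels contain one class only")
    fpr, tpr = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC polyline over thresholds at every distinct score (ties -> diagonal segments)."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos, n_neg = y.sum(), y.size - y.sum()
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return fpr, tpr


@dataclass
class MetricsReport:
    """Point metrics (with optional across-fold 95% t-intervals) and the ROC."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    confusion: dict[str, int]
    roc: tuple[np.ndarray, np.ndarray] | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_fold: dict[str, list[float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": dict(self.confusion),
        }
        if self.ci:
            d["ci95"] = {k: list(v) for k, v in self.ci.items()}
        if self.per_fold:
            d["per_fold"] = {k: list(v) for k, v in self.per_fold.items()}
        return d

    def summary(self) -> str:
        rows = [f"{'metric':<13}{'value':>8}  {'95% CI':>17}"]
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            cell = "   --" if v is None else f"{v:8.3f}"
            ci = self.ci.get(name)
            ci_cell = f"({ci[0]:.3f}, {ci[1]:.3f})" if ci else ""
            rows.append(f"{name:<13}{cell}  {ci_cell:>17}")
        c = self.confusion
        rows.append(
            f"confusion    TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}"
        )
        return "\n".join(rows)


def evaluate(
    model, X: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Evaluate a fitted model on a test set (tumour = positive class).

    The confusion matrix uses a 0.5 probability threshold; AUC is None (with
    the other metrics still reported) when the test labels are single-class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty test set")
    scores = np.asarray(model.predict_proba(X))[:, 1]
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / y.size
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    try:
        auc = compute_auc(scores, y)
        roc = roc_points(scores, y)
    except UndefinedMetricError:
        auc, roc = None, None
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc=roc,
    )


def _t_interval(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if arr.size < 2 or np.allclose(arr, arr[0]):
        return (float(mean), float(mean))
    se = arr.std(ddof=1) / np.sqrt(arr.size)
    tcrit = stats.t.ppf(0.975, arr.size - 1)
    return (float(mean - tcrit * se), float(mean + tcrit * se))


def design_matrix(sset: SpectrumSet, representation: str = "intensities"):
    """(X, y, patients) arrays from a processed set.

    ``representation``: "intensities" (the full spectral sequence), "shape"
    (the 9 shape features) or "both".
    """
    y = (sset.labels == POSITIVE_LABEL).astype(int)
    patients = sset.patient_ids
    if representation == "intensities":
        X = sset.intensity_matrix()
    else:
        from .features import FEATURE_NAMES, feature_table

        tab = feature_table(sset)
        shape = tab[list(FEATURE_NAMES)].to_numpy(dtype=float)
        shape = np.nan_to_num(shape, nan=0.5)  # undefined saturation -> midpoint
        if representation == "shape":
            X = shape
        elif representation == "both":
            X = np.hstack([sset.intensity_matrix(), shape])
        else:
            raise ValueError(f"unknown representation {representation!r}")
    return X, y, patients


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    patients: Sequence[str],
    kinds: Sequence[str] = ("rf",),
    k: int = 5,
    seed: int = 0,
    config: SpecNetConfig | dict | None = None,
) -> dict[str, MetricsReport]:
    """Patient-wise stratified k-fold cross-validation for several classifiers.

    Every fold is fitted on the other k-1 folds and evaluated on its held-out
    patients; the report per kind carries fold-mean metrics with 95%
    t-intervals and the pooled out-of-fold ROC. Asserts that no patient
    appears on both sides of any split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    patients = np.asarray(patients)
    folds = make_patient_folds(patients, y.astype(str), k=k, seed=seed)
    reports: dict[str, MetricsReport] = {}
    for kind in kinds:
        per_fold: dict[str, list[float]] = {
            m: [] for m in ("accuracy", "sensitivity", "specificity", "auc")
        }
        oof_scores = np.full(y.size, np.nan)
        for f in range(k):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            overlap = set(patients[tr]) & set(patients[te])
            assert not overlap, f"patient leakage across fold {f}: {overlap}"
            model = train_classifier(kind, X[tr], y[tr], config=config, seed=seed + f)
            rep = evaluate(model, X[te], y[te])
            oof_scores[te] = np.asarray(model.predict_proba(X[te]))[:, 1]
            for m in per_fold:
                v = getattr(rep, m)
                if v is not None and np.isfinite(v):
                    per_fold[m].append(float(v))
        means = {m: float(np.mean(v)) if v else None for m, v in per_fold.items()}
        pred = (oof_scores >= 0.5).astype(int)
        confusion = {
            "tp": int(np.sum((pred == 1) & (y == 1))),
            "fp": int(np.sum((pred == 1) & (y == 0))),
            "tn": int(np.sum((pred == 0) & (y == 0))),
            "fn": int(np.sum((pred == 0) & (y == 1))),
        }
        reports[kind] = MetricsReport(
            accuracy=means["accuracy"],
            sensitivity=means["sensitivity"],
            specificity=means["specificity"],
            auc=means["auc"],
            confusion=confusion,
            roc=roc_points(oof_scores, y),
            ci={m: _t_interval(v) for m, v in per_fold.items() if v},
            per_fold=per_fold,
        )
    return reports
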