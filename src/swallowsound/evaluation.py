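"""Cross-validated evaluation of loud-event classification.

Events are split into five stratified folds; per fold, feature
standardisation is fitted on the training split only, a model is trained
and the held-out events scored.  Six indices summarise a 2x2 confusion
table — accuracy, sensitivity, specificity, PPV, NPV (percentages) and
the F1 score (harmonic mean of sensitivity and PPV, in [0, 1]).  Because
the event mix is imbalanced (roughly 1 swallow to 3 non-swallow), every
metric is reported twice, once with each class treated as positive, and
the macro-F1 averages the two classes' mean F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import predict, train_ensemble, train_linear_svm, train_mlp

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVReport",
    "confusion",
    "compute_metrics",
    "f1_from_percent",
    "kfold_split",
    "cross_validate",
    "tune_regularization",
    "format_cv_report",
]

MODEL_KINDS = ("svm", "mlp", "elm")
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for a fixed positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Six evaluation indices; percentages except the unitless F1.

    A ratio with a zero denominator is reported as NaN (with a warning),
    never silently as zero.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(
    predictions: np.ndarray, labels: np.ndarray, positive_class: int = 1
) -> ConfusionCounts:
    """Count the 2x2 confusion table with the stated positive class."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have equal length")
    pos_p = pred == positive_class
    pos_l = lab == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_p & pos_l)),
        fp=int(np.sum(pos_p & ~pos_l)),
        tn=int(np.sum(~pos_p & ~pos_l)),
        fn=int(np.sum(~pos_p & pos_l)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def f1_from_percent(sensitivity_pct: float, ppv_pct: float) -> float:
    """F1 (unitless, in [0, 1]) from sensitivity and PPV given in percent.

    F1 is the harmonic mean of sensitivity and PPV:
    ``2 * sens * PPV / (sens + PPV)``.
    """
    if sensitivity_pct + ppv_pct <= 0:
        warnings.warn("F1 undefined (sensitivity + PPV is zero); reporting NaN")
        return float("nan")
    return 2.0 * sensitivity_pct * ppv_pct / (sensitivity_pct + ppv_pct) / 100.0


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The six indices from a confusion table.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(FN+TN), all as
    percentages; F1 = 2*sens*PPV/(sens+PPV) on the fractional scale.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    ppv = _ratio(counts.tp, counts.tp + counts.fp, "PPV")
    npv = _ratio(counts.tn, counts.fn + counts.tn, "NPV")
    return MetricsReport(
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        ppv=100.0 * ppv,
        npv=100.0 * npv,
        f1=f1_from_percent(100.0 * sens, 100.0 * ppv),
    )


def kfold_split(
    n: int,
    k: int = 5,
    stratify_labels: np.ndarray | None = None,
    seed: int | None = 0,
) -> list[np.ndarray]:
    """Partition ``range(n)`` into ``k`` folds (test-index arrays).

    With ``stratify_labels`` the per-fold class counts deviate from exact
    proportionality by at most one.  Deterministic for a fixed seed.
    """
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if stratify_labels is not None:
        labels = np.asarray(stratify_labels)
        if labels.shape != (n,):
            raise ValueError("stratify_labels must have length n")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-score fitted on a training split."""

    mean: np.ndarray
    scale: np.ndarray  # std with zero-variance features clamped to 1

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        return cls(mean=mean, scale=np.where(std > 0, std, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.scale


def _fit_model(kind: str, x: np.ndarray, y: np.ndarray, seed: int, params: dict):
    if kind == "svm":
        return train_linear_svm(x, y, c=params.get("svm_c", 0.05))
    if kind == "mlp":
        return train_mlp(
            x,
            y,
            max_epochs=params.get("mlp_max_epochs", 2000),
            grad_tol=params.get("mlp_grad_tol", 1e-6),
            seed=seed,
        )
    if kind == "elm":
        return train_ensemble(
            x,
            y,
            n_svm=params.get("n_svm", 5),
            n_mlp=params.get("n_mlp", 5),
            svm_c=params.get("svm_c", 0.05),
            mlp_max_epochs=params.get("mlp_max_epochs", 2000),
            mlp_grad_tol=params.get("mlp_grad_tol", 1e-6),
            seed=seed,
            learner_order=params.get("learner_order", "alternate"),
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass(frozen=True)
class CVReport:
    """Per-fold and aggregated cross-validation metrics.

    ``per_fold`` maps the positive-class view ("class1" / "class0") to a
    list of per-fold :class:`MetricsReport`.  ``mean`` and ``sd`` carry
    the same structure with metric-name dicts.  ``macro_f1`` is the mean
    of the two classes' mean F1; ``micro_f1`` is the F1 of the pooled
    predictions with class 1 positive.
    """

    model_kind: str
    k: int
    seed: int
    per_fold: dict[str, list[MetricsReport]]
    mean: dict[str, dict[str, float]]
    sd: dict[str, dict[str, float]]
    macro_f1: float
    micro_f1: float
    pooled: dict[str, MetricsReport] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "k": self.k,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "per_fold": {
                view: [m.as_dict() for m in reports]
                for view, reports in self.per_fold.items()
            },
            "pooled": {view: m.as_dict() for view, m in self.pooled.items()},
        }


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    model_kind: str = "elm",
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
    stratify: bool = True,
    **model_params,
) -> CVReport:
    """Stratified k-fold cross-validation of one model kind.

    Per fold the feature standardiser is fitted on the training split only
    (no leakage), the model is trained and the held-out events predicted.
    Metrics are aggregated for both positive-class views.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    for cls in (0, 1):
        if np.sum(y == cls) < k:
            raise ValueError(f"need at least {k} events of class {cls} for {k}-fold CV")
    folds = kfold_split(len(y), k=k, stratify_labels=y if stratify else None, seed=seed)
    used = np.concatenate(folds)
    assert len(np.unique(used)) == len(y) == len(used), "folds must partition the data"

    seed_seq = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_seq.spawn(k)]
    per_fold: dict[str, list[MetricsReport]] = {"class1": [], "class0": []}
    all_pred = np.full(len(y), -1, dtype=np.int64)
    for fold_idx, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        x_train, y_train = x[train_mask], y[train_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {fold_idx}: a class is absent from the training split")
        if standardize:
            scaler = Standardizer.fit(x_train)
            x_train = scaler.transform(x_train)
            x_test = scaler.transform(x[test_idx])
        else:
            x_test = x[test_idx]
        model = _fit_model(model_kind, x_train, y_train, fold_seeds[fold_idx], model_params)
        pred = predict(model, x_test).predicted_class
        all_pred[test_idx] = pred
        for view, pos in (("class1", 1), ("class0", 0)):
            per_fold[view].append(
                compute_metrics(confusion(pred, y[test_idx], positive_class=pos))
            )

    mean: dict[str, dict[str, float]] = {}
    sd: dict[str, dict[str, float]] = {}
    for view, reports in per_fold.items():
        vals = {m: np.array([r.as_dict()[m] for r in reports]) for m in METRIC_NAMES}
        mean[view] = {m: float(np.nanmean(v)) for m, v in vals.items()}
        sd[view] = {m: float(np.nanstd(v, ddof=1)) for m, v in vals.items()}
    macro_f1 = 0.5 * (mean["class1"]["f1"] + mean["class0"]["f1"])
    pooled = {
        view: compute_metrics(confusion(all_pred, y, positive_class=pos))
        for view, pos in (("class1", 1), ("class0", 0))
    }
    return CVReport(
        model_kind=model_kind,
        k=k,
        seed=seed,
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        macro_f1=macro_f1,
        micro_f1=pooled["class1"].f1,
        pooled=pooled,
    )


def tune_regularization(
    features: np.ndarray,
    labels: np.ndarray,
    grid: list[float],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Grid search for the SVM regularisation C by mean CV F1 (class 1).

    Ties resolve to the smaller C (stronger regularisation).
    """
    if not grid:
        raise ValueError("C grid must be non-empty")
    best_c, best_f1 = None, -np.inf
    for c in sorted(grid):
        report = cross_validate(
            features, labels, model_kind="svm", k=k, seed=seed, svm_c=c
        )
        f1 = report.mean["class1"]["f1"]
        if f1 > best_f1:
            best_c, best_f1 = c, f1
    return float(best_c)


def format_cv_report(report: CVReport) -> str:
    """Render a report as a text table (mean +/- SD per class view)."""
    lines = [
        f"{report.k}-fold cross-validation, model={report.model_kind}, seed={report.seed}",
        f"{'metric':<14}{'class1 mean':>12}{'class1 SD':>11}{'class0 mean':>12}{'class0 SD':>11}",
    ]
    for m in METRIC_NAMES:
        fmt = "{:.2f}"
        lines.append(
            f"{m:<14}"
            f"{fmt.format(report.mean['class1'][m]):>12}"
            f"{fmt.format(report.sd['class1'][m]):>11}"
            f"{fmt.format(report.mean['class0'][m]):>12}"
            f"{fmt.format(report.sd['class0'][m]):>11}"
        )
    lines.append(f"macro-F1 = {report.macro_f1:.2f}   micro-F1 = {report.micro_f1:.2f}")
    return "\n".join(lines)
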