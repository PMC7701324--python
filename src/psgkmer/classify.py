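"""Logistic-regression classification and confusion-based evaluation.

The classifier is a plain L2-regularized logistic regression (sigmoid of
an affine score) fitted by L-BFGS at unit regularization strength — the
selected descriptor space is small enough (401 columns by default) that
no tuning is warranted.  Evaluation covers the confusion-derived metrics
(accuracy, precision, sensitivity, specificity as percentages; F1 and
MCC as fractions), ROC/PR curves with their areas, and a repeated
stratified k-fold cross-validation protocol that re-runs feature
selection inside every training fold to avoid leakage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .encoder import FeatureMatrix, encode_dataset
from .selection import ForestConfig, SelectionResult, groupwise_select
from .sequences import Dataset

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The optimizer hit its iteration cap before reaching tolerance."""

    def __init__(self, n_iter: int, cap: int) -> None:
        super().__init__(
            f"logistic regression did not converge within {cap} iterations "
            f"(ran {n_iter})"
        )
        self.n_iter = n_iter


@dataclass(frozen=True)
class LRConfig:
    """L2 penalty at unit strength, L-BFGS, tolerance 1e-4, cap 1000."""

    C: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-4


@dataclass
class TrainedModel:
    """A fitted logistic model over a fixed, ordered descriptor set."""

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.feature_names),):
            raise ValueError("one coefficient per descriptor required")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=payload["feature_names"],
            coefficients=np.array(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            threshold=float(payload["threshold"]),
            metadata=payload.get("metadata", {}),
        )


def _config_digest(**kwargs) -> str:
    blob = json.dumps(kwargs, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def fit_lr(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    config: LRConfig = LRConfig(),
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit the logistic model on a selected-feature matrix.

    Deterministic for fixed input; raises :class:`ConvergenceError` when
    the L-BFGS iteration cap is reached before the gradient tolerance.
    """
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels required to fit")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("fitting requires both classes present")
    lr = LogisticRegression(
        C=config.C,
        solver="lbfgs",
        max_iter=config.max_iter,
        tol=config.tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            lr.fit(matrix.values, labels)
        except ConvergenceWarning:
            raise ConvergenceError(config.max_iter, config.max_iter) from None
    n_iter = int(np.max(lr.n_iter_))
    if n_iter >= config.max_iter:
        raise ConvergenceError(n_iter, config.max_iter)
    return TrainedModel(
        feature_names=matrix.names,
        coefficients=lr.coef_.ravel(),
        intercept=float(lr.intercept_[0]),
        threshold=threshold,
        metadata={
            "n_training_samples": matrix.n_samples,
            "n_iter": n_iter,
            "config_digest": _config_digest(
                C=config.C, max_iter=config.max_iter, tol=config.tol
            ),
        },
    )


def predict(
    model: TrainedModel, matrix: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls (1 iff p >= threshold).

    The matrix columns must equal the model's descriptor names in order.
    """
    if matrix.names != model.feature_names:
        for got, want in zip(matrix.names, model.feature_names):
            if got != want:
                raise ValueError(
                    f"feature mismatch: matrix has {got!r} where the model "
                    f"expects {want!r}"
                )
        raise ValueError(
            f"matrix has {matrix.n_features} features, model expects "
            f"{len(model.feature_names)}"
        )
    X = matrix.values
    scores = np.asarray(X @ model.coefficients).ravel() + model.intercept
    probs = 1.0 / (1.0 + np.exp(-scores))
    calls = (probs >= model.threshold).astype(int)
    return probs, calls


@dataclass
class EvalReport:
    """Confusion counts, derived metrics and (optionally) curves.

    Accuracy, precision, sensitivity and specificity are percentages;
    F1 and MCC are fractions.  ``flags`` records any division-by-zero
    convention that fired (the affected metric is reported as 0).
    """

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    accuracy: float = 0.0
    precision: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    f1: float = 0.0
    mcc: float = 0.0
    auroc: float | None = None
    aupr: float | None = None
    roc_points: np.ndarray | None = None
    pr_points: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    per_fold: list["EvalReport"] | None = None
    per_repeat: list[dict[str, float]] | None = None
    mean: dict[str, float] | None = None
    std: dict[str, float] | None = None
    protocol: dict | None = None

    METRIC_NAMES = (
        "accuracy",
        "precision",
        "sensitivity",
        "specificity",
        "f1",
        "mcc",
        "auroc",
        "aupr",
    )

    def metric_dict(self) -> dict[str, float]:
        out = {}
        for m in self.METRIC_NAMES:
            v = getattr(self, m)
            if v is not None:
                out[m] = float(v)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "metrics": self.metric_dict(),
            "flags": self.flags,
        }
        if self.mean is not None:
            payload["mean"] = self.mean
            payload["std"] = self.std
            payload["per_repeat"] = self.per_repeat
        if self.protocol is not None:
            payload["protocol"] = self.protocol
        if self.per_fold is not None:
            payload["per_fold"] = [
                {"confusion": {"tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn},
                 "metrics": f.metric_dict()}
                for f in self.per_fold
            ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def metrics_table(self, path: str | Path) -> None:
        """Delimited metric table (metric, value[, std])."""
        lines = ["metric\tvalue" + ("\tstd" if self.std else "")]
        source = self.mean if self.mean is not None else self.metric_dict()
        for m, v in source.items():
            row = f"{m}\t{v:.4f}"
            if self.std:
                row += f"\t{self.std.get(m, float('nan')):.4f}"
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")

    def curves_to_text(self, roc_path: str | Path, pr_path: str | Path) -> None:
        for pts, path, header in (
            (self.roc_points, roc_path, "fpr\ttpr"),
            (self.pr_points, pr_path, "recall\tprecision"),
        ):
            if pts is None:
                continue
            lines = [header] + [f"{a:.6f}\t{b:.6f}" for a, b in pts]
            Path(path).write_text("\n".join(lines) + "\n")


def confusion_metrics(labels: np.ndarray, calls: np.ndarray) -> EvalReport:
    """Confusion counts and the six derived metrics.

    Percent metrics follow 100*TP+TN/total etc.; a zero denominator
    yields 0 with a flag rather than an exception.
    """
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape:
        raise ValueError(
            f"labels ({labels.shape}) and calls ({calls.shape}) differ in length"
        )
    if labels.size == 0:
        raise ValueError("empty evaluation")
    tp = int(np.sum((labels == 1) & (calls == 1)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name} undefined (zero denominator); reported 0")
            return 0.0
        return num / den

    accuracy = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    precision = 100.0 * ratio(tp, tp + fp, "precision")
    sensitivity = 100.0 * ratio(tp, tp + fn, "sensitivity")
    specificity = 100.0 * ratio(tn, tn + fp, "specificity")
    p_frac, r_frac = precision / 100.0, sensitivity / 100.0
    if p_frac + r_frac == 0:
        flags.append("f1 undefined (zero precision and recall); reported 0")
        f1 = 0.0
    else:
        f1 = 2 * p_frac * r_frac / (p_frac + r_frac)
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        flags.append("mcc undefined (zero denominator); reported 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=precision,
        sensitivity=sensitivity, specificity=specificity,
        f1=f1, mcc=mcc, flags=flags,
    )


def curves_and_areas(
    labels: np.ndarray, probabilities: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """ROC and PR curves with their areas.

    auROC integrates the ROC curve by the trapezoid rule; auPR uses
    step-wise interpolation over recall (no linear PR interpolation,
    which would be optimistic).
    """
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("curves require both classes present")
    fpr, tpr, _ = roc_curve(labels, probabilities)
    auroc = float(auc(fpr, tpr))
    prec, rec, _ = precision_recall_curve(labels, probabilities)
    # arrays come recall-descending; step integral sums P_i * ΔR_i
    aupr = float(-np.sum(np.diff(rec) * prec[:-1]))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([rec, prec])[::-1]
    return roc_points, auroc, pr_points, aupr


def evaluate(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Full evaluation of probabilistic predictions at a threshold."""
    calls = (np.asarray(probabilities) >= threshold).astype(int)
    report = confusion_metrics(labels, calls)
    roc_pts, auroc, pr_pts, aupr = curves_and_areas(labels, probabilities)
    report.roc_points, report.auroc = roc_pts, auroc
    report.pr_points, report.aupr = pr_pts, aupr
    return report


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    dataset: Dataset,
    folds: int = 5,
    repeats: int = 10,
    k: int = 100,
    seed: int = 0,
    forest: ForestConfig = ForestConfig(),
    lr_config: LRConfig = LRConfig(),
    matrix: FeatureMatrix | None = None,
    collect_selections: bool = False,
) -> EvalReport | tuple[EvalReport, list[SelectionResult]]:
    """Repeated stratified k-fold cross-validation with in-fold selection.

    Protocol per repeat: split the data into ``folds`` stratified folds;
    for each fold, run group-wise selection and fit the logistic model on
    the training folds only, then evaluate on the held-out fold.  The
    report carries per-fold metrics, per-repeat means, and mean/std of
    the per-repeat means across repeats.  Fully reproducible from
    ``seed``.  ``matrix`` may carry a pre-encoded copy of ``dataset`` to
    avoid re-encoding; ``collect_selections`` additionally returns every
    fold's SelectionResult (for stable-feature intersection analysis).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = dataset.labels
    if labels is None:
        raise ValueError("cross-validation requires labels")
    pos, neg = dataset.label_counts()
    # folds == n is leave-one-out, where stratification is vacuous
    leave_one_out = folds == len(dataset)
    if min(pos, neg) < folds and not leave_one_out:
        raise ValueError(
            f"smallest class ({min(pos, neg)}) cannot fill {folds} stratified folds"
        )
    if matrix is None:
        matrix = encode_dataset(dataset)

    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(repeats)
    per_fold_reports: list[EvalReport] = []
    per_repeat: list[dict[str, float]] = []
    selections: list[SelectionResult] = []
    for r, rs in enumerate(repeat_seeds):
        fold_ss = rs.spawn(folds + 1)
        if leave_one_out:
            splitter = KFold(
                n_splits=folds, shuffle=True,
                random_state=_child_seed(fold_ss[0]),
            )
        else:
            splitter = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=_child_seed(fold_ss[0]),
            )
        fold_reports: list[EvalReport] = []
        for f, (train_idx, val_idx) in enumerate(
            splitter.split(np.zeros(len(labels)), labels)
        ):
            train = matrix.select_rows(train_idx)
            val = matrix.select_rows(val_idx)
            sel = groupwise_select(
                train, labels[train_idx], k=k,
                seed=_child_seed(fold_ss[f + 1]), forest=forest,
            )
            if collect_selections:
                selections.append(sel)
            cols = [matrix.column_index(n) for n in sel.selected_names]
            model = fit_lr(
                train.select_columns(cols), labels[train_idx], config=lr_config
            )
            probs, calls = predict(model, val.select_columns(cols))
            if len(np.unique(labels[val_idx])) == 2:
                report = evaluate(labels[val_idx], probs, model.threshold)
            else:  # single-class fold (e.g. leave-one-out): no curves
                report = confusion_metrics(labels[val_idx], calls)
            fold_reports.append(report)
            logger.debug(
                "repeat %d fold %d: accuracy %.1f", r, f, report.accuracy
            )
        per_fold_reports.extend(fold_reports)
        repeat_means: dict[str, float] = {}
        for m in EvalReport.METRIC_NAMES:
            vals = [
                fr.metric_dict()[m]
                for fr in fold_reports
                if m in fr.metric_dict()
            ]
            if vals:
                repeat_means[m] = float(np.mean(vals))
        per_repeat.append(repeat_means)
    metrics_present = [
        m for m in EvalReport.METRIC_NAMES if all(m in pr for pr in per_repeat)
    ]
    mean = {
        m: float(np.mean([pr[m] for pr in per_repeat])) for m in metrics_present
    }
    std = {
        m: float(np.std([pr[m] for pr in per_repeat])) for m in metrics_present
    }
    summary = EvalReport(
        per_fold=per_fold_reports,
        per_repeat=per_repeat,
        mean=mean,
        std=std,
        protocol={
            "folds": folds,
            "repeats": repeats,
            "k": k,
            "seed": seed,
            "n_samples": len(dataset),
        },
    )
    # convenience: surface the across-repeat means on the top-level fields
    summary.accuracy = mean["accuracy"]
    summary.precision = mean["precision"]
    summary.sensitivity = mean["sensitivity"]
    summary.specificity = mean["specificity"]
    summary.f1 = mean["f1"]
    summary.mcc = mean["mcc"]
    summary.auroc = mean.get("auroc")
    summary.aupr = mean.get("aupr")
    for fr in per_fold_reports:
        summary.tp += fr.tp
        summary.tn += fr.tn
        summary.fp += fr.fp
        summary.fn += fr.fn
    if collect_selections:
        return summary, selections
    return summary
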