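"""Leave-one-out cross-validation, threshold scanning, metrics, ROC/AUC.

Metric definitions over the fourfold table (TP, FP, TN, FN):

    SN  = 100 * TP / (TP + FN)                     (sensitivity, %)
    SP  = 100 * TN / (TN + FP)                     (specificity, %)
    ACC = 100 * (TP + TN) / (TP + TN + FP + FN)    (accuracy, %)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    PPV = TP / (TP + FP)

MCC = 0 means prediction no better than chance, MCC = 1 perfect
agreement. All metrics are computed and stored at full precision;
rounding is presentation-layer only. Degenerate denominators are
flagged rather than propagated as NaN.

LOO CV trains n models, each on n-1 sequences, and records the held-out
decision score of the remaining one; encodings are per-sequence, so they
are computed once with no information leakage between folds. Held-out
scores are then swept over a threshold grid (default -1.0 to 1.0 in
steps of 0.1, 21 thresholds) with the label rule ``score >= threshold``;
the operating point is chosen to maximize accuracy, breaking ties toward
equal sensitivity and specificity, then toward the lower threshold.

The ROC curve and its trapezoidal AUC are computed on the held-out LOO
scores (threshold-independent performance on data each model never saw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import classify
from .classify import ANNConfig, SVMConfig, TrainedModel
from .features import encode_matrix
from .pssm import PSSMProfile, encode_pssm400
from .sequence_io import LabeledDataset


class EvaluationError(ValueError):
    """Raised for invalid evaluation input."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The five performance measures at one decision threshold."""

    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float
    ppv: float
    threshold: float
    counts: ConfusionCounts
    mcc_degenerate: bool = False
    ppv_undefined: bool = False

    def as_row(self) -> dict:
        return {
            "Th": self.threshold,
            "SN": self.sensitivity,
            "SP": self.specificity,
            "ACC": self.accuracy,
            "MCC": self.mcc,
            "PPV": self.ppv,
        }


@dataclass(frozen=True)
class ROCCurve:
    """(FPR, TPR) points over distinct score cut-points, plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class CVResult:
    """Held-out LOO scores with the threshold scan built on top of them."""

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    threshold_table: list[MetricsReport]
    best: MetricsReport
    roc: ROCCurve

    @property
    def per_sequence_scores(self) -> dict[str, float]:
        return dict(zip(self.ids, map(float, self.scores)))


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Fourfold counts from aligned binary label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.size == 0:
        raise EvaluationError("label vectors must be equal-length and non-empty")
    for v in (t, p):
        if not set(np.unique(v)) <= {0, 1}:
            raise EvaluationError("labels must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(counts: ConfusionCounts, threshold: float = 0.0) -> MetricsReport:
    """Compute SN/SP/ACC/MCC/PPV from fourfold counts at a threshold."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    n_pos, n_neg = tp + fn, tn + fp
    if counts.n == 0:
        raise EvaluationError("empty confusion table")
    sn = 100.0 * tp / n_pos if n_pos else 0.0
    sp = 100.0 * tn / n_neg if n_neg else 0.0
    acc = 100.0 * (tp + tn) / counts.n

    denom_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_degenerate = denom_sq == 0.0
    mcc = 0.0 if mcc_degenerate else (tp * tn - fp * fn) / np.sqrt(denom_sq)

    ppv_undefined = (tp + fp) == 0
    ppv = 0.0 if ppv_undefined else tp / (tp + fp)

    return MetricsReport(
        sensitivity=sn,
        specificity=sp,
        accuracy=acc,
        mcc=float(mcc),
        ppv=float(ppv),
        threshold=float(threshold),
        counts=counts,
        mcc_degenerate=mcc_degenerate,
        ppv_undefined=ppv_undefined,
    )


def threshold_grid(start: float = -1.0, stop: float = 1.0, step: float = 0.1) -> np.ndarray:
    if step <= 0:
        raise EvaluationError("step must be positive")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def threshold_scan(
    scores, labels, start: float = -1.0, stop: float = 1.0, step: float = 0.1
) -> list[MetricsReport]:
    """One MetricsReport per grid threshold, label rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must align")
    reports = []
    for th in threshold_grid(start, stop, step):
        pred = (scores >= th).astype(int)
        reports.append(metrics(confusion(labels, pred), threshold=float(th)))
    return reports


def select_best(table: list[MetricsReport]) -> MetricsReport:
    """Pick the operating point: max accuracy, then min |SN-SP|, then lower Th."""
    if not table:
        raise EvaluationError("empty threshold table")
    return min(
        table,
        key=lambda r: (-r.accuracy, abs(r.sensitivity - r.specificity), r.threshold),
    )


def roc_auc(scores, labels) -> ROCCurve:
    """ROC over distinct score cut-points and its trapezoidal AUC.

    Tied scores are grouped (one step per distinct value). Requires both
    classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(np.unique(labels))) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, th = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=th, auc=auc)


def _held_out_scores(
    X: np.ndarray, y: np.ndarray, model_config, encoding: str
) -> np.ndarray:
    n = X.shape[0]
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if len(set(np.unique(y_train))) < 2:
            raise EvaluationError(
                f"fold {i}: training split is single-class; dataset too small for LOO"
            )
        if isinstance(model_config, SVMConfig):
            model = classify.train_svm(X[mask], y_train, model_config, encoding_name=encoding)
        elif isinstance(model_config, ANNConfig):
            # offset the seed by fold index so the whole CV is reproducible
            fold_cfg = ANNConfig(
                hidden_units=model_config.hidden_units,
                activations=model_config.activations,
                learning_rate=model_config.learning_rate,
                max_cycles=model_config.max_cycles,
                seed=model_config.seed + i,
            )
            model = classify.train_ann(X[mask], y_train, fold_cfg, encoding_name=encoding)
        else:
            raise EvaluationError(f"unsupported model config {type(model_config).__name__}")
        scores[i] = classify.decision_scores(model, X[i : i + 1])[0]
        mask[i] = True
    return scores


def loocv(
    dataset: LabeledDataset,
    encoding: str,
    model_config: "SVMConfig | ANNConfig" = SVMConfig(),
    profiles: "list[PSSMProfile] | None" = None,
    scan: tuple[float, float, float] = (-1.0, 1.0, 0.1),
) -> CVResult:
    """Leave-one-out cross-validation over a labeled dataset.

    Each sequence is held out exactly once; its decision score comes from
    a model trained on the other n-1. ``encoding`` names the feature
    encoder; PSSM400 additionally needs one profile per sequence, in
    dataset order. Returns held-out scores, the threshold scan, the
    selected operating point, and the ROC on the held-out scores.
    """
    y = dataset.labels
    if dataset.n_pos < 2 or dataset.n_neg < 2:
        raise EvaluationError("LOO CV needs at least 2 members of each class")
    if encoding == "PSSM400":
        if profiles is None or len(profiles) != len(dataset):
            raise EvaluationError("PSSM400 requires one profile per sequence")
        X = np.vstack(
            [encode_pssm400(s, p).values for s, p in zip(dataset.sequences, profiles)]
        )
    else:
        X, _ = encode_matrix(dataset.sequences, encoding)

    scores = _held_out_scores(X, y, model_config, encoding)
    table = threshold_scan(scores, y, *scan)
    return CVResult(
        ids=dataset.ids,
        scores=scores,
        labels=y,
        threshold_table=table,
        best=select_best(table),
        roc=roc_auc(scores, y),
    )


def scan_table_tsv(table: list[MetricsReport], sink) -> None:
    """Write a threshold table as TSV with columns Th/SN/SP/ACC/MCC/PPV."""
    import pandas as pd

    pd.DataFrame([r.as_row() for r in table]).to_csv(sink, sep="\t", index=False, float_format="%.6g")


def roc_tsv(curve: ROCCurve, sink) -> None:
    """Write ROC points as TSV (FPR, TPR) for plotting."""
    import pandas as pd

    pd.DataFrame({"FPR": curve.fpr, "TPR": curve.tpr}).to_csv(sink, sep="\t", index=False)
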