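"""Evaluation metrics for ordinal level classification.

Covers the benchmark table quartet (accuracy, macro F1, MAE, RMSE), quadratic
weighted kappa, the probability-ordering consistency check for a predicted
class-probability vector, and the Welch two-sample t-test used for the primary
paired-fold comparison between training losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, f1_score

from .encodings import OrdinalLabel

__all__ = [
    "MetricSet",
    "TTestResult",
    "ConsistencyVerdict",
    "classification_metrics",
    "qwk",
    "ordinal_consistency",
    "welch_t_test",
]


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    f1_macro: float
    mae: float
    rmse: float
    qwk: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "f1_macro": self.f1_macro,
            "mae": self.mae,
            "rmse": self.rmse,
            "qwk": self.qwk,
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ConsistencyVerdict:
    consistent: bool
    violations: list[tuple[int, int]] = field(default_factory=list)


def _as_indices(labels, n_classes: int | None) -> tuple[np.ndarray, int]:
    c = np.array(
        [l.c if isinstance(l, OrdinalLabel) else int(l) for l in labels], dtype=int
    )
    if n_classes is None:
        ns = {l.n_classes for l in labels if isinstance(l, OrdinalLabel)}
        if len(ns) > 1:
            raise ValueError("labels disagree on the number of classes")
        n_classes = ns.pop() if ns else int(c.max()) + 1
    if np.any(c < 0) or np.any(c >= n_classes):
        raise ValueError("label outside 0..N-1")
    return c, n_classes


def qwk(true_labels, pred_labels, n_classes: int | None = None) -> float:
    """Cohen's kappa with quadratic weights ``w_ij = (i - j)^2 / (N - 1)^2``.

    Returns 0 (with a warning) in the degenerate case where chance agreement
    is already perfect, e.g. all labels on both sides identical.
    """
    t, n = _as_indices(true_labels, n_classes)
    p, _ = _as_indices(pred_labels, n)
    if t.size == 0:
        raise ValueError("empty prediction list")
    if len(np.unique(np.concatenate([t, p]))) < 2:
        warnings.warn("degenerate agreement table; QWK undefined, returning 0")
        return 0.0
    return float(
        cohen_kappa_score(t, p, labels=np.arange(n), weights="quadratic")
    )


def classification_metrics(
    true_labels, pred_labels, n_classes: int | None = None
) -> MetricSet:
    """Accuracy, macro F1, MAE, RMSE and QWK over paired label lists.

    Macro F1 averages per-class F1 over ALL ``n_classes`` classes; a class
    absent from both truth and prediction contributes F1 = 0 and still counts
    in the average.  MAE/RMSE treat class indices as rank positions, so errors
    grow with ordinal distance.
    """
    t, n = _as_indices(true_labels, n_classes)
    p, _ = _as_indices(pred_labels, n)
    if t.size == 0 or t.size != p.size:
        raise ValueError("need non-empty, equal-length truth and prediction lists")
    err = p - t
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quiet degenerate-QWK warning in bulk use
        kappa = qwk(t, p, n)
    return MetricSet(
        accuracy=float(np.mean(t == p)),
        f1_macro=float(
            f1_score(t, p, labels=np.arange(n), average="macro", zero_division=0)
        ),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err.astype(float) ** 2))),
        qwk=kappa,
    )


def ordinal_consistency(
    p: np.ndarray, reference: OrdinalLabel | int | None = None
) -> ConsistencyVerdict:
    """Check that class probabilities decay monotonically away from a reference.

    Walks outward from the reference class on each side and records a violation
    ``(nearer, farther)`` whenever the farther class has strictly higher
    probability than its neighbour one step nearer. With ``reference=None`` the
    argmax class is used (ties toward the lowest index). The verdict is
    invariant to uniform rescaling of ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("expected a 1-D probability vector of length >= 2")
    if reference is None:
        c = int(np.argmax(p))
    elif isinstance(reference, OrdinalLabel):
        if reference.n_classes != p.size:
            raise ValueError("reference arity does not match the vector")
        c = reference.c
    else:
        c = int(reference)
        if not 0 <= c < p.size:
            raise ValueError(f"reference {c} outside 0..{p.size - 1}")
    violations: list[tuple[int, int]] = []
    for i in range(c + 1, p.size):  # rightward walk
        if p[i] > p[i - 1]:
            violations.append((i - 1, i))
    for i in range(c - 1, -1, -1):  # leftward walk
        if p[i] > p[i + 1]:
            violations.append((i + 1, i))
    return ConsistencyVerdict(consistent=not violations, violations=violations)


def welch_t_test(xs, ys) -> TTestResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    ``t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y)`` with sample
    variances; degrees of freedom by Welch-Satterthwaite; p from the Student-t
    survival function. Degenerate zero-variance samples yield t = 0, p = 1
    when the means agree and an error otherwise.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise ValueError("both samples have zero variance but different means")
    sem2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sem2)
    df = sem2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)))
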