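"""Ordinal-regression loss functions and their gradients.

The training objectives benchmarked on the vertebral-level task:

* ``cross_entropy`` — plain CE, ``-log p_c``; ignores class order.
* ``ordinal_residual_loss`` (ORL) — ``-sum_i log(1 - |d_i|)`` where
  ``d_i = p_i - O_i`` is the residual against the linearly decaying target
  profile ``O`` of :func:`ordvert.encodings.ordinal_target_profile`.
* ``ordinal_residual_dual_loss`` (ORDL) — CE + lambda * ORL; the proposed
  objective (lambda defaults to 1, an unweighted sum).
* ``cdw_ce`` — class-distance-weighted CE,
  ``-sum_i |i - c|^a log(1 - p_i)``; the true-class term carries weight 0.
* ``corn_loss`` — conditional binary tasks on chained subsets (CORN).

All log arguments are clamped at ``EPS = 1e-12`` so every loss is finite and
non-negative even at probability-simplex corners (``|d_i| = 1`` is reachable).

The signed-residual reading of the ORL formula (``log(1 - d_i)`` without the
absolute value) rewards under-prediction with negative loss; it is available
behind ``signed=True`` for fidelity experiments but absolute residuals are the
default.

``*_grad`` / ``softmax_loss_and_grad`` return analytic gradients with respect
to the pre-softmax logits, which is what the NumPy training loop consumes.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .encodings import OrdinalLabel, ordinal_target_profile

EPS = 1e-12

__all__ = [
    "EPS",
    "probs_from_logits",
    "cross_entropy",
    "ordinal_residual_loss",
    "ordinal_residual_dual_loss",
    "cdw_ce",
    "corn_conditional_subsets",
    "corn_loss",
    "corn_loss_and_grad",
    "corn_chain_probs",
    "corn_predict",
    "coral_task_probs",
    "softmax_loss_and_grad",
    "SOFTMAX_LOSSES",
]


def _label_index(label: OrdinalLabel | int, n_classes: int) -> int:
    if isinstance(label, OrdinalLabel):
        if label.n_classes != n_classes:
            raise ValueError(
                f"label has {label.n_classes} classes, probability vector has {n_classes}"
            )
        return label.c
    c = int(label)
    if not 0 <= c < n_classes:
        raise ValueError(f"class index {c} outside 0..{n_classes - 1}")
    return c


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("expected a 1-D probability vector of length >= 2")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def probs_from_logits(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, label: OrdinalLabel | int) -> float:
    """``-log p_c`` with the true-class probability clamped at EPS."""
    p = _check_probs(p)
    c = _label_index(label, p.size)
    return float(-np.log(max(p[c], EPS)))


def ordinal_residual_loss(
    p: np.ndarray, label: OrdinalLabel | int, *, signed: bool = False
) -> float:
    """``-sum_i log(1 - |p_i - O_i|)`` against the linear target profile O."""
    p = _check_probs(p)
    c = _label_index(label, p.size)
    o = ordinal_target_profile(OrdinalLabel(c, p.size))
    d = p - o
    arg = (1.0 - d) if signed else (1.0 - np.abs(d))
    return float(-np.sum(np.log(np.maximum(arg, EPS))))


def ordinal_residual_dual_loss(
    p: np.ndarray,
    label: OrdinalLabel | int,
    lam: float = 1.0,
    *,
    signed: bool = False,
) -> float:
    """Cross-entropy plus ``lam`` times the ordinal residual loss."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return cross_entropy(p, label) + lam * ordinal_residual_loss(p, label, signed=signed)


def cdw_ce(p: np.ndarray, label: OrdinalLabel | int, alpha: float) -> float:
    """Class-distance-weighted CE: ``-sum_i |i - c|^a log(1 - p_i)``.

    The true-class term is excluded (its distance weight is 0), so a one-hot
    prediction at the true class scores exactly 0.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    p = _check_probs(p)
    c = _label_index(label, p.size)
    i = np.arange(p.size)
    w = np.abs(i - c).astype(float) ** alpha
    w[c] = 0.0
    return float(-np.sum(w * np.log(np.maximum(1.0 - p, EPS))))


# ---------------------------------------------------------------------------
# CORN / CORAL binary-task heads
# ---------------------------------------------------------------------------


def corn_conditional_subsets(
    labels: Sequence[OrdinalLabel | int], n_classes: int
) -> list[np.ndarray]:
    """Index sets of the chained conditional training subsets.

    Task ``k`` (k = 0..N-2) estimates P(y > k | y > k-1) and trains on the
    samples with label >= k; task 0 sees the full set.
    """
    if len(labels) == 0:
        raise ValueError("empty label list")
    c = np.array([_label_index(l, n_classes) for l in labels])
    return [np.flatnonzero(c >= k) for k in range(n_classes - 1)]


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log(1 + exp(-|z|)) + max(z, 0) - z*y, stable for large |z|
    return np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def corn_loss_and_grad(
    task_logits: np.ndarray, labels: Sequence[OrdinalLabel | int]
) -> tuple[float, np.ndarray]:
    """CORN loss and its gradient with respect to the task logits.

    ``task_logits`` is (n_samples, N-1). Each task accumulates binary
    cross-entropy over its conditional subset; the total is normalised by the
    number of contributing (sample, task) pairs so sparsely populated tasks do
    not dominate.
    """
    z = np.atleast_2d(np.asarray(task_logits, dtype=float))
    n, n_tasks = z.shape
    n_classes = n_tasks + 1
    if len(labels) != n:
        raise ValueError("labels and task logits disagree in sample count")
    c = np.array([_label_index(l, n_classes) for l in labels])

    subsets = corn_conditional_subsets(c, n_classes)
    total = 0.0
    grad = np.zeros_like(z)
    n_pairs = 0
    for k, idx in enumerate(subsets):
        if idx.size == 0:
            continue
        y = (c[idx] > k).astype(float)
        zk = z[idx, k]
        total += float(_bce_with_logits(zk, y).sum())
        grad[idx, k] = _sigmoid(zk) - y
        n_pairs += idx.size
    if n_pairs == 0:
        warnings.warn("no (sample, task) pair contributes to the CORN loss")
        return 0.0, grad
    return total / n_pairs, grad / n_pairs


def corn_loss(task_logits: np.ndarray, labels: Sequence[OrdinalLabel | int]) -> float:
    return corn_loss_and_grad(task_logits, labels)[0]


def corn_chain_probs(task_probs: np.ndarray) -> np.ndarray:
    """Unconditional rank probabilities via the chain rule: cumprod of tasks.

    ``q_k = P(y > k) = prod_{j <= k} f_j``; non-increasing for any input in
    [0, 1], which is the rank-consistency guarantee of the chained design.
    """
    f = np.asarray(task_probs, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("conditional task probabilities must lie in [0, 1]")
    return np.cumprod(f, axis=-1)


def corn_predict(task_logits: np.ndarray) -> np.ndarray:
    """Decode class indices from CORN task logits (chain then count > 0.5)."""
    z = np.atleast_2d(np.asarray(task_logits, dtype=float))
    q = corn_chain_probs(_sigmoid(z))
    return np.count_nonzero(q > 0.5, axis=-1)


def coral_task_probs(g: np.ndarray | float, biases: np.ndarray) -> np.ndarray:
    """CORAL head: ``sigma(g + b_k)`` — a shared score with per-task biases.

    With biases sorted non-increasing the task probabilities are non-increasing
    for any score ``g``, giving rank consistency by construction.
    """
    g = np.asarray(g, dtype=float)
    b = np.asarray(biases, dtype=float)
    return _sigmoid(g[..., None] + b) if g.ndim else _sigmoid(g + b)


# ---------------------------------------------------------------------------
# Batched loss + gradient wrt logits, for the training loop
# ---------------------------------------------------------------------------

SOFTMAX_LOSSES = ("ce", "ordl", "orl", "cdw_ce")


def _grad_wrt_probs(
    p: np.ndarray, c: int, name: str, lam: float, alpha: float, signed: bool
) -> np.ndarray:
    """dL/dp for one sample; clamped consistently with the loss values."""
    n = p.size
    g = np.zeros(n)
    if name in ("ce", "ordl"):
        g[c] += -1.0 / max(p[c], EPS)
    if name in ("ordl", "orl"):
        o = ordinal_target_profile(OrdinalLabel(c, n))
        d = p - o
        if signed:
            g_orl = 1.0 / np.maximum(1.0 - d, EPS)
        else:
            g_orl = np.sign(d) / np.maximum(1.0 - np.abs(d), EPS)
        g += (lam if name == "ordl" else 1.0) * g_orl
    if name == "cdw_ce":
        i = np.arange(n)
        w = np.abs(i - c).astype(float) ** alpha
        w[c] = 0.0
        g += w / np.maximum(1.0 - p, EPS)
    return g


def softmax_loss_and_grad(
    name: str,
    logits: np.ndarray,
    labels: Sequence[OrdinalLabel | int],
    *,
    lam: float = 1.0,
    alpha: float = 1.0,
    signed: bool = False,
) -> tuple[float, np.ndarray]:
    """Batch-mean loss and gradient wrt logits for the softmax-head losses.

    ``name`` is one of ``ce``, ``ordl`` (CE + lam * ORL), ``orl`` (residual
    term alone), ``cdw_ce``. Gradients are chained through the softmax
    Jacobian: ``dL/dz = p * (g - <g, p>)`` with ``g = dL/dp``.
    """
    if name not in SOFTMAX_LOSSES:
        raise ValueError(f"unknown softmax loss {name!r}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    n, n_classes = z.shape
    p = probs_from_logits(z)
    total = 0.0
    grad = np.empty_like(z)
    for j in range(n):
        c = _label_index(labels[j], n_classes)
        if name == "ce":
            total += cross_entropy(p[j], c)
        elif name == "orl":
            total += ordinal_residual_loss(p[j], c, signed=signed)
        elif name == "ordl":
            total += ordinal_residual_dual_loss(p[j], c, lam, signed=signed)
        else:
            total += cdw_ce(p[j], c, alpha)
        gp = _grad_wrt_probs(p[j], c, name, lam, alpha, signed)
        grad[j] = p[j] * (gp - gp @ p[j])
    return total / n, grad / n
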