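"""Ordinal label encodings.

Three encodings of an ordinal class label ``c`` among ``N`` ordered classes
(vertebral levels T12 < L1 < ... < L4 in the motivating application):

* the *target probability profile* ``O_i = 1 - |i - c| / (N - 1)`` — peak 1 at
  the true class, decaying linearly with rank distance to 0 at the far end.
  It is intentionally NOT normalised to sum to one; it is a per-class target,
  not a distribution.
* *extended binary labels* for the classical reduction of ordinal regression
  to N-1 binary "is the label greater than rank k?" tasks;
* rank decoding from binary-task probabilities by counting tasks whose
  probability exceeds 0.5.

Class indices are 0-based everywhere (``c = 0`` is the first ordered class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrdinalLabel",
    "ordinal_target_profile",
    "extended_binary_labels",
    "rank_from_binary_probs",
]


@dataclass(frozen=True)
class OrdinalLabel:
    """A 0-based class index ``c`` among ``N`` ordered classes."""

    c: int
    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"need at least 2 ordered classes, got {self.n_classes}")
        if not 0 <= self.c <= self.n_classes - 1:
            raise ValueError(f"class index {self.c} outside 0..{self.n_classes - 1}")


def ordinal_target_profile(label: OrdinalLabel) -> np.ndarray:
    """Linearly decaying target probabilities ``O_i = 1 - |i - c|/(N - 1)``.

    ``O_c = 1`` exactly; entries fall off linearly with rank distance and hit 0
    only at distance ``N - 1``. The profile is symmetric about ``c`` and is not
    renormalised.
    """
    i = np.arange(label.n_classes)
    return 1.0 - np.abs(i - label.c) / (label.n_classes - 1)


def extended_binary_labels(label: OrdinalLabel) -> np.ndarray:
    """Binary task labels: ``bits[k] = 1`` iff ``c > k`` for k = 0..N-2.

    The bits are non-increasing (a run of ones then zeros) and sum to ``c``.
    """
    k = np.arange(label.n_classes - 1)
    return (label.c > k).astype(np.int64)


def rank_from_binary_probs(task_probs: np.ndarray) -> int:
    """Decode a rank from binary-task probabilities: count entries > 0.5.

    A probability of exactly 0.5 does not count ("greater than 0.5" strictly).
    The result is the 0-based predicted class among ``len(task_probs) + 1``
    ordered classes.
    """
    p = np.asarray(task_probs, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one binary-task probability")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("task probabilities must lie in [0, 1]")
    return int(np.count_nonzero(p > 0.5))
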