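"""Acceptance criteria gating every knot operation.

Every change to a PPC model (knot removal, continuity adjustment, knot move)
must pass a user-selected statistical criterion before it is applied.  The
criteria compare areas ``A_i`` under the original run-length-encoded signal
with the corresponding areas ``P_i`` under the candidate polynomial, run by
run, over the affected region only:

``relative``
    ``|A_i - P_i| <= alpha * max(|A_i|, eps)`` for every run; ``alpha`` is a
    relative-deviation threshold.  Suitable for generic tracks.

``poisson``
    ``|A_i - P_i| <= alpha * sqrt(max(A_i, 1))`` for every run: deviations
    bounded in units of the Poisson standard deviation (variance = mean),
    with ``alpha`` modulating under-/over-dispersion.  Suitable for
    counts-like sequencing coverage; requires non-negative areas.

``ttest``
    Welch two-sample t-test between the data on the two sides of a knot,
    with each run expanded to per-unit observations (value repeated length
    times) and ``alpha`` acting as the p-value cutoff.  Merging is allowed
    when the sides are *not* significantly different (p > alpha).  Restricted
    to order-0 (segmentation) mode; suited to array CGH and read-depth data.

``alpha = 0`` is the strict limit: every change is rejected and the model
stays identical to the input.  Large ``alpha`` (relative/poisson) is the
loose limit where the model collapses to a single segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import stdtr

from .poly_core import AreaPair

__all__ = [
    "MethodConfig",
    "METHODS",
    "check_relative",
    "check_poisson",
    "check_ttest",
    "welch_from_stats",
    "side_stats",
]

METHODS = ("relative", "poisson", "ttest")

#: Guard for zero-area runs in the relative criterion.
EPS_AREA = 1e-12


@dataclass(frozen=True)
class MethodConfig:
    """Smoothing configuration: criterion name, its parameter alpha, the
    polynomial order cap, RNG seed and the safety cap on passes."""

    method: str = "relative"
    alpha: float = 0.05
    order: int = 0
    seed: int = 0
    pass_cap: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.alpha < 0 or not math.isfinite(self.alpha):
            raise ValueError("alpha must be a finite non-negative real")
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if self.method == "ttest" and self.order != 0:
            raise ValueError("the ttest method operates in order-0 (segmentation) mode")
        if self.pass_cap is not None and self.pass_cap < 1:
            raise ValueError("pass_cap must be >= 1")


def _pairs_arrays(pairs: Sequence[AreaPair] | tuple[np.ndarray, np.ndarray]):
    if isinstance(pairs, tuple):
        return np.asarray(pairs[0], dtype=float), np.asarray(pairs[1], dtype=float)
    A = np.array([p.A for p in pairs])
    P = np.array([p.P for p in pairs])
    return A, P


def check_relative(pairs, alpha: float) -> bool:
    """True iff ``|A_i - P_i| <= alpha * max(|A_i|, eps)`` for ALL pairs.

    ``alpha = 0`` rejects every change (strict limit), including zero-error
    ones, so the strict-limit model is bit-identical to the input.
    """
    if alpha == 0:
        return False
    A, P = _pairs_arrays(pairs)
    return bool(np.all(np.abs(A - P) <= alpha * np.maximum(np.abs(A), EPS_AREA)))


def check_poisson(pairs, alpha: float) -> bool:
    """True iff ``|A_i - P_i| <= alpha * sqrt(max(A_i, 1))`` for ALL pairs.

    Requires counts-like (non-negative) areas; raises otherwise, pointing the
    user to the relative or ttest criteria.
    """
    A, P = _pairs_arrays(pairs)
    if np.any(A < 0):
        raise ValueError(
            "poisson criterion requires non-negative areas (counts-like signal); "
            "use method='relative' or method='ttest' for signed data"
        )
    if alpha == 0:
        return False
    return bool(np.all(np.abs(A - P) <= alpha * np.sqrt(np.maximum(A, 1.0))))


def side_stats(lengths: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """(n, mean, sample variance) of a run slice expanded to per-unit
    observations, computed from run summaries without expansion."""
    n = float(np.sum(lengths))
    if n <= 0:
        return 0.0, 0.0, 0.0
    lv = lengths * values
    mean = float(np.sum(lv) / n)
    ssq = float(np.dot(lv, values)) - n * mean * mean
    var = max(ssq, 0.0) / (n - 1.0) if n > 1 else 0.0
    return n, mean, var


def welch_from_stats(n1, m1, v1, n2, m2, v2) -> float:
    """Two-sided Welch t-test p-value from per-side summary statistics.

    Zero-variance convention (degenerate array data): if both sides are
    constant, equal means give p = 1 and unequal means give p = 0 (t = inf).
    """
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0.0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1.0) + (v2 / n2) ** 2 / (n2 - 1.0))
    return 2.0 * float(stdtr(df, -abs(t)))


def check_ttest(left, right, alpha: float) -> bool:
    """True (merge allowed) iff the two sides are not significantly different.

    ``left``/``right`` are :class:`~ppctrack.rle_io.RleSignal` objects or
    ``(lengths, values)`` pairs; each run contributes ``length`` per-unit
    observations, so probe signals (unit runs) reduce to the classical
    empirical t-test while long runs are weighted by their length.  Sides
    with fewer than 2 observations cannot be tested and allow the merge.
    """
    if alpha == 0:
        return False
    l1, v1 = _side_arrays(left)
    l2, v2 = _side_arrays(right)
    n1, m1, s1 = side_stats(l1, v1)
    n2, m2, s2 = side_stats(l2, v2)
    if n1 < 2 or n2 < 2:
        return True
    return welch_from_stats(n1, m1, s1, n2, m2, s2) > alpha


def _side_arrays(side) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(side, tuple):
        return (
            np.asarray(side[0], dtype=np.float64),
            np.asarray(side[1], dtype=np.float64),
        )
    return side.lengths.astype(np.float64), side.values
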