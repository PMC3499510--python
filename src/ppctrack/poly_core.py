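"""Integral least-squares fitting of polynomial pieces to RLE data.

A piecewise polynomial curve (PPC) is an ordered, gap-free list of
:class:`PpcSegment` pieces; the value of a segment at coordinate ``x`` is
``sum_j c_j (x - start)^j`` on ``[start, start + length)``.  Because the data
are curves (run-length-encoded staircases) rather than point sets, fitting
minimizes the *integral* of the squared difference between the polynomial and
the staircase, not a pointwise sum of squares:

    E = integral_a^b (p(x) - f(x))^2 dx.

All integrals are evaluated in closed form run-by-run (each run of the
staircase contributes analytically), so every operation costs O(runs in the
window), never O(bases).  Fits are solved from the normal equations built on
interval moments in a unit-scaled local coordinate, which keeps the linear
systems well conditioned even on 1e8-scale genomic coordinates; coefficients
are then re-expressed about the segment start.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .rle_io import RleSignal

__all__ = [
    "PpcSegment",
    "PpcModel",
    "AreaPair",
    "eval_model",
    "poly_area",
    "fit_poly",
    "fit_poly_constrained",
    "local_error",
    "area_pairs",
    "shift_origin",
]

#: Condition-number threshold above which the fit falls back to a lower order.
COND_LIMIT = 1e12


@dataclass(frozen=True)
class PpcSegment:
    """One polynomial piece on ``[start, start + length)``.

    ``coefficients[j]`` multiplies ``(x - start)^j``; the polynomial origin is
    the segment start so coefficients stay well-conditioned at genomic scale.
    ``continuous_left`` records whether the piece was constrained to join the
    previous piece continuously.
    """

    start: int
    length: int
    order: int
    coefficients: tuple[float, ...]
    continuous_left: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.order not in (0, 1, 2):
            raise ValueError("polynomial order must be 0, 1 or 2")
        if len(self.coefficients) != self.order + 1:
            raise ValueError("order p requires p+1 coefficients")
        if not all(np.isfinite(c) for c in self.coefficients):
            raise ValueError("coefficients must be finite")

    @property
    def end(self) -> int:
        return self.start + self.length

    def __call__(self, x) -> float | np.ndarray:
        u = np.asarray(x, dtype=np.float64) - self.start
        out = np.zeros_like(u)
        for c in reversed(self.coefficients):
            out = out * u + c
        return out if out.ndim else float(out)

    @property
    def slope_at_start(self) -> float:
        return self.coefficients[1] if self.order >= 1 else 0.0

    def value_at_end(self) -> float:
        """Left limit of the segment value at its right boundary (the
        polynomial evaluated at u = length)."""
        out = 0.0
        for c in reversed(self.coefficients):
            out = out * self.length + c
        return out


@dataclass
class PpcModel:
    """Ordered, non-overlapping, gap-free PPC covering a signal extent."""

    chrom: str
    segments: list[PpcSegment]
    _starts: list[int] | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("model must contain at least one segment")
        pos = self.segments[0].start
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(f"segment tiling broken at {seg.start} (expected {pos})")
            pos = seg.end

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def breakpoints(self) -> np.ndarray:
        """Interior piece boundaries (knots surviving in the model)."""
        return np.array([s.start for s in self.segments[1:]], dtype=np.int64)

    def segment_at(self, x: float) -> PpcSegment:
        if not self.start <= x < self.end:
            raise ValueError(f"coordinate {x} outside model extent [{self.start}, {self.end})")
        if self._starts is None or len(self._starts) != len(self.segments):
            self._starts = [s.start for s in self.segments]
        return self.segments[bisect_right(self._starts, x) - 1]

    def __call__(self, x) -> float | np.ndarray:
        if np.ndim(x) == 0:
            return self.segment_at(float(x))(x)
        return np.array([self.segment_at(float(xi))(xi) for xi in np.asarray(x)])


@dataclass(frozen=True)
class AreaPair:
    """Area under one original run (A) vs under the candidate model (P) over
    the same window; the windows of the pairs partition the candidate span."""

    run_index: int
    A: float
    P: float


def eval_model(segments: PpcModel | Sequence[PpcSegment], x: float) -> float:
    """Value of the unique segment containing ``x`` (half-open convention)."""
    model = segments if isinstance(segments, PpcModel) else PpcModel("", list(segments))
    return float(model.segment_at(x)(x))


def poly_area(segment: PpcSegment, a: float, b: float) -> float:
    """Exact integral of the segment polynomial over ``[a, b)``.

    The window must lie within the segment.
    """
    if not (segment.start <= a <= b <= segment.end):
        raise ValueError("window outside segment")
    ua, ub = a - segment.start, b - segment.start
    return _poly_integral(np.asarray(segment.coefficients), ua, ub)


def _poly_integral(coefs: np.ndarray, ua, ub):
    """integral of sum_j c_j u^j over [ua, ub); ua/ub may be arrays."""
    total = 0.0
    for j, c in enumerate(coefs):
        total = total + c / (j + 1) * (ub ** (j + 1) - ua ** (j + 1))
    return total


def shift_origin(coefs: Sequence[float], delta: float) -> tuple[float, ...]:
    """Re-express ``sum c_j u1^j`` with ``u1 = u2 + delta`` as coefficients in
    ``u2`` (i.e. move the polynomial origin forward by ``delta``)."""
    c = list(coefs) + [0.0, 0.0]
    c0 = c[0] + c[1] * delta + c[2] * delta * delta
    c1 = c[1] + 2.0 * c[2] * delta
    c2 = c[2]
    return tuple((c0, c1, c2)[: len(coefs)])


def _window_runs(signal: "RleSignal", a: float, b: float):
    """Indices and clipped bounds of runs overlapping [a, b)."""
    bounds = signal.run_bounds
    if not (bounds[0] <= a < b <= bounds[-1]):
        raise ValueError(f"window [{a}, {b}) outside signal extent")
    i = int(np.searchsorted(bounds, a, side="right")) - 1
    j = int(np.searchsorted(bounds, b, side="left"))
    lo = np.maximum(bounds[i:j].astype(np.float64), a)
    hi = np.minimum(bounds[i + 1 : j + 1].astype(np.float64), b)
    return i, j, lo, hi


def _data_moments(signal: "RleSignal", a: float, b: float, max_j: int):
    """Moments d_j = integral tau^j f(x) dx, tau = (x - a)/(b - a), j <= max_j,
    plus integral f(x)^2 dx, accumulated run-by-run in closed form."""
    w = b - a
    i, j, lo, hi = _window_runs(signal, a, b)
    v = signal.values[i:j]
    tlo, thi = (lo - a) / w, (hi - a) / w
    d = np.empty(max_j + 1)
    for m in range(max_j + 1):
        d[m] = w / (m + 1) * np.dot(v, thi ** (m + 1) - tlo ** (m + 1))
    f2 = float(np.dot(v * v, hi - lo))
    return d, f2


def _scaled_to_origin(chat: np.ndarray, a: float, w: float, origin: float) -> tuple[float, ...]:
    """Convert coefficients in tau = (x - a)/w to coefficients in u = x - origin."""
    e = np.zeros(3)
    for m, c in enumerate(chat):
        e[m] = c / w**m
    return shift_origin(e[: len(chat)], a - origin)


def fit_poly(
    signal: "RleSignal", a: float, b: float, order: int, origin: float | None = None
) -> tuple[float, ...]:
    """Polynomial of the given order minimizing the integral squared error
    against the staircase signal on ``[a, b)``.

    Solved in closed form from the normal equations on interval moments.  If
    the (scaled) normal matrix is ill-conditioned (estimate above
    ``COND_LIMIT``), the order is reduced; the returned tuple length reflects
    the order actually used.  Coefficients are expressed about ``origin``
    (default ``a``).
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if b - a < 1:
        raise ValueError("window must have width >= 1")
    origin = a if origin is None else origin
    w = float(b - a)
    d, _ = _data_moments(signal, a, b, order)
    for p in range(order, -1, -1):
        G = w * _hilbert(p + 1)
        if p > 0 and np.linalg.cond(G) > COND_LIMIT:
            continue
        chat = np.linalg.solve(G, d[: p + 1])
        return _scaled_to_origin(chat, a, w, origin)
    raise RuntimeError("unreachable: order-0 system is never singular")


def fit_poly_constrained(
    signal: "RleSignal",
    a: float,
    b: float,
    order: int,
    boundary: Sequence[tuple[float, float]],
    origin: float | None = None,
) -> tuple[float, ...]:
    """Integral least-squares fit subject to exact point constraints
    ``p(x_k) = v_k`` (constraint coordinates in ``[a, b]``).

    Solved as a KKT system (Lagrange multipliers on the normal equations).
    With zero constraints this is identical to :func:`fit_poly`; with
    ``order + 1`` constraints the polynomial is fully determined by
    interpolation.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if len(boundary) > order + 1:
        raise ValueError("more constraints than polynomial degrees of freedom")
    if not boundary:
        return fit_poly(signal, a, b, order, origin=origin)
    origin = a if origin is None else origin
    w = float(b - a)
    d, _ = _data_moments(signal, a, b, order)
    n = order + 1
    m = len(boundary)
    A = np.empty((m, n))
    rhs_c = np.empty(m)
    for k, (xk, vk) in enumerate(boundary):
        if not (a <= xk <= b):
            raise ValueError("constraint coordinate outside window")
        tk = (xk - a) / w
        A[k] = [tk**j for j in range(n)]
        rhs_c[k] = vk
    if m == n:
        chat = np.linalg.solve(A, rhs_c)
        return _scaled_to_origin(chat, a, w, origin)
    G = w * _hilbert(n)
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = G
    kkt[:n, n:] = A.T
    kkt[n:, :n] = A
    rhs = np.concatenate([d[:n], rhs_c])
    sol = np.linalg.solve(kkt, rhs)
    return _scaled_to_origin(sol[:n], a, w, origin)


def local_error(
    segments: PpcModel | Sequence[PpcSegment] | PpcSegment,
    signal: "RleSignal",
    a: float,
    b: float,
) -> float:
    """Exact ``integral_a^b (model - f)^2 dx`` over the intersection partition
    of model segments and data runs.

    Non-negative; zero iff the model equals the staircase almost everywhere on
    the window.
    """
    if isinstance(segments, PpcSegment):
        segments = [segments]
    seglist = segments.segments if isinstance(segments, PpcModel) else list(segments)
    total = 0.0
    for seg in seglist:
        wa, wb = max(a, seg.start), min(b, seg.end)
        if wa >= wb:
            continue
        _, _, lo, hi = _window_runs(signal, wa, wb)
        i0 = int(np.searchsorted(signal.run_bounds, wa, side="right")) - 1
        v = signal.values[i0 : i0 + len(lo)]
        c = np.asarray(seg.coefficients)
        q = np.convolve(c, c)  # coefficients of p(u)^2
        ulo, uhi = lo - seg.start, hi - seg.start
        int_p2 = _poly_integral(q, ulo, uhi)
        int_p = _poly_integral(c, ulo, uhi)
        total += float(np.sum(int_p2 - 2.0 * v * int_p + v * v * (uhi - ulo)))
    return max(total, 0.0)


def area_pairs(
    signal: "RleSignal",
    segments: PpcModel | Sequence[PpcSegment] | PpcSegment,
    a: float,
    b: float,
) -> list[AreaPair]:
    """Per-run area comparison over ``[a, b)``.

    One pair per original run overlapping the window (clipped to it): ``A`` is
    the area under the staircase, ``P`` the integral of the candidate model
    over the same sub-window.  The sum of ``P`` equals the model integral over
    the window exactly.
    """
    if isinstance(segments, PpcSegment):
        segments = [segments]
    seglist = segments.segments if isinstance(segments, PpcModel) else list(segments)
    i, j, lo, hi = _window_runs(signal, a, b)
    v = signal.values[i:j]
    A = v * (hi - lo)
    P = np.zeros_like(A)
    for seg in seglist:
        wa, wb = max(a, seg.start), min(b, seg.end)
        if wa >= wb:
            continue
        plo = np.maximum(lo, wa)
        phi = np.minimum(hi, wb)
        mask = phi > plo
        if not mask.any():
            continue
        c = np.asarray(seg.coefficients)
        P[mask] += _poly_integral(c, plo[mask] - seg.start, phi[mask] - seg.start)
    return [AreaPair(i + k, float(A[k]), float(P[k])) for k in range(len(A))]


def _hilbert(n: int) -> np.ndarray:
    """Moment matrix of the monomial basis on [0, 1]: H[j, k] = 1/(j + k + 1)."""
    idx = np.arange(n)
    return 1.0 / (idx[:, None] + idx[None, :] + 1.0)
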