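"""Bottom-up stochastic knot adjustment: RLE signal -> PPC model.

The smoother starts from the run-length-encoded input, where every run is an
order-0 segment and every run boundary is a *knot*, and repeatedly tries three
local operations at each knot, in this order, stopping at the first success:

1. **removal** — replace the two adjacent segments by a single polynomial
   fitted over their union;
2. **continuity adjustment** — refit both adjacent segments constrained to
   share a common value at the knot (the shared value is itself optimized);
3. **relocation** — move the knot to the original run boundary inside the two
   adjacent segments that minimizes the combined integral squared error.

Each operation is accepted only if the configured criterion
(:mod:`ppctrack.criteria`) holds on every original run it affects, so the
final model provably satisfies the per-run inequality genome-wide for the
area-based criteria.  Knots are visited in a fresh random order each pass;
after the first pass only knots modified in the previous pass (or their
immediate neighbors) are revisited, and the procedure stops when no knot
changes or when all interior knots are gone.  Randomization means repeated
runs can give slightly different, equally acceptable models; a fixed seed
makes any single run deterministic.

The knot store is a hash map crossed with a doubly linked list: constant-time
lookup, removal and neighbor access, which keeps every operation O(runs in
the affected window) and the whole procedure subquadratic in the run count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .criteria import EPS_AREA, MethodConfig, welch_from_stats
from .poly_core import PpcModel, PpcSegment, _hilbert
from .rle_io import RleSignal

__all__ = [
    "KnotStore",
    "SmoothResult",
    "build_knots",
    "try_remove",
    "try_continuity_adjust",
    "try_move",
    "smooth",
    "smooth_multi",
]

_TIE_TOL = 1e-12  # equal-error tolerance in knot moves: keep current position
_ADJ_TOL = 1e-10  # allowed error increase in continuity adjustments

# ones^T H^-1 ones == e0^T H^-1 e0 for the unit-interval moment matrix H
_CONSTRAINT_GAIN = {1: 1.0, 2: 4.0, 3: 9.0}
_HINV_ONES = {2: np.array([-2.0, 6.0]), 3: np.array([3.0, -24.0, 30.0])}
_HINV_E0 = {2: np.array([4.0, -6.0]), 3: np.array([9.0, -36.0, 30.0])}


class KnotStore:
    """Mutable set of segment boundaries with O(1) lookup/removal/neighbors.

    Knots are identified by run-boundary index ``0..n`` into the original
    signal (index ``t`` sits at absolute position ``run_bounds[t]``); indices
    0 and n are non-removable sentinels.  Each interior node owns the segment
    starting at its position, stored as ``(coefficients, continuous_left)``
    with the polynomial origin at the segment start.
    """

    def __init__(self, signal: RleSignal):
        self.signal = signal
        self.bounds = signal.run_bounds
        n = signal.n_runs
        self.n = n
        # node: [prev_idx, next_idx, coefs, continuous_left]
        self.nodes: dict[int, list] = {}
        for t in range(n):
            self.nodes[t] = [t - 1, t + 1, (float(signal.values[t]),), False]
        self.nodes[n] = [n - 1, n + 1, None, False]
        self.nodes[0][0] = -1
        self.modified: set[int] = set()
        # engine context (prefix sums), attached by build_knots
        self._ctx: "_Context | None" = None

    # -- contract surface -------------------------------------------------
    def __contains__(self, idx: int) -> bool:
        return idx in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def is_interior(self, idx: int) -> bool:
        return idx in self.nodes and 0 < idx < self.n

    def neighbors(self, idx: int) -> tuple[int, int]:
        node = self.nodes[idx]
        return node[0], node[1]

    def index_of(self, position: int) -> int:
        """Run-boundary index of an absolute knot position."""
        t = int(np.searchsorted(self.bounds, position))
        if t >= len(self.bounds) or self.bounds[t] != position or t not in self.nodes:
            raise KeyError(f"no knot at position {position}")
        return t

    def interior_knots(self) -> list[int]:
        return [t for t in self.nodes if 0 < t < self.n]

    def mark_modified(self, *idxs: int) -> None:
        for t in idxs:
            if self.is_interior(t):
                self.modified.add(t)

    def remove(self, idx: int) -> None:
        prev_i, next_i, _, _ = self.nodes.pop(idx)
        self.nodes[prev_i][1] = next_i
        self.nodes[next_i][0] = prev_i

    def insert(self, idx: int, prev_i: int, next_i: int) -> None:
        self.nodes[idx] = [prev_i, next_i, None, False]
        self.nodes[prev_i][1] = idx
        self.nodes[next_i][0] = idx

    def to_model(self) -> PpcModel:
        segs = []
        t = 0
        while t < self.n:
            prev_i, next_i, coefs, cont = self.nodes[t]
            segs.append(
                PpcSegment(
                    start=int(self.bounds[t]),
                    length=int(self.bounds[next_i] - self.bounds[t]),
                    order=len(coefs) - 1,
                    coefficients=tuple(float(c) for c in coefs),
                    continuous_left=cont,
                )
            )
            t = next_i
        return PpcModel(self.signal.chrom, segs)


class _Context:
    """Prefix sums over the original runs for O(window-runs) fits and checks."""

    def __init__(self, signal: RleSignal, config: MethodConfig):
        self.config = config
        self.bounds = signal.run_bounds.astype(np.float64)
        self.v = signal.values
        l = signal.lengths.astype(np.float64)
        self.lv = l * signal.values
        self.cl = _prefix(l)
        self.clv = _prefix(self.lv)
        self.clv2 = _prefix(self.lv * signal.values)

    # -- fits --------------------------------------------------------------
    def fit(self, i: int, j: int, order: int) -> tuple[tuple[float, ...], float]:
        """Least-squares fit over runs i..j-1; coefficients about bounds[i];
        returns (coefficients, integral squared error)."""
        if order == 0:
            S0 = self.cl[j] - self.cl[i]
            S1 = self.clv[j] - self.clv[i]
            S2 = self.clv2[j] - self.clv2[i]
            c0 = S1 / S0
            return (c0,), max(S2 - S1 * c0, 0.0)
        w = self.bounds[j] - self.bounds[i]
        tau = (self.bounds[i : j + 1] - self.bounds[i]) / w
        v = self.v[i:j]
        p = order
        d = np.empty(p + 1)
        pw = tau.copy()
        for m in range(p + 1):
            pw *= tau if m else 1.0  # pw = tau^(m+1)
            d[m] = w / (m + 1) * np.dot(v, np.diff(pw))
        chat = np.linalg.solve(w * _hilbert(p + 1), d)
        F2 = self.clv2[j] - self.clv2[i]
        err = max(F2 - float(np.dot(d, chat)), 0.0)
        coefs = tuple(chat[m] / w**m for m in range(p + 1))
        return coefs, err

    def fit_free_endpoint(self, i: int, j: int, order: int, at_end: bool):
        """Unconstrained fit plus the data needed to slide its value at one
        endpoint: returns (chat_tau, err, yhat, gain, w).

        Constraining the fit to value y at that endpoint costs
        ``(y - yhat)^2 * gain / w`` extra error, with the constrained
        coefficients ``chat + hinv_dir * (y - yhat) / K`` in tau coordinates.
        """
        w = self.bounds[j] - self.bounds[i]
        tau = (self.bounds[i : j + 1] - self.bounds[i]) / w
        v = self.v[i:j]
        p = order
        d = np.empty(p + 1)
        pw = tau.copy()
        for m in range(p + 1):
            pw *= tau if m else 1.0
            d[m] = w / (m + 1) * np.dot(v, np.diff(pw))
        chat = np.linalg.solve(w * _hilbert(p + 1), d)
        F2 = self.clv2[j] - self.clv2[i]
        err = max(F2 - float(np.dot(d, chat)), 0.0)
        yhat = float(np.sum(chat)) if at_end else float(chat[0])
        K = _CONSTRAINT_GAIN[p + 1]
        return chat, err, yhat, K / w, w

    # -- per-run model areas and errors ------------------------------------
    def pred_areas(self, i: int, j: int, coefs, origin_idx: int) -> np.ndarray:
        """Integral of the candidate polynomial over each run i..j-1."""
        ub = self.bounds[i : j + 1] - self.bounds[origin_idx]
        P = coefs[0] * np.diff(ub)
        if len(coefs) > 1:
            pw = ub * ub
            P += coefs[1] / 2.0 * np.diff(pw)
            if len(coefs) > 2:
                pw *= ub
                P += coefs[2] / 3.0 * np.diff(pw)
        return P

    def seg_error(self, i: int, j: int, coefs, origin_idx: int) -> float:
        """Integral squared error of an arbitrary segment over runs i..j-1."""
        c = np.asarray(coefs)
        q = np.convolve(c, c)
        ua = self.bounds[i] - self.bounds[origin_idx]
        ub = self.bounds[j] - self.bounds[origin_idx]
        int_p2 = 0.0
        for m, qm in enumerate(q):
            int_p2 += qm / (m + 1) * (ub ** (m + 1) - ua ** (m + 1))
        int_pf = float(np.dot(self.v[i:j], self.pred_areas(i, j, coefs, origin_idx)))
        F2 = self.clv2[j] - self.clv2[i]
        return max(int_p2 - 2.0 * int_pf + F2, 0.0)

    # -- criteria -----------------------------------------------------------
    def check_areas(self, i: int, j: int, P: np.ndarray) -> bool:
        cfg = self.config
        if cfg.alpha == 0:
            return False
        A = self.lv[i:j]
        dev = np.abs(A - P)
        if cfg.method == "relative":
            return bool(np.all(dev <= cfg.alpha * np.maximum(np.abs(A), EPS_AREA)))
        return bool(np.all(dev <= cfg.alpha * np.sqrt(np.maximum(A, 1.0))))

    def ttest_p(self, i: int, k: int, j: int) -> float:
        """Welch p-value between per-unit observations of runs i..k-1 and
        k..j-1; p = 1 when either side has < 2 observations."""
        n1 = self.cl[k] - self.cl[i]
        n2 = self.cl[j] - self.cl[k]
        if n1 < 2 or n2 < 2:
            return 1.0
        m1 = (self.clv[k] - self.clv[i]) / n1
        m2 = (self.clv[j] - self.clv[k]) / n2
        v1 = max(self.clv2[k] - self.clv2[i] - n1 * m1 * m1, 0.0) / (n1 - 1.0)
        v2 = max(self.clv2[j] - self.clv2[k] - n2 * m2 * m2, 0.0) / (n2 - 1.0)
        return welch_from_stats(n1, m1, v1, n2, m2, v2)


def _prefix(x: np.ndarray) -> np.ndarray:
    out = np.empty(len(x) + 1)
    out[0] = 0.0
    np.cumsum(x, out=out[1:])
    return out


def build_knots(signal: RleSignal, config: MethodConfig | int = 0) -> KnotStore:
    """Initial knot store: one interior knot per run boundary, initial
    segments order-0 copies of the runs, all interior knots candidates."""
    if isinstance(config, int):
        config = MethodConfig(order=config)
    store = KnotStore(signal)
    store._ctx = _Context(signal, config)
    store.mark_modified(*range(1, store.n))
    return store


def _ctx(store: KnotStore, config: MethodConfig) -> _Context:
    # prefix sums depend only on the signal; the config is swapped in place
    if store._ctx is None:
        store._ctx = _Context(store.signal, config)
    else:
        store._ctx.config = config
    return store._ctx


def _resolve(store: KnotStore, knot: int) -> int:
    """Validate a knot given as run-boundary index (see
    :meth:`KnotStore.index_of` to translate absolute positions)."""
    if not store.is_interior(knot):
        raise KeyError(f"no interior knot with boundary index {knot}")
    return knot


def try_remove(store: KnotStore, knot: int, signal: RleSignal, config: MethodConfig) -> bool:
    """Attempt to delete a knot, merging its two segments into one polynomial
    of order ``config.order`` fitted over the union span."""
    k = _resolve(store, knot)
    ctx = _ctx(store, config)
    i, j = store.neighbors(k)
    if config.method == "ttest":
        ok = ctx.ttest_p(i, k, j) > config.alpha and config.alpha > 0
        if not ok:
            return False
        coefs, _ = ctx.fit(i, j, config.order)
    else:
        coefs, _ = ctx.fit(i, j, config.order)
        if not ctx.check_areas(i, j, ctx.pred_areas(i, j, coefs, i)):
            return False
    store.remove(k)
    store.nodes[i][2] = coefs
    store.nodes[i][3] = False  # unconstrained refit: continuity at i is void
    if j < store.n:
        store.nodes[j][3] = False
    store.mark_modified(i, j)
    return True


def try_continuity_adjust(
    store: KnotStore, knot: int, signal: RleSignal, config: MethodConfig
) -> bool:
    """Attempt to remove the discontinuity at a knot by refitting both
    adjacent segments with a shared (jointly optimized) value at the knot.

    Skipped in order-0 mode, where a continuous constant pair is a removal.
    Accepted only if the criterion holds on both spans and the combined
    integral squared error does not increase.
    """
    if config.order < 1 or config.method == "ttest":
        return False
    k = _resolve(store, knot)
    ctx = _ctx(store, config)
    i, j = store.neighbors(k)
    p = config.order
    chatL, errL, yL, gainL, wL = ctx.fit_free_endpoint(i, k, p, at_end=True)
    chatR, errR, yR, gainR, wR = ctx.fit_free_endpoint(k, j, p, at_end=False)
    # joint optimum of errL + gainL (y-yL)^2 + errR + gainR (y-yR)^2
    y = (gainL * yL + gainR * yR) / (gainL + gainR)
    K = _CONSTRAINT_GAIN[p + 1]
    cL = chatL + _HINV_ONES[p + 1] * ((y - yL) / K)
    cR = chatR + _HINV_E0[p + 1] * ((y - yR) / K)
    coefsL = tuple(cL[m] / wL**m for m in range(p + 1))
    coefsR = tuple(cR[m] / wR**m for m in range(p + 1))
    new_err = errL + gainL * (y - yL) ** 2 + errR + gainR * (y - yR) ** 2
    old_err = ctx.seg_error(i, k, store.nodes[i][2], i) + ctx.seg_error(
        k, j, store.nodes[k][2], k
    )
    if new_err > old_err + _ADJ_TOL:
        return False
    if not ctx.check_areas(i, k, ctx.pred_areas(i, k, coefsL, i)):
        return False
    if not ctx.check_areas(k, j, ctx.pred_areas(k, j, coefsR, k)):
        return False
    store.nodes[i][2] = coefsL
    store.nodes[i][3] = False  # left segment refit unconstrained at its start
    store.nodes[k][2] = coefsR
    store.nodes[k][3] = True
    if j < store.n:
        store.nodes[j][3] = False
    store.mark_modified(k)
    return True


def try_move(store: KnotStore, knot: int, signal: RleSignal, config: MethodConfig) -> bool:
    """Attempt to relocate a knot to the original run boundary inside its two
    adjacent segments that minimizes the combined integral squared error.

    Adopted only on a strict error decrease that also passes the criterion;
    ties (within 1e-12) keep the current position.
    """
    k = _resolve(store, knot)
    ctx = _ctx(store, config)
    i, j = store.neighbors(k)
    if j - i < 2:
        return False
    cand = np.arange(i + 1, j)
    cand = cand[cand != k]
    if len(cand) == 0:
        return False
    p = config.order
    if p == 0:
        S0L = ctx.cl[cand] - ctx.cl[i]
        S1L = ctx.clv[cand] - ctx.clv[i]
        S2L = ctx.clv2[cand] - ctx.clv2[i]
        S0R = ctx.cl[j] - ctx.cl[cand]
        S1R = ctx.clv[j] - ctx.clv[cand]
        S2R = ctx.clv2[j] - ctx.clv2[cand]
        errs = (S2L - S1L * S1L / S0L) + (S2R - S1R * S1R / S0R)
    elif p == 1:
        errs = _move_errors_linear(ctx, i, j, cand)
    else:
        errs = np.array(
            [ctx.fit(i, int(c), p)[1] + ctx.fit(int(c), j, p)[1] for c in cand]
        )
    best = int(np.argmin(errs))
    c_best = int(cand[best])
    cur_err = ctx.seg_error(i, k, store.nodes[i][2], i) + ctx.seg_error(
        k, j, store.nodes[k][2], k
    )
    if not (errs[best] < cur_err - _TIE_TOL):
        return False
    coefsL, _ = ctx.fit(i, c_best, p)
    coefsR, _ = ctx.fit(c_best, j, p)
    if config.method == "ttest":
        # a knot is statistically justified at the candidate position iff the
        # two sides differ significantly there
        if not (config.alpha > 0):
            return False
        n1 = ctx.cl[c_best] - ctx.cl[i]
        n2 = ctx.cl[j] - ctx.cl[c_best]
        if n1 >= 2 and n2 >= 2 and ctx.ttest_p(i, c_best, j) > config.alpha:
            return False
    else:
        if not ctx.check_areas(i, c_best, ctx.pred_areas(i, c_best, coefsL, i)):
            return False
        if not ctx.check_areas(c_best, j, ctx.pred_areas(c_best, j, coefsR, c_best)):
            return False
    store.remove(k)
    store.insert(c_best, i, j)
    store.nodes[i][2] = coefsL
    store.nodes[i][3] = False
    store.nodes[c_best][2] = coefsR
    store.nodes[c_best][3] = False
    if j < store.n:
        store.nodes[j][3] = False
    store.mark_modified(i, c_best, j)
    return True


def _move_errors_linear(ctx: _Context, i: int, j: int, cand: np.ndarray) -> np.ndarray:
    """Combined order-1 fit errors for all candidate split points of runs
    i..j-1, vectorized via local prefix moments (origin at the span start)."""
    u = ctx.bounds[i : j + 1] - ctx.bounds[i]
    v = ctx.v[i:j]
    J0 = np.diff(u)
    J1 = np.diff(u * u) / 2.0
    d0 = _prefix(v * J0)
    d1 = _prefix(v * J1)
    F2 = _prefix(v * v * J0)
    ci = cand - i
    uc = u[ci]
    W = u[-1]

    def fit_err(M0, M1, M2, a0, a1, f2):
        det = M0 * M2 - M1 * M1
        c0 = (a0 * M2 - a1 * M1) / det
        c1 = (M0 * a1 - M1 * a0) / det
        return np.maximum(f2 - (c0 * a0 + c1 * a1), 0.0)

    eL = fit_err(uc, uc**2 / 2.0, uc**3 / 3.0, d0[ci], d1[ci], F2[ci])
    wR = W - uc
    # right side re-originated at the candidate position
    a0R = d0[-1] - d0[ci]
    a1R = (d1[-1] - d1[ci]) - uc * a0R
    eR = fit_err(wR, wR**2 / 2.0, wR**3 / 3.0, a0R, a1R, F2[-1] - F2[ci])
    return eL + eR


@dataclass(frozen=True)
class SmoothResult:
    """Outcome of one smoothing run."""

    model: PpcModel
    passes_used: int
    knots_removed: int
    seed: int
    converged: bool


def default_pass_cap(n_runs: int) -> int:
    """Safety cap on passes: 100 + 20*log2(initial run count); in practice
    convergence is reached long before it binds."""
    return int(100 + 20 * math.log2(max(n_runs, 2)))


def smooth(signal: RleSignal, config: MethodConfig) -> SmoothResult:
    """Run the full bottom-up smoothing procedure on one signal.

    Pass 1 visits every interior knot in uniform random order, applying
    removal, continuity adjustment and relocation in that order and stopping
    at the first success per knot; later passes revisit only knots modified
    in the previous pass or adjacent to one.  Terminates when a pass changes
    nothing, when no interior knots remain, or at the pass cap (the result is
    then flagged unconverged but is still a valid model).
    """
    if config.method == "poisson" and np.any(signal.values < 0):
        raise ValueError(
            "poisson criterion requires a non-negative (counts-like) signal"
        )
    store = build_knots(signal, config)
    ctx = store._ctx
    rng = np.random.default_rng(config.seed)
    n0 = signal.n_runs
    cap = config.pass_cap if config.pass_cap is not None else default_pass_cap(n0)
    do_adjust = config.order >= 1 and config.method != "ttest"
    active = np.arange(1, n0)
    passes = 0
    converged = True
    while len(active) and passes < cap:
        passes += 1
        store.modified.clear()
        order_idx = rng.permutation(len(active))
        for t in active[order_idx]:
            t = int(t)
            if not store.is_interior(t):
                continue
            if try_remove(store, t, signal, config):
                continue
            if do_adjust and try_continuity_adjust(store, t, signal, config):
                continue
            try_move(store, t, signal, config)
        if not store.modified:
            break
        nxt: set[int] = set()
        for m in store.modified:
            if m not in store.nodes:
                continue
            nxt.add(m)
            prev_i, next_i = store.neighbors(m)
            nxt.add(prev_i)
            nxt.add(next_i)
        active = np.array(
            sorted(t for t in nxt if store.is_interior(t)), dtype=np.int64
        )
        if len(active) and passes >= cap:
            converged = False  # pass cap exhausted with work remaining
    model = store.to_model()
    return SmoothResult(
        model=model,
        passes_used=passes,
        knots_removed=n0 - model.n_segments,
        seed=config.seed,
        converged=converged,
    )


def smooth_multi(signal: RleSignal, config: MethodConfig, k: int) -> list[SmoothResult]:
    """``k`` independent smoothing runs with seeds ``seed, seed+1, ...``;
    deterministic given ``(config.seed, k)``."""
    if k < 1:
        raise ValueError("repeat count must be >= 1")
    return [smooth(signal, replace(config, seed=config.seed + t)) for t in range(k)]
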