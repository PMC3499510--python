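"""Downstream analyses of PPC models.

Compression metrics (inverse compression ratio, mean squared error against
the original track), fixed-window baselines, composite segmentation by
medians over repeated stochastic runs, copy-number classification of
windows/segments against a known truth, RNA-seq boundary diagnostics
(discontinuity positions, inward boundary slopes, sign-bias binomial test),
and mutual information between CG content and coverage depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .poly_core import PpcModel, PpcSegment, local_error, poly_area
from .rle_io import RleSignal, compact
from .simulate import ExonTruth

__all__ = [
    "ClassificationCounts",
    "SlopeRecord",
    "icr",
    "mse",
    "fixed_window_average",
    "composite_median",
    "probewise_sse",
    "label_windows",
    "classification_rates",
    "detect_discontinuities",
    "match_boundaries",
    "boundary_slopes",
    "steep_filter",
    "binomial_sign_test",
    "cg_mi",
    "model_windows",
    "median_segment_length",
]


def icr(signal: RleSignal, model: PpcModel) -> float:
    """Inverse compression ratio: storage cost of the run-length encoding
    divided by that of the PPC model.

    Costs count serialized fields: 2 per run (length, value) and
    ``2 + order`` per segment (length plus ``order + 1`` coefficients), so
    the identity model has ICR exactly 1.  Values below 1 are possible: a
    low-coverage track whose RLE is already efficient may not compress.
    """
    cost_rle = 2 * signal.n_runs
    cost_ppc = sum(2 + seg.order for seg in model.segments)
    return cost_rle / cost_ppc


def mse(model: PpcModel, signal: RleSignal) -> float:
    """Mean squared error between model and track over the whole extent."""
    return local_error(model, signal, signal.origin, signal.end) / signal.length


def fixed_window_average(signal: RleSignal, w: int) -> RleSignal:
    """Average the track in non-overlapping windows of fixed width ``w``
    (last window truncated); each window takes its integral mean, so total
    area is preserved exactly."""
    if w < 1:
        raise ValueError("window width must be >= 1")
    L = signal.length
    edges = np.arange(signal.origin, signal.origin + L + 1, w, dtype=np.int64)
    if edges[-1] != signal.origin + L:
        edges = np.append(edges, signal.origin + L)
    areas = _area_prefix(signal, edges.astype(np.float64))
    widths = np.diff(edges)
    means = np.diff(areas) / widths
    return RleSignal(signal.chrom, signal.origin, widths, means)


def _area_prefix(signal: RleSignal, positions: np.ndarray) -> np.ndarray:
    """Area under the staircase from the origin to each position."""
    bounds = signal.run_bounds
    clv = np.concatenate(([0.0], np.cumsum(signal.lengths * signal.values)))
    idx = np.clip(np.searchsorted(bounds, positions, side="right") - 1, 0, signal.n_runs - 1)
    return clv[idx] + signal.values[idx] * (positions - bounds[idx])


def composite_median(models: Sequence[PpcModel]) -> PpcModel:
    """Median composite of repeated stochastic segmentations.

    At every position the composite takes the median of the models' values;
    it is re-encoded as order-0 segments with breakpoints at the union of all
    input breakpoints (for order-0 inputs this is exact; higher-order pieces
    contribute their integral mean per union interval) and then compacted.
    """
    if not models:
        raise ValueError("need at least one model")
    start, end = models[0].start, models[0].end
    for m in models:
        if (m.start, m.end) != (start, end):
            raise ValueError("models must share the same extent")
    edges = sorted({start, end}.union(*({int(b) for b in m.breakpoints} for m in models)))
    edges = np.array(edges, dtype=np.int64)
    values = np.empty((len(models), len(edges) - 1))
    for r, m in enumerate(models):
        k = 0
        for seg in m.segments:
            while k < len(edges) - 1 and edges[k + 1] <= seg.end:
                a, b = int(edges[k]), int(edges[k + 1])
                if a >= seg.start:
                    values[r, k] = poly_area(seg, a, b) / (b - a)
                    k += 1
                else:  # pragma: no cover - edges align with breakpoints
                    break
    med = np.median(values, axis=0)
    sig = compact(RleSignal(models[0].chrom, int(start), np.diff(edges), med))
    segs = [
        PpcSegment(int(s), int(l), 0, (float(v),))
        for s, l, v in zip(sig.run_bounds[:-1], sig.lengths, sig.values)
    ]
    return PpcModel(models[0].chrom, segs)


def probewise_sse(model: PpcModel, truth_levels: np.ndarray) -> float:
    """Sum over probes of squared distance between the model and the true
    (noise-free) level; probes are the unit cells of the model extent and the
    model contributes its value at the cell midpoint."""
    truth_levels = np.asarray(truth_levels, dtype=np.float64)
    n = len(truth_levels)
    if model.end - model.start != n:
        raise ValueError("truth length must equal model extent")
    fitted = np.empty(n)
    for seg in model.segments:
        x = np.arange(seg.start, seg.end) + 0.5
        fitted[seg.start - model.start : seg.end - model.start] = seg(x)
    return float(np.sum((fitted - truth_levels) ** 2))


def model_windows(windows) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a PPC model, RLE signal, or explicit interval list into
    (starts, ends) arrays."""
    if isinstance(windows, PpcModel):
        starts = np.array([s.start for s in windows.segments], dtype=np.int64)
        ends = np.array([s.end for s in windows.segments], dtype=np.int64)
    elif isinstance(windows, RleSignal):
        starts = windows.run_bounds[:-1].copy()
        ends = windows.run_bounds[1:].copy()
    else:
        arr = np.asarray(windows, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
    return starts, ends


def _overlap_with_regions(starts, ends, regions) -> np.ndarray:
    overlap = np.zeros(len(starts), dtype=np.int64)
    for rs, re in regions:
        overlap += np.clip(np.minimum(ends, re) - np.maximum(starts, rs), 0, None)
    return overlap


def label_windows(windows, truth_regions: Sequence[tuple[int, int]]) -> np.ndarray:
    """Label each window/segment copy-number aberrant iff more than half of
    its width (strict) overlaps a truth aberrant region; blind to how the
    windows were produced."""
    starts, ends = model_windows(windows)
    overlap = _overlap_with_regions(starts, ends, truth_regions)
    return overlap * 2 > (ends - starts)


@dataclass(frozen=True)
class ClassificationCounts:
    """Per-base confusion counts of a perfect caller given a segmentation."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / max(self.tp + self.fn, 1)

    @property
    def tnr(self) -> float:
        return self.tn / max(self.tn + self.fp, 1)


def classification_rates(
    windows, labels: np.ndarray, truth_regions: Sequence[tuple[int, int]]
) -> ClassificationCounts:
    """Base-level confusion counts treating each window's label as the call
    for all of its bases; counts always sum to the analyzed length."""
    starts, ends = model_windows(windows)
    labels = np.asarray(labels, dtype=bool)
    widths = ends - starts
    overlap = _overlap_with_regions(starts, ends, truth_regions)
    tp = int(np.sum(overlap[labels]))
    fn = int(np.sum(overlap[~labels]))
    fp = int(np.sum((widths - overlap)[labels]))
    tn = int(np.sum((widths - overlap)[~labels]))
    return ClassificationCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def detect_discontinuities(model: PpcModel, tolerance_jump: float = 1e-9) -> np.ndarray:
    """Interior segment boundaries where the one-sided polynomial limits
    differ by more than ``tolerance_jump``."""
    positions = []
    for left, right in zip(model.segments[:-1], model.segments[1:]):
        left_limit = _poly_at(left.coefficients, left.length)
        right_limit = right.coefficients[0]
        if abs(left_limit - right_limit) > tolerance_jump:
            positions.append(left.end)
    return np.array(positions, dtype=np.int64)


def match_boundaries(
    detected: np.ndarray, annotated: np.ndarray, slack: int = 3
) -> np.ndarray:
    """For each annotated boundary, whether a detected discontinuity lies
    within ``slack`` bases of it."""
    detected = np.sort(np.asarray(detected, dtype=np.int64))
    annotated = np.asarray(annotated, dtype=np.int64)
    if len(detected) == 0:
        return np.zeros(len(annotated), dtype=bool)
    pos = np.searchsorted(detected, annotated)
    left = detected[np.clip(pos - 1, 0, len(detected) - 1)]
    right = detected[np.clip(pos, 0, len(detected) - 1)]
    dist = np.minimum(np.abs(annotated - left), np.abs(annotated - right))
    return dist <= slack


@dataclass(frozen=True)
class SlopeRecord:
    """Innermost model segment touching one exon boundary, with the slope
    oriented in the inward direction (into the exon)."""

    exon_id: int
    side: str  # "left" | "right"
    direction: str  # "up" | "down" | "flat" (inward orientation)
    length: int
    slope: float  # inward-oriented slope, signal units per nt

    @property
    def signed_length(self) -> int:
        """Positive for upward, negative for downward inward slopes."""
        return self.length if self.direction == "up" else -self.length


FLAT_SLOPE = 1e-9


def boundary_slopes(
    model: PpcModel,
    exons: ExonTruth | Sequence[tuple[int, int]],
    min_width: int = 100,
) -> list[SlopeRecord]:
    """Inward slope of the innermost model segment at each boundary of each
    exon wider than ``min_width``.

    The innermost segment is the one containing the first base inside the
    exon on that side; its polynomial slope at that base is reported,
    oriented inward (so a coverage ramp rising into the exon is "up" on
    either side).
    """
    if isinstance(exons, ExonTruth):
        intervals = [(ex.start, ex.end) for ex in exons.exons]
    else:
        intervals = [(int(s), int(e)) for s, e in exons]
    records = []
    for exon_id, (s, e) in enumerate(intervals):
        if e - s <= min_width:
            continue
        for side, inner_base, orient in (("left", s, 1.0), ("right", e - 1, -1.0)):
            if not (model.start <= inner_base < model.end):
                continue
            seg = model.segment_at(inner_base)
            raw = _poly_slope(seg.coefficients, inner_base - seg.start)
            slope = orient * raw
            if abs(slope) < FLAT_SLOPE:
                direction = "flat"
            else:
                direction = "up" if slope > 0 else "down"
            records.append(
                SlopeRecord(exon_id, side, direction, seg.length, float(slope))
            )
    return records


def steep_filter(
    records: Sequence[SlopeRecord], min_slope: float = 0.7, min_length: int = 25
) -> list[SlopeRecord]:
    """Keep boundary segments that are steep (|slope| above ``min_slope``)
    and longer than ``min_length`` nt."""
    return [r for r in records if abs(r.slope) > min_slope and r.length > min_length]


def binomial_sign_test(n_up: int, n_down: int) -> float:
    """Exact two-sided binomial test of up- vs down-sloping counts against
    equal proportions; symmetric in its arguments."""
    if n_up + n_down < 1:
        raise ValueError("need at least one observation")
    return float(binomtest(n_up, n_up + n_down, 0.5, alternative="two-sided").pvalue)


def cg_mi(
    windows,
    sequence: np.ndarray,
    coverage: RleSignal,
    bins: int = 16,
    units: str = "nats",
) -> float:
    """Mutual information between per-window CG fraction and mean coverage.

    Both variables are discretized by equal-frequency binning into ``bins``
    bins (reduced with a warning when there are fewer windows than bins);
    the MI of the resulting joint histogram is returned in nats or bits.
    """
    starts, ends = model_windows(windows)
    seq = np.asarray(sequence)
    if seq.dtype.kind in "US":
        seq = np.frombuffer("".join(seq.tolist()).encode() if seq.ndim else str(seq).encode(), dtype=np.uint8)
    is_cg = (seq == ord("C")) | (seq == ord("G"))
    cg_prefix = np.concatenate(([0], np.cumsum(is_cg)))
    off = coverage.origin
    cg = (cg_prefix[ends - off] - cg_prefix[starts - off]) / (ends - starts)
    areas = _area_prefix(coverage, np.asarray(ends, dtype=np.float64)) - _area_prefix(
        coverage, np.asarray(starts, dtype=np.float64)
    )
    depth = areas / (ends - starts)
    n = len(starts)
    if n < bins:
        warnings.warn(f"only {n} windows; reducing bins from {bins} to {max(n, 1)}")
        bins = max(n, 1)
    bx = _equal_freq_bins(cg, bins)
    by = _equal_freq_bins(depth, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / (px * py))
    mi = float(np.nansum(term))
    if units == "bits":
        mi /= np.log(2.0)
    elif units != "nats":
        raise ValueError("units must be 'nats' or 'bits'")
    return max(mi, 0.0)


def median_segment_length(model: PpcModel) -> float:
    return float(np.median([seg.length for seg in model.segments]))


def _equal_freq_bins(x: np.ndarray, bins: int) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(len(x))
    return np.minimum((ranks * bins) // len(x), bins - 1)


def _poly_at(coefs, u: float) -> float:
    out = 0.0
    for c in reversed(coefs):
        out = out * u + c
    return out


def _poly_slope(coefs, u: float) -> float:
    if len(coefs) < 2:
        return 0.0
    s = coefs[1]
    if len(coefs) > 2:
        s += 2.0 * coefs[2] * u
    return s
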