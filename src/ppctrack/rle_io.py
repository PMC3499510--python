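"""Reading, writing and validation of run-length-encoded genomic tracks.

A genomic track (coverage depth, array log-ratio, mappability score, ...) is
represented as an :class:`RleSignal`: an ordered list of runs ``(length,
value)`` tiling a half-open coordinate interval on one chromosome.  All
internal coordinates are 0-based, half-open; the 1-based wiggle dialects are
converted on ingress/egress.  Strand is ignored: tracks are strandless
functions of position.

Supported on-disk formats:

* bedGraph (``chrom  start  end  value``), gaps filled with zero-valued runs;
* wiggle, both ``fixedStep`` and ``variableStep`` with ``span``;
* a plain headerless two-column ``length<TAB>value`` RLE table;
* the piecewise-polynomial-curve (PPC) model table written by
  :func:`write_ppc` (one segment per row with its polynomial coefficients).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .poly_core import PpcModel, PpcSegment

__all__ = [
    "RleSignal",
    "FormatError",
    "compact",
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
    "read_rle_table",
    "write_rle_table",
    "read_ppc",
    "write_ppc",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class RleSignal:
    """A run-length-encoded one-dimensional genomic track.

    Runs tile ``[origin, origin + sum(lengths))`` with no gaps or overlaps.
    Adjacent runs with equal values are permitted (the encoding need not be
    canonical); use :func:`compact` to merge them.
    """

    chrom: str
    origin: int
    lengths: np.ndarray
    values: np.ndarray
    _bounds: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.lengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("lengths and values must be one-dimensional")
        if len(self.lengths) != len(self.values):
            raise ValueError("lengths and values must have equal size")
        if len(self.lengths) < 1:
            raise ValueError("signal must contain at least one run")
        if np.any(self.lengths < 1):
            raise ValueError("every run length must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("run values must be finite")

    @property
    def n_runs(self) -> int:
        return len(self.lengths)

    @property
    def length(self) -> int:
        """Total extent L = sum of run lengths."""
        return int(self.lengths.sum())

    @property
    def end(self) -> int:
        return self.origin + self.length

    @property
    def run_bounds(self) -> np.ndarray:
        """Absolute run boundary positions, shape ``(n_runs + 1,)``."""
        if self._bounds is None or len(self._bounds) != self.n_runs + 1:
            b = np.empty(self.n_runs + 1, dtype=np.int64)
            b[0] = self.origin
            np.cumsum(self.lengths, out=b[1:])
            b[1:] += self.origin
            self._bounds = b
        return self._bounds

    @property
    def area(self) -> float:
        """Total area sum(length * value)."""
        return float(np.dot(self.lengths, self.values))

    def run_slice(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Lengths and values of runs ``i:j``."""
        return self.lengths[i:j], self.values[i:j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RleSignal):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.origin == other.origin
            and np.array_equal(self.lengths, other.lengths)
            and np.array_equal(self.values, other.values)
        )


def compact(signal: RleSignal) -> RleSignal:
    """Merge adjacent equal-valued runs; idempotent.

    Preserves total extent and total area exactly (merging sums integer
    lengths of runs sharing a bit-identical value).
    """
    v = signal.values
    keep = np.empty(len(v), dtype=bool)
    keep[0] = True
    np.not_equal(v[1:], v[:-1], out=keep[1:])
    if keep.all():
        return RleSignal(signal.chrom, signal.origin, signal.lengths.copy(), v.copy())
    idx = np.flatnonzero(keep)
    lengths = np.add.reduceat(signal.lengths, idx)
    return RleSignal(signal.chrom, signal.origin, lengths, v[idx])


def _from_intervals(chrom: str, starts, ends, values) -> RleSignal:
    """Build a contiguous signal from sorted, non-overlapping intervals.

    Gaps between intervals are filled with zero-valued runs (coverage
    semantics: no reported interval means depth zero).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if np.any(ends <= starts):
        raise FormatError(f"{chrom}: empty or inverted interval")
    if np.any(starts[1:] < ends[:-1]):
        k = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
        raise FormatError(
            f"{chrom}: overlapping intervals around position {int(starts[k + 1])}"
        )
    out_l: list[int] = []
    out_v: list[float] = []
    pos = int(starts[0])
    origin = pos
    for s, e, v in zip(starts, ends, values):
        if s > pos:
            out_l.append(int(s - pos))
            out_v.append(0.0)
        out_l.append(int(e - s))
        out_v.append(float(v))
        pos = int(e)
    return compact(RleSignal(chrom, origin, np.array(out_l), np.array(out_v)))


def read_bedgraph(path) -> dict[str, RleSignal]:
    """Read a bedGraph file into one :class:`RleSignal` per chromosome.

    Intervals are 0-based half-open.  Gaps are filled with zero runs and
    adjacent equal-valued intervals merged.  Overlapping intervals raise
    :class:`FormatError`.
    """
    per_chrom: dict[str, tuple[list, list, list]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
            chrom = parts[0]
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None
            st, en, va = per_chrom.setdefault(chrom, ([], [], []))
            st.append(s)
            en.append(e)
            va.append(v)
    if not per_chrom:
        raise FormatError("no data lines")
    return {c: _from_intervals(c, s, e, v) for c, (s, e, v) in per_chrom.items()}


def write_bedgraph(signal: RleSignal, path, header: str | None = None) -> None:
    """Write a signal as bedGraph (inverse of :func:`read_bedgraph` up to
    compaction; zero-valued runs are written explicitly so the extent is
    preserved)."""
    with _open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        b = signal.run_bounds
        for i in range(signal.n_runs):
            fh.write(f"{signal.chrom}\t{b[i]}\t{b[i + 1]}\t{float(signal.values[i])!r}\n")


def read_wiggle(path) -> dict[str, RleSignal]:
    """Read a wiggle file (``fixedStep``/``variableStep``, honoring ``span``).

    Wiggle coordinates are 1-based; they are shifted to the internal 0-based
    half-open convention.
    """
    per_chrom: dict[str, tuple[list, list, list]] = {}
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("var", chrom, span)
    n_data = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                attrs = dict(tok.split("=", 1) for tok in line.split()[1:])
                chrom = attrs.get("chrom", "chr")
                span = int(attrs.get("span", 1))
                if line.startswith("fixedStep"):
                    start0 = int(attrs["start"]) - 1
                    step = int(attrs.get("step", 1))
                    if span > step:
                        raise FormatError(f"line {lineno}: span > step")
                    mode = ["fixed", chrom, start0, step, span]
                else:
                    mode = ["var", chrom, span]
                continue
            if mode is None:
                raise FormatError(f"line {lineno}: data before declaration line")
            parts = line.split()
            try:
                if mode[0] == "fixed":
                    if len(parts) != 1:
                        raise FormatError(
                            f"line {lineno}: fixedStep block expects one value per line"
                        )
                    value = float(parts[0])
                    _, chrom, start0, step, span = mode
                    s, e = start0, start0 + span
                    mode[2] = start0 + step
                else:
                    if len(parts) != 2:
                        raise FormatError(
                            f"line {lineno}: variableStep block expects two columns"
                        )
                    _, chrom, span = mode
                    s = int(parts[0]) - 1
                    e = s + span
                    value = float(parts[1])
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None
            st, en, va = per_chrom.setdefault(chrom, ([], [], []))
            st.append(s)
            en.append(e)
            va.append(value)
            n_data += 1
    if n_data == 0:
        raise FormatError("no runs")
    return {c: _from_intervals(c, s, e, v) for c, (s, e, v) in per_chrom.items()}


def read_rle_table(path, chrom: str = "chr", origin: int = 0) -> RleSignal:
    """Read a plain headerless two-column ``length<TAB>value`` RLE table."""
    lengths: list[int] = []
    values: list[float] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            try:
                lengths.append(int(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field ({exc})") from None
    if not lengths:
        raise FormatError("no runs")
    return RleSignal(chrom, origin, np.array(lengths), np.array(values))


def write_rle_table(signal: RleSignal, path, header: str | None = None) -> None:
    with _open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for l, v in zip(signal.lengths, signal.values):
            fh.write(f"{int(l)}\t{float(v)!r}\n")


_PPC_HEADER = "#chrom\tstart\tlength\torder\tcoefficients\tcontinuous_left"


def write_ppc(model: PpcModel, path, header: str | None = None) -> None:
    """Write a PPC model as a TSV table of segments.

    One row per segment: chromosome, 0-based start, length, polynomial order,
    ``order + 1`` comma-separated coefficients (value at position x is
    ``sum_j c_j (x - start)^j``), and the left-continuity flag.  Floats use 10
    significant digits, so ``read_ppc(write_ppc(m))`` reproduces ``m`` at that
    precision.
    """
    model.validate()
    with _open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write(_PPC_HEADER + "\n")
        for seg in model.segments:
            coefs = ",".join(f"{c:.10g}" for c in seg.coefficients)
            fh.write(
                f"{model.chrom}\t{seg.start}\t{seg.length}\t{seg.order}\t"
                f"{coefs}\t{int(seg.continuous_left)}\n"
            )


def read_ppc(path) -> dict[str, PpcModel]:
    """Read a PPC table (inverse of :func:`write_ppc`); one model per
    chromosome.  Gap or overlap in the segment tiling raises
    :class:`FormatError`."""
    per_chrom: dict[str, list[PpcSegment]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"line {lineno}: expected 6 columns")
            chrom = parts[0]
            try:
                start, length, order = int(parts[1]), int(parts[2]), int(parts[3])
                coefs = tuple(float(c) for c in parts[4].split(","))
                cont = bool(int(parts[5]))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad field ({exc})") from None
            if len(coefs) != order + 1:
                raise FormatError(
                    f"line {lineno}: order {order} requires {order + 1} coefficients"
                )
            per_chrom.setdefault(chrom, []).append(
                PpcSegment(start, length, order, coefs, cont)
            )
    if not per_chrom:
        raise FormatError("no segments")
    out = {}
    for chrom, segs in per_chrom.items():
        segs.sort(key=lambda s: s.start)
        model = PpcModel(chrom, segs)
        try:
            model.validate()
        except ValueError as exc:
            raise FormatError(f"{chrom}: {exc}") from None
        out[chrom] = model
    return out


def _open(path, mode: str = "r"):
    if isinstance(path, io.IOBase):
        return _NoCloseWrapper(path)
    return open(path, mode)


class _NoCloseWrapper:
    """Context manager that leaves caller-owned file handles open."""

    def __init__(self, fh):
        self._fh = fh

    def __enter__(self):
        return self._fh

    def __exit__(self, *exc):
        return False
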