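"""Synthetic genomic tracks with known ground truth.

These generators emulate the statistical structure of the signals the PPC
smoother is designed for, so every downstream analysis can run without
external data:

* uniform random placement of fixed-length reads on a chromosome (coverage
  compression experiments);
* Gaussian array-CGH probe signals with planted constant-shift copy-number
  events;
* read-depth coverage over a diploid genome carrying a deleted or duplicated
  region (reads are placed on the aberrant genome and projected back to
  reference coordinates, so deletions lose coverage and duplications gain
  it);
* RNA-seq exon coverage: Poisson noise around per-exon expression plateaus,
  optional linear ramps inside boundaries, near-zero intronic background and
  a sharp discontinuity at every annotated boundary.

All generators are deterministic given their seed, and read-placement
generators conserve total area exactly (reads x read length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rle_io import RleSignal

__all__ = [
    "AcghTruth",
    "CnGenomeTruth",
    "ExonSpec",
    "ExonTruth",
    "rle_from_array",
    "simulate_read_coverage",
    "simulate_acgh",
    "make_cn_truth",
    "simulate_cn_coverage",
    "make_exon_truth",
    "simulate_rnaseq_exons",
    "random_sequence",
]

#: Read length used throughout the sequencing simulations (nt).
DEFAULT_READ_LEN = 75


def rle_from_array(arr: np.ndarray, chrom: str = "chr", origin: int = 0) -> RleSignal:
    """Run-length encode a dense per-base (or per-probe) array."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("expected a non-empty 1-D array")
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(arr)]))
    return RleSignal(chrom, origin, ends - starts, arr[starts])


def simulate_read_coverage(
    chrom_len: int,
    n_reads: int | None = None,
    read_len: int = DEFAULT_READ_LEN,
    rate: float | None = None,
    seed: int = 0,
    chrom: str = "chr",
) -> RleSignal:
    """Coverage from single reads placed uniformly at random.

    Read starts are uniform on ``[0, chrom_len - read_len]`` so every read
    lies fully on the chromosome and total area equals
    ``n_reads * read_len`` exactly.  The read density can be given either as
    an absolute count ``n_reads`` or as a rate in reads per nucleotide
    (``n_reads = round(rate * chrom_len)``).
    """
    if read_len > chrom_len:
        raise ValueError("read length exceeds chromosome length")
    if n_reads is None:
        if rate is None:
            raise ValueError("provide n_reads or rate")
        n_reads = int(round(rate * chrom_len))
    rng = np.random.default_rng(seed)
    delta = np.zeros(chrom_len + 1, dtype=np.int64)
    if n_reads > 0:
        starts = rng.integers(0, chrom_len - read_len + 1, size=n_reads)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + read_len, -1)
    coverage = np.cumsum(delta[:-1])
    return rle_from_array(coverage, chrom=chrom)


@dataclass(frozen=True)
class AcghTruth:
    """Planted copy-number events in a simulated aCGH signal: ``events`` are
    ``(start_probe, length, amplitude)`` on a zero baseline."""

    n_probes: int
    events: tuple[tuple[int, int, float], ...]

    @property
    def breakpoints(self) -> np.ndarray:
        bps = sorted({s for s, l, _ in self.events} | {s + l for s, l, _ in self.events})
        return np.array([b for b in bps if 0 < b < self.n_probes], dtype=np.int64)

    def level_at(self, probes: np.ndarray) -> np.ndarray:
        """True (noise-free) signal level at each probe index."""
        level = np.zeros(len(probes))
        for s, l, a in self.events:
            level += a * ((probes >= s) & (probes < s + l))
        return level


def simulate_acgh(
    n_probes: int,
    n_events: int,
    event_len_range: tuple[int, int] = (20, 150),
    seed: int = 0,
    min_amplitude: float = 0.0,
    chrom: str = "chr",
) -> tuple[RleSignal, AcghTruth]:
    """Array-CGH probe signal: N(0, 1) noise plus planted constant shifts.

    Each of the 1..10 events adds an amplitude drawn from N(0, 1)
    (optionally re-drawn until ``|a| >= min_amplitude``) over a window whose
    length is uniform in ``event_len_range``.  Events are placed without
    overlap (rejection sampling) so the truth breakpoints are unambiguous.
    Probes are returned as unit-length runs.
    """
    if not 0 <= n_events <= 10:
        raise ValueError("between 0 and 10 events supported")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_probes)
    events: list[tuple[int, int, float]] = []
    occupied = np.zeros(n_probes, dtype=bool)
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("cannot place non-overlapping events; signal too short")
        length = int(rng.integers(event_len_range[0], event_len_range[1] + 1))
        if length >= n_probes:
            continue
        start = int(rng.integers(0, n_probes - length + 1))
        if occupied[start : start + length].any():
            continue
        amp = float(rng.standard_normal())
        while abs(amp) < min_amplitude:
            amp = float(rng.standard_normal())
        occupied[start : start + length] = True
        events.append((start, length, amp))
        noise[start : start + length] += amp
    truth = AcghTruth(n_probes, tuple(sorted(events)))
    signal = RleSignal(chrom, 0, np.ones(n_probes, dtype=np.int64), noise)
    return signal, truth


@dataclass(frozen=True)
class CnGenomeTruth:
    """Copy-number state of one simulated chromosome: diploid baseline 2 with
    ``regions`` of ``(start, length, copies)`` where copies counts both
    homologues (0 = homozygous deletion ... 4 = duplication of both)."""

    chrom: str
    chrom_len: int
    regions: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        for s, l, c in self.regions:
            if not (0 <= s and s + l <= self.chrom_len):
                raise ValueError("region outside chromosome")
            if c not in (0, 1, 2, 3, 4):
                raise ValueError("copy state must be in 0..4")

    @property
    def aberrant_regions(self) -> list[tuple[int, int]]:
        return [(s, s + l) for s, l, c in self.regions if c != 2]

    def copy_intervals(self) -> list[tuple[int, int, int]]:
        """(start, end, copies) intervals tiling the chromosome."""
        out = []
        pos = 0
        for s, l, c in sorted(self.regions):
            if s > pos:
                out.append((pos, s, 2))
            out.append((s, s + l, c))
            pos = s + l
        if pos < self.chrom_len:
            out.append((pos, self.chrom_len, 2))
        return out


def make_cn_truth(
    chrom_len: int,
    seed: int = 0,
    region_len: int = 2000,
    chrom: str = "chr",
    states: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> CnGenomeTruth:
    """One ~2 kb region per chromosome, deleted, duplicated or left in place
    in either one or both copies (uniform over ``states``)."""
    rng = np.random.default_rng(seed)
    length = min(region_len, chrom_len)
    start = int(rng.integers(0, chrom_len - length + 1))
    copies = int(rng.choice(states))
    return CnGenomeTruth(chrom, chrom_len, ((start, length, copies),))


def simulate_cn_coverage(
    truth: CnGenomeTruth,
    read_len: int = DEFAULT_READ_LEN,
    depth: float = 30.0,
    seed: int = 0,
) -> RleSignal:
    """Read-depth coverage of the reference given an aberrant genome.

    Reads are placed uniformly on the concatenated aberrant genome (each
    region appears once per retained copy) and projected base-by-base back to
    reference coordinates.  Expected reference coverage is
    ``depth * copies / 2``: deleted regions receive no reads, duplications
    proportionally more; reads spanning region junctions project across them.
    """
    intervals = truth.copy_intervals()
    pieces = []
    for s, e, c in intervals:
        for _ in range(c):
            pieces.append(np.arange(s, e, dtype=np.int64))
    if not pieces:
        raise ValueError("aberrant genome is empty")
    ab2ref = np.concatenate(pieces)
    La = len(ab2ref)
    if read_len > La:
        raise ValueError("read length exceeds aberrant genome length")
    n_reads = int(round(depth * La / (2.0 * read_len)))
    rng = np.random.default_rng(seed)
    delta = np.zeros(La + 1, dtype=np.int64)
    if n_reads > 0:
        starts = rng.integers(0, La - read_len + 1, size=n_reads)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + read_len, -1)
    cov_ab = np.cumsum(delta[:-1]).astype(np.float64)
    cov_ref = np.bincount(ab2ref, weights=cov_ab, minlength=truth.chrom_len)
    return rle_from_array(cov_ref, chrom=truth.chrom)


@dataclass(frozen=True)
class ExonSpec:
    """One exon: interval, expression plateau and optional inward linear
    ramps.  A positive ``*_slope`` rises in the inward direction; the ramp
    meets the plateau at its inner end, so the coverage at the boundary is
    ``level - slope * ramp_len`` (clipped at 0)."""

    start: int
    end: int
    level: float
    left_ramp_len: int = 0
    left_ramp_slope: float = 0.0
    right_ramp_len: int = 0
    right_ramp_slope: float = 0.0

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonTruth:
    """Non-overlapping exons on one chromosome plus the intronic background
    rate."""

    chrom: str
    length: int
    exons: tuple[ExonSpec, ...]
    background: float = 0.2

    def __post_init__(self) -> None:
        pos = 0
        for ex in self.exons:
            if ex.start < pos or ex.end > self.length:
                raise ValueError("exons must be non-overlapping and inside the extent")
            pos = ex.end

    @property
    def boundaries(self) -> np.ndarray:
        out = []
        for ex in self.exons:
            out.extend([ex.start, ex.end])
        return np.array(out, dtype=np.int64)

    def expected(self) -> np.ndarray:
        """Noise-free per-base expected coverage."""
        mu = np.full(self.length, self.background)
        for ex in self.exons:
            mu[ex.start : ex.end] = ex.level
            if ex.left_ramp_len > 0:
                n = min(ex.left_ramp_len, ex.width)
                ramp = ex.level - ex.left_ramp_slope * (n - np.arange(n))
                mu[ex.start : ex.start + n] = np.maximum(ramp, 0.0)
            if ex.right_ramp_len > 0:
                n = min(ex.right_ramp_len, ex.width)
                ramp = ex.level - ex.right_ramp_slope * (n - np.arange(n))
                mu[ex.end - n : ex.end] = np.maximum(ramp[::-1], 0.0)
        return mu


def make_exon_truth(
    n_exons: int,
    seed: int = 0,
    exon_len_range: tuple[int, int] = (120, 300),
    intron_len_range: tuple[int, int] = (200, 500),
    level_range: tuple[float, float] = (50.0, 150.0),
    ramp_prob: float = 0.0,
    ramp_len_range: tuple[int, int] = (26, 40),
    ramp_slope_range: tuple[float, float] = (0.8, 1.5),
    background: float = 0.2,
    chrom: str = "chr",
) -> ExonTruth:
    """Random exon layout: alternating introns and exons with uniform widths,
    expression levels, and (with probability ``ramp_prob`` per side) an
    inward ramp of uniform length and slope magnitude (sign split 50/50)."""
    rng = np.random.default_rng(seed)
    exons = []
    pos = int(rng.integers(*intron_len_range))
    for _ in range(n_exons):
        width = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        level = float(rng.uniform(*level_range))
        kw = {}
        for side in ("left", "right"):
            if rng.random() < ramp_prob:
                kw[f"{side}_ramp_len"] = int(
                    rng.integers(ramp_len_range[0], ramp_len_range[1] + 1)
                )
                mag = float(rng.uniform(*ramp_slope_range))
                kw[f"{side}_ramp_slope"] = mag if rng.random() < 0.5 else -mag
        exons.append(ExonSpec(pos, pos + width, level, **kw))
        pos += width + int(rng.integers(*intron_len_range))
    return ExonTruth(chrom, pos, tuple(exons), background=background)


def simulate_rnaseq_exons(truth: ExonTruth, seed: int = 0) -> RleSignal:
    """Per-base Poisson coverage around the expected exon profile."""
    rng = np.random.default_rng(seed)
    coverage = rng.poisson(truth.expected()).astype(np.float64)
    return rle_from_array(coverage, chrom=truth.chrom)


def random_sequence(
    length: int, seed: int = 0, cg_content: float | np.ndarray = 0.5
) -> np.ndarray:
    """I.i.d. random DNA sequence as a byte array (``A C G T``).

    ``cg_content`` may be a scalar or a per-base array, allowing slowly
    varying CG-rate modulation along the chromosome.
    """
    rng = np.random.default_rng(seed)
    cg = np.broadcast_to(np.asarray(cg_content, dtype=float), (length,))
    is_cg = rng.random(length) < cg
    half = rng.random(length) < 0.5
    seq = np.where(is_cg, np.where(half, ord("C"), ord("G")), np.where(half, ord("A"), ord("T")))
    return seq.astype(np.uint8)
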