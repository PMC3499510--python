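# Methods

## Model

A track is a function on a half-open genomic interval, stored run-length
encoded: runs `(length, value)` tiling `[origin, origin + L)` with positive
integer lengths and finite values. A piecewise polynomial curve (PPC) is an
ordered, gap-free list of segments; segment `s` carries `order + 1`
coefficients and evaluates to `Σ_j c_j (x − start_s)^j` on
`[start_s, start_s + length_s)`. Orders are capped at 2; continuity between
neighboring segments is recorded per boundary but never imposed globally —
the model is free to be discontinuous wherever the data demand it.

All fitting is *functional*: the loss is the integral of the squared
difference between the polynomial and the RLE staircase, not a pointwise sum
over bases. Each run contributes its moment integrals in closed form, so a
fit over a window costs O(runs in the window) regardless of base-pair
length. This is the property that makes genome-scale smoothing feasible: a
signal of length 10^8 with regional correlation may encode into far fewer
runs, and all costs scale with the run count.

## The smoothing procedure

Starting from one order-0 segment per run, the algorithm repeatedly visits
knots (segment boundaries) in a fresh uniform-random order per pass and
tries, in this order, stopping at the first success:

1. **Removal**: fit one polynomial of the configured order over the union of
   the two adjacent segments; delete the knot if the acceptance criterion
   holds on every original run under the union.
2. **Continuity adjustment** (order ≥ 1): refit both segments constrained to
   a common value `y` at the knot. For a single endpoint constraint the
   constrained optimum has a closed form — the extra error is
   `(y − ŷ)²·K/w` with `ŷ` the unconstrained fit's endpoint value, `w` the
   window width and `K` a constant of the order (4 for linear, 9 for
   quadratic) — so the jointly optimal `y` is the width-weighted average of
   the two endpoint values. Accepted only if the criterion holds on both
   spans and the combined error does not increase (tolerance 1e-10).
3. **Relocation**: evaluate every original run boundary strictly inside the
   two adjacent segments as an alternative knot position, refitting both
   sides; adopt the error-minimizing candidate if it strictly decreases the
   combined error (ties within 1e-12 keep the current position) and passes
   the criterion.

Passes after the first visit only knots modified in the previous pass or
adjacent to one; the run ends when a pass changes nothing or all interior
knots are gone. A safety cap of `100 + 20·log₂(n₀)` passes (n₀ = initial run
count) guards pathological inputs; in every experiment here convergence
occurs within ~10 passes and the cap never binds. The knot store is a hash
map over a doubly linked list, giving O(1) lookup, removal and neighbor
access.

Randomized visiting order means repeated runs can produce different, equally
criterion-satisfying models. This is exploited rather than suppressed:
`smooth_multi` runs the procedure k times (seeds `seed..seed+k−1`) and
`composite_median` re-encodes the position-wise median as an order-0 model,
which empirically reduces probe-wise error relative to single runs. A fixed
seed makes every run bit-reproducible.

## Acceptance criteria

Every operation is gated by one criterion, applied to each original run in
the affected window only (keeping operations local and O(window runs)):

* **relative** — `|A_i − P_i| ≤ α·max(|A_i|, 1e-12)`; α is a unitless
  relative deviation bound. The 1e-12 floor makes zero-area runs effectively
  unmergeable, which is the conservative choice.
* **poisson** — `|A_i − P_i| ≤ α·√max(A_i, 1)`: deviations bounded in
  Poisson standard deviations (variance = mean), with α the
  under/over-dispersion multiplier. Requires counts-like non-negative
  signals. The floor at 1 keeps zero-count runs mergeable at the ±α scale.
* **ttest** — Welch two-sample t-test between the data under the two
  adjacent segments, each run expanded (by weight, not materialization) to
  per-unit observations; α is the p-value cutoff and merging is allowed when
  `p > α`. Restricted to order 0, where segmentation is the natural reading.
  Degenerate inputs are deterministic: both sides constant and equal → merge;
  constant and unequal → block; fewer than 2 observations on a side → merge.

`α = 0` rejects every change, including zero-error ones, so the strict-limit
output is bit-identical to the input. Because knots only ever sit at
original run boundaries, every original run lies under exactly one final
segment, and that segment passed the per-run inequality when installed — so
for the area criteria the final model satisfies the inequality genome-wide,
not just locally (verified by the test suite).

One polarity choice was genuinely open: whether the t-test also gates knot
*relocation*. Here it does, with the move-appropriate sign — a candidate
position is acceptable when the two sides differ *significantly* there
(`p ≤ α`), i.e. when a knot is statistically justified at the new position.
The opposite polarity would forbid moving a knot onto a true breakpoint,
which is the one move that matters.

## Synthetic data

The generators produce every input the analyses need, deterministically per
seed:

* **Read coverage** (`simulate_read_coverage`): single reads of fixed length
  (default 75 nt) placed uniformly with all reads fully on the chromosome,
  so total area equals reads × read length exactly. Density is
  parameterized as reads per nucleotide.
* **aCGH** (`simulate_acgh`): unit-length probe runs with N(0, 1) noise plus
  1–10 planted constant shifts, amplitudes from N(0, 1) (optionally
  truncated to a minimum magnitude), lengths uniform in (20, 150) probes by
  default. Events are placed without overlap so truth breakpoints are
  unambiguous.
* **Copy-number genomes** (`make_cn_truth` / `simulate_cn_coverage`): a
  diploid chromosome with one ~2 kb region deleted or duplicated in one or
  both copies (copy states 0–4). Reads are placed uniformly on the
  concatenated aberrant genome and projected base-by-base to reference
  coordinates, so expected coverage is `depth·copies/2`, deletions lose
  coverage, duplications gain it, and reads spanning region junctions
  project across them. Default depth 30, matching a standard whole-genome
  design.
* **RNA-seq exons** (`make_exon_truth` / `simulate_rnaseq_exons`):
  non-overlapping exons (widths 120–300 nt, expression plateaus 50–150)
  separated by introns at a near-zero background (0.2), optional linear
  ramps inside boundaries, and per-base Poisson noise around the expected
  profile. The boundary discontinuity is the plateau-to-background jump,
  exact at the annotated position.
* **Sequence** (`random_sequence`): i.i.d. A/C/G/T with a scalar or per-base
  CG rate, for CG-content/coverage mutual-information analyses.

What the generators deliberately do **not** emulate: aligner behavior
(junction mismapping, mappability holes), fragment-length autocorrelation in
RNA-seq noise, and GC-dependent capture bias unless explicitly injected.
Consequently, passing tests show the algorithm behaves correctly under the
stated statistical models; they do not certify performance on artifacts
absent from those models. One concrete instance: with i.i.d. per-base
Poisson noise at plateau ~50–150 and the Poisson criterion at α = 2, the
per-base exceedance rate keeps linear segments short (tens of nt), so
planted 30 nt boundary ramps are read out mostly by slope *direction*, not
as single long segments; read-correlated real coverage merges further at
the same α.

## Downstream measurements

* **ICR** — cost(RLE)/cost(PPC) counting serialized fields: 2 per run,
  `2 + order` per segment. The identity model has ICR exactly 1; ICR < 1 is
  possible for sparse tracks whose RLE is already efficient. Field counts
  rather than interpreter memory were chosen because they are reproducible
  across languages and runtimes.
* **MSE** — integral squared error over the extent divided by L.
* **Fixed windows** — integral means over non-overlapping windows, the
  baseline every comparison uses, with width matched to the PPC's median
  segment length per signal.
* **Copy-number evaluation** — windows/segments labeled aberrant when
  strictly more than half their width overlaps a truth region (a rule blind
  to the segmentation method); per-base confusion counts then describe the
  best classifier possible given the segmentation.
* **RNA-seq diagnostics** — discontinuities are interior boundaries whose
  one-sided polynomial limits differ by more than a tolerance (10 signal
  units in the experiments, half the minimum planted jump); a detection
  matches an annotation within 3 bases. Boundary slopes report the segment
  containing the first base inside the exon, oriented inward, with "flat"
  below 1e-9; the steep subset keeps |slope| > 0.7 and length > 25 nt, and
  the up/down imbalance is assessed by an exact two-sided binomial test.
* **CG mutual information** — per-segment CG fraction vs mean coverage,
  equal-frequency binned into 16 bins per variable (reduced with a warning
  when segments are scarce), MI in nats by default.

## Numerical choices

Polynomial origins sit at segment starts, and fits are solved in the
unit-scaled coordinate `(x − a)/w`, whose moment matrix is a fixed
well-conditioned Hilbert-type matrix — coefficients stay stable at 10^8
coordinate scales. A condition estimate above 1e12 (possible only in
degenerate windows) falls back to the next lower order. Engine-internal
order-0 operations use global prefix sums (O(1) per window); order-1/2
operations build local moments per window; relocation scans are vectorized
over all candidate split points. Errors are clamped at 0 against floating
cancellation.

## Known limitations

* No global objective is minimized; results are "acceptable" models, and
  different seeds give different ones. A Monte-Carlo refinement on top of
  the output is possible but out of scope.
* Breakpoint localization at small effect sizes is bounded by changepoint
  estimation theory, not by the algorithm: for aCGH shifts near one noise
  standard deviation, even the exact maximum-likelihood changepoint locator
  misplaces a substantial fraction of breakpoints by more than 2 probes, and
  the recovery rate reported by `scripts/acceptance.py` sits at that
  regime's ceiling rather than near 100%.
* The relative criterion is extremely strict across zero-valued runs; use
  the Poisson criterion for counts data containing zeros.
* Multi-chromosome inputs are processed independently (seeds offset per
  chromosome); there is no cross-chromosome normalization.
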