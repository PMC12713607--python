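# Methods

## Problem setting

A 1D nonuniform-sampling (NUS) schedule for a multidimensional NMR
experiment selects `n` of the `N` uniformly spaced indirect-dimension
evolution increments (the Nyquist grid). Reconstruction of NUS data
convolves the true spectrum with the point spread function (PSF) of the
sampling mask, so the schedule's structure — not just its weighting —
controls the sampling artifacts. Two failure modes matter:

* **local patterning** — short periodic subsequences, most prominently
  the alternating `1 0` repeat that random draws produce in the densely
  sampled early region, which alias as discrete spectral spikes;
* **global bias** — long-range structure visible as strong isolated
  sidelobes of the PSF.

The toolkit generates base schedules and then treats the two failure
modes in a fixed order: a Thue-Morse (TM) two-bit swap filter for local
patterning, then an iterative PSF polisher for global bias ("TMPF").
The TM filter runs first because its own corrections can introduce weak
global structure (the TM sequence is biased toward period-3 positions),
which the polisher then treats.

## Base schedulers

All schedulers operate on 0-based indices over a grid of `N` increments
and return exactly `n` unique sorted indices. All randomness flows from
one explicit integer seed through `numpy.random.default_rng`; reruns are
bit-identical.

**Quantile sampling (QS).** Deterministic inverse-CDF placement: with
normalized cumulative weight `C(g)`, sample `i` lands on the smallest
`g` with `C(g) >= (i + 0.5)/n` (midpoint levels; level placement is a
free choice and the midpoint rule keeps the first and last samples away
from the CDF's clamped ends). Collisions advance to the nearest unused
higher index. The default weighting is a chord of the sine function,
`sin` mapped over `[pi/2, pi]`, decaying monotonically from 1 to 0 so
sampling thins toward long evolution times; the chord endpoints are
configurable.

**Poisson gap (PG).** Gaps between consecutive samples are Poisson
deviates with rate `lambda * sin(theta)`, `theta` ramping `0 -> pi/2`
across the schedule, giving short gaps at early evolution times and a
long nearly uniform tail. `lambda` starts at the value that makes the
expected gap total equal `N - n` and is calibrated by bisection on a
multiplicative factor (at most 200 evaluations, each re-drawing from a
freshly seeded generator so the calibration is deterministic) until the
`n` gaps fit the grid; any residual overshoot is removed by greedily
decrementing the largest gaps. The first sample sits at index 0 and the
last sample is relocated to `N - 1` when absent, so the final grid point
is guaranteed for every seed.

**Schedule averaging.** Each replicate draws `n` uniform quantile
levels, maps them through the density's inverse CDF (linear
interpolation of the cumulative mass at grid points), and sorts; the
i-th order statistics are averaged across replicates, rounded, and
deduplicated. As replicates grow the mean order statistics converge to
fixed quantiles of the density, so the result converges to quantile
placement (verified at 5000 replicates: mean absolute deviation from
the quantile schedule below one grid point at `N=64, n=16`). Exponential
schedules use this generator with density `exp(-g/(decay*(N-1)))`,
`decay` defaulting to 0.5 grid fractions; 512 replicates by default.

**Random unweighted (RU).** Uniform draws without replacement, with
optional *backfill*: each backfill step inserts one sample at the floor
midpoint of the current largest zero run (boundary runs included, ties
to the earliest run). Backfill is defined here as largest-gap midpoint
insertion; it is an interpretation of a procedure the source material
names but does not specify.

**Uniform prefix.** Weighted methods force a short initial uniform
region (default 2 increments; RU default 0). Each forced insertion
removes one sample from the least-weighted occupied index outside the
prefix (ties to the highest index), preserving `n`. The literature
recommends "very short" initial uniform regions without fixing a
length; 2 is the package default and is configurable.

## Thue-Morse filter

The TM sequence (symbol `i` of the 0-start sequence is the parity of
the set bits of `i`) is cube-free: it contains no `X X X` for any
binary string `X`. Symbols are materialized through this closed form so
arbitrary windows of the infinite sequence cost O(length).

The filter steps the schedule through overlapping two-bit windows
(step 1) and compares each window with the aligned TM slice starting at
a user-chosen offset (default 0; the offset acts like a seed). A window
is swapped to match the TM slice iff both bits are the logical opposite
of the TM bits **and** the pair contains exactly one sample — pairs with
zero or two samples are invariant under bit exchange and are skipped.
Consequences, all asserted in tests:

* sample count is conserved and no sample moves more than one position;
* a swapped window matches the TM slice, so the following window cannot
  swap the same position: swaps are pairwise disjoint and the filter is
  idempotent at a fixed offset;
* with endpoint protection (default on) the first and last increments
  are never vacated — the last point guarantee of PG and the first
  increment expected by processing software survive filtering.

**What the filter can and cannot decrease.** Because swapped regions
align to the TM sequence, the filter eliminates the patterns TM itself
excludes — alternating repeats of three or more units (`101010...`) —
and the ensemble total of such runs drops sharply (with `k >= 4` runs
eliminated outright in the tested ensembles). The TM sequence is
overlap-free but does contain `(1 0)^2`, so two-unit alternations can
be *created* where the filter makes corrections; the two-unit count is
therefore not a monotone diagnostic of this filter, and the test suite
asserts the decrease on runs of three or more units.

## PSF polisher

The PSF is the `N`-point DFT of the mask (no zero-filling, so PSF bins
and grid indices correspond one-to-one under the inverse transform).
For a 0/1 mask the DC coefficient equals `n`, the coefficients are
conjugate-symmetric, and total power is fixed at `N*n` (Parseval) — the
polisher can only redistribute power, which is exactly the point: it
moves power out of strong spikes into the quiet background.

Each iteration, recomputed from scratch on the current schedule:

1. **Central-peak trim.** Walking outward from DC independently in each
   frequency direction (cyclically), bins join the central exclusion
   while magnitudes strictly decrease; the first nondecreasing bin is
   retained as a sidelobe. A zero-magnitude bin also stops the walk and
   is retained: a vanished coefficient is not a peak flank. (This
   tie-break makes the fully sampled schedule exclude only DC and
   report PSR 0.)
2. **Rank threshold.** Non-excluded magnitudes are ranked decreasing;
   the threshold is the magnitude at rank `k = max(1, round(N*tau))`
   (clipped to the number of candidates). `tau` defaults to 0.01 — on a
   256-point grid the top ~3 sidelobe pairs are treated per iteration.
   Bins at or above the threshold are retained with their symmetric
   partners; retained magnitudes are shrunk by the threshold with
   phases preserved (the classic soft-threshold operator; hard
   retention is the other defensible reading, and shrinkage was chosen
   because it suppresses the rank-k baseline all retained features
   share). Ties at the threshold are all retained, making the set
   order-independent. Zero-magnitude bins are never retained.
3. **td-PSF.** The inverse DFT of the thresholded coefficients; the
   symmetric retained set makes it real to numerical tolerance
   (imaginary residue checked against 1e-9 of the largest amplitude,
   with an absolute floor of 1e-12 for the fully shrunk case), and its
   absolute amplitudes per grid index are the "footprint" of the
   strongest PSF features.
4. **Swap selection.** Over adjacent pairs with a sample at `i` and a
   hole at `j`, neither previously swapped (and neither at a protected
   endpoint), the pair maximizing `amp[i] - amp[j]` is applied — the
   move that best goes against the grain of the dominant PSF features.
   Ties break to the lowest `i`, then `j = i + 1`. A selected swap is
   applied even when its gain is nonpositive: termination is by
   exhaustion of eligible positions (each swap consumes two, bounding
   iterations by `N/2`), and harmful tail swaps are discarded by the
   penalty minimum below.

Every snapshot (initial schedule plus one per swap) is scored with
`penalty = PSR + c * swaps`, where PSR is the largest surviving
sidelobe magnitude divided by `n` (in `[0, 1]`, lower better) and the
swap cost `c` (default 0.001) sets how much PSR one extra swap must
buy. The snapshot with the lowest penalty is returned (earliest on
ties), so the result is never worse than the input. The penalty counts
polisher swaps only; TM-filter swaps are a separate stage and are
reported separately. No guard prevents the polisher from reverting TM
swaps — the interaction is observable in the per-stage metrics rather
than prevented.

## Metrics

* **Repeat-length histogram.** A maximal strictly alternating segment
  of the mask of length `L` holds `k = floor(L/2)` two-bit units and
  contributes one count at key `k` when `k >= 2`; both orientations
  (`10...` and `01...`) are pooled in one scan. This definition is a
  reconstruction — the defining prior reference is not reproduced here —
  and the caveat above about two-unit runs applies to any user reading
  before/after comparisons.
* **Gap statistics.** Maximal zero runs, boundary runs included (an
  early hole is as damaging as an interior one); largest-gap ties go to
  the earliest run.
* **PSR** as defined for the polisher. PSR comparisons are meaningful
  within a polish trace, not as a screen between unrelated schedules.
* **ScheduleReport** bundles coverage, PSR, largest gap, the histogram
  and per-stage swap counts; the CLI embeds it as `#` comments in the
  schedule file for provenance.

## Synthetic fixtures

`make_flawed_fixture` embeds one flaw in an otherwise quantile layout:
an `(1 0)^k` alternating run at the schedule start, or a zero run of a
requested length carved at a seeded location with evicted samples
redistributed. These emulate the flaw classes of sparse random
schedules — they do not emulate instrument data, reconstruction
behavior, or signal content, so passing tests demonstrate schedule
properties only, not spectral quality.

## Numerical and testing choices

* Problem sizes in the test suite (grids up to 512, ensembles of
  50–1000 schedules, 5000 averaging replicates) were chosen as the
  smallest sizes at which the asserted ensemble effects are stable.
* Parseval power is asserted to 1e-10 relative; td-PSF reality to 1e-9
  relative with a 1e-12 absolute floor.
* Degenerate inputs: `n = 0` or `n = N` schedules pass through the
  polisher unchanged; a single-point grid passes through the TM filter
  unchanged; empty schedules are rejected by gap statistics and PSR.
* All tie-breaks (cube reporting, collision resolution, swap selection,
  largest gap) are deterministic and positional, so every pipeline
  output is bit-reproducible from its configuration.

## Known limitations

* The filter/polisher operate on 1D schedules only; multidimensional
  NUS masks are out of scope.
* PSR, the histogram, and gap metrics diagnose the schedule, not the
  reconstruction; no spectral reconstruction is performed.
* The sine-chord endpoints, `tau`, the swap cost, and the uniform
  prefix length are package defaults chosen as described above, not
  values with published provenance.
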