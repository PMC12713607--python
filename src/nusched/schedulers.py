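"""Base 1D-NUS schedule generators.

Four families are provided:

* :func:`quantile_schedule` — deterministic placement at quantiles of a
  weighting density (default density: a chord of the sine function, giving
  sampling that thins toward long evolution times);
* :func:`poisson_gap_schedule` — inter-sample gaps drawn from Poisson
  deviates whose rate is modulated sinusoidally along the grid, with the
  last grid point guaranteed;
* :func:`averaged_schedule` — schedule averaging: order statistics of
  repeated random inverse-CDF draws, used here for exponential weighting;
* :func:`random_unweighted_schedule` — uniform draws without replacement,
  with optional backfill of the largest gaps.

All indices are 0-based over a grid of ``N`` increments.  Every stochastic
generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedule import SamplingSchedule

__all__ = [
    "WeightingDensity",
    "density_sine_chord",
    "density_exponential",
    "density_uniform",
    "quantile_schedule",
    "poisson_gap_schedule",
    "averaged_schedule",
    "random_unweighted_schedule",
    "apply_uniform_prefix",
]


@dataclass(frozen=True)
class WeightingDensity:
    """Non-negative sampling weight per grid index, with provenance."""

    name: str
    values: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("density values must be a non-empty 1-D array")
        if (vals < 0).any():
            raise ValueError("density values must be non-negative")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)

    @property
    def grid_size(self) -> int:
        return int(self.values.size)

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


def density_uniform(grid_size: int) -> WeightingDensity:
    """Flat weighting over the grid."""
    if grid_size < 1:
        raise ValueError("grid_size must be positive")
    return WeightingDensity("uniform", np.ones(grid_size), {})


def density_sine_chord(
    grid_size: int,
    chord_start: float = math.pi / 2,
    chord_end: float = math.pi,
) -> WeightingDensity:
    """Sine-chord weighting: ``sin`` evaluated along an arc of ``[0, pi]``.

    ``values[g] = sin(chord_start + (chord_end - chord_start) * g/(N-1))``.
    The default chord ``[pi/2, pi]`` decays monotonically from 1 at the
    first increment to 0 at the last, i.e. sparser sampling at long
    evolution times.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be positive")
    if not (0 <= chord_start < chord_end <= math.pi):
        raise ValueError("chord must satisfy 0 <= start < end <= pi")
    if grid_size == 1:
        args = np.array([chord_start])
    else:
        args = chord_start + (chord_end - chord_start) * np.arange(grid_size) / (
            grid_size - 1
        )
    values = np.sin(args)
    values[np.abs(values) < 1e-15] = 0.0
    return WeightingDensity(
        "sine_chord",
        values,
        {"chord_start": chord_start, "chord_end": chord_end},
    )


def density_exponential(grid_size: int, decay: float = 0.5) -> WeightingDensity:
    """Exponential weighting ``exp(-g / (decay * (N-1)))``.

    ``decay`` is the 1/e point as a fraction of the grid; larger values
    approach uniform weighting.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be positive")
    if decay <= 0:
        raise ValueError("decay must be positive")
    g = np.arange(grid_size, dtype=float)
    scale = decay * (grid_size - 1) if grid_size > 1 else decay
    return WeightingDensity("exponential", np.exp(-g / scale), {"decay": decay})


def _check_counts(grid_size: int, sample_count: int) -> None:
    if grid_size < 1:
        raise ValueError("grid_size must be positive")
    if sample_count < 1:
        raise ValueError("sample_count must be positive")
    if sample_count > grid_size:
        raise ValueError(
            f"cannot place {sample_count} samples on a {grid_size}-point grid"
        )


def _resolve_collisions(targets: np.ndarray, grid_size: int) -> np.ndarray:
    """Map possibly colliding grid targets to unique indices.

    Each target advances to the nearest unused higher index; if the grid is
    exhausted upward, it falls back to the nearest unused lower index.
    """
    used = np.zeros(grid_size, dtype=bool)
    out = np.empty(targets.size, dtype=np.int64)
    for i, t in enumerate(targets):
        g = int(t)
        while g < grid_size and used[g]:
            g += 1
        if g >= grid_size:
            g = int(t) - 1
            while g >= 0 and used[g]:
                g -= 1
            if g < 0:
                raise RuntimeError("no free grid index left")  # n <= N prevents this
        used[g] = True
        out[i] = g
    return np.sort(out)


def _force_last_point(schedule: SamplingSchedule) -> SamplingSchedule:
    mask = schedule.mask.copy()
    if mask[-1] == 0:
        mask[int(np.flatnonzero(mask).max())] = 0
        mask[-1] = 1
    return SamplingSchedule(mask)


def quantile_schedule(
    grid_size: int,
    sample_count: int,
    density: WeightingDensity | None = None,
    guarantee_last: bool = False,
) -> SamplingSchedule:
    """Deterministic quantile sampling from a weighting density.

    The normalized cumulative mass ``C(g)`` is inverted at the midpoint
    levels ``(i + 0.5)/n``: sample ``i`` lands on the smallest ``g`` with
    ``C(g) >= (i + 0.5)/n``.  Collisions advance to the nearest unused
    higher index.  ``guarantee_last`` relocates the highest sample to the
    final grid point when it is unsampled (off by default; only the
    Poisson-gap scheduler pins the last point by construction).
    """
    _check_counts(grid_size, sample_count)
    if density is None:
        density = density_sine_chord(grid_size)
    if density.grid_size != grid_size:
        raise ValueError("density length must equal grid_size")
    if density.total_mass <= 0:
        raise ValueError("density has zero total mass")
    cum = np.cumsum(density.values) / density.total_mass
    levels = (np.arange(sample_count) + 0.5) / sample_count
    targets = np.searchsorted(cum, levels, side="left")
    targets = np.minimum(targets, grid_size - 1)
    schedule = SamplingSchedule.from_indices(
        _resolve_collisions(targets, grid_size), grid_size
    )
    return _force_last_point(schedule) if guarantee_last else schedule


def _pg_gaps(rng: np.random.Generator, sample_count: int, lam: float) -> np.ndarray:
    # sinusoidal ramp theta: 0 -> pi/2 across the schedule (midpoint rule)
    theta = (np.arange(sample_count) + 0.5) / sample_count * (math.pi / 2)
    return rng.poisson(lam * np.sin(theta))


def poisson_gap_schedule(
    grid_size: int, sample_count: int, seed: int
) -> SamplingSchedule:
    """Sinusoidally weighted Poisson-gap schedule with a guaranteed last point.

    Gaps between consecutive samples are Poisson deviates with rate
    ``lambda * sin(theta)``, ``theta`` ramping from 0 to pi/2 along the
    schedule, so gaps are short at early evolution times.  ``lambda`` is
    calibrated by bisection on a multiplicative factor until the ``n``
    samples span the grid; the first sample sits at index 0 and the last
    is relocated to ``N - 1`` if it did not land there.
    """
    _check_counts(grid_size, sample_count)
    if sample_count < 2:
        raise ValueError(
            "poisson_gap_schedule needs n >= 2 to pin both grid endpoints"
        )
    n, N = sample_count, grid_size
    if n == N:
        return SamplingSchedule(np.ones(N, dtype=np.int8))

    slack = N - n  # total zero-gap budget
    # mean of sin over the ramp is 2/pi; lam0 makes E[sum gaps] ~= slack
    lam0 = slack / (n * 2 / math.pi)

    def extent(factor: float) -> tuple[int, np.ndarray]:
        rng = np.random.default_rng(seed)
        gaps = _pg_gaps(rng, n, factor * lam0)
        return int(gaps.sum()), gaps

    lo, hi = 0.0, 1.0
    total, gaps = extent(hi)
    grow = 0
    while total < slack and grow < 60:
        lo, hi = hi, hi * 2
        total, gaps = extent(hi)
        grow += 1
    best_gaps = None
    for _ in range(200):
        mid = (lo + hi) / 2
        total, gaps = extent(mid)
        if total == slack:
            best_gaps = gaps
            break
        if total > slack:
            hi = mid
        else:
            lo = mid
            best_gaps = gaps  # largest undershoot seen
    if best_gaps is None:
        total, best_gaps = extent(lo)
        if total > slack:
            best_gaps = np.zeros(n, dtype=np.int64)
    gaps = np.asarray(best_gaps, dtype=np.int64).copy()
    # greedy trim of the largest gaps until the schedule fits the grid
    while gaps.sum() > slack:
        gaps[int(np.argmax(gaps))] -= 1
    indices = np.cumsum(np.concatenate(([0], gaps[:-1] + 1)))
    if indices[-1] != N - 1:
        indices[-1] = N - 1  # guarantee the last grid point
    return SamplingSchedule.from_indices(indices, N)


def _inverse_cdf(density: WeightingDensity, levels: np.ndarray) -> np.ndarray:
    cum = np.cumsum(density.values) / density.total_mass
    return np.interp(levels, cum, np.arange(density.grid_size, dtype=float))


def averaged_schedule(
    grid_size: int,
    sample_count: int,
    density: WeightingDensity,
    replicates: int,
    seed: int,
    guarantee_last: bool = False,
) -> SamplingSchedule:
    """Schedule averaging: mean order statistics of random inverse-CDF draws.

    Each of ``replicates`` draws samples ``n`` uniform quantile levels,
    maps them through the density's inverse CDF, and sorts; the i-th order
    statistics are averaged across replicates, rounded to the grid, and
    collisions resolved as in :func:`quantile_schedule`.  As the number of
    replicates grows this converges to quantile placement.
    """
    _check_counts(grid_size, sample_count)
    if replicates < 1:
        raise ValueError("replicates must be positive")
    if density.grid_size != grid_size:
        raise ValueError("density length must equal grid_size")
    if density.total_mass <= 0:
        raise ValueError("density has zero total mass")
    rng = np.random.default_rng(seed)
    levels = rng.random((replicates, sample_count))
    positions = _inverse_cdf(density, levels)
    positions.sort(axis=1)
    mean_positions = positions.mean(axis=0)
    targets = np.clip(np.floor(mean_positions + 0.5), 0, grid_size - 1).astype(
        np.int64
    )
    schedule = SamplingSchedule.from_indices(
        _resolve_collisions(targets, grid_size), grid_size
    )
    return _force_last_point(schedule) if guarantee_last else schedule


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, length), boundaries included."""
    runs = []
    start = None
    for g, bit in enumerate(mask):
        if bit == 0 and start is None:
            start = g
        elif bit == 1 and start is not None:
            runs.append((start, g - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def random_unweighted_schedule(
    grid_size: int,
    sample_count: int,
    seed: int,
    backfill: int = 0,
) -> SamplingSchedule:
    """Uniform random schedule with optional largest-gap backfill.

    ``sample_count`` indices are drawn uniformly without replacement, then
    ``backfill`` extra samples are inserted one at a time at the floor
    midpoint of the current largest gap (ties: earliest gap).  The result
    carries ``sample_count + backfill`` samples.
    """
    _check_counts(grid_size, sample_count)
    if backfill < 0:
        raise ValueError("backfill must be non-negative")
    if sample_count + backfill > grid_size:
        raise ValueError("sample_count + backfill exceeds grid_size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(grid_size, size=sample_count, replace=False)
    mask = np.zeros(grid_size, dtype=np.int8)
    mask[idx] = 1
    for _ in range(backfill):
        runs = _zero_runs(mask)
        start, length = max(runs, key=lambda r: (r[1], -r[0]))
        insert = (start + (start + length - 1)) // 2  # floor midpoint of the run
        mask[insert] = 1
    return SamplingSchedule(mask)


def apply_uniform_prefix(
    schedule: SamplingSchedule,
    prefix_length: int,
    density: WeightingDensity | None = None,
) -> SamplingSchedule:
    """Force a short uniform region at the start of the schedule.

    Indices ``0 .. prefix_length-1`` are set; for each forced insertion one
    sample is removed from the least-weighted occupied index outside the
    prefix (ties: highest index), so the sample count is unchanged.
    """
    N = schedule.grid_size
    if prefix_length < 0 or prefix_length > N:
        raise ValueError("prefix_length must be in [0, grid_size]")
    if prefix_length == 0:
        return schedule
    if schedule.sample_count < prefix_length:
        raise ValueError("schedule has fewer samples than the requested prefix")
    weights = (
        density.values if density is not None else np.ones(N, dtype=float)
    )
    if density is not None and density.grid_size != N:
        raise ValueError("density length must equal grid_size")
    mask = schedule.mask.copy()
    for g in range(prefix_length):
        if mask[g]:
            continue
        outside = np.flatnonzero(mask[prefix_length:]) + prefix_length
        if outside.size == 0:
            raise ValueError("no sample outside the prefix to relocate")
        w = weights[outside]
        # least weight first, ties -> highest index
        victim = outside[np.lexsort((-outside, w))][0]
        mask[victim] = 0
        mask[g] = 1
    return SamplingSchedule(mask)
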