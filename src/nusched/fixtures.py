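"""Synthetic flawed schedules for exercising the decoherence filters.

Real-world failure modes of random unweighted schedules fall into two
classes: long strictly alternating runs (local patterning) and large
unsampled gaps (global holes).  These constructors embed one flaw of a
requested magnitude into an otherwise well-behaved quantile layout so
that tests can verify the Thue-Morse filter and the PSF polisher detect
and reduce them.
"""

from __future__ import annotations

import numpy as np

from .schedule import SamplingSchedule
from .schedulers import density_sine_chord, quantile_schedule

__all__ = ["make_flawed_fixture"]


def _alternating_run(N: int, n: int, units: int) -> SamplingSchedule:
    if units == 0:
        return quantile_schedule(N, n, density_sine_chord(N))
    run_len = 2 * units
    if run_len > N or units > n:
        raise ValueError("alternating run does not fit the schedule")
    mask = np.zeros(N, dtype=np.int8)
    mask[0:run_len:2] = 1  # (1 0)^units at the schedule start
    remaining = n - units
    if remaining > 0:
        tail = N - run_len - 1  # leave one zero so the run stays maximal
        if remaining > tail:
            raise ValueError("too many samples to place after the alternating run")
        rest = quantile_schedule(tail, remaining, density_sine_chord(tail))
        mask[run_len + 1 :] = rest.mask
    return SamplingSchedule(mask)


def _large_gap(N: int, n: int, gap: int, seed: int) -> SamplingSchedule:
    if gap == 0:
        return quantile_schedule(N, n, density_sine_chord(N))
    if gap >= N or n > N - gap:
        raise ValueError("gap does not leave room for the requested samples")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, N - gap + 1))
    base = quantile_schedule(N, n, density_sine_chord(N))
    mask = base.mask.copy()
    evicted = int(mask[start : start + gap].sum())
    mask[start : start + gap] = 0
    free = np.flatnonzero(mask == 0)
    free = free[(free < start) | (free >= start + gap)]
    if evicted > free.size:
        raise ValueError("cannot redistribute samples around the gap")
    refill = rng.choice(free, size=evicted, replace=False)
    mask[refill] = 1
    return SamplingSchedule(mask)


def make_flawed_fixture(
    kind: str, N: int, n: int, param: int, seed: int = 0
) -> SamplingSchedule:
    """Build a schedule with one embedded flaw.

    ``kind="alternating_run"`` embeds a ``(1 0)^param`` run at the start;
    ``kind="large_gap"`` carves a zero run of length ``param`` at a seeded
    location, redistributing the evicted samples so ``n`` is preserved.
    ``param=0`` returns a plain quantile schedule.
    """
    if param < 0:
        raise ValueError("param must be non-negative")
    if kind == "alternating_run":
        return _alternating_run(N, n, param)
    if kind == "large_gap":
        return _large_gap(N, n, param, seed)
    raise ValueError(f"unknown fixture kind: {kind!r}")
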