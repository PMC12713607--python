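"""Iterative-thresholding PSF polisher for global decoherence.

Where the Thue-Morse filter corrects local patterning, the polisher
targets long-range (global) biases visible as strong spikes in the PSF.
Each iteration recomputes the full pipeline on the current schedule —
PSF, central-peak trim, rank-based soft threshold, inverse transform to
the time-domain PSF — and then applies the single most impactful
adjacent swap: the pair ``(i, j)``, ``|i - j| = 1``, with ``mask[i] = 1``
and ``mask[j] = 0``, that maximizes ``amplitude(i) - amplitude(j)`` of
the td-PSF.  Moving a sample against the strongest retained PSF feature
redistributes that feature's power into quieter regions, smoothing the
PSF.  Positions already swapped are never reused, so the loop terminates
after at most ``N/2`` swaps.

Every intermediate schedule is scored with ``PSR + c * swaps``, where the
swap cost ``c`` sets how much PSR improvement one extra swap must buy;
the lowest-penalty snapshot is returned, which both implements the
diminishing-returns exit and guarantees the result is never worse than
the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psf import compute_psf, psr, soft_threshold, td_psf, trim_central_peak
from .schedule import SamplingSchedule

__all__ = ["PolishSnapshot", "PolishTrace", "penalty", "select_swap", "polish"]

DEFAULT_TAU = 0.01
DEFAULT_SWAP_COST = 0.001


def penalty(psr_value: float, swaps_applied: int, swap_cost: float) -> float:
    """Penalty score ``PSR + swap_cost * number_of_swaps``."""
    if psr_value < 0 or swaps_applied < 0 or swap_cost < 0:
        raise ValueError("penalty inputs must be non-negative")
    return psr_value + swap_cost * swaps_applied


@dataclass(frozen=True)
class PolishSnapshot:
    swap: tuple[int, int] | None  # (from, to); None for the initial schedule
    psr: float
    penalty: float
    schedule: SamplingSchedule


@dataclass(frozen=True)
class PolishTrace:
    """Per-iteration record of the polish loop."""

    snapshots: tuple[PolishSnapshot, ...]
    best_index: int
    swapped_positions: frozenset[int]

    @property
    def swaps_applied(self) -> int:
        return len(self.snapshots) - 1

    @property
    def best_swaps(self) -> int:
        """Swaps leading to the returned (lowest-penalty) schedule."""
        return self.best_index

    def to_tsv(self) -> str:
        """Trace as tab-separated text: iteration, from, to, PSR, penalty."""
        lines = ["iteration\tswap_from\tswap_to\tpsr\tpenalty"]
        for it, snap in enumerate(self.snapshots):
            frm = "" if snap.swap is None else str(snap.swap[0])
            to = "" if snap.swap is None else str(snap.swap[1])
            lines.append(f"{it}\t{frm}\t{to}\t{snap.psr:.10g}\t{snap.penalty:.10g}")
        return "\n".join(lines) + "\n"


def select_swap(
    schedule: SamplingSchedule,
    amplitudes: np.ndarray,
    swapped_positions: frozenset[int] | set[int] = frozenset(),
    protect_endpoints: bool = True,
) -> tuple[int, int] | None:
    """Most impactful adjacent sample move implied by the td-PSF.

    Over all adjacent pairs with a sample at ``i`` and a hole at ``j``,
    neither position previously swapped (and endpoints untouched when
    protected), returns the pair maximizing ``amplitudes[i] -
    amplitudes[j]``.  Ties prefer the lowest ``i``, then ``j = i + 1``
    over ``j = i - 1``.  Returns ``None`` when no pair is eligible.
    """
    mask = schedule.mask
    N = schedule.grid_size
    if amplitudes.shape != (N,):
        raise ValueError("amplitudes must have one value per grid point")
    best: tuple[int, int] | None = None
    best_gain = -np.inf
    for i in range(N):
        if mask[i] != 1 or i in swapped_positions:
            continue
        for j in (i + 1, i - 1):
            if not 0 <= j < N or mask[j] != 0 or j in swapped_positions:
                continue
            if protect_endpoints and {i, j} & {0, N - 1}:
                continue
            gain = float(amplitudes[i] - amplitudes[j])
            if gain > best_gain:
                best_gain = gain
                best = (i, j)
    return best


def polish(
    schedule: SamplingSchedule,
    tau: float = DEFAULT_TAU,
    swap_cost: float = DEFAULT_SWAP_COST,
    protect_endpoints: bool = True,
) -> tuple[SamplingSchedule, PolishTrace]:
    """Run the iterative-thresholding polish loop to the lowest-penalty schedule.

    The loop applies the selected swap even when its amplitude gain is not
    positive: the exit condition is exhaustion of eligible swaps, and the
    penalty minimum over the trace discards any harmful tail.
    """
    n, N = schedule.sample_count, schedule.grid_size
    psr0 = psr(schedule) if n else 0.0
    initial = PolishSnapshot(None, psr0, penalty(psr0, 0, swap_cost), schedule)
    if n == 0 or n == N:
        trace = PolishTrace((initial,), 0, frozenset())
        return schedule, trace
    snapshots = [initial]
    swapped: set[int] = set()
    current = schedule
    while True:
        tpsf = soft_threshold(trim_central_peak(compute_psf(current)), tau)
        amplitudes = td_psf(tpsf, compute_psf(current))
        pair = select_swap(current, amplitudes, swapped, protect_endpoints)
        if pair is None:
            break
        i, j = pair
        mask = current.mask.copy()
        mask[i], mask[j] = 0, 1
        current = SamplingSchedule(mask)
        swapped.update(pair)
        value = psr(current)
        snapshots.append(
            PolishSnapshot(
                pair, value, penalty(value, len(snapshots), swap_cost), current
            )
        )
    penalties = [s.penalty for s in snapshots]
    best_index = int(np.argmin(penalties))  # earliest minimum on ties
    best = snapshots[best_index]
    assert best.penalty <= snapshots[0].penalty
    assert best.schedule.sample_count == schedule.sample_count
    trace = PolishTrace(tuple(snapshots), best_index, frozenset(swapped))
    return best.schedule, trace
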