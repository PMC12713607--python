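"""Local decoherence filter based on the Thue-Morse sequence.

Weighted and unweighted NUS schedules alike develop patterned
subsequences — most prominently the alternating ``1 0`` repeat in the
densely sampled early region — which leak periodic artifacts into
spectral reconstructions.  The filter steps the schedule through
overlapping two-bit windows and compares each window against the aligned
slice of the cube-free Thue-Morse sequence.  A window whose two bits are
the exact logical opposite of the TM bits, and which contains exactly one
sample, is swapped to match the TM sequence.  Each swap moves one sample
by one grid position, so the intended sampling distribution is barely
perturbed; windows with zero or two samples are no-ops under bit
exchange and are skipped.

Because a swapped window now matches the TM slice, the following window
can never swap the same position again: the filter is idempotent at a
fixed offset, and no position appears in two swaps.

The filter's single tunable is the initiation offset into the infinite
TM sequence, analogous to a random seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .schedule import SamplingSchedule
from .tm import tm_slice

__all__ = ["TmFilterResult", "tm_filter", "tm_filter_idempotence_check"]


@dataclass(frozen=True)
class TmFilterResult:
    """Outcome of one TM-filter pass."""

    schedule: SamplingSchedule
    swaps: tuple[tuple[int, int], ...]
    offset: int
    start_symbol: int


def tm_filter(
    schedule: SamplingSchedule,
    start_symbol: int = 1,
    offset: int = 0,
    protect_endpoints: bool = True,
) -> TmFilterResult:
    """Swap two-bit windows that are the logical opposite of the TM slice.

    Windows ``(i, i+1)`` are visited left to right with step 1.  A window
    is swapped iff both its bits are the complement of the aligned TM bits
    and the pair holds exactly one sample.  With ``protect_endpoints`` the
    first and last grid increments are never vacated.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    N = schedule.grid_size
    if N < 2:
        return TmFilterResult(schedule, (), offset, start_symbol)
    tm = tm_slice(start_symbol, offset, N).symbols
    mask = schedule.mask.copy()
    swaps: list[tuple[int, int]] = []
    for i in range(N - 1):
        a, b = int(mask[i]), int(mask[i + 1])
        if a == b:
            continue  # 0 or 2 samples: bit exchange is the identity
        if a == tm[i] or b == tm[i + 1]:
            continue  # not fully opposite of the TM window
        if protect_endpoints and (
            (i == 0 and a == 1) or (i + 1 == N - 1 and b == 1)
        ):
            continue  # would vacate a protected endpoint
        mask[i], mask[i + 1] = b, a
        swaps.append((i, i + 1))
    filtered = SamplingSchedule(mask)
    assert filtered.sample_count == schedule.sample_count
    return TmFilterResult(filtered, tuple(swaps), offset, start_symbol)


def tm_filter_idempotence_check(
    schedule: SamplingSchedule,
    start_symbol: int = 1,
    offset: int = 0,
    protect_endpoints: bool = True,
) -> bool:
    """True iff applying the filter twice equals applying it once."""
    once = tm_filter(schedule, start_symbol, offset, protect_endpoints)
    twice = tm_filter(once.schedule, start_symbol, offset, protect_endpoints)
    return twice.schedule == once.schedule and not twice.swaps
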