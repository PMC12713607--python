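"""Schedule diagnostics: alternating-repeat histogram, gaps, summary report.

The repeat-length histogram counts maximal alternating runs in the mask:
a maximal segment of strictly alternating bits of length ``L`` holds
``k = L // 2`` full two-bit units, and contributes one count at key ``k``
when ``k >= 2``.  Both orientations (``1 0`` and ``0 1``) are pooled.
This is the local-patterning diagnostic the Thue-Morse filter is meant
to drive down.

Gap statistics count maximal zero runs, including the runs before the
first and after the last sample — an unsampled region at the start of
the evolution grid is as damaging as one in the middle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psf import psr as _psr
from .schedule import SamplingSchedule

__all__ = [
    "RepeatHistogram",
    "ScheduleReport",
    "repeat_length_histogram",
    "gap_statistics",
    "build_report",
]


@dataclass(frozen=True)
class RepeatHistogram:
    """Counts of maximal alternating runs by number of two-bit units."""

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)


def repeat_length_histogram(schedule: SamplingSchedule) -> RepeatHistogram:
    """Histogram of maximal alternating (two-bit-unit) runs, unit count >= 2."""
    mask = schedule.mask
    N = schedule.grid_size
    counts: dict[int, int] = {}
    start = 0
    for g in range(1, N + 1):
        if g == N or mask[g] == mask[g - 1]:
            k = (g - start) // 2
            if k >= 2:
                counts[k] = counts.get(k, 0) + 1
            start = g
    return RepeatHistogram(counts)


def gap_statistics(
    schedule: SamplingSchedule,
) -> tuple[int, int | None, list[int]]:
    """(largest gap length, its start index, all gap lengths).

    Gaps are maximal zero runs, boundary runs included; ties for the
    largest go to the earliest.  A fully sampled schedule reports
    ``(0, None, [])``.
    """
    if schedule.sample_count == 0:
        raise ValueError("gap statistics are undefined for an empty schedule")
    mask = schedule.mask
    gaps: list[tuple[int, int]] = []  # (start, length)
    start: int | None = None
    for g, bit in enumerate(mask):
        if bit == 0 and start is None:
            start = g
        elif bit == 1 and start is not None:
            gaps.append((start, g - start))
            start = None
    if start is not None:
        gaps.append((start, schedule.grid_size - start))
    if not gaps:
        return 0, None, []
    best_start, best_len = max(gaps, key=lambda r: (r[1], -r[0]))
    return best_len, best_start, [length for _, length in gaps]


@dataclass(frozen=True)
class ScheduleReport:
    grid_size: int
    sample_count: int
    coverage: float
    psr: float
    largest_gap: int
    largest_gap_start: int | None
    repeat_histogram: RepeatHistogram
    tm_swaps: int | None = None
    polish_swaps: int | None = None

    def to_text(self) -> str:
        lines = [
            f"grid_size        {self.grid_size}",
            f"sample_count     {self.sample_count}",
            f"coverage         {self.coverage:.6f}",
            f"psr              {self.psr:.6f}",
            f"largest_gap      {self.largest_gap}"
            + (
                f" (start {self.largest_gap_start})"
                if self.largest_gap_start is not None
                else ""
            ),
        ]
        if self.repeat_histogram:
            hist = ", ".join(
                f"{k}:{v}" for k, v in sorted(self.repeat_histogram.counts.items())
            )
        else:
            hist = "(none)"
        lines.append(f"repeat_histogram {hist}")
        if self.tm_swaps is not None:
            lines.append(f"tm_swaps         {self.tm_swaps}")
        if self.polish_swaps is not None:
            lines.append(f"polish_swaps     {self.polish_swaps}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "grid_size": self.grid_size,
            "sample_count": self.sample_count,
            "coverage": self.coverage,
            "psr": self.psr,
            "largest_gap": self.largest_gap,
            "largest_gap_start": self.largest_gap_start,
            "repeat_histogram": dict(sorted(self.repeat_histogram.counts.items())),
        }
        if self.tm_swaps is not None:
            d["tm_swaps"] = self.tm_swaps
        if self.polish_swaps is not None:
            d["polish_swaps"] = self.polish_swaps
        return d


def build_report(
    schedule: SamplingSchedule,
    tm_result=None,
    polish_trace=None,
) -> ScheduleReport:
    """Assemble the full metrics bundle for a (possibly filtered) schedule."""
    if tm_result is not None and tm_result.schedule.grid_size != schedule.grid_size:
        raise ValueError("TM-filter result grid size does not match schedule")
    largest, start, _ = gap_statistics(schedule)
    return ScheduleReport(
        grid_size=schedule.grid_size,
        sample_count=schedule.sample_count,
        coverage=schedule.coverage,
        psr=_psr(schedule),
        largest_gap=largest,
        largest_gap_start=start,
        repeat_histogram=repeat_length_histogram(schedule),
        tm_swaps=len(tm_result.swaps) if tm_result is not None else None,
        polish_swaps=polish_trace.best_swaps if polish_trace is not None else None,
    )
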