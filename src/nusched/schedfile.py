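"""Plain-text schedule files: one grid index per line.

The format follows common NUS sample-list ("nuslist") conventions:
ascending integer indices, one per line, optional ``#``-prefixed comment
lines.  Indices are 0-based by default; a flag supports 1-based consumer
dialects.
"""

from __future__ import annotations

import warnings
from os import PathLike
from typing import IO, Iterable, Union

from .schedule import SamplingSchedule

__all__ = ["write_schedule", "read_schedule", "ScheduleFormatError"]

Destination = Union[str, PathLike, IO[str]]


class ScheduleFormatError(ValueError):
    """Raised for malformed schedule files."""


def write_schedule(
    schedule: SamplingSchedule,
    destination: Destination,
    one_based: bool = False,
    header: Iterable[str] = (),
) -> None:
    """Write ascending sample indices, one per line.

    ``header`` lines are emitted first, each prefixed with ``"# "``.
    """
    offset = 1 if one_based else 0
    lines = [f"# {line}" for line in header]
    lines += [str(int(g) + offset) for g in schedule.indices]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="ascii") as fh:
            fh.write(text)


def read_schedule(
    source: Destination, grid_size: int, one_based: bool = False
) -> SamplingSchedule:
    """Read a sample-list file back into a schedule.

    ``#`` comment lines and blank lines are ignored; duplicate indices
    are deduplicated with a warning; out-of-range or non-integer entries
    raise :class:`ScheduleFormatError` naming the offending line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="ascii") as fh:
            text = fh.read()
    offset = 1 if one_based else 0
    indices: list[int] = []
    seen: set[int] = set()
    duplicates = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            value = int(line)
        except ValueError:
            raise ScheduleFormatError(
                f"line {lineno}: non-integer token {line!r}"
            ) from None
        g = value - offset
        if not 0 <= g < grid_size:
            raise ScheduleFormatError(
                f"line {lineno}: index {value} out of range for grid of "
                f"{grid_size} points"
            )
        if g in seen:
            duplicates += 1
            continue
        seen.add(g)
        indices.append(g)
    if duplicates:
        warnings.warn(
            f"schedule file contained {duplicates} duplicate indices; deduplicated",
            stacklevel=2,
        )
    return SamplingSchedule.from_indices(sorted(indices), grid_size)
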