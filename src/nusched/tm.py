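"""The Thue-Morse binary sequence and its pattern-resistance checks.

The Thue-Morse (TM) sequence is built by starting from a single symbol and
repeatedly appending the bitwise complement of everything so far:
``1 -> 1 0 -> 1 0 0 1 -> 1 0 0 1 0 1 1 0 -> ...``.  Equivalently, symbol
``i`` of the 0-start sequence is the parity of the number of set bits of
``i``; the 1-start sequence is its complement.  The sequence is cube-free:
it contains no substring ``X X X`` for any binary string ``X``, which is
the property the local decoherence filter exploits.

Symbols are materialized lazily through the bit-parity closed form, so an
arbitrary window of the infinite sequence costs O(length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _popcount_parity(values: np.ndarray) -> np.ndarray:
    # vectorized parity of set bits; values fit in int64
    v = values.astype(np.uint64)
    parity = np.zeros_like(v)
    while v.any():
        parity ^= v & np.uint64(1)
        v >>= np.uint64(1)
    return parity.astype(np.int8)


def generate_tm(start_symbol: int, length: int) -> np.ndarray:
    """First ``length`` symbols of the TM sequence beginning with ``start_symbol``.

    >>> generate_tm(1, 8)
    array([1, 0, 0, 1, 0, 1, 1, 0], dtype=int8)
    """
    if start_symbol not in (0, 1):
        raise ValueError("start_symbol must be 0 or 1")
    if length < 1:
        raise ValueError("length must be positive")
    parity = _popcount_parity(np.arange(length, dtype=np.int64))
    return (parity ^ start_symbol).astype(np.int8)


@dataclass(frozen=True)
class ThueMorseSlice:
    """A window of the infinite TM sequence.

    ``symbols[i] = start_symbol XOR parity_of_set_bits(offset + i)``.
    """

    start_symbol: int
    offset: int
    symbols: np.ndarray

    @property
    def length(self) -> int:
        return int(self.symbols.size)


def tm_slice(start_symbol: int, offset: int, length: int) -> ThueMorseSlice:
    """Window ``[offset, offset + length)`` of the infinite TM sequence."""
    if start_symbol not in (0, 1):
        raise ValueError("start_symbol must be 0 or 1")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if length < 1:
        raise ValueError("length must be positive")
    positions = np.arange(offset, offset + length, dtype=np.int64)
    symbols = (_popcount_parity(positions) ^ start_symbol).astype(np.int8)
    symbols.setflags(write=False)
    return ThueMorseSlice(start_symbol=start_symbol, offset=offset, symbols=symbols)


def find_cube(sequence) -> tuple[int, int] | None:
    """First cube ``X X X`` in a binary sequence, or ``None`` if cube-free.

    Searches every (start, block-length) pair; the reported occurrence is
    the one with the lowest start index, ties broken by the shortest block.

    >>> find_cube([1, 0, 1, 0, 1, 0])
    (0, 2)
    """
    seq = np.asarray(sequence, dtype=np.int8)
    n = seq.size
    candidates: list[tuple[int, int]] = []
    for block in range(1, n // 3 + 1):
        # eq[s] == True iff seq[s] == seq[s + block]; a cube of this block
        # length at start s needs eq[s : s + 2*block] all true.
        eq = seq[: n - block] == seq[block:]
        window = 2 * block
        if eq.size < window:
            continue
        cum = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
        run = cum[window:] - cum[:-window]  # sliding window-sum of eq
        starts = np.flatnonzero(run == window)
        if starts.size:
            candidates.append((int(starts[0]), block))
    if not candidates:
        return None
    return min(candidates, key=lambda sb: (sb[0], sb[1]))
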