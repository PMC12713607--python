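"""The sampling-schedule container shared by every stage of the toolkit.

A 1D-NUS schedule is a binary mask over an ``N``-point Nyquist grid of
indirect-dimension evolution increments: ``mask[g] = 1`` means increment
``g`` is acquired.  All generators and filters in this package consume and
produce :class:`SamplingSchedule` objects; file I/O lives in
:mod:`nusched.schedfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SamplingSchedule:
    """Binary sampling mask over an ``N``-point Nyquist grid.

    Parameters
    ----------
    mask : numpy.ndarray
        One-dimensional 0/1 integer array of length ``N``.

    Attributes
    ----------
    grid_size : int
        Number of Nyquist increments ``N``.
    sample_count : int
        Number of acquired increments ``n`` (ones in the mask).
    indices : numpy.ndarray
        Sorted, unique acquired grid indices in ``[0, N-1]``.
    """

    mask: np.ndarray = field()

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 1 or mask.size == 0:
            raise ValueError("mask must be a non-empty 1-D array")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "mask", mask.astype(np.int8))
        self.mask.setflags(write=False)

    @property
    def grid_size(self) -> int:
        return int(self.mask.size)

    @property
    def sample_count(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def coverage(self) -> float:
        """Fraction of grid points sampled, ``n / N``."""
        return self.sample_count / self.grid_size

    @classmethod
    def from_indices(cls, indices, grid_size: int) -> "SamplingSchedule":
        """Build a schedule from acquired grid indices.

        Raises
        ------
        ValueError
            If an index falls outside ``[0, grid_size - 1]`` or appears twice.
        """
        idx = np.asarray(indices, dtype=np.int64).ravel()
        if grid_size < 1:
            raise ValueError("grid_size must be positive")
        if idx.size and (idx.min() < 0 or idx.max() >= grid_size):
            raise ValueError(
                f"sample index out of range for grid of {grid_size} points"
            )
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate sample indices")
        mask = np.zeros(grid_size, dtype=np.int8)
        mask[idx] = 1
        return cls(mask)

    def with_mask(self, mask: np.ndarray) -> "SamplingSchedule":
        """Return a new schedule with the given mask (same grid)."""
        return SamplingSchedule(mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SamplingSchedule):
            return NotImplemented
        return self.mask.shape == other.mask.shape and bool(
            (self.mask == other.mask).all()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SamplingSchedule(N={self.grid_size}, n={self.sample_count}, "
            f"coverage={self.coverage:.4f})"
        )
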