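"""Point-spread-function diagnostics of a sampling schedule.

The point spread function (PSF) is the discrete Fourier transform of the
0/1 sampling mask; any reconstructed spectrum is the true spectrum
convolved with it, so non-central PSF features measure the sampling
artifacts a schedule will imprint.  For a mask with ``n`` samples the DC
coefficient equals ``n``, the coefficients are conjugate-symmetric, and
Parseval fixes the total power at ``N * n`` regardless of where the
samples sit — only the *distribution* of PSF power can be shaped.

This module computes the PSF, strips its central peak (which convolves
with true signal and needs no treatment), applies a rank-based soft
threshold to isolate the strongest sidelobes, and inverse-transforms the
thresholded PSF into a time-domain PSF (td-PSF) whose per-grid-point
amplitudes drive the polisher's swap selection.  The scalar summary is
the peak-to-sidelobe ratio (PSR), used here as sidelobe/central so that
smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import SamplingSchedule

__all__ = [
    "PointSpreadFunction",
    "ThresholdedPsf",
    "compute_psf",
    "trim_central_peak",
    "soft_threshold",
    "td_psf",
    "psr",
]


@dataclass(frozen=True)
class PointSpreadFunction:
    """DFT coefficients of a sampling mask with central-peak bookkeeping.

    ``coefficients`` follow standard DFT ordering (DC at bin 0);
    ``central_exclusion`` holds the bins assigned to the central peak.
    """

    coefficients: np.ndarray
    grid_size: int
    sample_count: int
    central_exclusion: frozenset[int]

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def sidelobe_bins(self) -> np.ndarray:
        """Bins outside the central exclusion, ascending."""
        keep = np.ones(self.grid_size, dtype=bool)
        keep[list(self.central_exclusion)] = False
        return np.flatnonzero(keep)


@dataclass(frozen=True)
class ThresholdedPsf:
    """Sidelobe bins surviving the rank-``k`` soft threshold.

    ``coefficients`` hold the retained complex values after shrinking each
    magnitude by the threshold ``lam`` (phases preserved); all other bins
    are zero.  ``retained_bins`` is closed under ``k <-> N-k`` symmetry.
    """

    retained_bins: frozenset[int]
    coefficients: np.ndarray
    lam: float
    selection_threshold: float
    rank: int


def compute_psf(schedule: SamplingSchedule) -> PointSpreadFunction:
    """N-point DFT of the mask, no zero-filling; DC alone starts excluded."""
    coefficients = np.fft.fft(schedule.mask.astype(float))
    coefficients.setflags(write=False)
    return PointSpreadFunction(
        coefficients=coefficients,
        grid_size=schedule.grid_size,
        sample_count=schedule.sample_count,
        central_exclusion=frozenset({0}),
    )


def trim_central_peak(psf: PointSpreadFunction) -> PointSpreadFunction:
    """Assign the central peak's flanks to the exclusion set.

    Walking outward from DC independently in each frequency direction
    (cyclically), bins are excluded while the magnitudes strictly
    decrease; the first nondecreasing bin is retained as a sidelobe.  A
    bin of zero magnitude also terminates the walk and is retained: a
    vanished coefficient is no longer part of the peak's flank.
    """
    N = psf.grid_size
    mags = psf.magnitudes
    excluded = {0}
    for step in (1, -1):
        prev = mags[0]
        for d in range(1, N):
            b = (step * d) % N
            if b == 0 or b in excluded:
                break  # wrapped onto DC or onto the other flank
            if 0 < mags[b] < prev:
                excluded.add(b)
                prev = mags[b]
            else:
                break
    return PointSpreadFunction(
        coefficients=psf.coefficients,
        grid_size=N,
        sample_count=psf.sample_count,
        central_exclusion=frozenset(excluded),
    )


def soft_threshold(psf: PointSpreadFunction, tau: float = 0.01) -> ThresholdedPsf:
    """Rank-based soft threshold of the trimmed PSF.

    The non-excluded magnitudes are ranked in decreasing order; the
    threshold ``lam`` is the magnitude at rank ``k = max(1, round(N*tau))``
    (clipped to the number of candidates).  Bins with magnitude ``>= lam``
    are retained together with their symmetric partners, and each retained
    magnitude is shrunk by ``lam`` with its phase preserved.
    """
    if not (0 < tau <= 1):
        raise ValueError("tau must lie in (0, 1]")
    N = psf.grid_size
    candidates = psf.sidelobe_bins()
    if candidates.size == 0:
        raise ValueError("no non-excluded bins to threshold")
    mags = psf.magnitudes
    k = max(1, int(np.floor(N * tau + 0.5)))
    k = min(k, candidates.size)
    order = np.sort(mags[candidates])[::-1]
    lam = float(order[k - 1])
    # zero-magnitude bins carry no feature and are never retained
    retained = set(
        candidates[(mags[candidates] >= lam) & (mags[candidates] > 0)].tolist()
    )
    retained |= {(N - b) % N for b in retained}
    retained -= set(psf.central_exclusion)
    coefficients = np.zeros(N, dtype=complex)
    for b in sorted(retained):
        m = mags[b]
        if m > 0:
            coefficients[b] = psf.coefficients[b] * max(m - lam, 0.0) / m
    coefficients.setflags(write=False)
    return ThresholdedPsf(
        retained_bins=frozenset(retained),
        coefficients=coefficients,
        lam=lam,
        selection_threshold=tau,
        rank=k,
    )


def td_psf(tpsf: ThresholdedPsf, psf: PointSpreadFunction) -> np.ndarray:
    """Time-domain PSF: absolute amplitudes of the IFT of the thresholded PSF.

    The retained bin set is symmetric, so the inverse transform is real to
    numerical tolerance; the imaginary residue is checked and discarded.
    """
    N = psf.grid_size
    for b in tpsf.retained_bins:
        if (N - b) % N not in tpsf.retained_bins:
            raise AssertionError("retained bins are not conjugate-symmetric")
    amplitudes = np.fft.ifft(tpsf.coefficients)
    scale = np.abs(amplitudes).max()
    # absolute floor guards the fully shrunk case where everything is ~eps
    if np.abs(amplitudes.imag).max() > 1e-9 * scale + 1e-12:
        raise AssertionError("td-PSF has a non-negligible imaginary part")
    return np.abs(amplitudes.real)


def export_psf_magnitudes(psf: PointSpreadFunction, destination) -> None:
    """Write PSF magnitudes as two-column text (bin, magnitude) for plotting."""
    lines = [f"{b}\t{m:.10g}" for b, m in enumerate(psf.magnitudes)]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="ascii") as fh:
            fh.write(text)


def psr(schedule: SamplingSchedule) -> float:
    """Peak-to-sidelobe ratio, cast as sidelobe/central so lower is better.

    The largest PSF magnitude outside the trimmed central peak divided by
    the DC magnitude ``n``; 0 when no sidelobe survives trimming.
    """
    if schedule.sample_count < 1:
        raise ValueError("schedule has no samples")
    trimmed = trim_central_peak(compute_psf(schedule))
    bins = trimmed.sidelobe_bins()
    if bins.size == 0:
        return 0.0
    top = float(trimmed.magnitudes[bins].max())
    return top / schedule.sample_count
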