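"""Hz labelling of the coefficient axis and tremor-peak location.

A spatially drawn spiral carries no time information by itself.  Given
the wall-clock drawing time ``t_to_draw`` (and assuming the hand moves
at a constant arc-length rate), coefficient ``k`` of the signal's DFT
corresponds to ``k`` cycles over the retained record, whose effective
duration is ``t_to_draw * cropping_ratio``.  Coefficient ``k`` thus
maps to

    f_k = k / (t_to_draw * cropping_ratio)   [Hz]

Essential-tremor and parkinsonian tremor live below ~12 Hz, so the peak
search is restricted to a band of interest (default 1–12 Hz; the lower
edge excludes the drawing's slow drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoPeakError, ValidationError
from .spectral import SpectralResult

DEFAULT_BAND_HZ = (1.0, 12.0)


@dataclass(frozen=True)
class FrequencyAxis:
    """Mapping from DFT coefficient index to Hz."""

    hz_per_index: float
    t_to_draw: float
    cropping_ratio: float
    band_of_interest: tuple[float, float] = DEFAULT_BAND_HZ

    def __post_init__(self) -> None:
        if self.hz_per_index <= 0:
            raise ValidationError("hz_per_index must be positive")
        lo, hi = self.band_of_interest
        if not lo < hi:
            raise ValidationError("band_of_interest must satisfy low < high")

    def frequency(self, k: int | np.ndarray) -> float | np.ndarray:
        return k * self.hz_per_index


def build_axis(
    spec: SpectralResult,
    t_to_draw: float,
    cropping_ratio: float,
    band_of_interest: tuple[float, float] = DEFAULT_BAND_HZ,
) -> FrequencyAxis:
    """Construct the Hz axis for a spectrum given the drawing time.

    The retained record spans ``t_to_draw * cropping_ratio`` seconds,
    so the DFT bin width is its reciprocal.
    """
    if t_to_draw is None or t_to_draw <= 0:
        raise ValidationError("t_to_draw must be a positive number of seconds")
    if not (0.0 < cropping_ratio <= 1.0):
        raise ValidationError("cropping_ratio must be in (0, 1]")
    return FrequencyAxis(
        hz_per_index=1.0 / (t_to_draw * cropping_ratio),
        t_to_draw=float(t_to_draw),
        cropping_ratio=float(cropping_ratio),
        band_of_interest=band_of_interest,
    )


def peak_frequency(spec: SpectralResult, axis: FrequencyAxis) -> tuple[float, float]:
    """Frequency (Hz) and magnitude of the strongest in-band coefficient.

    Searches only indices whose frequency lies inside
    ``axis.band_of_interest``; exact ties resolve to the lower
    frequency.

    Raises
    ------
    NoPeakError
        If no coefficient falls in the band or every in-band magnitude
        is zero (e.g. a tremor-free drawing after low-pass filtering).
    """
    k = np.arange(spec.ncoeff)
    f = axis.frequency(k)
    lo, hi = axis.band_of_interest
    in_band = (f >= lo) & (f <= hi)
    if not in_band.any():
        raise NoPeakError(
            f"no DFT coefficient falls inside the {lo}-{hi} Hz band"
        )
    mags = np.where(in_band, spec.magnitude, -np.inf)
    k_peak = int(np.argmax(mags))  # argmax takes the first (lowest-f) maximum
    if spec.magnitude[k_peak] <= 0.0:
        raise NoPeakError("spectrum carries no energy inside the band of interest")
    return float(f[k_peak]), float(spec.magnitude[k_peak])
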