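"""Real-DFT feature reduction of the extracted signal.

The N-sample deviation signal is transformed with the real FFT, giving
``Ncoeff = N/2 + 1`` magnitude/phase pairs.  High-frequency noise is
removed with a brick-wall low-pass at a fraction (default 0.4) of
Ncoeff, and the spectrum is truncated to a small leading set of
``ntrunc`` coefficients (150 by default) — 2*ntrunc numbers in place of
N samples.  The quality of that reduced representation is quantified by
the percent RMS error between the original signal and the inverse FFT
of the truncated spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import ValidationError
from .signal_extraction import DiscreteSignal

DEFAULT_LP_FRAC = 0.4
DEFAULT_NTRUNC = 150
SAVGOL_WINDOW = 51
SAVGOL_POLYORDER = 3


@dataclass(frozen=True)
class SpectralResult:
    """Magnitude/phase coefficients of a real DFT.

    ``magnitude[k]`` and ``phase[k]`` describe coefficient ``k`` of the
    one-sided real DFT of an N-sample signal; ``Ncoeff = N//2 + 1``.
    ``lp_cutoff_index`` / ``ntrunc`` record the filtering and truncation
    applied (``None`` if not applied).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    N: int
    lp_cutoff_index: int | None = None
    ntrunc: int | None = None

    @property
    def ncoeff(self) -> int:
        return self.N // 2 + 1

    def complex_coefficients(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


def forward_fft(sig: DiscreteSignal | np.ndarray) -> SpectralResult:
    """Real DFT of the signal as magnitude/phase pairs.

    Requires an even sample count (the resampler always emits even N)
    so that ``Ncoeff = N/2 + 1`` exactly.
    """
    y = sig.y if isinstance(sig, DiscreteSignal) else np.asarray(sig, dtype=np.float64)
    n = y.shape[0]
    if n < 4 or n % 2:
        raise ValidationError(f"signal length must be even and >= 4, got {n}")
    coeff = np.fft.rfft(y)
    return SpectralResult(
        magnitude=np.abs(coeff), phase=np.angle(coeff), N=n
    )


def inverse_fft(spec: SpectralResult) -> np.ndarray:
    """Length-N real signal reconstructed from the coefficient set."""
    return np.fft.irfft(spec.complex_coefficients(), n=spec.N)


def low_pass(spec: SpectralResult, frac: float = DEFAULT_LP_FRAC) -> SpectralResult:
    """Brick-wall low-pass: zero all coefficients above ``floor(frac*Ncoeff)``.

    Removes high-frequency noise well outside the tremor band.  Phases
    of zeroed coefficients are set to 0 for determinism.
    """
    if not (0.0 < frac <= 1.0):
        raise ValidationError(f"frac must be in (0, 1], got {frac}")
    cutoff = int(np.floor(frac * spec.ncoeff))
    keep = np.arange(spec.ncoeff) <= cutoff
    return SpectralResult(
        magnitude=np.where(keep, spec.magnitude, 0.0),
        phase=np.where(keep, spec.phase, 0.0),
        N=spec.N,
        lp_cutoff_index=cutoff,
        ntrunc=spec.ntrunc,
    )


def truncate(spec: SpectralResult, ntrunc: int = DEFAULT_NTRUNC) -> SpectralResult:
    """Keep only the first ``ntrunc`` magnitude/phase pairs.

    The reduced representation needs ``2*ntrunc`` numbers (magnitude and
    phase are both required to invert).
    """
    if not (1 <= ntrunc <= spec.ncoeff):
        raise ValidationError(
            f"ntrunc must be in [1, {spec.ncoeff}], got {ntrunc}"
        )
    keep = np.arange(spec.ncoeff) < ntrunc
    return SpectralResult(
        magnitude=np.where(keep, spec.magnitude, 0.0),
        phase=np.where(keep, spec.phase, 0.0),
        N=spec.N,
        lp_cutoff_index=spec.lp_cutoff_index,
        ntrunc=ntrunc,
    )


def rms_error_pct(
    a: np.ndarray, b: np.ndarray, denominator: str = "signal"
) -> float:
    """Percent RMS difference between a reference signal and a reconstruction.

    ``100 * RMS(a - b) / RMS(a)`` with ``a`` the untruncated signal.
    ``denominator="bound"`` divides by the fixed 1000-px normalization
    bound instead of the signal RMS.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError("signals must have equal length")
    num = float(np.sqrt(np.mean((a - b) ** 2)))
    if denominator == "signal":
        den = float(np.sqrt(np.mean(a**2)))
        if den == 0.0:
            raise ValidationError("reference signal has zero RMS")
    elif denominator == "bound":
        den = 1000.0
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return 100.0 * num / den


def parameter_reduction_factor(n_original_pixels: int, ntrunc: int) -> float:
    """Factor by which the truncated representation shrinks the raw profile.

    ``n_original_pixels / (2*ntrunc)`` — e.g. a 3228-pixel profile kept
    as 150 magnitude + 150 phase coefficients is a 10.76-fold reduction.
    """
    if n_original_pixels <= 0 or ntrunc <= 0:
        raise ValidationError("counts must be positive")
    return n_original_pixels / (2.0 * ntrunc)


def savgol_display(
    magnitude: np.ndarray,
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_POLYORDER,
) -> np.ndarray:
    """Savitzky–Golay-smoothed copy of a magnitude spectrum, for plots only.

    The input array is never modified; smoothing must not leak into any
    analysis quantity.
    """
    if window % 2 == 0 or window < 3 or polyorder >= window:
        raise ValidationError(
            f"window must be odd >= 3 and polyorder < window (got {window}, {polyorder})"
        )
    magnitude = np.asarray(magnitude, dtype=np.float64)
    return savgol_filter(magnitude, window_length=window, polyorder=polyorder)


def feature_vector(spec: SpectralResult, rms_raw: float) -> np.ndarray:
    """Reduced feature set: ntrunc magnitudes, ntrunc phases, and rms_raw.

    The signal is normalized before the FFT, so the pre-normalization
    RMS is appended to retain amplitude information — 2*ntrunc + 1
    values in total.
    """
    if spec.ntrunc is None:
        raise ValidationError("truncate() the spectrum before exporting features")
    k = spec.ntrunc
    return np.concatenate([spec.magnitude[:k], spec.phase[:k], [rms_raw]])
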