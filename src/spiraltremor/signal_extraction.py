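"""From a cropped flattened band to a uniform, normalized 1-D signal.

The cropped flattened image still holds a multi-pixel-wide stroke.  A
single-valued profile is read off column by column: scanning upward,
the first pixel whose density reaches a threshold wins (this is what
latches onto the lower branch when the drawing loops over itself); a
column whose ink never reaches the threshold falls back to its darkest
pixel.  The abscissa is then converted from the flattened angle
``phi = theta + theta_r`` to arc length ``s = b*phi**2/2``, a noise
sliver near the spiral center may be cropped away, and the profile is
resampled onto N uniform arc-length samples and normalized to zero mean
with peak magnitude 1000 pixels.

The fraction of the originally extracted arc-length extent that
survives all cropping steps is accumulated in ``cropping_ratio``; it
later rescales the drawing time when labelling the spectrum in Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSignalError,
    EmptySignalError,
    NoSignalError,
    ValidationError,
)
from .flattening import FlattenedImage
from .spiral_geometry import SpiralParams

DEFAULT_THRESHOLD = 0.5
DEFAULT_N = 1000
MAX_GAP_FRACTION = 0.05
NORM_BOUND = 1000.0


@dataclass
class RawProfile:
    """Per-column profile before resampling.

    ``x`` is the flattened abscissa (or arc length after
    :func:`to_arc_length`), ``y`` the deviation in source pixels, and
    ``missing`` marks columns with no ink at all.
    """

    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    params: SpiralParams
    n_original_pixels: int
    alpha: float = 1.0
    cropping_ratio: float = 1.0
    is_arc_length: bool = False


@dataclass
class DiscreteSignal:
    """N uniformly spaced samples of hand-drawing deviation vs arc length."""

    s: np.ndarray
    y: np.ndarray
    N: int
    cropping_ratio: float
    rms_raw: float
    n_original_pixels: int
    t_to_draw: float | None = None
    params: SpiralParams | None = None


def extract_profile(
    fimg: FlattenedImage, threshold: float = DEFAULT_THRESHOLD
) -> RawProfile:
    """Read a single-valued profile off a cropped flattened band.

    For each x-column the rows are scanned in increasing y and the first
    density >= ``threshold`` is taken; a column that never reaches the
    threshold contributes its darkest pixel instead, and a column with
    no ink at all is marked missing.  ``n_original_pixels`` counts the
    non-missing columns.
    """
    dens = fimg.density
    hit = dens >= threshold
    has_hit = hit.any(axis=0)
    first_hit = hit.argmax(axis=0)
    col_max = dens.max(axis=0)
    fallback = col_max > 0.0
    idx = np.where(has_hit, first_hit, dens.argmax(axis=0))
    missing = ~(has_hit | fallback)
    if missing.all():
        raise NoSignalError("every column of the cropped band is empty")
    y = fimg.y_axis[idx] / fimg.config.beta  # deviation in source pixels
    y = np.where(missing, np.nan, y)
    return RawProfile(
        x=fimg.x_axis.copy(),
        y=y,
        missing=missing,
        params=fimg.params,
        n_original_pixels=int((~missing).sum()),
        alpha=fimg.config.alpha,
    )


def to_arc_length(profile: RawProfile) -> RawProfile:
    """Convert the profile abscissa from flattened angle to arc length.

    ``s = b * phi**2 / 2`` with ``phi = x / alpha``; the map is
    monotone, so sample order is preserved (spacing becomes
    quadratically stretched).
    """
    if profile.is_arc_length:
        return profile
    phi = profile.x / profile.alpha  # flattened x is alpha*phi
    s = 0.5 * profile.params.b * phi * phi
    return RawProfile(
        x=s,
        y=profile.y.copy(),
        missing=profile.missing.copy(),
        params=profile.params,
        n_original_pixels=profile.n_original_pixels,
        alpha=profile.alpha,
        cropping_ratio=profile.cropping_ratio,
        is_arc_length=True,
    )


def crop_noise_region(profile: RawProfile, s_min: float) -> RawProfile:
    """Drop samples with ``s < s_min`` (noise sliver near the center).

    The removed fraction of the arc-length extent is folded into
    ``cropping_ratio``.
    """
    if s_min < 0:
        raise ValidationError("s_min must be >= 0")
    if not profile.is_arc_length:
        raise ValidationError("crop_noise_region expects an arc-length profile")
    if s_min <= profile.x[0]:
        return profile
    keep = profile.x >= s_min
    if not keep.any():
        raise EmptySignalError(f"s_min={s_min} removes every sample")
    extent_before = profile.x[-1] - profile.x[0]
    x = profile.x[keep]
    extent_after = x[-1] - x[0]
    ratio = profile.cropping_ratio * (
        extent_after / extent_before if extent_before > 0 else 1.0
    )
    return RawProfile(
        x=x,
        y=profile.y[keep],
        missing=profile.missing[keep],
        params=profile.params,
        n_original_pixels=profile.n_original_pixels,
        alpha=profile.alpha,
        cropping_ratio=ratio,
        is_arc_length=True,
    )


def resample_and_normalize(
    profile: RawProfile,
    N: int = DEFAULT_N,
    t_to_draw: float | None = None,
) -> DiscreteSignal:
    """Fill gaps, resample onto N uniform arc-length points, normalize.

    Missing columns are filled by linear interpolation between their
    neighbours (gaps wider than 5 % of the extent raise a warning);
    leading/trailing missing columns are trimmed and the trimmed
    fraction folded into ``cropping_ratio``.  The pre-normalization,
    mean-removed RMS is recorded in pixels, then the signal is scaled to
    zero mean with max |y| = 1000.
    """
    if N < 4 or N % 2:
        raise ValidationError(f"N must be even and >= 4, got {N}")
    good = ~profile.missing & np.isfinite(profile.y)
    if good.sum() < 2:
        raise NoSignalError("fewer than 2 non-missing samples to resample")
    xg = profile.x[good]
    yg = profile.y[good]
    gaps = np.diff(xg)
    extent_full = profile.x[-1] - profile.x[0]
    if extent_full > 0 and np.any(gaps > MAX_GAP_FRACTION * extent_full):
        warnings.warn(
            "profile has a gap wider than 5% of its extent; interpolation "
            "across it may distort the signal",
            stacklevel=2,
        )
    ratio = profile.cropping_ratio
    if extent_full > 0:
        ratio *= (xg[-1] - xg[0]) / extent_full
    s = np.linspace(xg[0], xg[-1], N)
    y = np.interp(s, xg, yg)
    y = y - y.mean()
    rms_raw = float(np.sqrt(np.mean(y * y)))
    peak = float(np.max(np.abs(y)))
    if peak < 1e-9:  # flat to well below any pixel scale
        raise DegenerateSignalError("profile is constant; cannot normalize")
    y = y * (NORM_BOUND / peak)
    y = y - y.mean()  # re-center after scaling (no-op up to rounding)
    return DiscreteSignal(
        s=s,
        y=y,
        N=N,
        cropping_ratio=float(ratio),
        rms_raw=rms_raw,
        n_original_pixels=profile.n_original_pixels,
        t_to_draw=t_to_draw,
        params=profile.params,
    )


def amplitude_rms(sig: DiscreteSignal) -> float:
    """Tremor amplitude: pre-normalization, mean-removed RMS in pixels."""
    return sig.rms_raw
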