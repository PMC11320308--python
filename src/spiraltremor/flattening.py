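"""Zone-family mapping of the spiral image into Flattened Space.

A pixel at polar coordinates ``r, theta'`` about the spiral origin maps
to the flattened point

    x = alpha * (theta + theta_r),   y = beta * (r - b*(theta + theta_r))

where ``theta = theta' + 2*pi*(n-1)`` unwraps the polar angle with the
pixel's turn index (zone) ``n``.  The image gives no way to know a
pixel's zone, so every ink pixel is mapped once *per candidate* ``n`` in
a short list.  The correctly-unwrapped copies of each curve then stitch
themselves into one continuous band, while the wrong-``n`` copies form
parallel bands offset vertically by multiples of ``2*pi*b`` — the
reference spiral becomes a family of horizontal lines at
``y = 2*pi*b*k`` and the hand drawing a family of parallel wiggly
curves.  A crop rectangle then isolates a single stitched band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CropError, EmptyImageError
from .image_io import InkImage
from .spiral_geometry import TWO_PI, PolarPoint, SpiralParams

DEFAULT_N_LIST = (1, 2, 3, 4)


@dataclass(frozen=True)
class FlattenConfig:
    """Parameters of the flattening map and its target raster.

    alpha, beta:
        Scale constants of the mapping; 1 keeps flattened units equal to
        radians (x) and source pixels (y).
    n_list:
        Candidate zone indices used for the family mapping; must cover
        every turn of the drawing.
    density_floor:
        Ink density below which a source pixel is not mapped (skips the
        background).
    x_pitch, y_pitch:
        Flattened-grid spacing; ``None`` picks x_pitch so that one
        column matches one source pixel on the average ring and
        y_pitch = one source pixel.
    """

    alpha: float = 1.0
    beta: float = 1.0
    n_list: tuple[int, ...] = DEFAULT_N_LIST
    density_floor: float = 0.1
    x_pitch: float | None = None
    y_pitch: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if len(self.n_list) == 0 or any(
            b <= a for a, b in zip(self.n_list, self.n_list[1:])
        ) or self.n_list[0] < 1:
            raise ValueError("n_list must be non-empty strictly increasing positive ints")
        if not (0.0 <= self.density_floor < 1.0):
            raise ValueError("density_floor must be in [0, 1)")


@dataclass
class FlattenedImage:
    """Raster in flattened coordinates.

    ``density[j, i]`` holds the ink at ``(x_axis[i], y_axis[j])``; both
    axes are uniform and strictly increasing.  ``retained_x`` records
    the x-extent kept by the most recent crop for cropping-ratio
    bookkeeping.
    """

    density: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    params: SpiralParams
    config: FlattenConfig = field(default_factory=FlattenConfig)
    retained_x: tuple[float, float] | None = None

    @property
    def x_pitch(self) -> float:
        return float(self.x_axis[1] - self.x_axis[0])

    @property
    def y_pitch(self) -> float:
        return float(self.y_axis[1] - self.y_axis[0])


def flatten_point(
    p: PolarPoint, params: SpiralParams, cfg: FlattenConfig = FlattenConfig()
) -> list[tuple[float, float]]:
    """Map one polar point to its family of flattened points.

    Returns one ``(x, y)`` per candidate zone in ``cfg.n_list``;
    consecutive members are spaced by exactly
    ``(2*pi*alpha, -2*pi*b*beta)``.
    """
    out = []
    for n in cfg.n_list:
        theta = p.theta + TWO_PI * (n - 1)
        phi = theta + params.theta_r
        out.append((cfg.alpha * phi, cfg.beta * (p.r - params.b * phi)))
    return out


def flatten_image(
    img: InkImage, params: SpiralParams, cfg: FlattenConfig = FlattenConfig()
) -> FlattenedImage:
    """Flatten every sufficiently inked pixel of a spiral image.

    Each source pixel with density >= ``cfg.density_floor`` is mapped
    via the zone family; every mapped point with ``x >= 0`` deposits the
    pixel's density into the nearest flattened-grid cell, aggregating by
    maximum so the darkest ink wins (matching the darkest-pixel
    extraction rule downstream).
    """
    x0, y0 = params.origin
    ys, xs = np.nonzero(img.density >= cfg.density_floor)
    if ys.size == 0:
        raise EmptyImageError("no pixel at or above the density floor")
    dens = img.density[ys, xs]
    dx = xs.astype(np.float64) - x0
    dy = ys.astype(np.float64) - y0
    r = np.hypot(dx, dy)
    keep = r > 0.0
    dx, dy, r, dens = dx[keep], dy[keep], r[keep], dens[keep]
    theta_p = np.arctan2(dy, dx) % TWO_PI

    x_pitch = cfg.x_pitch
    if x_pitch is None:
        # one column per source pixel on the average inked ring
        x_pitch = cfg.alpha / max(float(np.mean(r)), 1.0)
    y_pitch = cfg.y_pitch if cfg.y_pitch is not None else cfg.beta * 1.0

    fx_parts, fy_parts, fd_parts = [], [], []
    for n in cfg.n_list:
        phi = theta_p + TWO_PI * (n - 1) + params.theta_r
        fx = cfg.alpha * phi
        fy = cfg.beta * (r - params.b * phi)
        m = fx >= 0.0
        fx_parts.append(fx[m])
        fy_parts.append(fy[m])
        fd_parts.append(dens[m])
    fx = np.concatenate(fx_parts)
    fy = np.concatenate(fy_parts)
    fd = np.concatenate(fd_parts)
    if fx.size == 0:
        raise EmptyImageError("no mapped point with x >= 0")

    ix = np.rint(fx / x_pitch).astype(np.intp)
    y_min = float(np.floor(fy.min() / y_pitch)) * y_pitch
    iy = np.rint((fy - y_min) / y_pitch).astype(np.intp)
    nx = int(ix.max()) + 1
    ny = int(iy.max()) + 1
    grid = np.zeros((ny, nx), dtype=np.float64)
    np.maximum.at(grid, (iy, ix), fd)
    x_axis = np.arange(nx) * x_pitch
    y_axis = y_min + np.arange(ny) * y_pitch
    return FlattenedImage(
        density=grid, x_axis=x_axis, y_axis=y_axis, params=params, config=cfg
    )


def crop_rect(
    fimg: FlattenedImage,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> FlattenedImage:
    """Extract the sub-image inside a flattened-space rectangle.

    Used to isolate one stitched hand-drawing band.  Keeping the
    ``x = 0`` edge inside the rectangle matters when a signal will be
    extracted next (otherwise the arc-length origin and the original
    pixel count are lost); a crop excluding it triggers a warning.
    """
    xm = (fimg.x_axis >= x_range[0]) & (fimg.x_axis <= x_range[1])
    ym = (fimg.y_axis >= y_range[0]) & (fimg.y_axis <= y_range[1])
    if not xm.any() or not ym.any():
        raise CropError(f"crop rectangle {x_range} x {y_range} misses the grid")
    if x_range[0] > 0.0:
        warnings.warn(
            "crop rectangle excludes x = 0; arc-length bookkeeping will be "
            "inaccurate for signal extraction",
            stacklevel=2,
        )
    sub = fimg.density[np.ix_(ym, xm)]
    x_axis = fimg.x_axis[xm]
    return FlattenedImage(
        density=sub.copy(),
        x_axis=x_axis,
        y_axis=fimg.y_axis[ym],
        params=fimg.params,
        config=fimg.config,
        retained_x=(float(x_axis[0]), float(x_axis[-1])),
    )
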