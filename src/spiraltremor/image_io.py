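"""Raster input, ink-density conversion, and all file outputs.

Scanned spiral drawings arrive as 8-bit greyscale or RGB rasters in
which dark ink sits on a light (often light-grey) background.  All the
downstream mathematics wants the opposite convention — larger value
means darker ink — so images are inverted on read into an *ink density*
in ``[0, 1]``.  Row order is flipped so that internal coordinates are
y-up; image files remain y-down on disk.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ImageReadError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .signal_extraction import DiscreteSignal

# Rec. 601 luma weights for RGB -> greyscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class InkImage:
    """2-D ink-density raster in y-up orientation.

    ``density[y, x]`` is in ``[0, 1]`` with 1 = fully dark ink and
    0 = white background; row index 0 is the *bottom* image row.
    """

    density: np.ndarray
    source_path: str = ""

    @property
    def height(self) -> int:
        return self.density.shape[0]

    @property
    def width(self) -> int:
        return self.density.shape[1]


def density_from_grey(grey: np.ndarray) -> np.ndarray:
    """Invert 8-bit grey values into ink density: ``1 - grey/255``."""
    return 1.0 - np.asarray(grey, dtype=np.float64) / 255.0


def grey_from_density(density: np.ndarray) -> np.ndarray:
    """Inverse of :func:`density_from_grey`, rounded back to uint8."""
    grey = np.rint((1.0 - np.asarray(density, dtype=np.float64)) * 255.0)
    return np.clip(grey, 0, 255).astype(np.uint8)


def contrast_stretch(density: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linearly rescale densities so the given percentiles map to 0 and 1.

    Values outside the percentile window are clipped.  Suppresses the
    light-grey background haze that photocopying introduces without
    touching the dark ink.  A constant image is returned unchanged.
    """
    lo, hi = np.percentile(density, [low_pct, high_pct])
    if hi <= lo:
        return density.copy()
    return np.clip((density - lo) / (hi - lo), 0.0, 1.0)


def read_image(path: str | Path, contrast_stretch_flag: bool = False) -> InkImage:
    """Read a PNG/JPEG/TIFF raster into an :class:`InkImage`.

    RGB input is converted to luminance with Rec. 601 weights; an alpha
    channel, if present, is ignored.  ``density = 1 - grey/255``; rows
    are flipped so the result is y-up.  With ``contrast_stretch_flag``
    the densities are rescaled so their 1st/99th percentiles map to 0/1.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ImageReadError(f"unsupported image shape {arr.shape} in {path}")
    if raw.dtype != np.uint8 and arr.max() > 255:
        raise ImageReadError(f"{path}: only 8-bit rasters are supported")
    density = density_from_grey(arr)
    density = np.flipud(density)  # y-up internally
    if contrast_stretch_flag:
        density = contrast_stretch(density)
    return InkImage(density=np.ascontiguousarray(density), source_path=str(path))


def write_image(img: InkImage, path: str | Path) -> None:
    """Write an :class:`InkImage` back to an 8-bit greyscale file."""
    grey = grey_from_density(np.flipud(img.density))
    iio.imwrite(Path(path), grey)


def write_signal_csv(signal: "DiscreteSignal", path: str | Path) -> None:
    """Save a discrete signal as CSV plus a JSON metadata sidecar.

    The CSV has header ``s,y`` with arc length (pixels) and deviation
    (normalized pixels).  The sidecar ``<path>.json`` carries the fitted
    spiral parameters and the bookkeeping needed to rebuild a Hz axis:
    cropping_ratio, pre-normalization RMS, drawing time, and N.
    """
    path = Path(path)
    df = pd.DataFrame({"s": signal.s, "y": signal.y})
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "N": int(signal.N),
        "cropping_ratio": float(signal.cropping_ratio),
        "rms_raw": float(signal.rms_raw),
        "n_original_pixels": int(signal.n_original_pixels),
        "t_to_draw": None if signal.t_to_draw is None else float(signal.t_to_draw),
    }
    if signal.params is not None:
        meta["spiral"] = {
            "b": float(signal.params.b),
            "theta_r": float(signal.params.theta_r),
            "origin": [float(v) for v in signal.params.origin],
        }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(str(csv_path) + ".json")


def read_signal_csv(path: str | Path) -> "DiscreteSignal":
    """Round-trip counterpart of :func:`write_signal_csv`."""
    from .signal_extraction import DiscreteSignal
    from .spiral_geometry import SpiralParams

    path = Path(path)
    df = pd.read_csv(path)
    if not {"s", "y"}.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns 's,y'")
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    params = None
    if "spiral" in meta:
        sp = meta["spiral"]
        params = SpiralParams(b=sp["b"], theta_r=sp["theta_r"], origin=tuple(sp["origin"]))
    return DiscreteSignal(
        s=df["s"].to_numpy(dtype=np.float64),
        y=df["y"].to_numpy(dtype=np.float64),
        N=int(meta.get("N", len(df))),
        cropping_ratio=float(meta.get("cropping_ratio", 1.0)),
        rms_raw=float(meta.get("rms_raw", float("nan"))),
        n_original_pixels=int(meta.get("n_original_pixels", len(df))),
        t_to_draw=meta.get("t_to_draw"),
        params=params,
    )


def append_log(logfile: str | Path, event: str) -> None:
    """Append a timestamped event line to the run log."""
    if not event or not event.strip():
        raise ValidationError("log event message must be non-empty")
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(logfile, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp}\t{event}\n")
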