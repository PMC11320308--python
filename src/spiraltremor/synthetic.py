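"""Synthetic spiral-drawing images with known ground truth.

Real inputs are scans of a printed reference Archimedes spiral with a
patient's pen drawing on top: arbitrary page rotation, multi-pixel
strokes of varying grey level, light-grey scan background, and assorted
artifacts (gaps where the pen lifted, small loops, strokes crossing the
reference, stray marks near the center).  This module emulates all of
that with a parametric model whose truth is known exactly, so every
pipeline stage can be tested without external data.

The tremulous hand is modelled as a radial sinusoid drawn at constant
arc-length speed: with total drawing time ``T`` over total arc length
``s_total``, the deviation from the reference spiral is

    d(s) = A * sin(2*pi * f * (s / s_total) * T + phase)

so a tremor of frequency ``f`` Hz completes ``f*T`` cycles along the
drawing.  The printed reference is rendered lighter than the pen stroke
(as in practice), which is what lets threshold-based extraction pick
the hand drawing off the shared flattened band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .image_io import InkImage, write_image
from .spiral_geometry import TWO_PI, SpiralParams

ARC_STEP = 0.4  # px between consecutive stamped points along a stroke


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to render one synthetic spiral drawing."""

    params: SpiralParams
    image_size: int = 1024
    turns: float = 4.0
    stroke_width_ref: float = 2.0
    stroke_width_hand: float = 3.0
    tremor_amplitude: float = 8.0  # px
    tremor_freq: float = 5.0  # Hz
    t_to_draw: float = 10.0  # s
    phase: float = 0.0
    background_grey: float = 0.06  # background ink density
    grey_jitter: float = 0.08  # stroke-intensity variation
    ref_ink: float = 0.40  # printed template is lighter than the pen
    hand_ink: float = 0.85
    artifacts: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tremor_amplitude < 0 or self.tremor_freq < 0:
            raise ValidationError("tremor amplitude and frequency must be >= 0")
        if self.t_to_draw <= 0:
            raise ValidationError("t_to_draw must be positive")
        if self.stroke_width_ref < 1 or self.stroke_width_hand < 1:
            raise ValidationError("stroke widths must be >= 1 px")
        unknown = set(self.artifacts) - {"gaps", "loops", "crossings", "origin_spike"}
        if unknown:
            raise ValidationError(f"unknown artifact flags: {sorted(unknown)}")

    @property
    def phi_max(self) -> float:
        return TWO_PI * self.turns

    @property
    def s_total(self) -> float:
        return 0.5 * self.params.b * self.phi_max**2


@dataclass
class GroundTruth:
    """Truth sidecar: the radial deviation actually drawn, densely sampled."""

    s: np.ndarray  # arc length, px
    d: np.ndarray  # radial deviation at s, px (includes artifact bumps)
    tremor_freq: float
    tremor_amplitude: float
    t_to_draw: float
    params: SpiralParams
    s_total: float


def default_params(
    image_size: int = 1024,
    turns: float = 4.0,
    theta_r: float = 0.0,
    origin: tuple[float, float] | None = None,
    fill: float = 0.45,
) -> SpiralParams:
    """Spiral scale chosen so the outermost turn fills ``fill`` of the image."""
    if origin is None:
        origin = (image_size / 2.0, image_size / 2.0)
    b = fill * image_size / (TWO_PI * turns)
    return SpiralParams(b=b, theta_r=theta_r, origin=origin)


def _arc_samples(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Uniform arc-length samples: (s, phi) with phi = sqrt(2 s / b)."""
    n = max(int(spec.s_total / ARC_STEP), 64)
    s = np.linspace(0.0, spec.s_total, n)
    phi = np.sqrt(2.0 * s / spec.params.b)
    return s, phi


def _ink_levels(
    n: int, base: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Slowly varying stroke intensity, like a pen's uneven ink flow."""
    if jitter <= 0:
        return np.full(n, base)
    noise = rng.standard_normal(n)
    smooth = uniform_filter1d(noise, size=max(n // 40, 5), mode="nearest")
    scale = smooth.std() or 1.0
    return np.clip(base + jitter * smooth / scale, 0.15, 1.0)


def _stamp(
    canvas: np.ndarray,
    px: np.ndarray,
    py: np.ndarray,
    width: float,
    levels: np.ndarray,
) -> None:
    """Stamp anti-aliased disks of diameter ``width`` at sub-pixel centers."""
    half = width / 2.0
    k = int(math.ceil(half + 0.5))
    offs = np.arange(-k, k + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    cx = np.rint(px).astype(np.intp)
    cy = np.rint(py).astype(np.intp)
    gx = cx[:, None, None] + ox[None]
    gy = cy[:, None, None] + oy[None]
    dist = np.hypot(gx - px[:, None, None], gy - py[:, None, None])
    cover = np.clip(half + 0.5 - dist, 0.0, 1.0)
    val = levels[:, None, None] * cover
    h, w = canvas.shape
    ok = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h) & (val > 0)
    np.maximum.at(canvas, (gy[ok], gx[ok]), val[ok])


def _check_bounds(spec: SimulationSpec, max_r: float) -> None:
    x0, y0 = spec.params.origin
    pad = max(spec.stroke_width_ref, spec.stroke_width_hand) + 1
    if (
        x0 - max_r - pad < 0
        or y0 - max_r - pad < 0
        or x0 + max_r + pad > spec.image_size - 1
        or y0 + max_r + pad > spec.image_size - 1
    ):
        raise ValidationError(
            f"spiral of max radius {max_r:.0f} px does not fit in a "
            f"{spec.image_size}-px image at origin {spec.params.origin}"
        )


def render_reference(spec: SimulationSpec) -> InkImage:
    """Rasterize the reference spiral alone onto a blank canvas."""
    b, theta_r = spec.params.b, spec.params.theta_r
    _check_bounds(spec, b * spec.phi_max)
    _, phi = _arc_samples(spec)
    theta = phi - theta_r
    r = b * phi
    x0, y0 = spec.params.origin
    px = x0 + r * np.cos(theta)
    py = y0 + r * np.sin(theta)
    rng = np.random.default_rng(spec.seed)
    levels = _ink_levels(len(px), spec.ref_ink, spec.grey_jitter * 0.5, rng)
    canvas = np.zeros((spec.image_size, spec.image_size))
    _stamp(canvas, px, py, spec.stroke_width_ref, levels)
    return InkImage(density=canvas, source_path="synthetic:reference")


def render_hand_drawing(spec: SimulationSpec) -> tuple[InkImage, GroundTruth]:
    """Rasterize the simulated hand drawing and return it with its truth.

    The curve is ``r(theta) = b*(theta+theta_r) + d(s)`` with the
    sinusoidal tremor above; artifact flags add pen-lift gaps, a small
    closed loop, a crossing excursion past the ring half-spacing, or a
    dark spike near the origin.  The returned truth records the
    deviation actually drawn (including artifact excursions, excluding
    the loop overlay and spike, which are extra strokes, not the curve).
    """
    b, theta_r = spec.params.b, spec.params.theta_r
    _check_bounds(spec, b * spec.phi_max + spec.tremor_amplitude)
    s, phi = _arc_samples(spec)
    rng = np.random.default_rng(spec.seed + 1)
    d = spec.tremor_amplitude * np.sin(
        TWO_PI * spec.tremor_freq * (s / spec.s_total) * spec.t_to_draw + spec.phase
    )
    if "crossings" in spec.artifacts:
        # smooth excursion past the half ring spacing pi*b
        center = rng.uniform(0.45, 0.75) * spec.s_total
        width = 0.05 * spec.s_total
        u = (s - center) / width
        d = d + 1.3 * math.pi * b * np.exp(-0.5 * u**2)
    theta = phi - theta_r
    r = b * phi + d
    x0, y0 = spec.params.origin
    px = x0 + r * np.cos(theta)
    py = y0 + r * np.sin(theta)

    draw = np.ones(len(s), dtype=bool)
    draw[s < 2.0] = False  # pen-down happens just off the exact center
    if "gaps" in spec.artifacts:
        for _ in range(2):
            g0 = rng.uniform(0.15, 0.85) * spec.s_total
            g1 = g0 + rng.uniform(0.015, 0.03) * spec.s_total
            draw &= ~((s >= g0) & (s <= g1))

    levels = _ink_levels(len(px), spec.hand_ink, spec.grey_jitter, rng)
    canvas = np.zeros((spec.image_size, spec.image_size))
    _stamp(canvas, px[draw], py[draw], spec.stroke_width_hand, levels[draw])

    if "loops" in spec.artifacts:
        i = int(rng.uniform(0.3, 0.7) * len(s))
        rad = max(6.0, spec.tremor_amplitude)
        ang = np.linspace(0.0, TWO_PI, int(TWO_PI * rad / ARC_STEP))
        lx = px[i] + rad * (np.cos(ang) - 1.0)
        ly = py[i] + rad * np.sin(ang)
        _stamp(canvas, lx, ly, spec.stroke_width_hand, np.full(len(lx), spec.hand_ink))
    if "origin_spike" in spec.artifacts:
        n_spike = 4
        ang = rng.uniform(0.0, TWO_PI, n_spike)
        rad = rng.uniform(2.0, 6.0, n_spike)
        _stamp(
            canvas,
            x0 + rad * np.cos(ang),
            y0 + rad * np.sin(ang),
            2.0,
            np.full(n_spike, spec.hand_ink),
        )
    truth = GroundTruth(
        s=s,
        d=d,
        tremor_freq=spec.tremor_freq,
        tremor_amplitude=spec.tremor_amplitude,
        t_to_draw=spec.t_to_draw,
        params=spec.params,
        s_total=spec.s_total,
    )
    return InkImage(density=canvas, source_path="synthetic:hand"), truth


def compose(spec: SimulationSpec) -> tuple[InkImage, GroundTruth]:
    """Full synthetic sample: background + reference + hand drawing."""
    ref = render_reference(spec)
    hand, truth = render_hand_drawing(spec)
    rng = np.random.default_rng(spec.seed + 2)
    bg = spec.background_grey * (0.6 + 0.4 * rng.random(ref.density.shape))
    density = np.maximum(bg, np.maximum(ref.density, hand.density))
    return InkImage(density=density, source_path="synthetic:composite"), truth


# --- cohort ---------------------------------------------------------------

_ARTIFACT_CYCLE: tuple[frozenset[str], ...] = (
    frozenset(),
    frozenset(),
    frozenset({"gaps"}),
    frozenset({"loops"}),
    frozenset({"crossings"}),
    frozenset({"origin_spike"}),
)


def make_cohort(
    n: int = 18, seed: int = 0, image_size: int = 1024
) -> list[tuple[InkImage, GroundTruth, SimulationSpec]]:
    """Generate a cohort of composite drawings with varied parameters.

    Mild-to-moderate tremor conditions: amplitude 3–20 px, frequency
    3–8 Hz, arbitrary rotation, stroke widths 1–5 px, drawing times
    8–15 s, with artifact flags cycled across the cohort so gaps,
    loops, crossings, and origin spikes each appear several times.
    Fully reproducible from the seed.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        # fill chosen so the widest-amplitude drawing plus origin jitter
        # still fits inside the canvas
        params = default_params(
            image_size=image_size,
            theta_r=rng.uniform(0.0, TWO_PI),
            origin=(
                image_size / 2 + rng.uniform(-8, 8),
                image_size / 2 + rng.uniform(-8, 8),
            ),
            fill=0.42,
        )
        spec = SimulationSpec(
            params=params,
            image_size=image_size,
            stroke_width_ref=float(rng.uniform(1.0, 3.0)),
            stroke_width_hand=float(rng.uniform(1.5, 5.0)),
            tremor_amplitude=float(rng.uniform(3.0, 20.0)),
            tremor_freq=float(rng.uniform(3.0, 8.0)),
            t_to_draw=float(rng.uniform(8.0, 15.0)),
            phase=float(rng.uniform(0.0, TWO_PI)),
            grey_jitter=float(rng.uniform(0.04, 0.12)),
            artifacts=_ARTIFACT_CYCLE[i % len(_ARTIFACT_CYCLE)],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, truth = compose(spec)
        out.append((img, truth, spec))
    return out


def write_cohort(
    samples: list[tuple[InkImage, GroundTruth, SimulationSpec]],
    outdir: str | Path,
) -> Path:
    """Write cohort PNGs, JSON truth sidecars, and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth, spec) in enumerate(samples, start=1):
        name = f"S{i:02d}"
        write_image(img, outdir / f"{name}.png")
        meta = {
            "tremor_amplitude": truth.tremor_amplitude,
            "tremor_freq": truth.tremor_freq,
            "t_to_draw": truth.t_to_draw,
            "s_total": truth.s_total,
            "b": truth.params.b,
            "theta_r": truth.params.theta_r,
            "origin": list(truth.params.origin),
            "artifacts": sorted(spec.artifacts),
            "seed": spec.seed,
        }
        (outdir / f"{name}.truth.json").write_text(json.dumps(meta, indent=2))
        rows.append({"sample": name, "image": f"{name}.png", **{
            k: v for k, v in meta.items() if k not in ("origin",)
        }})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def analysis_inputs(spec: SimulationSpec, truth: GroundTruth | None = None) -> dict:
    """Coordinates a user would click, derived from the ground truth.

    Returns origin, two on-spiral fit points (zones 1 and 2), a crop
    rectangle bracketing the stitched hand band, and a noise-crop bound
    past the wrongly-unwrapped sliver near the center — everything the
    pipeline needs besides the image itself.
    """
    from .spiral_geometry import spiral_xy

    params = spec.params
    t1, t2 = 2.2, 2.2 + TWO_PI
    p1 = spiral_xy(params, t1)
    p2 = spiral_xy(params, t2)
    x0, y0 = params.origin
    half_band = min(
        spec.tremor_amplitude + spec.stroke_width_hand + 8.0,
        0.9 * math.pi * params.b,
    )
    return {
        "origin": (x0, y0),
        "fit_point_1": (x0 + p1[0], y0 + p1[1]),
        "fit_point_2": (x0 + p2[0], y0 + p2[1]),
        "zones": (1, 2),
        "crop_rect": ((0.0, spec.phi_max), (-half_band, half_band)),
        "s_min": 0.5 * params.b * (params.theta_r + 0.5) ** 2,
        "t_to_draw": spec.t_to_draw,
    }
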