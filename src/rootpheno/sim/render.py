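"""Rasterize simulated root systems into grayscale seedling photographs.

Polylines are drawn with round joints at the thickness given by the primary
diameter taper (laterals at the tip diameter). The clean render is binary
(foreground bright on dark); an optional :class:`NoiseConfig` adds a linear
illumination gradient, circular bright speckles ("water spots") and pixel
noise to exercise thresholding downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from rootpheno.sim.roots import RootSystemTruth, STEP_CM

MARGIN_CM = 0.25


@dataclass(frozen=True)
class NoiseConfig:
    """Photographic nuisance model for rendered root images."""

    fg_level: int = 200
    bg_level: int = 30
    gradient_amplitude: float = 0.0  # peak-to-peak added along the image rows
    speckle_count: int = 0
    speckle_radius_cm: float = 0.1
    speckle_level: int = 120
    gaussian_sd: float = 0.0
    seed: int = 0


@dataclass
class RootImage:
    """8-bit grayscale raster with acquisition metadata."""

    pixels: np.ndarray  # (H, W) uint8
    px_per_cm: float
    day: float
    meta: dict = field(default_factory=dict)


def render_root_image(
    truth: RootSystemTruth,
    day: float,
    px_per_cm: float | None = None,
    noise: NoiseConfig | None = None,
) -> RootImage:
    """Render the root system at ``day``; deterministic for identical inputs.

    Resolutions of at least 10 px/cm are recommended for reliable trait
    recovery downstream.
    """
    truth._check_day(day)
    px = float(px_per_cm if px_per_cm is not None else truth.px_per_cm)
    p = truth.params

    primary = truth.primary_at(day)
    prl = truth.primary_length_at(day)
    lats = truth.laterals_at(day)
    polys = [primary] + [poly for _, poly in lats]

    r_max = 0.5 * p.diameter_base_cm
    xs = np.concatenate([poly[:, 0] for poly in polys])
    ys = np.concatenate([poly[:, 1] for poly in polys])
    x0 = xs.min() - r_max - MARGIN_CM
    y0 = ys.min() - r_max - MARGIN_CM
    w_px = int(np.ceil((xs.max() + r_max + MARGIN_CM - x0) * px))
    h_px = int(np.ceil((ys.max() + r_max + MARGIN_CM - y0) * px))

    canvas = Image.new("L", (w_px, h_px), 0)
    draw = ImageDraw.Draw(canvas)

    def to_px(poly: np.ndarray) -> np.ndarray:
        return (poly - [x0, y0]) * px

    # primary with linear taper along current arclength
    pts = to_px(primary)
    s = STEP_CM * np.arange(len(primary))
    frac = s / prl if prl > 0 else s * 0.0
    diam_px = (p.diameter_base_cm + (p.diameter_tip_cm - p.diameter_base_cm) * frac) * px
    _draw_polyline(draw, pts, diam_px)
    d_lat = p.diameter_tip_cm * px
    for _, poly in lats:
        pts = to_px(poly)
        _draw_polyline(draw, pts, np.full(len(pts), d_lat))

    mask = np.asarray(canvas, dtype=np.uint8) > 0
    if noise is None:
        pixels = np.where(mask, 255, 0).astype(np.uint8)
    else:
        rng = np.random.default_rng(noise.seed)
        img = np.where(mask, float(noise.fg_level), float(noise.bg_level))
        if noise.gradient_amplitude:
            ramp = np.linspace(-0.5, 0.5, h_px) * noise.gradient_amplitude
            img = img + ramp[:, None]
        if noise.speckle_count:
            rr, cc = np.mgrid[0:h_px, 0:w_px]
            rad = noise.speckle_radius_cm * px
            for _ in range(noise.speckle_count):
                cy = rng.uniform(0, h_px)
                cx = rng.uniform(0, w_px)
                blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
                img = np.where(blob, np.maximum(img, noise.speckle_level), img)
        if noise.gaussian_sd:
            img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
        pixels = np.clip(img, 0, 255).astype(np.uint8)

    meta = {
        "px_per_cm": px,
        "day": day,
        "seed": p.seed,
        "origin_cm": [float(x0), float(y0)],
        **truth.meta,
    }
    return RootImage(pixels=pixels, px_per_cm=px, day=day, meta=meta)


def _draw_polyline(draw: ImageDraw.ImageDraw, pts: np.ndarray, diam_px: np.ndarray) -> None:
    """Draw segments with per-vertex width and round joints."""
    for i in range(len(pts) - 1):
        w = max(1, int(round(0.5 * (diam_px[i] + diam_px[i + 1]))))
        draw.line(
            [tuple(pts[i]), tuple(pts[i + 1])], fill=255, width=w
        )
        if w > 2:
            r = w / 2.0
            for q in (pts[i], pts[i + 1]):
                draw.ellipse([q[0] - r, q[1] - r, q[0] + r, q[1] + r], fill=255)


def save_image(image: RootImage, path: str | Path) -> None:
    """Write the raster as 8-bit PNG with a sidecar JSON of metadata."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="L").save(path)
    with path.with_suffix(".json").open("w") as fh:
        json.dump(image.meta, fh, indent=1)
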