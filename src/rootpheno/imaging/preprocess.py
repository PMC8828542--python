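"""Segmentation of seedling photographs into binary root masks.

Mirrors a standard paper-roll imaging workflow: rotate to portrait, crop the
label band, threshold in a configurable color space (Otsu by default), keep
the largest connected component and drop small debris (water spots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage.filters import threshold_otsu
from skimage.measure import label

from rootpheno.sim.render import RootImage


class BlankImageError(ValueError):
    """No root foreground found — a blank (non-germinated) image."""


@dataclass
class RootMask:
    """Binary root raster: True = root foreground."""

    mask: np.ndarray
    px_per_cm: float
    provenance: dict = field(default_factory=dict)

    @property
    def area_cm2(self) -> float:
        return float(self.mask.sum()) / self.px_per_cm**2


def _to_channel(img: np.ndarray, color_space: str) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim == 3 and img.shape[2] >= 3:
        rgb = img[..., :3].astype(float)
        if rgb.max() > 1:
            rgb = rgb / 255.0
        if color_space == "gray":
            return skcolor.rgb2gray(rgb)
        if color_space == "lab":
            return skcolor.rgb2lab(rgb)[..., 0]
        if color_space == "hsv":
            return skcolor.rgb2hsv(rgb)[..., 2]
        if color_space in ("red", "green", "blue"):
            return rgb[..., ("red", "green", "blue").index(color_space)]
        raise ValueError(f"unknown color space {color_space!r}")
    raise ValueError(f"cannot interpret image with shape {img.shape}")


def preprocess(
    image: RootImage | np.ndarray | str | Path,
    px_per_cm: float | None = None,
    *,
    color_space: str = "gray",
    foreground: str = "bright",
    rotate_to_portrait: bool = True,
    crop_top_frac: float = 0.0,
    min_object_px: int = 25,
    threshold: float | None = None,
) -> RootMask:
    """Threshold a root photograph into a :class:`RootMask`.

    Parameters
    ----------
    image:
        A rendered :class:`~rootpheno.sim.render.RootImage`, a numpy array
        (grayscale or RGB), or a path to a PNG/TIFF file.
    px_per_cm:
        Image resolution; taken from ``RootImage`` metadata when available.
    foreground:
        ``"bright"`` (default) for light roots on a dark background, or
        ``"dark"``.
    crop_top_frac:
        Fraction of image height removed from the top (label/tag band).
    threshold:
        Fixed threshold; defaults to Otsu's choice on the selected channel.

    Raises
    ------
    BlankImageError
        If no foreground remains after thresholding and cleanup; such
        images are excluded from analysis.
    """
    meta: dict = {}
    if isinstance(image, RootImage):
        arr = image.pixels
        px_per_cm = image.px_per_cm if px_per_cm is None else px_per_cm
        meta.update(image.meta)
    elif isinstance(image, (str, Path)):
        arr = np.asarray(Image.open(image))
        meta["source"] = str(image)
    else:
        arr = np.asarray(image)
    if px_per_cm is None:
        raise ValueError("px_per_cm must be provided (argument or image metadata)")

    chan = _to_channel(arr, color_space)
    rotated = False
    if rotate_to_portrait and chan.shape[1] > chan.shape[0]:
        chan = np.rot90(chan, k=-1)  # 90 degrees clockwise
        rotated = True
    if crop_top_frac > 0:
        chan = chan[int(round(crop_top_frac * chan.shape[0])):]

    if chan.max() == chan.min():
        raise BlankImageError("image is constant; no root foreground")
    t = threshold_otsu(chan) if threshold is None else threshold
    mask = chan > t if foreground == "bright" else chan < t
    # 8-connected components: drop debris below min_object_px, keep the largest
    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    counts[counts < min_object_px] = 0
    if counts.max() == 0:
        raise BlankImageError("no foreground after thresholding and cleanup")
    mask = lab == counts.argmax()

    meta.update(
        threshold=float(t),
        color_space=color_space,
        foreground=foreground,
        rotated=rotated,
        crop_top_frac=crop_top_frac,
        min_object_px=min_object_px,
    )
    return RootMask(mask=mask, px_per_cm=float(px_per_cm), provenance=meta)
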