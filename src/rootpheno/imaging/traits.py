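"""Morphometric trait set computed from mask + skeleton graph + primary path.

Traits and units follow the conventions of 2D seedling root phenomics:

==========  =====================================================================
TRL         total root length: sum of skeleton edge lengths (cm)
PRL         primary root length: primary path length (cm)
TRL_Upper   skeleton length in the upper third of the root's depth extent (cm)
DEP, WID    bounding-box extents of the root silhouette (cm)
DIA         median primary diameter from the distance transform (cm)
LRB         number of lateral emergence points on the primary path
NWA         skeleton ("network") pixel count, optionally rescaled
CVA         convex-hull area of the silhouette (cm^2)
SOL         solidity: silhouette area / convex area (ratio in (0, 1])
RHZO        rhizosphere area: a 2 mm dilation band around the silhouette (cm^2)
PRA, VOL    primary-root lateral surface (cm^2) and volume (cm^3), cylinder model
LRA         median lateral-root tangent angle from the vertical axis (degrees)
LED         length distribution TRL_Upper / TRL_Lower (shallowness index)
TRL_GR      growth rate between two imaging days (cm/day)
==========  =====================================================================

All angles are measured from the vertical (gravity) axis; 0 degrees is
perfectly steep. A configuration flag converts to the from-horizontal
convention downstream where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt
from skimage.morphology import convex_hull_image, disk

from rootpheno.imaging.preprocess import RootMask, preprocess
from rootpheno.imaging.skeleton import (
    PrimaryPath,
    SkeletonGraph,
    identify_primary_path,
    skeletonize_mask,
)
from rootpheno.sim.roots import STEP_CM


@dataclass
class TraitRecord:
    """One observation (genotype x replicate x day) of the trait set."""

    day: float | None = None
    genotype: str | None = None
    chamber: int | None = None
    block: int | None = None
    sub_block: int | None = None
    replicate: int | None = None
    TRL: float = math.nan
    PRL: float = math.nan
    TRL_Upper: float = math.nan
    TRL_Lower: float = math.nan
    DEP: float = math.nan
    WID: float = math.nan
    DIA: float = math.nan
    LRB: float = math.nan
    NWA: float = math.nan
    CVA: float = math.nan
    RHZO: float = math.nan
    PRA: float = math.nan
    VOL: float = math.nan
    LRA: float = math.nan
    SOL: float = math.nan
    LED: float = math.nan
    TRL_GR: float = math.nan
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("meta")
        return d


def _resample_chain_cm(pixels: np.ndarray, px_per_cm: float, step_cm: float = STEP_CM) -> np.ndarray:
    """Resample a pixel chain to evenly spaced points (cm coordinates).

    The chain is first smoothed with a short moving average so that tangents
    taken on the resampled points track the underlying curve with sub-pixel
    precision rather than the quantized pixel staircase.
    """
    from scipy.ndimage import uniform_filter1d

    pixels = pixels.astype(float)
    if len(pixels) > 2:
        pixels = uniform_filter1d(pixels, size=3, axis=0, mode="nearest")
    pts = pixels / px_per_cm
    if len(pts) < 2:
        return pts
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return pts[:1]
    n = max(int(round(total / step_cm)), 1)
    si = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def _lateral_angle_deg(chains: list[np.ndarray], px_per_cm: float) -> float:
    """Median tangent angle from vertical over all sampled lateral points.

    Sampling step 0.05 cm, tangents by central difference over +-0.1 cm —
    the same convention as the simulator's ground truth. Chains shorter
    than 5 px are junction-scale skeleton debris (rungs and frays produced
    by thinning where a lateral meets the primary), not lateral tissue, and
    are excluded from the sample.
    """
    from rootpheno.sim.roots import tangent_angles_from_vertical

    angles = []
    for chain in chains:
        if len(chain) < 5:
            continue
        pts = _resample_chain_cm(chain, px_per_cm)
        # pixel rows are y (down), columns are x: reorder to (x, y)
        if len(pts) >= 2:
            angles.append(tangent_angles_from_vertical(pts[:, ::-1]))
    if not angles:
        return math.nan
    return float(np.median(np.concatenate(angles)))


def extract_traits(
    mask: RootMask,
    skel: SkeletonGraph | None = None,
    path: PrimaryPath | None = None,
    *,
    day: float | None = None,
    length_method: str = "resampled",
    nwa_divisor: float = 1.0,
    sol_scale: float = 1.0,
    rhizo_radius_cm: float = 0.2,
    prune_cm: float = 0.05,
    **labels,
) -> TraitRecord:
    """Compute the full trait record for one root image.

    ``skel`` and ``path`` are recomputed from the mask when not supplied.
    ``nwa_divisor`` and ``sol_scale`` expose the undocumented rescalings of
    the NWA and SOL2 conventions (default 1: raw pixel count and a ratio in
    (0, 1]); the values used are recorded in the output metadata.
    """
    px = mask.px_per_cm
    if skel is None:
        skel = skeletonize_mask(mask, prune_cm=prune_cm)
    if path is None:
        path = identify_primary_path(skel, prune_cm=prune_cm)

    m = mask.mask
    trl = skel.total_length_cm(length_method)
    prl = path.length_cm

    rows = np.where(m.any(axis=1))[0]
    cols = np.where(m.any(axis=0))[0]
    dep = (rows[-1] - rows[0] + 1) / px
    wid = (cols[-1] - cols[0] + 1) / px

    edt = distance_transform_edt(m)
    path_px = path.pixels
    # EDT measures to the first background cell: 2*EDT - 1 is the pixel width
    diam_cm = np.maximum(2.0 * edt[path_px[:, 0], path_px[:, 1]] - 1.0, 1.0) / px
    dia = float(np.median(diam_cm))

    hull = convex_hull_image(m)
    area_px = float(m.sum())
    cva = float(hull.sum()) / px**2
    sol = (area_px / float(hull.sum())) * sol_scale

    r_px = max(1, int(round(rhizo_radius_cm * px)))
    dil = binary_dilation(m, structure=disk(r_px))
    rhzo = float(dil.sum() - m.sum()) / px**2

    seg = np.hypot(*np.diff(path_px.astype(float), axis=0).T) / px
    d_mid = 0.5 * (diam_cm[:-1] + diam_cm[1:])
    pra = float(np.sum(math.pi * d_mid * seg))
    vol = float(np.sum(math.pi * (d_mid / 2.0) ** 2 * seg))

    # depth thirds on the skeleton's own depth extent
    all_edges = [d for *_, d in skel.graph.edges(keys=True, data=True)]
    skel_rows = np.concatenate([d["pixels"][:, 0] for d in all_edges])
    r_min, r_max = int(skel_rows.min()), int(skel_rows.max())
    band = r_min + (r_max - r_min) / 3.0
    upper = 0.0
    key = "length_cm" if length_method == "resampled" else "chain_cm"
    for d in all_edges:
        pxs = d["pixels"].astype(float)
        if len(pxs) < 2:
            continue
        step = np.hypot(*np.diff(pxs, axis=0).T)
        mid = 0.5 * (pxs[:-1, 0] + pxs[1:, 0])
        frac = step[mid <= band].sum() / step.sum() if step.sum() > 0 else 0.0
        upper += frac * d[key]
    lower = trl - upper
    led = upper / lower if lower > 1e-12 else math.nan

    lra = _lateral_angle_deg(path.lateral_chains, px)

    return TraitRecord(
        day=day,
        TRL=float(trl),
        PRL=float(prl),
        TRL_Upper=float(upper),
        TRL_Lower=float(lower),
        DEP=float(dep),
        WID=float(wid),
        DIA=dia,
        LRB=float(path.n_laterals),
        NWA=float(skel.nwa_pixels) / nwa_divisor,
        CVA=cva,
        RHZO=rhzo,
        PRA=pra,
        VOL=vol,
        LRA=lra,
        SOL=float(sol),
        LED=float(led),
        meta={
            "px_per_cm": px,
            "length_method": length_method,
            "nwa_divisor": nwa_divisor,
            "sol_scale": sol_scale,
            "angle_reference": "vertical",
            **mask.provenance,
        },
        **labels,
    )


def traits_from_image(image, px_per_cm=None, *, day=None, preprocess_kwargs=None, **kwargs) -> TraitRecord:
    """Convenience pipeline: preprocess -> skeletonize -> path -> traits."""
    mask = preprocess(image, px_per_cm, **(preprocess_kwargs or {}))
    return extract_traits(mask, day=day, **kwargs)


def compute_growth_rate(rec_early: TraitRecord, rec_late: TraitRecord) -> float:
    """TRL growth rate (cm/day) between two imaging days of one seedling.

    Returns nan if either TRL is missing; raises if the records disagree on
    genotype/replicate or the day gap is not positive.
    """
    for attr in ("genotype", "replicate"):
        a, b = getattr(rec_early, attr), getattr(rec_late, attr)
        if a is not None and b is not None and a != b:
            raise ValueError(f"records differ in {attr}: {a!r} vs {b!r}")
    if rec_early.day is None or rec_late.day is None or rec_late.day <= rec_early.day:
        raise ValueError("records must carry increasing day numbers")
    if math.isnan(rec_early.TRL) or math.isnan(rec_late.TRL):
        return math.nan
    return (rec_late.TRL - rec_early.TRL) / (rec_late.day - rec_early.day)


def growth_rate_table(
    table: pd.DataFrame,
    day_from: int = 12,
    day_to: int = 15,
    keys: tuple[str, ...] = ("genotype", "chamber"),
) -> pd.DataFrame:
    """Per-seedling TRL_GR from a long trait table with a ``day`` column.

    Pairs observations by ``keys``; rows with a missing member of the pair
    are dropped (no imputation).
    """
    keys = [k for k in keys if k in table.columns]
    a = table[table["day"] == day_from].set_index(keys)["TRL"]
    b = table[table["day"] == day_to].set_index(keys)["TRL"]
    common = a.index.intersection(b.index)
    gr = (b.loc[common] - a.loc[common]) / (day_to - day_from)
    out = gr.rename("TRL_GR").reset_index()
    return out
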