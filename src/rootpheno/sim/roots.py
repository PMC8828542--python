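"""Forward simulator for seedling root systems.

A root system is modelled as a primary axis growing downward from the seed
point in fixed 0.05 cm steps, with per-step Gaussian heading noise
(tortuosity) and gravitropic relaxation of the heading toward vertical.
First-order laterals emerge along the primary as a Poisson process in
arclength (within the day window in which that arclength was produced), with
an initial heading drawn around a mean emergence angle and a random
left/right sign, then grow by the same step process.

Coordinates are in cm with the seed at the origin and *y increasing
downward*; all angles are measured from the vertical (gravity) axis, so 0°
is perfectly steep. The continuous polylines are the ground-truth oracle for
every image-derived trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

#: Growth-step length in cm; small enough that polyline arclength error is
#: negligible (<0.1%) for realistic tortuosity.
STEP_CM = 0.05


@dataclass(frozen=True)
class RootParams:
    """Parameters of the forward root-growth model.

    Defaults are tuned to bracket a mung-bean-like seedling at day 15:
    primary length ~43 cm, ~130 visible laterals, total root length
    ~230 cm, median lateral angle ~50 degrees from vertical, and a median
    primary diameter ~0.24 cm.
    """

    primary_rate: float = 2.85  # cm/day primary elongation
    lateral_rate_per_cm: float = 3.2  # expected emergences per cm of new primary
    lateral_angle_mean_deg: float = 50.0  # mean emergence angle from vertical
    lateral_angle_sd_deg: float = 10.0
    lateral_rate: float = 0.19  # cm/day lateral elongation
    tortuosity_sd_deg: float = 2.0  # per-step heading noise
    gravitropism: float = 0.02  # per-step relaxation of heading toward vertical
    diameter_base_cm: float = 0.32  # primary thickness at the seed
    diameter_tip_cm: float = 0.16  # primary thickness at the tip
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lateral_angle_mean_deg <= 90.0):
            raise ValueError("lateral_angle_mean_deg must be in [0, 90]")
        for name in ("primary_rate", "lateral_rate_per_cm", "lateral_rate",
                     "lateral_angle_sd_deg", "tortuosity_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.gravitropism <= 1.0):
            raise ValueError("gravitropism must be in [0, 1]")
        if self.diameter_base_cm <= 0 or self.diameter_tip_cm <= 0:
            raise ValueError("diameters must be > 0")
        if self.diameter_tip_cm > self.diameter_base_cm:
            raise ValueError("diameter_tip_cm must be <= diameter_base_cm")


@dataclass
class Lateral:
    """One first-order lateral, fully grown to the last simulated day."""

    emergence_arclength_cm: float
    emergence_day: int
    polyline: np.ndarray  # (n, 2) cm, fully grown
    emergence_angle_deg: float

    def length_at(self, day: float, rate: float) -> float:
        return max(0.0, rate * (day - self.emergence_day))

    def polyline_at(self, day: float, rate: float) -> np.ndarray | None:
        """Clipped polyline at ``day``; None if not yet visibly emerged."""
        n = int(round(self.length_at(day, rate) / STEP_CM))
        if n < 1:
            return None
        return self.polyline[: min(n, len(self.polyline) - 1) + 1]


@dataclass
class RootSystemTruth:
    """Continuous polyline model of a simulated root system.

    ``primary_polyline`` is fully grown to ``max(days)``; per-day snapshots
    are obtained by truncating at the day's arclength (each polyline step is
    exactly :data:`STEP_CM` of arclength).
    """

    primary_polyline: np.ndarray  # (n, 2) cm, y down, starts at the seed point
    laterals: list[Lateral]
    days: tuple[int, ...]
    params: RootParams
    px_per_cm: float = 20.0
    meta: dict = field(default_factory=dict)

    def primary_length_at(self, day: float) -> float:
        total = (len(self.primary_polyline) - 1) * STEP_CM
        return min(self.params.primary_rate * day, total)

    def primary_at(self, day: float) -> np.ndarray:
        n = int(round(self.primary_length_at(day) / STEP_CM))
        return self.primary_polyline[: n + 1]

    def laterals_at(self, day: float) -> list[tuple[Lateral, np.ndarray]]:
        """Laterals visibly emerged by ``day`` with their clipped polylines."""
        out = []
        for lat in self.laterals:
            poly = lat.polyline_at(day, self.params.lateral_rate)
            if poly is not None:
                out.append((lat, poly))
        return out

    def _check_day(self, day: float) -> None:
        if day not in self.days:
            raise KeyError(f"day {day} not simulated; available: {self.days}")


def _grow_polyline(
    start: np.ndarray,
    theta0_deg: float,
    n_steps: int,
    tortuosity_sd_deg: float,
    gravitropism: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a polyline by the AR(1)-heading step process.

    The heading (degrees from vertical, signed) evolves as
    ``theta_t = (1 - gravitropism) * theta_{t-1} + eps_t`` and each step adds
    exactly :data:`STEP_CM` of arclength.
    """
    if n_steps < 1:
        return start[None, :].copy()
    eps = rng.normal(0.0, tortuosity_sd_deg, size=n_steps)
    a = 1.0 - gravitropism
    # theta_t = a^t * theta0 + sum a^(t-k) eps_k  -> linear filter
    theta = lfilter([1.0], [1.0, -a], eps) + theta0_deg * a ** np.arange(1, n_steps + 1)
    rad = np.deg2rad(theta)
    dx = STEP_CM * np.sin(rad)
    dy = STEP_CM * np.cos(rad)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    pts[1:, 0] = start[0] + np.cumsum(dx)
    pts[1:, 1] = start[1] + np.cumsum(dy)
    return pts


def simulate_root_system(
    params: RootParams,
    days: tuple[int, ...] = (12, 15, 18),
    min_lateral_spacing_cm: float | None = None,
) -> RootSystemTruth:
    """Simulate a seedling root system observed at the requested days.

    Deterministic given ``params.seed``. Lateral emergences within the day
    window ``(w-1, w]`` follow Poisson(``lateral_rate_per_cm`` x primary
    arclength grown in that window), positioned uniformly along the new
    arclength, so the total count at day ``d`` is Poisson(rate x length(d)).

    ``min_lateral_spacing_cm`` optionally thins the emergence process to a
    hard-core (Matern-I style) process: a new lateral is rejected when it
    would emerge closer than the given arclength spacing to an already
    accepted one. This produces the well-separated laterals that image-based
    branch counting can resolve; the default (None) keeps the pure Poisson
    process.
    """
    days = tuple(days)
    if list(days) != sorted(days):
        raise ValueError("days must be sorted ascending")
    max_day = max(days)
    rng = np.random.default_rng(params.seed)

    n_primary = int(round(params.primary_rate * max_day / STEP_CM))
    primary = _grow_polyline(
        np.zeros(2), 0.0, n_primary, params.tortuosity_sd_deg, params.gravitropism, rng
    )
    arclen = STEP_CM * np.arange(len(primary))

    laterals: list[Lateral] = []
    length_prev = 0.0
    for w in range(1, max_day + 1):
        length_now = min(params.primary_rate * w, arclen[-1])
        delta = length_now - length_prev
        n_new = rng.poisson(params.lateral_rate_per_cm * delta) if delta > 0 else 0
        if n_new:
            ss = np.sort(rng.uniform(length_prev, length_now, size=n_new))
            angles = rng.normal(
                params.lateral_angle_mean_deg, params.lateral_angle_sd_deg, size=n_new
            )
            signs = rng.choice([-1.0, 1.0], size=n_new)
            if min_lateral_spacing_cm is not None:
                taken = [lat.emergence_arclength_cm for lat in laterals]
                keep = []
                for i, s in enumerate(ss):
                    if all(abs(s - t) >= min_lateral_spacing_cm for t in taken):
                        keep.append(i)
                        taken.append(s)
                ss, angles, signs = ss[keep], angles[keep], signs[keep]
            for s, ang, sign in zip(ss, angles, signs):
                start = np.array(
                    [np.interp(s, arclen, primary[:, 0]), np.interp(s, arclen, primary[:, 1])]
                )
                n_steps = int(round(params.lateral_rate * (max_day - w) / STEP_CM))
                poly = _grow_polyline(
                    start, sign * ang, n_steps,
                    params.tortuosity_sd_deg, params.gravitropism, rng,
                )
                laterals.append(
                    Lateral(
                        emergence_arclength_cm=float(s),
                        emergence_day=w,
                        polyline=poly,
                        emergence_angle_deg=abs(float(ang)),
                    )
                )
        length_prev = length_now

    return RootSystemTruth(
        primary_polyline=primary, laterals=laterals, days=days, params=params
    )


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


def tangent_angles_from_vertical(poly: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Angle from vertical (degrees, [0, 90]) of local tangents along a polyline.

    Tangents are central differences over ``half_window`` vertices on each
    side (0.1 cm at the simulator step); shorter polylines fall back to the
    widest available window.
    """
    n = len(poly)
    if n < 2:
        return np.empty(0)
    idx = np.arange(n)
    lo = np.maximum(idx - half_window, 0)
    hi = np.minimum(idx + half_window, n - 1)
    d = poly[hi] - poly[lo]
    return np.degrees(np.arctan2(np.abs(d[:, 0]), np.abs(d[:, 1])))


def _silhouette_extents(truth: RootSystemTruth, day: float) -> tuple[float, float]:
    """(depth, width) in cm of the thickness-inflated root silhouette."""
    p = truth.params
    primary = truth.primary_at(day)
    length = truth.primary_length_at(day)
    s = STEP_CM * np.arange(len(primary))
    frac = s / length if length > 0 else s * 0.0
    r = 0.5 * (p.diameter_base_cm + (p.diameter_tip_cm - p.diameter_base_cm) * frac)
    xs_min = [np.min(primary[:, 0] - r)]
    xs_max = [np.max(primary[:, 0] + r)]
    ys_min = [np.min(primary[:, 1] - r)]
    ys_max = [np.max(primary[:, 1] + r)]
    r_lat = 0.5 * p.diameter_tip_cm
    for _, poly in truth.laterals_at(day):
        xs_min.append(np.min(poly[:, 0]) - r_lat)
        xs_max.append(np.max(poly[:, 0]) + r_lat)
        ys_min.append(np.min(poly[:, 1]) - r_lat)
        ys_max.append(np.max(poly[:, 1]) + r_lat)
    return float(max(ys_max) - min(ys_min)), float(max(xs_max) - min(xs_min))


def true_traits(truth: RootSystemTruth, day: float) -> dict:
    """Ground-truth trait record computed on polylines, not pixels.

    Returns the analytically known subset: TRL, PRL, DEP, WID, LRB, LRA,
    TRL_Upper, TRL_Lower, LED, DIA, marked ``ground_truth=True``.  The
    depth-thirds banding and the LRA tangent-sampling convention match the
    image pipeline exactly (centerline depth extent split into three equal
    bands; median over 0.05 cm-sampled lateral tangent angles from vertical).
    """
    truth._check_day(day)
    p = truth.params
    primary = truth.primary_at(day)
    prl = truth.primary_length_at(day)
    lats = truth.laterals_at(day)
    trl = prl + sum(_polyline_length(poly) for _, poly in lats)

    dep, wid = _silhouette_extents(truth, day)

    # depth thirds on the centerline extent
    all_polys = [primary] + [poly for _, poly in lats]
    ys = np.concatenate([poly[:, 1] for poly in all_polys])
    y_min, y_max = float(ys.min()), float(ys.max())
    band = y_min + (y_max - y_min) / 3.0
    upper = 0.0
    for poly in all_polys:
        seg_len = np.hypot(*np.diff(poly, axis=0).T)
        mid_y = 0.5 * (poly[:-1, 1] + poly[1:, 1])
        upper += float(seg_len[mid_y <= band].sum())
    lower = trl - upper
    led = upper / lower if lower > 0 else math.nan

    angles = [tangent_angles_from_vertical(poly) for _, poly in lats]
    lra = float(np.median(np.concatenate(angles))) if angles else math.nan

    # DIA: median diameter along the primary (linear taper over current length)
    frac = (STEP_CM * np.arange(len(primary))) / prl if prl > 0 else np.zeros(len(primary))
    dia = float(
        np.median(p.diameter_base_cm + (p.diameter_tip_cm - p.diameter_base_cm) * frac)
    )

    return {
        "day": day,
        "TRL": float(trl),
        "PRL": float(prl),
        "DEP": dep,
        "WID": wid,
        "LRB": len(lats),
        "LRA": lra,
        "TRL_Upper": float(upper),
        "TRL_Lower": float(lower),
        "LED": led,
        "DIA": dia,
        "ground_truth": True,
    }
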