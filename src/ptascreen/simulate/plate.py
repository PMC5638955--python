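"""Synthetic plate time-lapses: growing colonies rendered with known truth.

Colonies grow in *area* — exponential with a lag, saturating at a cap — and
are rendered as disks whose radius follows from the area, so the ground-truth
log-area slope equals the specified rate, which is exactly the estimand of
the downstream moving-window fit. A pixel belongs to a colony when its centre
lies inside the disk. Frames are grayscale-in-RGB (R = G = B), so the HSV
value channel of a rendered frame equals the rendered value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..imaging import ImageSeries


class PlateGeometryError(ValueError):
    """A colony disk would grow beyond the frame without being flagged edge_ok."""


@dataclass(frozen=True)
class ColonySpec:
    """One simulated colony.

    ``center_x_px`` is the column, ``center_y_px`` the row. Area is 0 before
    ``lag_h``, then ``initial_area_px * exp(growth_rate_per_h * (t - lag_h))``
    capped at ``max_area_px``. ``edge_ok`` permits disks that cross the frame
    border (the intended edge-colony test case).
    """

    center_x_px: float
    center_y_px: float
    lag_h: float
    initial_area_px: float
    growth_rate_per_h: float
    max_area_px: float
    edge_ok: bool = False


@dataclass
class SyntheticPlateSpec:
    """Geometry, optics and timing of a simulated plate scan.

    Levels are HSV value-channel units in [0, 1]; per-pixel Gaussian noise of
    sd ``noise_sd`` is added to every frame (identically on R, G and B).
    """

    image_height_px: int
    image_width_px: int
    frame_interval_h: float
    n_frames: int
    colonies: list[ColonySpec] = field(default_factory=list)
    background_level: float = 0.10
    colony_level: float = 0.60
    noise_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if not self.colony_level > self.background_level:
            raise ValueError("colony_level must exceed background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h, w = self.image_height_px, self.image_width_px
        for c in self.colonies:
            if not (0 <= c.center_x_px <= w - 1 and 0 <= c.center_y_px <= h - 1):
                raise ValueError(f"colony centre ({c.center_x_px}, {c.center_y_px}) outside image")
            if c.growth_rate_per_h < 0:
                raise ValueError("growth_rate_per_h must be >= 0")
            if c.initial_area_px <= 0:
                raise ValueError("initial_area_px must be positive")
            if c.max_area_px < c.initial_area_px:
                raise ValueError("max_area_px must be >= initial_area_px")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


def colony_true_area(colony: ColonySpec, t_h: float) -> float:
    """True (pre-rendering) area in px at time ``t_h``; 0 before the lag."""
    if t_h < colony.lag_h:
        return 0.0
    a = colony.initial_area_px * math.exp(colony.growth_rate_per_h * (t_h - colony.lag_h))
    return min(a, colony.max_area_px)


def render_colony_mask(shape: tuple[int, int], colony: ColonySpec, area_px: float) -> np.ndarray:
    """Rasterize a colony of the given area: pixels whose centre lies in the disk."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if area_px <= 0:
        return mask
    r = math.sqrt(area_px / math.pi)
    cy, cx = colony.center_y_px, colony.center_x_px
    y0 = max(0, int(math.floor(cy - r)))
    y1 = min(h - 1, int(math.ceil(cy + r)))
    x0 = max(0, int(math.floor(cx - r)))
    x1 = min(w - 1, int(math.ceil(cx + r)))
    if y0 > y1 or x0 > x1:
        return mask
    yy, xx = np.ogrid[y0 : y1 + 1, x0 : x1 + 1]
    mask[y0 : y1 + 1, x0 : x1 + 1] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return mask


@dataclass
class PlateTruth:
    """Ground truth emitted with a simulated plate (shares its rng_seed).

    ``true_areas[i, k]`` is colony i's analytic area at frame k.
    ``merge_events`` holds (i, j, frame_index): the first frame at which the
    rendered disks of colonies i and j share a pixel.
    """

    times_h: np.ndarray
    colonies: list[ColonySpec]
    true_areas: np.ndarray
    merge_events: list[tuple[int, int, int]]
    rng_seed: int

    def merged_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.merge_events}


def simulate_plate(
    spec: SyntheticPlateSpec, allow_visible_at_start: bool = False
) -> tuple[ImageSeries, PlateTruth]:
    """Render a plate time-lapse and its ground truth.

    By default every colony must still be invisible at the first frame, so
    that frame 0 is a valid colony-free background image; pass
    ``allow_visible_at_start=True`` to waive this (e.g. for zero-lag area
    checks that bypass background subtraction).
    """
    times = spec.times_h
    h, w = spec.image_height_px, spec.image_width_px
    n_col = len(spec.colonies)
    true_areas = np.array(
        [[colony_true_area(c, t) for t in times] for c in spec.colonies]
    ).reshape(n_col, len(times))
    if n_col and not allow_visible_at_start and np.any(true_areas[:, 0] > 0):
        raise ValueError(
            "frame 0 must be colony-free (all lag_h past the first frame); "
            "pass allow_visible_at_start=True to override"
        )
    for i, c in enumerate(spec.colonies):
        if c.edge_ok or n_col == 0:
            continue
        r = math.sqrt(true_areas[i].max() / math.pi) if true_areas[i].max() > 0 else 0.0
        if (
            c.center_x_px - r < 0
            or c.center_x_px + r > w - 1
            or c.center_y_px - r < 0
            or c.center_y_px + r > h - 1
        ):
            raise PlateGeometryError(
                f"colony {i} disk (radius {r:.1f}) exceeds the frame; "
                "set edge_ok=True if this edge colony is intended"
            )

    rng = np.random.default_rng(spec.rng_seed)
    frames = np.empty((len(times), h, w, 3))
    merge_events: list[tuple[int, int, int]] = []
    seen_pairs: set[tuple[int, int]] = set()
    for k in range(len(times)):
        v = np.full((h, w), spec.background_level)
        live: list[tuple[int, np.ndarray, float]] = []
        for i, c in enumerate(spec.colonies):
            a = true_areas[i, k]
            if a > 0:
                m = render_colony_mask((h, w), c, a)
                v[m] = spec.colony_level
                live.append((i, m, math.sqrt(a / math.pi)))
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                i, mi, ri = live[ai]
                j, mj, rj = live[bi]
                if (i, j) in seen_pairs:
                    continue
                ci, cj = spec.colonies[i], spec.colonies[j]
                d = math.hypot(ci.center_x_px - cj.center_x_px, ci.center_y_px - cj.center_y_px)
                if d <= ri + rj + 2 and bool((mi & mj).any()):
                    merge_events.append((i, j, k))
                    seen_pairs.add((i, j))
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
        v = np.clip(v, 0.0, 1.0)
        frames[k] = v[..., None]
    series = ImageSeries(frames, times)
    truth = PlateTruth(times, list(spec.colonies), true_areas, merge_events, spec.rng_seed)
    return series, truth


def random_plate_spec(
    n_colonies: int,
    *,
    image_height_px: int = 260,
    image_width_px: int = 400,
    frame_interval_h: float = 2.0,
    n_frames: int = 129,
    rate_range: tuple[float, float] = (0.1, 0.6),
    lag_range_h: tuple[float, float] = (20.0, 120.0),
    initial_area_px: float = 150.0,
    max_area_px: float = 3000.0,
    background_level: float = 0.10,
    colony_level: float = 0.60,
    noise_sd: float = 0.10,
    rng_seed: int = 0,
) -> SyntheticPlateSpec:
    """Well-separated random colonies on a jittered grid.

    Grid spacing exceeds twice the final radius, and centres keep clear of
    the border margin, so none of the generated colonies ever merges or
    touches the dish edge — the controlled setting for rate-recovery studies.
    """
    rng = np.random.default_rng(rng_seed)
    r_max = math.ceil(math.sqrt(max_area_px / math.pi))
    margin = r_max + 10
    spacing = 2 * r_max + 6
    rows = np.arange(margin, image_height_px - margin + 1, spacing)
    cols = np.arange(margin, image_width_px - margin + 1, spacing)
    cells = [(int(r), int(c)) for r in rows for c in cols]
    if n_colonies > len(cells):
        raise ValueError(
            f"cannot place {n_colonies} isolated colonies on a "
            f"{image_height_px}x{image_width_px} plate (room for {len(cells)})"
        )
    order = rng.permutation(len(cells))[:n_colonies]
    colonies = []
    for idx in order:
        r, c = cells[idx]
        jr, jc = rng.integers(-2, 3, size=2)
        colonies.append(
            ColonySpec(
                center_x_px=float(c + jc),
                center_y_px=float(r + jr),
                lag_h=float(rng.uniform(*lag_range_h)),
                initial_area_px=initial_area_px,
                growth_rate_per_h=float(rng.uniform(*rate_range)),
                max_area_px=max_area_px,
            )
        )
    return SyntheticPlateSpec(
        image_height_px=image_height_px,
        image_width_px=image_width_px,
        frame_interval_h=frame_interval_h,
        n_frames=n_frames,
        colonies=colonies,
        background_level=background_level,
        colony_level=colony_level,
        noise_sd=noise_sd,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
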