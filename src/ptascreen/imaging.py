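"""Plate-scan image analysis: colony time-lapses to per-colony area tracks.

The pipeline mirrors a flatbed-scanner colony screen. RGB frames are reduced
to the HSV value channel (V = max of R, G, B), the colony-free first frame is
subtracted as background, frames are smoothed twice with a fine-grain Gaussian
(sd 1 px, 7 px support) and thresholded with a single global threshold into
biomass masks. Colony centres are regional peaks of the through-time
z-projection (per-pixel sum of the binary masks), and touching colonies are
split every frame by a seeded watershed on the negated Euclidean distance
transform. A colony's area at a frame is the pixel count of its watershed
label; colonies on the dish edge, merged with an edge colony, or inside a
blob with an ambiguous number of peaks are flagged and excluded.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

EDGE = "edge"
MERGED_WITH_EDGE = "merged_with_edge"
AMBIGUOUS_MERGE = "ambiguous_merge"


@dataclass
class ImageSeries:
    """Timestamped stack of RGB plate frames.

    Parameters
    ----------
    frames : array, shape (n_frames, height, width, 3)
        RGB rasters with values in [0, 1]. Frame 0 is the colony-free
        background frame.
    times_h : array, shape (n_frames,)
        Strictly increasing acquisition times in hours.
    """

    frames: np.ndarray
    times_h: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be RGB with shape (n, h, w, 3)")
        if self.frames.shape[0] != self.times_h.shape[0]:
            raise ValueError("need exactly one timestamp per frame")
        if self.frames.shape[0] < 1:
            raise ValueError("empty image series")
        if self.times_h.size > 1 and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class PreprocessParams:
    """Preprocessing knobs for the mask pipeline.

    ``threshold_v`` is either a scalar in [0, 1] applied to every frame, or
    the sentinel ``"auto"``: Otsu's threshold computed on the final
    background-subtracted smoothed frame, whose histogram is the best
    separated. A degenerate (near-constant) final frame triggers a warning
    and a fall back to ``fallback_threshold_v``.
    """

    gaussian_sd_px: float = 1.0
    gaussian_width_px: int = 7
    smoothing_passes: int = 2
    threshold_v: float | str = "auto"
    fallback_threshold_v: float = 0.1
    invert: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_width_px < 1 or self.gaussian_width_px % 2 != 1:
            raise ValueError("gaussian_width_px must be odd and >= 1")
        if self.gaussian_sd_px <= 0:
            raise ValueError("gaussian_sd_px must be positive")
        if self.smoothing_passes < 1:
            raise ValueError("smoothing_passes must be >= 1")
        if isinstance(self.threshold_v, str):
            if self.threshold_v != "auto":
                raise ValueError("threshold_v must be a scalar or 'auto'")
        else:
            self.threshold_v = float(self.threshold_v)
            if not 0.0 <= self.threshold_v <= 1.0:
                raise ValueError("threshold_v must lie in [0, 1]")

    @property
    def kernel_radius_px(self) -> int:
        return (self.gaussian_width_px - 1) // 2

    @property
    def _truncate(self) -> float:
        # scipy's gaussian_filter truncates at truncate*sd; pin it so the
        # support is exactly gaussian_width_px samples.
        return self.kernel_radius_px / self.gaussian_sd_px


def gaussian_kernel_1d(params: PreprocessParams) -> np.ndarray:
    """Truncated, renormalized 1-D Gaussian kernel used by :func:`smooth`.

    The 2-D kernel is the outer product of this kernel with itself (the
    truncation window is a square, so separable filtering is exact).
    """
    r = params.kernel_radius_px
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / params.gaussian_sd_px) ** 2)
    return k / k.sum()


@dataclass(frozen=True)
class ColonySeed:
    """A colony centre: a regional peak of the z-projection."""

    seed_id: int
    row_px: int
    col_px: int


@dataclass
class ColonyTrack:
    """One colony's per-frame pixel area plus exclusion flags."""

    seed_id: int
    seed_row_px: int
    seed_col_px: int
    times_h: np.ndarray
    area_px: np.ndarray
    flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


def to_value_channel(series: ImageSeries, invert: bool = False) -> np.ndarray:
    """HSV value channel of every frame: per pixel V = max(R, G, B) in [0, 1].

    ``invert`` flips the signal (1 - V) for scans where colonies are darker
    than the background.
    """
    if not isinstance(series, ImageSeries):
        raise TypeError("to_value_channel expects an ImageSeries of RGB frames")
    v = series.frames.max(axis=-1)
    return 1.0 - v if invert else v


def subtract_background(values: np.ndarray) -> np.ndarray:
    """Subtract the colony-free first frame from every frame, clipped to [0, 1].

    Frame 0 becomes all-zero by construction.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] < 2:
        raise ValueError("need a grayscale stack with at least 2 frames")
    return np.clip(values - values[0], 0.0, 1.0)


def _smooth_frame(frame: np.ndarray, params: PreprocessParams, passes: int) -> np.ndarray:
    out = np.asarray(frame, dtype=float)
    for _ in range(passes):
        out = ndi.gaussian_filter(
            out, params.gaussian_sd_px, truncate=params._truncate, mode="reflect"
        )
    return out


def smooth(values: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Convolve each frame ``smoothing_passes`` times with the truncated
    renormalized Gaussian kernel (default: twice, sd 1 px, 7x7 support)."""
    params = params or PreprocessParams()
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i, frame in enumerate(values):
        out[i] = _smooth_frame(frame, params, params.smoothing_passes)
    return out


def resolve_threshold(values: np.ndarray, params: PreprocessParams) -> float:
    """Resolve the single global threshold (explicit scalar or Otsu 'auto')."""
    if not isinstance(params.threshold_v, str):
        return float(params.threshold_v)
    last = np.asarray(values[-1], dtype=float)
    span = float(last.max() - last.min())
    if span < 1e-6:
        log.warning(
            "auto threshold degenerate (final frame nearly constant); "
            "falling back to %.3f",
            params.fallback_threshold_v,
        )
        return params.fallback_threshold_v
    thr = float(threshold_otsu(last))
    if not last.min() < thr < last.max():
        log.warning(
            "Otsu threshold %.4f outside the data range; falling back to %.3f",
            thr,
            params.fallback_threshold_v,
        )
        return params.fallback_threshold_v
    return thr


def threshold_series(
    values: np.ndarray, params: PreprocessParams | None = None
) -> tuple[np.ndarray, float]:
    """Apply one scalar threshold to every frame; pixel on iff value > threshold.

    Returns the boolean mask stack and the threshold actually used.
    """
    params = params or PreprocessParams()
    values = np.asarray(values, dtype=float)
    thr = resolve_threshold(values, params)
    return values > thr, thr


def detect_colony_seeds(
    masks: np.ndarray,
    min_seed_separation_px: int = 10,
    params: PreprocessParams | None = None,
) -> list[ColonySeed]:
    """Colony centres as regional maxima of the through-time z-projection.

    The z-projection is the per-pixel sum of the binary masks over time,
    smoothed once with the preprocessing kernel to stabilize maxima on the
    integer-valued sum. Peaks closer than ``min_seed_separation_px`` are
    suppressed and every seed must lie on the final-frame foreground.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("masks must be a (n, h, w) boolean stack")
    zproj = masks.sum(axis=0).astype(float)
    if zproj.max() == 0:
        return []
    params = params or PreprocessParams()
    proj = _smooth_frame(zproj, params, passes=1)
    coords = peak_local_max(
        proj,
        min_distance=int(min_seed_separation_px),
        threshold_abs=1e-9,
        exclude_border=False,
    )
    final = masks[-1]
    kept = sorted((int(r), int(c)) for r, c in coords if final[r, c])
    return [ColonySeed(i + 1, r, c) for i, (r, c) in enumerate(kept)]


def split_merged_colonies(
    mask: np.ndarray, seeds: list[ColonySeed], warn_dropped: bool = True
) -> np.ndarray:
    """Partition one binary frame among seeds by watershed on the distance map.

    The Euclidean distance transform of the foreground is negated and flooded
    from the seed markers, so the dividing line between merged colonies falls
    along the ridge between their distance peaks. Background pixels get label
    0; seeds that do not lie on foreground are dropped (the colony has not
    appeared yet in this frame).
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.zeros(mask.shape, dtype=np.int32)
    dropped = []
    for s in seeds:
        if mask[s.row_px, s.col_px]:
            markers[s.row_px, s.col_px] = s.seed_id
        else:
            dropped.append(s.seed_id)
    if dropped and warn_dropped:
        log.warning("seeds off foreground dropped for this frame: %s", dropped)
    if not markers.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def track_areas(
    masks: np.ndarray, times_h: np.ndarray, seeds: list[ColonySeed]
) -> list[ColonyTrack]:
    """Per-seed area time series: pixels of each watershed label per frame.

    The watershed is rerun on every frame with the global seeds, so track
    identity is stable by construction; frames before a colony appears give
    area 0.
    """
    masks = np.asarray(masks, dtype=bool)
    times_h = np.asarray(times_h, dtype=float)
    if not seeds:
        return []
    max_id = max(s.seed_id for s in seeds)
    areas = np.zeros((max_id + 1, masks.shape[0]))
    for t, mask in enumerate(masks):
        labels = split_merged_colonies(mask, seeds, warn_dropped=False)
        counts = np.bincount(labels.ravel(), minlength=max_id + 1)
        areas[: len(counts), t] = counts
    return [
        ColonyTrack(s.seed_id, s.row_px, s.col_px, times_h, areas[s.seed_id].copy())
        for s in seeds
    ]


def apply_exclusions(
    tracks: list[ColonyTrack],
    masks: np.ndarray,
    edge_margin_px: int = 5,
    max_seeds_per_component: int = 5,
) -> list[ColonyTrack]:
    """Flag colonies excluded from the growth-rate analysis (in place).

    ``edge``: the colony's final-frame watershed region reaches within
    ``edge_margin_px`` of the image border. ``merged_with_edge``: the colony
    shares a final-frame connected component with an edge colony.
    ``ambiguous_merge``: its component holds more than
    ``max_seeds_per_component`` seeds. Any flag sets ``excluded``.
    """
    masks = np.asarray(masks, dtype=bool)
    final = masks[-1]
    seeds = [ColonySeed(t.seed_id, t.seed_row_px, t.seed_col_px) for t in tracks]
    labels = split_merged_colonies(final, seeds, warn_dropped=False)
    comp, _ = ndi.label(final)
    m = int(edge_margin_px)
    border = np.zeros(final.shape, dtype=bool)
    if m > 0:
        border[:m, :] = True
        border[-m:, :] = True
        border[:, :m] = True
        border[:, -m:] = True
    comp_of: dict[int, int] = {}
    for tr in tracks:
        region = labels == tr.seed_id
        if not region.any():
            comp_of[tr.seed_id] = 0
            continue
        comp_of[tr.seed_id] = int(comp[region][0])
        if bool((region & border).any()):
            tr.flags.add(EDGE)
    comp_counts = Counter(c for c in comp_of.values() if c > 0)
    edge_comps = {comp_of[t.seed_id] for t in tracks if EDGE in t.flags}
    for tr in tracks:
        c = comp_of[tr.seed_id]
        if c == 0:
            continue
        if c in edge_comps and EDGE not in tr.flags:
            tr.flags.add(MERGED_WITH_EDGE)
        if comp_counts[c] > max_seeds_per_component:
            tr.flags.add(AMBIGUOUS_MERGE)
    return tracks


@dataclass
class PlateAnalysis:
    """Everything the imaging stage produces for one plate."""

    tracks: list[ColonyTrack]
    seeds: list[ColonySeed]
    masks: np.ndarray
    threshold_v: float


def analyze_plate(
    series: ImageSeries,
    params: PreprocessParams | None = None,
    min_seed_separation_px: int = 10,
    edge_margin_px: int = 5,
    max_seeds_per_component: int = 5,
) -> PlateAnalysis:
    """Run the full imaging pipeline on one plate time-lapse."""
    params = params or PreprocessParams()
    v = to_value_channel(series, invert=params.invert)
    sub = subtract_background(v)
    sm = smooth(sub, params)
    masks, thr = threshold_series(sm, params)
    seeds = detect_colony_seeds(masks, min_seed_separation_px, params)
    tracks = track_areas(masks, series.times_h, seeds)
    apply_exclusions(tracks, masks, edge_margin_px, max_seeds_per_component)
    return PlateAnalysis(tracks=tracks, seeds=seeds, masks=masks, threshold_v=thr)
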