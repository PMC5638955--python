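"""The imaging pipeline: V channel, background, smoothing, masks, seeds,
watershed splitting, tracking and exclusions."""
import math

import numpy as np
import pytest
from scipy.signal import convolve2d

from ptascreen.imaging import (
    AMBIGUOUS_MERGE,
    EDGE,
    MERGED_WITH_EDGE,
    ColonySeed,
    ImageSeries,
    PreprocessParams,
    analyze_plate,
    apply_exclusions,
    detect_colony_seeds,
    gaussian_kernel_1d,
    smooth,
    split_merged_colonies,
    subtract_background,
    threshold_series,
    to_value_channel,
    track_areas,
)
from ptascreen.simulate import colony_true_area, simulate_plate
from conftest import make_colony, make_plate


# ---------------------------------------------------------------------- V channel

@pytest.mark.parametrize(
    "rgb,expected",
    [((255, 255, 255), 1.0), ((0, 0, 0), 0.0), ((51, 128, 77), 128 / 255)],
)
def test_value_channel_is_max_of_rgb(rgb, expected):
    frames = np.zeros((1, 1, 1, 3))
    frames[0, 0, 0] = np.array(rgb) / 255
    series = ImageSeries(frames, np.array([0.0]))
    assert to_value_channel(series)[0, 0, 0] == pytest.approx(expected)


def test_non_rgb_input_rejected():
    with pytest.raises(ValueError):
        ImageSeries(np.zeros((2, 4, 4)), np.array([0.0, 1.0]))
    with pytest.raises(TypeError):
        to_value_channel(np.zeros((2, 4, 4, 3)))


# ----------------------------------------------------------------- background

def test_identical_frames_subtract_to_zero():
    v = np.full((3, 8, 8), 0.4)
    assert np.all(subtract_background(v) == 0)


def test_disk_offset_survives_subtraction(gray_series):
    v = to_value_channel(gray_series)
    sub = subtract_background(v)
    assert np.all(sub[0] == 0)
    assert sub[1, 7, 7] == pytest.approx(0.4)
    assert sub[1, 0, 0] == pytest.approx(0.0)


# ------------------------------------------------------------------- smoothing

def test_constant_frame_unchanged_by_smoothing():
    v = np.full((1, 16, 16), 0.3)
    assert np.allclose(smooth(v), 0.3)


def test_impulse_center_equals_truncated_kernel_center_weight():
    # independent oracle: renormalized 7-tap Gaussian, squared for 2-D
    k = np.exp(-0.5 * np.arange(-3, 4.0) ** 2)
    k /= k.sum()
    expected = k[3] ** 2
    v = np.zeros((1, 21, 21))
    v[0, 10, 10] = 1.0
    out = smooth(v, PreprocessParams(smoothing_passes=1))
    assert out[0, 10, 10] == pytest.approx(expected, rel=1e-12)
    assert np.allclose(gaussian_kernel_1d(PreprocessParams()), k)


def test_two_passes_equal_self_convolved_kernel():
    rng = np.random.default_rng(3)
    img = rng.random((31, 31))
    params = PreprocessParams()  # two passes
    out = smooth(img[None], params)[0]
    k1 = np.outer(gaussian_kernel_1d(params), gaussian_kernel_1d(params))
    k2 = convolve2d(k1, k1)  # 13x13 self-convolution
    oracle = convolve2d(img, k2, mode="same", boundary="symm")
    # compare away from the border where boundary conventions differ
    assert np.allclose(out[8:-8, 8:-8], oracle[8:-8, 8:-8], atol=1e-10)


# ------------------------------------------------------------------ threshold

def test_threshold_trivial_masks():
    v = np.full((2, 6, 6), 0.4)
    masks, thr = threshold_series(v, PreprocessParams(threshold_v=0.5))
    assert thr == 0.5 and not masks.any()
    v[1, 2:4, 2:4] = 0.8
    masks, _ = threshold_series(v, PreprocessParams(threshold_v=0.5))
    assert masks[1].sum() == 4 and not masks[0].any()


def test_raising_threshold_never_grows_foreground(rng):
    v = rng.random((4, 16, 16))
    lo, _ = threshold_series(v, PreprocessParams(threshold_v=0.3))
    hi, _ = threshold_series(v, PreprocessParams(threshold_v=0.6))
    assert np.all(hi <= lo)


def test_auto_threshold_recovers_synthetic_areas_within_rasterization_error():
    colony = make_colony(70, 70, lag_h=4.0, initial_area_px=120.0, rate=0.2, max_area_px=2500.0)
    spec = make_plate([colony], noise_sd=0.01)
    series, truth = simulate_plate(spec)
    sub = subtract_background(to_value_channel(series))
    masks, thr = threshold_series(smooth(sub), PreprocessParams(threshold_v="auto"))
    assert 0.0 < thr < 0.5
    for k in range(series.n_frames):
        a = truth.true_areas[0, k]
        if a < 50:
            continue
        count = int(masks[k].sum())
        assert abs(count - a) <= 0.15 * a + 2 * math.pi * math.sqrt(a / math.pi)


def test_degenerate_auto_threshold_falls_back():
    v = np.full((2, 8, 8), 0.2)
    _, thr = threshold_series(v, PreprocessParams(threshold_v="auto", fallback_threshold_v=0.17))
    assert thr == 0.17


# ---------------------------------------------------------------------- seeds

def _pipeline_masks(spec):
    series, truth = simulate_plate(spec)
    sub = subtract_background(to_value_channel(series))
    masks, _ = threshold_series(smooth(sub), PreprocessParams(threshold_v=0.25))
    return series, truth, masks


def test_single_colony_gives_one_seed_inside_its_disk():
    colony = make_colony(70, 70, lag_h=4.0, rate=0.2)
    _, _, masks = _pipeline_masks(make_plate([colony], noise_sd=0.02))
    seeds = detect_colony_seeds(masks, 12)
    assert len(seeds) == 1
    assert math.hypot(seeds[0].row_px - 70, seeds[0].col_px - 70) < 10


def test_two_separated_colonies_give_two_seeds_near_truth_centers():
    colonies = [make_colony(40, 45, lag_h=4.0), make_colony(100, 95, lag_h=8.0)]
    _, _, masks = _pipeline_masks(make_plate(colonies, noise_sd=0.02))
    seeds = detect_colony_seeds(masks, 12)
    assert len(seeds) == 2


def test_late_merging_pair_still_gives_two_seeds():
    # disks eventually touch, but early frames dominate the z-projection
    c1 = make_colony(55, 70, lag_h=2.0, rate=0.15, max_area_px=1100.0)
    c2 = make_colony(85, 70, lag_h=6.0, rate=0.15, max_area_px=1100.0)
    _, truth, masks = _pipeline_masks(make_plate([c1, c2], n_frames=40, noise_sd=0.02))
    assert truth.merged_pairs() == {(0, 1)}
    seeds = detect_colony_seeds(masks, 12)
    assert len(seeds) == 2


def test_empty_masks_give_no_seeds():
    assert detect_colony_seeds(np.zeros((3, 10, 10), bool), 5) == []


def test_seed_count_matches_colony_count_on_random_plates():
    # colonies spaced >= 3x the seed separation: one seed per colony, always
    from ptascreen.simulate import random_plate_spec

    for i in range(15):
        spec = random_plate_spec(
            4,
            image_height_px=180,
            image_width_px=230,
            n_frames=33,
            initial_area_px=100.0,
            max_area_px=1500.0,
            noise_sd=0.05,
            lag_range_h=(6.0, 40.0),
            rate_range=(0.1, 0.4),
            rng_seed=100 + i,
        )
        series, truth = simulate_plate(spec)
        analysis = analyze_plate(series, min_seed_separation_px=12)
        assert len(analysis.seeds) == len(truth.colonies)


# ------------------------------------------------------------------ watershed

def test_single_seed_labels_whole_component():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    labels = split_merged_colonies(mask, [ColonySeed(1, 10, 10)])
    assert np.array_equal(labels > 0, mask)
    assert set(np.unique(labels)) == {0, 1}


def test_dumbbell_partition_conserves_component_area():
    mask = np.zeros((30, 50), bool)
    yy, xx = np.ogrid[:30, :50]
    mask |= (yy - 15) ** 2 + (xx - 15) ** 2 <= 81
    mask |= (yy - 15) ** 2 + (xx - 34) ** 2 <= 81
    mask[14:17, 15:35] = True  # bridge
    seeds = [ColonySeed(1, 15, 15), ColonySeed(2, 15, 34)]
    labels = split_merged_colonies(mask, seeds)
    a1, a2 = (labels == 1).sum(), (labels == 2).sum()
    assert a1 + a2 == mask.sum()
    assert a1 > 0 and a2 > 0


def test_merged_pair_split_close_to_bisector_oracle():
    # equal colonies merged at the final frame: watershed split should sit on
    # the perpendicular bisector, so label areas match a nearest-centre split
    c1 = make_colony(55, 70, lag_h=2.0, rate=0.25, max_area_px=1200.0)
    c2 = make_colony(85, 70, lag_h=2.0, rate=0.25, max_area_px=1200.0)
    spec = make_plate([c1, c2], n_frames=33, noise_sd=0.0)
    series, truth = simulate_plate(spec)
    k = truth.merge_events[0][2] + 3  # a few frames after first contact
    v = series.frames[k].max(axis=-1)
    mask = v > 0.35
    seeds = [ColonySeed(1, 70, 55), ColonySeed(2, 70, 85)]
    labels = split_merged_colonies(mask, seeds)
    yy, xx = np.indices(mask.shape)
    nearer1 = ((yy - 70) ** 2 + (xx - 55) ** 2) <= ((yy - 70) ** 2 + (xx - 85) ** 2)
    want1 = int((mask & nearer1).sum())
    want2 = int((mask & ~nearer1).sum())
    assert (labels == 1).sum() == pytest.approx(want1, rel=0.10)
    assert (labels == 2).sum() == pytest.approx(want2, rel=0.10)


def test_off_foreground_seeds_are_dropped():
    mask = np.zeros((10, 10), bool)
    mask[2:5, 2:5] = True
    labels = split_merged_colonies(mask, [ColonySeed(1, 3, 3), ColonySeed(2, 8, 8)])
    assert set(np.unique(labels)) == {0, 1}


# ------------------------------------------------------------------- tracking

def test_empty_plate_yields_no_tracks():
    assert track_areas(np.zeros((3, 8, 8), bool), np.arange(3.0), []) == []


def test_isolated_colony_track_matches_truth_within_tolerance():
    colony = make_colony(70, 70, lag_h=6.0, initial_area_px=120.0, rate=0.2, max_area_px=2500.0)
    analysis = analyze_plate(simulate_plate(make_plate([colony], noise_sd=0.02))[0],
                             min_seed_separation_px=13)
    assert len(analysis.tracks) == 1
    tr = analysis.tracks[0]
    assert not tr.excluded
    for k, t in enumerate(np.arange(33) * 2.0):
        a = colony_true_area(colony, t)
        if a >= 50:
            assert abs(tr.area_px[k] - a) / a <= 0.15
        if t < colony.lag_h:
            assert tr.area_px[k] == 0


def test_merged_pair_areas_sum_to_component_area():
    c1 = make_colony(55, 70, lag_h=2.0, rate=0.25, max_area_px=1200.0)
    c2 = make_colony(85, 70, lag_h=2.0, rate=0.25, max_area_px=1200.0)
    series, truth = simulate_plate(make_plate([c1, c2], noise_sd=0.02))
    analysis = analyze_plate(series, min_seed_separation_px=13)
    assert len(analysis.tracks) == 2
    for k in range(series.n_frames):
        total = sum(tr.area_px[k] for tr in analysis.tracks)
        assert total == analysis.masks[k].sum()


# ----------------------------------------------------------------- exclusions

def test_centered_colony_gets_no_flags():
    series, _ = simulate_plate(make_plate([make_colony(70, 70, lag_h=4.0)]))
    analysis = analyze_plate(series, min_seed_separation_px=13)
    assert analysis.tracks[0].flags == set()
    assert not analysis.tracks[0].excluded


def test_border_touching_colony_gets_edge_flag():
    colony = make_colony(70, 12, lag_h=4.0, rate=0.25, max_area_px=900.0, edge_ok=True)
    series, _ = simulate_plate(make_plate([colony]))
    analysis = analyze_plate(series, min_seed_separation_px=13)
    assert EDGE in analysis.tracks[0].flags
    assert analysis.tracks[0].excluded


def test_partner_of_edge_colony_gets_merged_with_edge():
    edge = make_colony(70, 12, lag_h=4.0, rate=0.25, max_area_px=900.0, edge_ok=True)
    partner = make_colony(70, 40, lag_h=6.0, rate=0.25, max_area_px=900.0)
    series, _ = simulate_plate(make_plate([edge, partner]))
    analysis = analyze_plate(series, min_seed_separation_px=13)
    flags = {(t.seed_row_px, t.seed_col_px < 26): t.flags for t in analysis.tracks}
    by_col = sorted(analysis.tracks, key=lambda t: t.seed_col_px)
    assert EDGE in by_col[0].flags
    assert by_col[1].flags == {MERGED_WITH_EDGE}


def test_six_way_blob_flagged_ambiguous_with_cap_five():
    colonies = [
        make_colony(30 + 22 * i, 70, lag_h=4.0 + 3 * i, initial_area_px=80.0,
                    rate=0.08, max_area_px=700.0)
        for i in range(6)
    ]
    series, _ = simulate_plate(make_plate(colonies, h=140, w=190, n_frames=60, noise_sd=0.02))
    analysis = analyze_plate(series, min_seed_separation_px=10, max_seeds_per_component=5)
    assert len(analysis.tracks) == 6
    for tr in analysis.tracks:
        assert AMBIGUOUS_MERGE in tr.flags


def test_apply_exclusions_leaves_zero_area_tracks_unflagged():
    masks = np.zeros((3, 20, 20), bool)
    masks[2, 5:9, 5:9] = True
    tracks = track_areas(masks, np.arange(3.0), [ColonySeed(1, 6, 6), ColonySeed(2, 15, 15)])
    apply_exclusions(tracks, masks, edge_margin_px=2)
    assert tracks[1].flags == set()
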