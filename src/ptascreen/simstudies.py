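"""End-to-end recovery studies on synthetic data with known ground truth.

Each study regenerates its inputs from a seed, runs the production code
path, and returns summary statistics: how well the imaging + moving-window
pipeline recovers colony growth rates, whether the watershed partition is
conserved, whether the interval-based conserved-region scan agrees with the
per-base oracle and with the closed-form run-count expectation, and so on.
These are the package's self-checks; the test suite asserts on their
outputs and ``scripts/acceptance.py`` reports them.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .growth import compare_groups, max_window_slope, od_rates_table
from .imaging import (
    AMBIGUOUS_MERGE,
    EDGE,
    MERGED_WITH_EDGE,
    analyze_plate,
    split_merged_colonies,
)
from .promoters import PromoterWindow, VariantSet, find_conserved_regions
from .simulate import (
    ColonySpec,
    SyntheticODSpec,
    SyntheticPlateSpec,
    WellSpec,
    bruteforce_conserved_regions,
    random_plate_spec,
    simulate_od,
    simulate_plate,
    simulate_snp_windows,
)


def _child_seed(seed: int, k: int) -> int:
    return (int(seed) * 9973 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Conserved-region studies
# ---------------------------------------------------------------------------

def cr_oracle_study(
    seed: int, n_windows: int = 1000, window_bp: int = 1000, snp_prob: float = 0.02
) -> dict:
    """Interval-based CR scan versus the per-base brute-force oracle.

    Returns the number of windows whose CR interval lists differ (should be
    zero) over ``n_windows`` random Bernoulli-SNP windows.
    """
    rng = np.random.default_rng(_child_seed(seed, 1))
    mismatches = 0
    for i, pos in enumerate(simulate_snp_windows(n_windows, window_bp, snp_prob, rng)):
        win = PromoterWindow(f"w{i}", "c", 1, window_bp, "+")
        got = [(cr.start, cr.end) for cr in find_conserved_regions(win, VariantSet({"c": pos}))]
        want = bruteforce_conserved_regions(1, window_bp, pos)
        if got != want:
            mismatches += 1
    return {
        "n_windows": n_windows,
        "n_mismatching_windows": mismatches,
        "match_fraction": (n_windows - mismatches) / n_windows,
    }


def cr_conservation_study(seed: int, n_windows: int = 1000) -> dict:
    """Sum of CR lengths + in-window variant count must equal window length.

    Window lengths and SNP densities vary randomly; returns the maximum
    absolute residual in bp (should be exactly 0).
    """
    rng = np.random.default_rng(_child_seed(seed, 2))
    max_resid = 0
    for i in range(n_windows):
        w = int(rng.integers(50, 1001))
        p = float(rng.uniform(0.0, 0.2))
        pos = simulate_snp_windows(1, w, p, rng)[0]
        win = PromoterWindow(f"w{i}", "c", 1, w, "+")
        crs = find_conserved_regions(win, VariantSet({"c": pos}))
        resid = w - (sum(cr.length for cr in crs) + len(pos))
        max_resid = max(max_resid, abs(resid))
    return {"n_windows": n_windows, "max_abs_residual_bp": max_resid}


def expected_run_count(window_bp: int, min_len: int, snp_prob: float) -> float:
    """Closed-form mean number of maximal SNP-free runs of length >= L.

    For iid per-base SNPs with probability p in a window of W bases:
    (1 - p)^L * (1 + (W - L) p).
    """
    p, w, L = snp_prob, window_bp, min_len
    return (1 - p) ** L * (1 + (w - L) * p)


def cr_run_count_study(
    seed: int,
    n_windows: int = 10000,
    window_bp: int = 1000,
    snp_prob: float = 0.02,
    min_len: int = 31,
) -> dict:
    """Mean count of targetable-length CRs per window versus the closed form."""
    rng = np.random.default_rng(_child_seed(seed, 3))
    counts = np.empty(n_windows)
    for i, pos in enumerate(simulate_snp_windows(n_windows, window_bp, snp_prob, rng)):
        win = PromoterWindow(f"w{i}", "c", 1, window_bp, "+")
        crs = find_conserved_regions(win, VariantSet({"c": pos}))
        counts[i] = sum(1 for cr in crs if cr.length >= min_len)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(n_windows))
    expected = expected_run_count(window_bp, min_len, snp_prob)
    return {
        "n_windows": n_windows,
        "mean_count": mean,
        "se": se,
        "expected": expected,
        "z": (mean - expected) / se,
    }


# ---------------------------------------------------------------------------
# Imaging / growth-rate studies
# ---------------------------------------------------------------------------

def growth_recovery_study(
    seed: int,
    n_plates: int = 10,
    colonies_per_plate: int = 10,
    n_zero_rate: int = 10,
    match_radius_px: float = 15.0,
) -> dict:
    """Recover colony growth rates end to end from rendered plate movies.

    ``n_plates * colonies_per_plate`` isolated colonies with rates drawn
    U[0.1, 0.6]/h are scanned every 2 h for 256 h at SNR 5 (colony 0.6 over
    background 0.1, noise sd 0.1) and pushed through the full imaging
    pipeline plus the 12-h moving-window estimator. A further plate of
    ``n_zero_rate`` zero-rate colonies checks that the no-growth phenotype
    stays below any real growth signal.
    """
    true_rates: list[float] = []
    est_rates: list[float] = []
    unmatched = 0
    for p in range(n_plates):
        spec = random_plate_spec(colonies_per_plate, rng_seed=_child_seed(seed, 10 + p))
        series, truth = simulate_plate(spec)
        analysis = analyze_plate(series, min_seed_separation_px=_seed_separation(spec))
        for i, colony in enumerate(truth.colonies):
            track = _nearest_track(analysis.tracks, colony, match_radius_px)
            if track is None or track.excluded:
                unmatched += 1
                continue
            res = max_window_slope(track)
            if not res.has_estimate:
                unmatched += 1
                continue
            true_rates.append(colony.growth_rate_per_h)
            est_rates.append(res.rate_per_h)
    true_arr = np.array(true_rates)
    est_arr = np.array(est_rates)
    rel_err = np.abs(est_arr - true_arr) / true_arr

    zero_spec = random_plate_spec(
        n_zero_rate, rate_range=(0.0, 0.0), rng_seed=_child_seed(seed, 99)
    )
    zseries, ztruth = simulate_plate(zero_spec)
    zanalysis = analyze_plate(zseries, min_seed_separation_px=_seed_separation(zero_spec))
    zero_rates = []
    for colony in ztruth.colonies:
        track = _nearest_track(zanalysis.tracks, colony, match_radius_px)
        if track is None:
            unmatched += 1
            continue
        res = max_window_slope(track)
        zero_rates.append(res.rate_per_h if res.has_estimate else 0.0)
    return {
        "n_colonies": n_plates * colonies_per_plate,
        "n_matched": int(true_arr.size),
        "n_unmatched": unmatched,
        "median_rel_err": float(np.median(rel_err)) if rel_err.size else float("nan"),
        "max_rel_err": float(rel_err.max()) if rel_err.size else float("nan"),
        "true_rates": true_arr,
        "est_rates": est_arr,
        "n_zero_rate": n_zero_rate,
        "zero_rate_max_estimate": float(max(zero_rates)) if zero_rates else float("nan"),
    }


def _seed_separation(spec: SyntheticPlateSpec) -> int:
    """Minimum seed separation: the colony diameter at first detection.

    Two regional peaks closer than a just-appeared colony's footprint must
    belong to the same colony, so the separation is set to the disk diameter
    of the smallest initial area on the plate (plus 1 px of slack).
    """
    a0 = min(c.initial_area_px for c in spec.colonies)
    return int(math.ceil(2 * math.sqrt(a0 / math.pi))) + 1


def _nearest_track(tracks, colony: ColonySpec, radius: float):
    best, best_d = None, radius
    for tr in tracks:
        d = math.hypot(tr.seed_col_px - colony.center_x_px, tr.seed_row_px - colony.center_y_px)
        if d <= best_d:
            best, best_d = tr, d
    return best


def exclusion_fixture_spec(seed: int) -> tuple[SyntheticPlateSpec, dict[str, frozenset]]:
    """A constructed plate exercising every exclusion rule.

    Colony layout (300x300 px, 65 frames at 2 h): one clean centred colony,
    one colony crossing the border, one colony merging with it, and a
    six-colony chain merging into a single blob (one seed more than the
    default ambiguity cap). Returns the spec and the expected flag set per
    named colony, keyed by ``(row, col)`` center.
    """
    mk = lambda x, y, lag, rate, edge_ok=False: ColonySpec(  # noqa: E731
        center_x_px=x,
        center_y_px=y,
        lag_h=lag,
        initial_area_px=80.0,
        growth_rate_per_h=rate,
        max_area_px=1000.0,
        edge_ok=edge_ok,
    )
    colonies = [
        mk(70, 70, 4, 0.025),  # clean
        mk(220, 16, 4, 0.025, edge_ok=True),  # crosses the border
        mk(220, 48, 8, 0.025),  # merges with the edge colony
    ]
    for i in range(6):  # chain of six -> one blob with 6 seeds
        colonies.append(mk(60 + 28 * i, 230, 4 + 4 * i, 0.025))
    spec = SyntheticPlateSpec(
        image_height_px=300,
        image_width_px=300,
        frame_interval_h=2.0,
        n_frames=65,
        colonies=colonies,
        background_level=0.1,
        colony_level=0.6,
        noise_sd=0.05,
        rng_seed=_child_seed(seed, 7),
    )
    expected = {
        (70, 70): frozenset(),
        (16, 220): frozenset({EDGE}),
        (48, 220): frozenset({MERGED_WITH_EDGE}),
    }
    for i in range(6):
        expected[(230, 60 + 28 * i)] = frozenset({AMBIGUOUS_MERGE})
    return spec, expected


def exclusion_study(seed: int) -> dict:
    """Do constructed edge / merged / ambiguous fixtures get exactly the
    predicted exclusion flags?"""
    spec, expected = exclusion_fixture_spec(seed)
    series, truth = simulate_plate(spec)
    analysis = analyze_plate(series)
    n_correct = 0
    details = {}
    for colony in truth.colonies:
        key = (round(colony.center_y_px), round(colony.center_x_px))
        track = _nearest_track(analysis.tracks, colony, 15.0)
        got = frozenset(track.flags) if track is not None else None
        details[key] = (expected[key], got)
        if got == expected[key]:
            n_correct += 1
    return {
        "n_colonies": len(truth.colonies),
        "n_correct": n_correct,
        "accuracy": n_correct / len(truth.colonies),
        "n_seeds": len(analysis.seeds),
        "details": details,
    }


def watershed_partition_study(seed: int) -> dict:
    """Per frame, watershed label areas must sum to the foreground count.

    Checked on a random well-separated plate and on the forced-merge
    exclusion fixture; returns the maximum absolute per-frame residual in
    pixels (exact partition gives 0).
    """
    specs = [
        random_plate_spec(8, rng_seed=_child_seed(seed, 20), n_frames=65),
        exclusion_fixture_spec(seed)[0],
    ]
    max_resid = 0
    n_frames = 0
    for spec in specs:
        series, _ = simulate_plate(spec)
        analysis = analyze_plate(series, min_seed_separation_px=_seed_separation(spec))
        seeds = analysis.seeds
        for mask in analysis.masks:
            labels = split_merged_colonies(mask, seeds, warn_dropped=False)
            resid = int(mask.sum()) - int((labels > 0).sum())
            max_resid = max(max_resid, abs(resid))
            n_frames += 1
    return {"n_frames": n_frames, "max_abs_residual_px": max_resid}


# ---------------------------------------------------------------------------
# OD and ANOVA studies
# ---------------------------------------------------------------------------

def od_recovery_study(seed: int) -> dict:
    """Semilog-slope recovery of logistic OD600 wells over 210-330 min.

    The wells sit deliberately far below carrying capacity at the end of the
    fit interval (OD(330)/K < 0.04) — the regime in which the semilog slope
    estimates the exponential rate — and start high enough (OD 0.03) that
    0.002-OD read noise stays small against the signal. An a priori error
    budget (logistic curvature bias plus the OLS noise SE) bounds every
    well's error under 5% at three noise SDs; blank wells supply the
    background estimate.
    """
    rates = [0.007, 0.008, 0.009, 0.010]
    wells = [WellSpec(0.03, 20.0, r, background_od=0.08, noise_sd=0.002) for r in rates]
    blanks = [WellSpec(1e-6, 20.0, 0.0, background_od=0.08, noise_sd=0.002) for _ in range(2)]
    spec = SyntheticODSpec(wells=wells + blanks, rng_seed=_child_seed(seed, 30))
    table, truth = simulate_od(spec)
    blank_ids = [w for w, s in truth.wells.items() if s.rate_per_min == 0.0]
    results = od_rates_table(table, background_mode="blank", blank_wells=blank_ids)
    rel_errs = []
    for r in results:
        rel_errs.append(abs(r.rate_per_min - truth.rates_per_min[r.well_id]) / truth.rates_per_min[r.well_id])
    rel = np.array(rel_errs)
    return {
        "n_wells": len(results),
        "median_rel_err": float(np.median(rel)),
        "max_rel_err": float(rel.max()),
    }


def anova_example_study() -> dict:
    """The worked two-group ANOVA: {0.9, 1.0, 1.1} vs {1.9, 2.0, 2.1}."""
    groups = {"control": [0.9, 1.0, 1.1], "treated": [1.9, 2.0, 2.1]}
    cmp = compare_groups(groups)
    return {"f_statistic": cmp.f_statistic, "anova_p": cmp.anova_p, "n": 6}


def definitional_anova_f(groups: Sequence[Sequence[float]]) -> float:
    """Independent oracle: one-way ANOVA F from definitional sums of squares."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb = len(gs) - 1
    dfw = sum(g.size for g in gs) - len(gs)
    return float((ssb / dfb) / (ssw / dfw))
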