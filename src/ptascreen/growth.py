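"""Growth-rate estimation and group comparison.

Colony rates come from the moving-window maximum-slope estimator: natural
log of area versus time is fitted by ordinary least squares inside every
12-h window that slides over the observed timestamps, and the largest slope
is the colony's growth rate (units: e-fold per hour). Zero areas are
dropped within windows rather than pseudo-counted, and windows left with
fewer than ``min_points`` positive frames are skipped; when no window
qualifies the result is an explicit no-estimate, distinct from slope 0.

Plate-reader rates are the semilog slope of background-subtracted OD600
over the linear portion of the curve (210-330 min by default). Conditions
are compared by one-way ANOVA followed by Tukey's HSD post-test.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .imaging import ColonyTrack

_EPS = 1e-9


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y on x and the fit's r-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate fit: all x identical")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    resid = y - (ym + slope * (x - xm))
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
    return slope, r2


@dataclass
class GrowthRateResult:
    """Maximum moving-window log-area slope of one colony track."""

    series_id: object
    rate_per_h: float | None
    window_start_h: float | None
    window_end_h: float | None
    n_points_in_window: int
    r_squared: float | None

    @property
    def has_estimate(self) -> bool:
        return self.rate_per_h is not None


def fit_max_window_slope(
    times_h: np.ndarray,
    area_px: np.ndarray,
    *,
    window_h: float = 12.0,
    min_points: int = 3,
    series_id: object = None,
) -> GrowthRateResult:
    """Largest ln(area)-vs-time slope over all sliding windows.

    Windows start at every observed timestamp (irregular sampling is fine)
    and span exactly ``window_h``; only frames with positive area enter a
    fit. Ties are broken toward the earliest window.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(area_px, dtype=float)
    if t.shape != a.shape:
        raise ValueError("times_h and area_px must have the same shape")
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    best: tuple[float, float, int, float] | None = None
    if t.size:
        pos = a > 0
        tmax = t.max()
        for t0 in np.unique(t):
            if t0 + window_h > tmax + _EPS:
                break
            sel = pos & (t >= t0 - _EPS) & (t <= t0 + window_h + _EPS)
            n = int(sel.sum())
            if n < min_points:
                continue
            slope, r2 = _ols(t[sel], np.log(a[sel]))
            # numerically tied slopes keep the earliest window
            if best is None or slope - best[0] > 1e-10 * max(1.0, abs(best[0])):
                best = (slope, float(t0), n, r2)
    if best is None:
        return GrowthRateResult(series_id, None, None, None, 0, None)
    slope, t0, n, r2 = best
    return GrowthRateResult(series_id, slope, t0, t0 + window_h, n, r2)


def max_window_slope(
    track: ColonyTrack, window_h: float = 12.0, min_points: int = 3
) -> GrowthRateResult:
    """Growth rate of one (non-excluded) colony track."""
    if track.excluded:
        raise ValueError(
            f"track {track.seed_id} is excluded ({sorted(track.flags)}); "
            "no growth rate is estimated for it"
        )
    return fit_max_window_slope(
        track.times_h,
        track.area_px,
        window_h=window_h,
        min_points=min_points,
        series_id=track.seed_id,
    )


@dataclass
class ODGrowthResult:
    """Semilog OD600 slope of one well over the configured fit interval."""

    well_id: object
    rate_per_min: float
    fit_start_min: float
    fit_end_min: float
    n_points: int
    r_squared: float
    background_od: float


def od_growth_rate(
    times_min: np.ndarray,
    od: np.ndarray,
    *,
    background: float | str = "first",
    fit_start_min: float = 210.0,
    fit_end_min: float = 330.0,
    well_id: object = None,
) -> ODGrowthResult:
    """Slope of ln(OD - background) versus minutes over the fit interval.

    ``background`` is either the string ``"first"`` (subtract the well's
    first reading — the default) or an explicit OD value (e.g. a blank-well
    mean). Non-positive background-subtracted readings inside the window are
    dropped; fewer than 3 surviving points is an error.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times_min and od must have the same shape")
    if t.min() > fit_start_min + _EPS or t.max() < fit_end_min - _EPS:
        raise ValueError("readings do not cover the fit interval")
    if isinstance(background, str):
        if background != "first":
            raise ValueError("background must be 'first' or an explicit OD value")
        bg = float(y[np.argmin(t)])
    else:
        bg = float(background)
    sel = (t >= fit_start_min - _EPS) & (t <= fit_end_min + _EPS)
    tt, yy = t[sel], y[sel] - bg
    keep = yy > 0
    if int(keep.sum()) < 3:
        raise ValueError(
            "fewer than 3 positive background-subtracted readings in the fit "
            "interval; no growth signal"
        )
    slope, r2 = _ols(tt[keep], np.log(yy[keep]))
    return ODGrowthResult(well_id, slope, fit_start_min, fit_end_min, int(keep.sum()), r2, bg)


def od_rates_table(
    od_table: pd.DataFrame,
    *,
    background_mode: str = "first",
    blank_wells: Sequence[str] = (),
    fit_start_min: float = 210.0,
    fit_end_min: float = 330.0,
) -> list[ODGrowthResult]:
    """Fit every well of a long-format (well, time_min, od) table.

    ``background_mode='blank'`` subtracts the mean OD of ``blank_wells``
    from every other well; ``'first'`` subtracts each well's first reading.
    """
    if background_mode == "blank":
        if not blank_wells:
            raise ValueError("background_mode='blank' requires blank_wells")
        bg = float(od_table[od_table["well"].isin(blank_wells)]["od"].mean())
        background: float | str = bg
    elif background_mode == "first":
        background = "first"
    else:
        raise ValueError("background_mode must be 'first' or 'blank'")
    out = []
    for well, grp in od_table.groupby("well", sort=True):
        if well in set(blank_wells):
            continue
        grp = grp.sort_values("time_min")
        out.append(
            od_growth_rate(
                grp["time_min"].to_numpy(),
                grp["od"].to_numpy(),
                background=background,
                fit_start_min=fit_start_min,
                fit_end_min=fit_end_min,
                well_id=well,
            )
        )
    return out


@dataclass
class GroupComparison:
    """One-way ANOVA over conditions plus Tukey HSD pairwise table."""

    rates_by_condition: dict[str, np.ndarray]
    f_statistic: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, mean_diff, p_adj, ci_low, ci_high, reject


def compare_groups(rates_by_condition: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Standard one-way ANOVA F and p, then Tukey's HSD adjusted pairwise p."""
    groups = {k: np.asarray(v, dtype=float) for k, v in rates_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("every condition needs at least 2 rates")
    within_ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    if within_ss == 0:
        raise ValueError("zero within-group variance in every condition; F is undefined")
    f_stat, p = stats.f_oneway(*groups.values())
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([np.repeat(k, g.size) for k, g in groups.items()])
    tk = pairwise_tukeyhsd(values, labels)
    pairs = list(combinations(tk.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "mean_diff": tk.meandiffs,
            "p_adj": tk.pvalues,
            "ci_low": tk.confint[:, 0],
            "ci_high": tk.confint[:, 1],
            "reject": tk.reject,
        }
    )
    return GroupComparison(groups, float(f_stat), float(p), tukey)
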