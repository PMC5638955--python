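"""File I/O: frame directories with manifests, tracks/rates CSVs, provenance.

Every CSV the pipeline writes starts with ``#``-prefixed provenance lines
(tool version, config hash, rng seed) so a result can always be traced back
to the exact run that produced it.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .growth import GrowthRateResult, ODGrowthResult
from .imaging import ColonyTrack, ImageSeries

MANIFEST_NAME = "manifest.csv"


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_lines(config: Mapping | None = None, seed: int | None = None) -> list[str]:
    lines = [f"# ptascreen={__version__}"]
    if config is not None:
        lines.append(f"# config_sha1={config_hash(config)}")
    if seed is not None:
        lines.append(f"# rng_seed={seed}")
    return lines


def _write_csv_with_header(df: pd.DataFrame, path, meta_lines: Iterable[str]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in meta_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_image_series(series: ImageSeries, outdir, bit_depth: int = 8) -> Path:
    """Write frames as frame_NNNN.tif plus a (frame_index, time_h) manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bit_depth == 8:
        scale, dtype = 255, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535, np.uint16
    else:
        raise ValueError("bit_depth must be 8 or 16")
    for i, frame in enumerate(series.frames):
        arr = np.clip(np.rint(frame * scale), 0, scale).astype(dtype)
        tifffile.imwrite(outdir / f"frame_{i:04d}.tif", arr)
    manifest = pd.DataFrame(
        {"frame_index": np.arange(series.n_frames), "time_h": series.times_h}
    )
    manifest.to_csv(outdir / MANIFEST_NAME, index=False)
    return outdir


def read_image_series(indir, manifest: str = MANIFEST_NAME) -> ImageSeries:
    """Read a frame directory (TIFF or PNG) back into an ImageSeries.

    Integer frames are rescaled to [0, 1] by their dtype maximum; grayscale
    frames are promoted to RGB.
    """
    indir = Path(indir)
    mf = pd.read_csv(indir / manifest).sort_values("frame_index")
    frames = []
    for idx in mf["frame_index"]:
        candidates = [indir / f"frame_{int(idx):04d}{ext}" for ext in (".tif", ".tiff", ".png")]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no frame file for index {idx} in {indir}")
        if path.suffix in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(path))
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(float)
        if arr.ndim == 2:
            arr = np.repeat(arr[..., None], 3, axis=-1)
        elif arr.shape[-1] == 4:
            arr = arr[..., :3]
        frames.append(arr)
    return ImageSeries(np.stack(frames), mf["time_h"].to_numpy(dtype=float))


def write_tracks_csv(tracks: list[ColonyTrack], path, meta: Mapping | None = None) -> None:
    """Tracks as long-format CSV: one row per colony-frame."""
    rows = []
    for tr in tracks:
        flags = ";".join(sorted(tr.flags))
        for t, a in zip(tr.times_h, tr.area_px):
            rows.append(
                {
                    "seed_id": tr.seed_id,
                    "seed_row_px": tr.seed_row_px,
                    "seed_col_px": tr.seed_col_px,
                    "time_h": t,
                    "area_px": a,
                    "flags": flags,
                    "excluded": tr.excluded,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["seed_id", "seed_row_px", "seed_col_px", "time_h", "area_px", "flags", "excluded"],
    )
    _write_csv_with_header(df, path, provenance_lines(meta))


def read_tracks_csv(path) -> list[ColonyTrack]:
    df = pd.read_csv(path, comment="#")
    tracks = []
    for seed_id, grp in df.groupby("seed_id", sort=True):
        grp = grp.sort_values("time_h")
        flags_str = grp["flags"].iloc[0]
        flags = set(str(flags_str).split(";")) if isinstance(flags_str, str) and flags_str else set()
        tracks.append(
            ColonyTrack(
                int(seed_id),
                int(grp["seed_row_px"].iloc[0]),
                int(grp["seed_col_px"].iloc[0]),
                grp["time_h"].to_numpy(dtype=float),
                grp["area_px"].to_numpy(dtype=float),
                flags,
            )
        )
    return tracks


def write_rates_csv(results: list[GrowthRateResult], path, meta: Mapping | None = None) -> None:
    """Colony growth rates (natural-log slope per hour)."""
    df = pd.DataFrame(
        [
            {
                "series_id": r.series_id,
                "rate_per_h": r.rate_per_h,
                "window_start_h": r.window_start_h,
                "window_end_h": r.window_end_h,
                "n_points": r.n_points_in_window,
                "r_squared": r.r_squared,
            }
            for r in results
        ],
        columns=["series_id", "rate_per_h", "window_start_h", "window_end_h", "n_points", "r_squared"],
    )
    lines = provenance_lines(meta) + ["# rate units: ln(area)/h (natural log)"]
    _write_csv_with_header(df, path, lines)


def write_od_rates_csv(results: list[ODGrowthResult], path, meta: Mapping | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "rate_per_min": r.rate_per_min,
                "fit_start_min": r.fit_start_min,
                "fit_end_min": r.fit_end_min,
                "n_points": r.n_points,
                "r_squared": r.r_squared,
                "background_od": r.background_od,
            }
            for r in results
        ]
    )
    lines = provenance_lines(meta) + ["# rate units: ln(OD)/min (natural log)"]
    _write_csv_with_header(df, path, lines)
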