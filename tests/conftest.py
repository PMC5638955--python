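import numpy as np
import pytest

from ptascreen.imaging import ImageSeries
from ptascreen.simulate import ColonySpec, SyntheticPlateSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


def make_colony(
    x, y, *, lag_h=4.0, initial_area_px=100.0, rate=0.2, max_area_px=1500.0, edge_ok=False
):
    return ColonySpec(
        center_x_px=x,
        center_y_px=y,
        lag_h=lag_h,
        initial_area_px=initial_area_px,
        growth_rate_per_h=rate,
        max_area_px=max_area_px,
        edge_ok=edge_ok,
    )


def make_plate(colonies, *, h=140, w=140, n_frames=33, noise_sd=0.02, seed=0, interval=2.0):
    return SyntheticPlateSpec(
        image_height_px=h,
        image_width_px=w,
        frame_interval_h=interval,
        n_frames=n_frames,
        colonies=colonies,
        background_level=0.1,
        colony_level=0.6,
        noise_sd=noise_sd,
        rng_seed=seed,
    )


@pytest.fixture
def gray_series():
    """A tiny hand-built RGB series: flat background, then a bright square."""
    frames = np.full((3, 20, 20, 3), 0.4)
    frames[1, 5:10, 5:10, :] = 0.8
    frames[2, 5:12, 5:12, :] = 0.8
    return ImageSeries(frames, np.array([0.0, 2.0, 4.0]))
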