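"""Shared fixtures: tiny programmatically generated movies and masks."""

import numpy as np
import pytest

import celledge as ce
from celledge.containers import CellMovie, MaskSeries


def make_disk_movie(radii, image_size=120, fg=100.0, bg=10.0,
                    pixel_size=0.26, frame_interval=40.0,
                    center=None, noise_sd=0.0, seed=0):
    """Single-channel movie of a disk with one radius (px) per frame."""
    h = w = image_size
    cy = cx = (image_size - 1) / 2 if center is None else center
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    frames = np.stack([np.where(r <= rad, fg, bg) for rad in radii])
    if noise_sd > 0:
        frames = frames + np.random.default_rng(seed).normal(
            0, noise_sd, frames.shape
        )
    return CellMovie(frames[None, ...], pixel_size, frame_interval, ["volume"])


def disk_mask(radius, image_size=120, center=None):
    cy = cx = (image_size - 1) / 2 if center is None else center
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    return np.hypot(xx - cx, yy - cy) <= radius


@pytest.fixture(scope="session")
def lag_movie():
    """100-frame movie with a 160 s signal-velocity coupling lag, 2% noise."""
    params = ce.SyntheticParams(
        n_frames=100, coupling_lag=160.0, coupling_gain=0.5, noise_sd=2.0,
        seed=1,
    )
    movie, truth = ce.generate_cell_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def null_movie():
    """Noise-free zero-coupling movie: sensor channel identical to volume."""
    params = ce.SyntheticParams(
        n_frames=60, coupling_gain=0.0, noise_sd=0.0, seed=5
    )
    movie, truth = ce.generate_cell_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def null_result(null_movie):
    params, movie, _ = null_movie
    cfg = ce.PipelineConfig(simulate=True, seed=params.seed)
    from celledge.pipeline import run_pipeline

    return run_pipeline(cfg, movie=movie)


@pytest.fixture(scope="session")
def growing_disk_maps():
    """Disk growing 1 px/frame: masks, boundaries and velocity map."""
    movie = make_disk_movie([20, 21, 22, 23, 24, 25])
    masks = ce.segment_cell(movie, "volume")
    boundaries = ce.extract_boundary(masks, 100)
    velocity = ce.compute_velocity_map(
        boundaries, masks, movie.pixel_size, movie.frame_interval
    )
    return movie, masks, boundaries, velocity
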