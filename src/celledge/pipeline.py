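"""End-to-end pipeline: segmentation -> boundary -> maps -> morphodynamics."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .config import PipelineConfig
from .containers import CellMovie
from .edgemap import (
    compute_signal_map,
    compute_velocity_map,
    extract_boundary,
    rescale_map_positions,
    segment_cell,
)
from .io import ResultBundle, read_movie
from .morpho import crosscorrelate_maps, cycle_durations, enrichment_function
from .synthetic import SyntheticParams, generate_cell_movie

log = logging.getLogger("celledge")

__all__ = ["run_pipeline", "load_or_simulate"]


def load_or_simulate(config: PipelineConfig) -> CellMovie:
    """Read the configured movie, or render the configured synthetic one."""
    if config.simulate or config.movie_path is None:
        params = SyntheticParams(**{"seed": config.seed, **config.synthetic})
        log.info("simulating movie: %s", params)
        movie, _ = generate_cell_movie(params)
        return movie
    log.info("reading movie from %s", config.movie_path)
    return read_movie(
        config.movie_path,
        channel_names=config.channel_order,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )


def _smooth_time(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along the time axis (edge-truncated)."""
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, ((0, 0), (pad, pad)), mode="edge")
    out = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, padded
    )
    return out[:, : values.shape[1]]


def run_pipeline(config: PipelineConfig, movie: CellMovie | None = None) -> ResultBundle:
    """Run segment -> boundary -> maps -> correlation/enrichment/cycles.

    Deterministic for a fixed config (the only randomness is the synthetic
    generator, seeded from ``config.seed``).
    """
    config.validate()
    if movie is None:
        movie = load_or_simulate(config)

    log.info("segmenting channel %r", config.volume_channel)
    masks = segment_cell(
        movie,
        config.volume_channel,
        method=config.segmentation_method,
        min_area=config.min_area,
        fixed_threshold=config.fixed_threshold,
    )
    log.info("extracting boundaries at %d positions", config.n_positions)
    boundaries = extract_boundary(masks, config.n_positions)

    velocity = compute_velocity_map(
        boundaries, masks, movie.pixel_size, movie.frame_interval
    )
    if config.smoothing_window > 1:
        velocity.values = _smooth_time(velocity.values, config.smoothing_window)
    signal = compute_signal_map(
        movie, config.signal_channel, masks, boundaries, config.band_depth
    )

    max_lag = max(1, int(round(config.max_lag_s / movie.frame_interval)))
    max_lag = min(max_lag, (signal.n_frames - 1) // 2)
    max_shift = max(1, int(round(config.shift_range_s / movie.frame_interval)))
    max_shift = min(max_shift, velocity.n_frames - 1)

    log.info("cross-correlating maps, lags +/-%d frames", max_lag)
    # velocity samples live at frame-midpoint times; averaging adjacent
    # signal frames puts both maps on the same time base, so the correlation
    # extremum falls on an integer lag instead of being split across two
    signal_mid = dataclasses.replace(
        signal,
        values=0.5 * (signal.values[:, :-1] + signal.values[:, 1:]),
        imputed=None,
    )
    cc = crosscorrelate_maps(signal_mid, velocity, max_lag)
    log.info("enrichment function, shifts +/-%d frames", max_shift)
    enrich = enrichment_function(
        signal,
        velocity,
        range(-max_shift, max_shift + 1),
        v_protrusion=config.v_protrusion,
        v_retraction=config.v_retraction,
    )
    cycles = cycle_durations(
        velocity,
        n_positions=100,
        v_protrusion=config.v_protrusion,
        v_retraction=config.v_retraction,
    )
    if np.all(np.isnan(cc.r)):
        log.info("done: %d cycles; correlation undefined (zero-variance maps)",
                 len(cycles.durations))
    else:
        log.info(
            "done: %d cycles, enrichment peak %+d frames, cc extremum %+d frames",
            len(cycles.durations), enrich.peak_shift, cc.extremum_lag,
        )

    velocity_out = (
        rescale_map_positions(velocity, config.n_positions)
        if velocity.n_positions != config.n_positions
        else velocity
    )
    return ResultBundle(
        velocity_map=velocity_out,
        signal_map=signal,
        crosscorrelation=cc,
        enrichment=enrich,
        cycles=cycles,
        provenance={"config_hash": config.content_hash(), "seed": config.seed},
    )
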