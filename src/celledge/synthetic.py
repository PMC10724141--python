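"""Seeded synthetic movies, toy maps, and migration tracks with ground truth.

The movie generator emulates the phenomenology of an adherent epithelial cell
imaged by TIRF: a roughly disk-shaped attachment area whose edge oscillates
locally (protrusion-retraction cycles with a minutes-scale period), a
spatially uniform cytosolic volume-marker channel, and a translocation-sensor
channel whose near-edge intensity follows the local edge velocity with a
configurable delay.  Because the cell model is star-convex, the edge velocity
is available in closed form and every downstream estimate can be checked
against exact ground truth.

The cell radius at polar angle theta and time tau (seconds) is

    R(theta, tau) = base_radius + A * sin(2*pi*(tau - phi(theta)) / T)

with per-lobe phase offsets phi, so the analytic outward edge velocity is

    v(theta, tau) = A * (2*pi/T) * cos(2*pi*(tau - phi(theta)) / T)

(in um/s; reported in um/min).  The sensor channel multiplies the volume
channel, inside an inward band of ``band_depth`` um, by

    1 + coupling_gain * v(theta, tau - coupling_lag) / max|v|

mirroring plasma-membrane recruitment of a sensor coupled to edge motion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .containers import CellMovie, MaskSeries, SignalMap, VelocityMap
from .errors import ParameterError
from .migration import Track

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "generate_cell_movie",
    "generate_toy_maps",
    "generate_migration_tracks",
    "render_tracks_to_labels",
]


@dataclass
class SyntheticParams:
    """Forward-model parameters for :func:`generate_cell_movie`.

    Defaults match the imaging regime the pipeline targets: 0.26 um/pixel,
    40 s frame interval, a ~13 um cell radius, and edge oscillations of
    2 um amplitude with a 600 s (10 min) period — minutes-scale spontaneous
    protrusion-retraction cycles.
    """

    image_size: tuple[int, int] = (160, 160)
    n_frames: int = 60
    pixel_size: float = 0.26          # um / pixel
    frame_interval: float = 40.0      # s
    base_radius: float = 13.0         # um
    oscillation_amplitude: float = 2.0  # um
    oscillation_period: float = 600.0   # s
    n_lobes: int = 6
    coupling_lag: float = 0.0         # s; signal follows velocity by this
    coupling_gain: float = 0.5        # fractional modulation per unit v-hat
    band_depth: float = 3.0           # um; inward band carrying the signal
    volume_intensity: float = 100.0   # AU inside the cell
    background_intensity: float = 10.0  # AU outside
    noise_sd: float = 2.0             # AU, additive i.i.d. Gaussian
    bleach_rate: float = 0.0          # 1/s; optional exponential decay
    n_positions: int = 100            # angular samples of the ground truth
    seed: int = 0

    def validate(self) -> None:
        if self.base_radius - self.oscillation_amplitude <= 0:
            raise ParameterError(
                "base_radius - oscillation_amplitude must be > 0 "
                "(the cell must never vanish)"
            )
        if self.oscillation_period < 2 * self.frame_interval:
            raise ParameterError(
                "oscillation_period must be >= 2 * frame_interval (Nyquist)"
            )
        for name in ("pixel_size", "frame_interval", "base_radius",
                     "volume_intensity", "band_depth"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("oscillation_amplitude", "noise_sd", "coupling_gain",
                     "background_intensity", "bleach_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.n_lobes < 1:
            raise ParameterError("n_lobes must be >= 1")
        # the oscillating edge must stay clear of the image border
        h, w = self.image_size
        max_r_px = (self.base_radius + self.oscillation_amplitude) / self.pixel_size
        if max_r_px >= min(h, w) / 2 - 2:
            raise ParameterError(
                "image_size too small for base_radius + oscillation_amplitude"
            )


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated movie.

    ``true_velocity_map`` is sampled on the measured map's grid:
    ``n_positions`` angles (position p at angle 2*pi*p/n_positions, counter-
    clockwise from the +x axis) by ``n_frames - 1`` midpoint times
    ``(t + 1/2) * frame_interval``, in um/min.
    """

    true_velocity_map: np.ndarray
    true_lag: float
    true_period: float
    lobe_phases: np.ndarray
    true_track_metrics: object | None = None


_BLEND = 0.3  # fraction of a sector over which neighbouring phases blend


def _lobe_phase_profile(theta: np.ndarray, phases: np.ndarray,
                        period: float | None = None) -> np.ndarray:
    """Phase offset phi(theta): piecewise constant per lobe, smoothly blended.

    Lobe ``k`` owns the angular sector ``[k, k+1) * 2*pi / n_lobes`` and is
    constant over its interior, so most of each lobe oscillates coherently
    (spatially local protrusions); a smoothstep transition of width
    ``_BLEND`` of a sector, centred on each sector edge, keeps the radius
    field continuous.  When ``period`` is given, neighbouring phases blend
    along the shorter way around the oscillation cycle.
    """
    n = len(phases)
    sector = 2 * np.pi / n
    th = np.mod(theta, 2 * np.pi)
    k = np.floor(th / sector).astype(int) % n
    u = th / sector - np.floor(th / sector)  # position within sector, [0, 1)
    half = _BLEND / 2.0

    def wrapped_step(base: np.ndarray, other: np.ndarray, t: np.ndarray):
        d = other - base
        if period is not None:
            d = np.mod(d + period / 2.0, period) - period / 2.0
        s = t * t * (3.0 - 2.0 * t)  # smoothstep
        return base + d * s

    out = phases[k].astype(float).copy()
    lo = u < half  # transition from the previous lobe
    if np.any(lo):
        t = (u[lo] + half) / _BLEND
        out[lo] = wrapped_step(phases[(k[lo] - 1) % n], phases[k[lo]], t)
    hi = u > 1.0 - half  # transition into the next lobe
    if np.any(hi):
        t = (u[hi] - 1.0 + half) / _BLEND
        out[hi] = wrapped_step(phases[k[hi]], phases[(k[hi] + 1) % n], t)
    return out


def _radius(params: SyntheticParams, theta: np.ndarray, tau: float,
            phases: np.ndarray) -> np.ndarray:
    phi = _lobe_phase_profile(theta, phases, params.oscillation_period)
    return params.base_radius + params.oscillation_amplitude * np.sin(
        2 * np.pi * (tau - phi) / params.oscillation_period
    )


def _velocity_um_per_min(params: SyntheticParams, theta: np.ndarray, tau: float,
                         phases: np.ndarray) -> np.ndarray:
    phi = _lobe_phase_profile(theta, phases, params.oscillation_period)
    omega = 2 * np.pi / params.oscillation_period
    return params.oscillation_amplitude * omega * np.cos(
        omega * (tau - phi)
    ) * 60.0


def _analytic_outline(params: SyntheticParams, tau: float, phases: np.ndarray,
                      fine: int = 2048) -> np.ndarray:
    """Closed polyline of the analytic outline at time ``tau``, resampled to
    ``fine`` roughly equal-arc-length vertices (first point repeated last),
    mimicking the vertex spacing of a traced pixel contour."""
    from .edgemap import _resample_closed

    theta_f = np.linspace(0.0, 2 * np.pi, 4 * fine + 1)
    r = _radius(params, theta_f, tau, phases)
    xy = np.column_stack([r * np.cos(theta_f), r * np.sin(theta_f)])
    pts = _resample_closed(xy, fine, 0.0)
    return np.vstack([pts, pts[:1]])


def _ground_truth_angles(params: SyntheticParams, phases: np.ndarray) -> np.ndarray:
    """Polar angles of the ground-truth sampling positions, per frame.

    Replicates the boundary extractor's parameterization on the analytic
    outline — equal arc length, counter-clockwise, frame-0 start at the
    maximal-x crossing of the horizontal through the contour centroid,
    then start-point continuity by nearest matching — so the ground-truth
    map shares its grid with the measured one.  Shape
    ``(n_positions, n_frames)``.
    """
    from .edgemap import (
        _nearest_arclength,
        _resample_closed,
        _start_arclength_frame0,
    )

    angles = np.empty((params.n_positions, params.n_frames))
    prev_start: np.ndarray | None = None
    for t in range(params.n_frames):
        xy = _analytic_outline(params, t * params.frame_interval, phases)
        if prev_start is None:
            s0 = _start_arclength_frame0(xy)
        else:
            s0 = _nearest_arclength(xy, prev_start)
        pts = _resample_closed(xy, params.n_positions, s0)
        prev_start = pts[0]
        angles[:, t] = np.arctan2(pts[:, 1], pts[:, 0])
    return angles


def generate_cell_movie(params: SyntheticParams) -> tuple[CellMovie, GroundTruth]:
    """Render a two-channel synthetic movie and its analytic ground truth.

    Channel 0 ("volume") is ``volume_intensity`` inside the star-shaped cell
    mask and ``background_intensity`` outside, plus Gaussian noise.  Channel 1
    ("sensor") is the volume channel additionally modulated, within the inward
    ``band_depth`` band, by ``1 + coupling_gain * v_hat(theta, tau -
    coupling_lag)`` where ``v_hat`` is the analytic edge velocity normalised
    to its maximum.  With ``coupling_gain = 0`` and ``noise_sd = 0`` the two
    channels are identical.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    phases = rng.uniform(0.0, params.oscillation_period, params.n_lobes)

    yy, xx = np.mgrid[0:h, 0:w]
    r_um = np.hypot(xx - cx, yy - cy) * params.pixel_size
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)

    vmax = params.oscillation_amplitude * 2 * np.pi / params.oscillation_period * 60.0

    frames = np.empty((2, params.n_frames, h, w), dtype=float)
    for t in range(params.n_frames):
        tau = t * params.frame_interval
        radius = _radius(params, theta, tau, phases)
        mask = r_um <= radius
        clean = np.where(mask, params.volume_intensity, params.background_intensity)

        sensor = clean.copy()
        if params.coupling_gain > 0 and vmax > 0:
            band = mask & (radius - r_um <= params.band_depth)
            v_hat = _velocity_um_per_min(
                params, theta, tau - params.coupling_lag, phases
            ) / vmax
            sensor = np.where(
                band, clean * (1.0 + params.coupling_gain * v_hat), clean
            )

        if params.bleach_rate > 0:
            decay = np.exp(-params.bleach_rate * tau)
            clean = clean * decay
            sensor = sensor * decay

        frames[0, t] = clean
        frames[1, t] = sensor

    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape)

    movie = CellMovie(
        frames=frames,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        channel_names=["volume", "sensor"],
    )

    angles = _ground_truth_angles(params, phases)
    vmap = np.empty((params.n_positions, params.n_frames - 1))
    for j in range(params.n_frames - 1):
        tau_mid = (j + 0.5) * params.frame_interval
        # circular mean of the flanking frames' sampling angles
        z = np.exp(1j * angles[:, j]) + np.exp(1j * angles[:, j + 1])
        theta_p = np.angle(z)
        vmap[:, j] = _velocity_um_per_min(params, theta_p, tau_mid, phases)

    truth = GroundTruth(
        true_velocity_map=vmap,
        true_lag=params.coupling_lag,
        true_period=params.oscillation_period,
        lobe_phases=phases,
    )
    return movie, truth


def generate_toy_maps(
    n_positions: int,
    n_frames: int,
    lag_frames: int,
    gain: float,
    noise_sd: float,
    seed: int = 0,
    frame_interval: float = 1.0,
    amplitude: float = 1.0,
) -> tuple[SignalMap, VelocityMap]:
    """Matched signal/velocity toy maps with a constructed integer-frame lag.

    Bypasses imaging entirely: each position's velocity is a unit-amplitude
    sinusoid (period ``n_frames / 2`` frames) with a random phase, and the
    signal is ``1 + gain * velocity`` evaluated ``lag_frames`` earlier, plus
    optional Gaussian noise.  Both maps sample integer frame times, so the
    cross-correlation extremum and the enrichment-peak shift sit exactly at
    ``lag_frames``.  The velocity map has ``n_frames - 1`` columns and the
    signal map ``n_frames``, matching the movie pipeline's shapes.
    """
    if n_positions < 1 or n_frames < 2:
        raise ParameterError("n_positions and n_frames must be positive (>= 1, >= 2)")
    if not 0 <= lag_frames < n_frames:
        raise ParameterError("lag_frames must satisfy 0 <= lag_frames < n_frames")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2 * np.pi, n_positions)
    period = n_frames / 2.0
    omega = 2 * np.pi / period

    t_v = np.arange(n_frames - 1)
    t_s = np.arange(n_frames)
    vel = amplitude * np.sin(omega * t_v[None, :] + phases[:, None])
    sig = 1.0 + gain * amplitude * np.sin(
        omega * (t_s[None, :] - lag_frames) + phases[:, None]
    )
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)

    signal_map = SignalMap(
        values=sig,
        band_depth=float("nan"),
        whole_cell_mean=float(sig.mean()),
        frame_interval=frame_interval,
    )
    velocity_map = VelocityMap(
        values=vel, pixel_size=float("nan"), frame_interval=frame_interval
    )
    return signal_map, velocity_map


def generate_migration_tracks(
    n_tracks: int,
    n_steps: int,
    persistence: float,
    step_sd: float,
    seed: int = 0,
    frame_interval: float = 60.0,
) -> list[Track]:
    """Correlated random-walk trajectories in the image plane.

    Headings evolve as ``theta_i = theta_{i-1} + (1 - persistence) * u`` with
    ``u ~ Uniform(-pi, pi)`` and step lengths are Rayleigh(step_sd), so
    ``persistence = 1`` gives perfectly straight tracks and ``persistence = 0``
    gives steps with independent isotropic Gaussian components of standard
    deviation ``step_sd``.
    """
    if not 0.0 <= persistence <= 1.0:
        raise ParameterError("persistence must lie in [0, 1]")
    if n_steps < 2:
        raise ParameterError("n_steps must be >= 2")
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    if step_sd <= 0:
        raise ParameterError("step_sd must be > 0")

    rng = np.random.default_rng(seed)
    tracks = []
    for _ in range(n_tracks):
        theta = rng.uniform(0, 2 * np.pi)
        pos = np.zeros((n_steps, 2))
        for i in range(1, n_steps):
            if i > 1:
                theta = theta + (1.0 - persistence) * rng.uniform(-np.pi, np.pi)
            length = rng.rayleigh(step_sd)
            pos[i] = pos[i - 1] + length * np.array([np.cos(theta), np.sin(theta)])
        tracks.append(Track(points=pos, frame_interval=frame_interval))
    return tracks


def render_tracks_to_labels(
    tracks: list[Track],
    image_size: tuple[int, int],
    pixel_size: float,
    radius_px: int = 4,
    origin_px: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterise tracks into a labelled-nuclei movie for tracker tests.

    Each track becomes a filled disk of ``radius_px`` pixels labelled
    ``index + 1`` in every frame; track coordinates (um) are mapped to pixels
    around ``origin_px`` (default: image centre).  Returns an int array of
    shape ``(n_frames, H, W)``.  Overlapping disks are not resolved; callers
    wanting crossing-free movies should space the tracks out first.
    """
    h, w = image_size
    n_frames = max(len(t.points) for t in tracks)
    if origin_px is None:
        origin_px = ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((n_frames, h, w), dtype=np.int32)
    for idx, track in enumerate(tracks):
        for t, (x_um, y_um) in enumerate(track.points):
            px = origin_px[0] + x_um / pixel_size
            py = origin_px[1] + y_um / pixel_size
            disk = (xx - px) ** 2 + (yy - py) ** 2 <= radius_px**2
            labels[t][disk] = idx + 1
    return labels


def _offset_tracks(tracks: list[Track], offsets_um: np.ndarray) -> list[Track]:
    """Translate each track by its row of ``offsets_um`` (testing helper)."""
    return [
        dataclasses.replace(t, points=t.points + off[None, :])
        for t, off in zip(tracks, offsets_um)
    ]
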