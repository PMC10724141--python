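"""Centroid tracking and migration metrics (distance, displacement, directionality).

Directionality — net displacement divided by total path distance — is the
standard straightness index for migration trajectories: 1 for a perfectly
straight path, 0 for a closed loop.  The tracker is a deliberately simple
greedy nearest-neighbour linker (no gap closing, no split/merge handling),
adequate for sparsely seeded labelled nuclei; tracks that approach the field
border are flagged incomplete and excluded from cohort summaries by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DimensionError, EmptyRegionWarning, ParameterError

__all__ = [
    "Track",
    "MigrationMetrics",
    "track_centroids",
    "migration_metrics",
    "summarize_tracks",
]


@dataclass
class Track:
    """A time-ordered centroid trajectory in micrometres.

    ``points`` has shape ``(n_points, 2)`` as ``(x, y)``; ``complete`` is
    False when the object came within one object radius of the image border
    at any time (such cells may leave the field of view and are excluded
    from cohort summaries).
    """

    points: np.ndarray
    frame_interval: float
    complete: bool = True
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise DimensionError(
                f"a track needs >= 2 (x, y) points; got shape {self.points.shape}"
            )
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class MigrationMetrics:
    """Per-track summary: path length, net displacement, straightness, speed."""

    distance: float          # um, sum of segment lengths
    displacement: float      # um, start to end
    directionality: float    # displacement / distance, in [0, 1]; NaN if distance 0
    mean_speed: float        # um / min


def migration_metrics(track: Track) -> MigrationMetrics:
    """Compute distance, displacement, directionality and mean speed.

    Directionality is undefined (NaN, with a warning) for a track that never
    moved; by the triangle inequality it lies in [0, 1] otherwise.
    """
    steps = np.diff(track.points, axis=0)
    distance = float(np.linalg.norm(steps, axis=1).sum())
    displacement = float(np.linalg.norm(track.points[-1] - track.points[0]))
    elapsed_min = (track.n_points - 1) * track.frame_interval / 60.0
    if distance > 0:
        directionality = displacement / distance
    else:
        warnings.warn(
            "zero-distance track: directionality undefined", EmptyRegionWarning,
            stacklevel=2,
        )
        directionality = float("nan")
    return MigrationMetrics(
        distance=distance,
        displacement=displacement,
        directionality=directionality,
        mean_speed=distance / elapsed_min if elapsed_min > 0 else float("nan"),
    )


@dataclass
class _OpenTrack:
    points: list
    radii: list
    start_frame: int
    last_frame: int
    complete: bool = True


def track_centroids(
    label_movie: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    max_link_distance: float,
) -> list[Track]:
    """Link per-frame labelled detections into tracks by greedy nearest neighbour.

    Parameters
    ----------
    label_movie
        Integer array ``(n_frames, H, W)``; nonzero connected regions are
        detections (labels need not be consistent across frames).
    max_link_distance
        Gate in micrometres: a detection farther than this from every open
        track end starts a new track.

    Links are assigned in ascending distance order, each track end and each
    detection used at most once per frame transition.  A track whose centroid
    comes within one object-equivalent radius of the image border is marked
    ``complete=False``.  Tracks shorter than two points are dropped.
    """
    label_movie = np.asarray(label_movie)
    if label_movie.ndim != 3:
        raise DimensionError("label_movie must be (time, H, W)")
    if label_movie.shape[0] < 2:
        raise ParameterError("tracking needs >= 2 frames")
    h, w = label_movie.shape[1:]

    def detections(frame):
        lab, n = ndimage.label(frame > 0)
        if n == 0:
            return np.empty((0, 2)), np.empty((0,))
        coms = ndimage.center_of_mass(frame > 0, lab, index=range(1, n + 1))
        areas = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        cents = np.array([(c[1], c[0]) for c in coms], dtype=float)  # (x, y) px
        radii = np.sqrt(np.asarray(areas, dtype=float) / np.pi)
        return cents, radii

    open_tracks: list[_OpenTrack] = []
    finished: list[_OpenTrack] = []
    any_detection = False

    for t in range(label_movie.shape[0]):
        cents, radii = detections(label_movie[t])
        any_detection = any_detection or len(cents) > 0

        active = [tr for tr in open_tracks if tr.last_frame == t - 1]
        assigned_det: set[int] = set()
        if active and len(cents):
            ends = np.array([tr.points[-1] for tr in active])
            d = np.linalg.norm(ends[:, None, :] - cents[None, :, :], axis=2)
            d_um = d * pixel_size
            order = np.dstack(np.unravel_index(np.argsort(d_um, axis=None), d.shape))[0]
            used_tr: set[int] = set()
            for i, j in order:
                if d_um[i, j] > max_link_distance:
                    break
                if i in used_tr or j in assigned_det:
                    continue
                active[i].points.append(cents[j])
                active[i].radii.append(radii[j])
                active[i].last_frame = t
                used_tr.add(int(i))
                assigned_det.add(int(j))

        for tr in open_tracks:
            if tr.last_frame < t:  # unmatched: terminate, no gap closing
                finished.append(tr)
        open_tracks = [tr for tr in open_tracks if tr.last_frame == t]

        for j in range(len(cents)):
            if j not in assigned_det:
                open_tracks.append(
                    _OpenTrack([cents[j]], [radii[j]], start_frame=t, last_frame=t)
                )

    finished.extend(open_tracks)
    if not any_detection:
        warnings.warn("no detections in any frame", EmptyRegionWarning, stacklevel=2)
        return []

    tracks: list[Track] = []
    for tr in finished:
        if len(tr.points) < 2:
            continue
        pts = np.asarray(tr.points)
        rad = np.asarray(tr.radii)
        near_border = (
            (pts[:, 0] < rad) | (pts[:, 0] > w - 1 - rad)
            | (pts[:, 1] < rad) | (pts[:, 1] > h - 1 - rad)
        ).any()
        tracks.append(
            Track(
                points=pts * pixel_size,
                frame_interval=frame_interval,
                complete=not bool(near_border),
                start_frame=tr.start_frame,
            )
        )
    return tracks


def summarize_tracks(
    tracks: list[Track], include_incomplete: bool = False
) -> list[MigrationMetrics]:
    """Metrics for a cohort; incomplete tracks are excluded unless requested."""
    return [
        migration_metrics(t)
        for t in tracks
        if include_incomplete or t.complete
    ]
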