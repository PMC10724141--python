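"""Core in-memory containers shared by the pipeline stages.

Conventions
-----------
* Image arrays are indexed ``[row, col]``; geometry is done in ``(x, y)``
  coordinates with ``x = col`` and ``y = row``.  "Counter-clockwise" means
  increasing polar angle ``atan2(y - cy, x - cx)`` in that plane.
* Frame index 0 is the first acquired frame.  The velocity sample ``(p, t)``
  describes the boundary displacement between frames ``t`` and ``t + 1`` and
  is attributed to the physical midpoint time ``(t + 1/2) * frame_interval``.
* Velocities are in micrometres per minute, positive outward (protrusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError


@dataclass
class CellMovie:
    """A time-ordered stack of co-registered channel frames.

    Parameters
    ----------
    frames
        Intensity array of shape ``(n_channels, n_frames, H, W)``.
    pixel_size
        Lateral calibration in micrometres per pixel.
    frame_interval
        Acquisition interval in seconds.
    channel_names
        One label per channel, e.g. ``["volume", "sensor"]``.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise DimensionError(
                f"frames must be (channel, time, H, W); got shape {self.frames.shape}"
            )
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if len(self.channel_names) != self.frames.shape[0]:
            raise DimensionError(
                f"{len(self.channel_names)} channel names for "
                f"{self.frames.shape[0]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(n_frames, H, W)`` stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.frames[idx]


@dataclass
class MaskSeries:
    """Per-frame binary cell masks from one source channel.

    Each frame holds exactly one connected foreground component.  Masks that
    touch the image border are recorded in :attr:`border_frames`; boundary
    extraction refuses such frames because their contour is not closed.
    """

    masks: np.ndarray
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise DimensionError(
                f"masks must be (time, H, W); got shape {self.masks.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def border_frames(self) -> list[int]:
        """Frames whose mask touches the image border."""
        out = []
        for t, m in enumerate(self.masks):
            if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
                out.append(t)
        return out

    def __getitem__(self, t: int) -> np.ndarray:
        return self.masks[t]


@dataclass
class BoundarySeries:
    """Sub-pixel cell outlines, one closed contour per frame.

    ``contours[t]`` has shape ``(n_positions, 2)`` in ``(x, y)`` pixel
    coordinates, counter-clockwise, without a repeated end point.  Position
    indices correspond across frames: frame 0 starts at the boundary point of
    maximal x on the horizontal through the centroid, and each later frame
    starts at the point nearest the previous frame's start.

    ``dense_contours`` keeps the full-resolution polylines (closed: first
    point repeated last) used for precise point-to-boundary distances.
    """

    contours: list[np.ndarray]
    n_positions: int
    dense_contours: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t, c in enumerate(self.contours):
            if c.shape != (self.n_positions, 2):
                raise DimensionError(
                    f"contour {t} has shape {c.shape}, expected "
                    f"({self.n_positions}, 2)"
                )

    @property
    def n_frames(self) -> int:
        return len(self.contours)


@dataclass
class VelocityMap:
    """Local edge velocity over boundary position x time.

    ``values`` has shape ``(n_positions, n_frames - 1)`` in um/min; positive
    values are outward motion (protrusion), negative inward (retraction).
    A static boundary yields a map of zeros.
    """

    values: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("velocity map must be 2-D (position x time)")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SignalMap:
    """Band-averaged fluorescence over boundary position x time.

    Each entry is the mean intensity of the mask pixels lying within
    ``band_depth`` micrometres inward of the edge and assigned to that
    boundary position; ``whole_cell_mean`` is the mean over *all* mask pixels
    of all frames and is the denominator of enrichment percentages.
    """

    values: np.ndarray
    band_depth: float
    whole_cell_mean: float
    frame_interval: float
    imputed: np.ndarray | None = None  # True where a position had no band pixels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("signal map must be 2-D (position x time)")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]
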