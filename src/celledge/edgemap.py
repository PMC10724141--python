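"""Cell segmentation, boundary parameterization, and edge velocity/signal maps.

The measurement geometry follows the kymograph-style mapping used for
protrusion-retraction analysis: the cell outline is traced per frame at
sub-pixel resolution, resampled to a fixed number of equal-arc-length
positions whose indices correspond across frames, and two position x time
matrices are built on that shared parameterization — the local edge velocity
(um/min, protrusion-positive) and the mean fluorescence in a band that
extends from the edge *inwards only* (so membrane-proximal signals are not
diluted by extracellular background).

Velocity definition
-------------------
Let ``D_t(x)`` be the signed Euclidean distance from point ``x`` to frame
``t``'s boundary polyline, positive inside the cell.  The velocity sample at
position ``p`` between frames ``t`` and ``t+1`` is the symmetrized
displacement

    v(p, t) = 1/2 * [ D_{t+1}(x_{p,t}) - D_t(x_{p,t+1}) ]

converted to um/min.  A boundary point engulfed by the next frame's cell
(local protrusion) gets positive velocity; the form is exactly antisymmetric
under time reversal, so playing a movie backwards negates its velocity map.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu

from .containers import BoundarySeries, CellMovie, MaskSeries, SignalMap, VelocityMap
from .errors import (
    BoundaryError,
    DimensionError,
    EmptyRegionWarning,
    ParameterError,
    SegmentationError,
)

__all__ = [
    "segment_cell",
    "extract_boundary",
    "compute_velocity_map",
    "compute_signal_map",
    "split_central_peripheral",
    "CentralPeripheralSplit",
    "rescale_map_positions",
]


def segment_cell(
    movie: CellMovie,
    channel: str,
    method: str = "otsu",
    min_area: int = 100,
    fixed_threshold: float | None = None,
) -> MaskSeries:
    """Threshold one channel per frame into a single-cell binary mask.

    Per frame: threshold (Otsu, or ``fixed_threshold``), fill holes, keep the
    largest connected component; a frame whose largest component is smaller
    than ``min_area`` pixels (or that is constant, under Otsu) raises
    :class:`SegmentationError` naming the frame.
    """
    if method not in ("otsu", "fixed_threshold"):
        raise ParameterError(f"unknown segmentation method {method!r}")
    if method == "fixed_threshold" and fixed_threshold is None:
        raise ParameterError("fixed_threshold method requires a threshold value")

    stack = movie.channel(channel)
    masks = np.empty(stack.shape, dtype=bool)
    for t, frame in enumerate(stack):
        if method == "otsu":
            if np.ptp(frame) == 0:
                raise SegmentationError(
                    f"frame {t}: constant image, Otsu threshold undefined"
                )
            thr = threshold_otsu(frame)
        else:
            thr = fixed_threshold
        fg = frame > thr
        fg = ndimage.binary_fill_holes(fg)
        lab, n = ndimage.label(fg)
        if n == 0:
            raise SegmentationError(f"frame {t}: empty foreground")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        if sizes[largest - 1] < min_area:
            raise SegmentationError(
                f"frame {t}: largest component {int(sizes[largest - 1])} px "
                f"< min_area {min_area}"
            )
        masks[t] = lab == largest
    return MaskSeries(masks=masks, source_channel=channel)


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _arclengths(closed_xy: np.ndarray) -> np.ndarray:
    """Cumulative arc length over a closed polyline (first point repeated last)."""
    seg = np.linalg.norm(np.diff(closed_xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _smooth_closed(closed_xy: np.ndarray, sigma: float) -> np.ndarray:
    """Circular Gaussian smoothing of a closed polyline (staircase removal).

    The contour of a binary mask is a pixel staircase; smoothing each
    coordinate along the (periodic) vertex index with a small sigma recovers
    a sub-pixel outline whose local normal distances are stable.  The input
    and output repeat the first vertex last.
    """
    if sigma <= 0:
        return closed_xy
    open_xy = closed_xy[:-1]
    sm = np.column_stack(
        [
            ndimage.gaussian_filter1d(open_xy[:, 0], sigma, mode="wrap"),
            ndimage.gaussian_filter1d(open_xy[:, 1], sigma, mode="wrap"),
        ]
    )
    return np.vstack([sm, sm[:1]])


def _resample_closed(closed_xy: np.ndarray, n: int, s0: float) -> np.ndarray:
    """``n`` equal-arc-length points along a closed polyline starting at ``s0``."""
    s = _arclengths(closed_xy)
    total = s[-1]
    targets = np.mod(s0 + np.arange(n) * total / n, total)
    x = np.interp(targets, s, closed_xy[:, 0])
    y = np.interp(targets, s, closed_xy[:, 1])
    return np.column_stack([x, y])


def _nearest_arclength(closed_xy: np.ndarray, point: np.ndarray) -> float:
    """Arc-length parameter of the polyline point nearest ``point``."""
    a = closed_xy[:-1]
    b = closed_xy[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    tproj = np.clip(np.einsum("ij,ij->i", point[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + tproj[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - point[None, :], proj - point[None, :])
    k = int(np.argmin(d2))
    s = _arclengths(closed_xy)
    return float(s[k] + tproj[k] * (s[k + 1] - s[k]))


def _start_arclength_frame0(closed_xy: np.ndarray) -> float:
    """Arc length of the contour point of maximal x on the centroid's horizontal."""
    cx, cy = closed_xy[:-1].mean(axis=0)
    s = _arclengths(closed_xy)
    best_x, best_s = -np.inf, 0.0
    y = closed_xy[:, 1]
    for k in range(len(closed_xy) - 1):
        y0, y1 = y[k] - cy, y[k + 1] - cy
        if y0 == y1:
            continue
        if y0 * y1 <= 0:  # segment crosses the horizontal
            f = y0 / (y0 - y1)
            x_cross = closed_xy[k, 0] + f * (closed_xy[k + 1, 0] - closed_xy[k, 0])
            if x_cross > best_x:
                best_x = x_cross
                best_s = s[k] + f * (s[k + 1] - s[k])
    if not np.isfinite(best_x):
        raise BoundaryError("degenerate contour: no crossing of the centroid row")
    return best_s


def extract_boundary(
    masks: MaskSeries, n_positions: int = 100, smooth_sigma: float = 2.0
) -> BoundarySeries:
    """Trace each mask's outline and resample it to matched positions.

    The 0.5 iso-contour of the binary mask gives a sub-pixel closed polyline
    per frame; it is smoothed along the contour (circular Gaussian,
    ``smooth_sigma`` vertices, to suppress the pixel staircase), oriented
    counter-clockwise, and resampled to ``n_positions`` equal-arc-length
    points.  The frame-0 start point is the boundary point of maximal x on
    the horizontal through the centroid; every later frame starts at the
    polyline point nearest the previous frame's start, which keeps position
    indices comparable over time.
    """
    if n_positions < 8:
        raise ParameterError("n_positions must be >= 8")
    border = masks.border_frames
    if border:
        raise BoundaryError(
            f"mask touches the image border in frames {border}; "
            "contour would not be closed"
        )

    contours: list[np.ndarray] = []
    dense: list[np.ndarray] = []
    prev_start: np.ndarray | None = None
    for t in range(masks.n_frames):
        found = measure.find_contours(masks[t].astype(float), 0.5)
        if not found:
            raise BoundaryError(f"frame {t}: no contour found")
        rc = max(found, key=len)  # outer contour of the single component
        xy = rc[:, ::-1].copy()  # (row, col) -> (x, y)
        if not np.allclose(xy[0], xy[-1]):
            raise BoundaryError(f"frame {t}: contour not closed")
        if _signed_area(xy[:-1]) < 0:
            xy = xy[::-1].copy()
        xy = _smooth_closed(xy, smooth_sigma)
        if prev_start is None:
            s0 = _start_arclength_frame0(xy)
        else:
            s0 = _nearest_arclength(xy, prev_start)
        pts = _resample_closed(xy, n_positions, s0)
        prev_start = pts[0]
        contours.append(pts)
        dense.append(xy)
    return BoundarySeries(contours=contours, n_positions=n_positions,
                          dense_contours=dense)


def _signed_distance(points: np.ndarray, dense_contour: np.ndarray) -> np.ndarray:
    """Distance from ``points`` to a closed polyline, positive inside."""
    ring = shapely.LineString(dense_contour)
    poly = shapely.Polygon(dense_contour)
    pts = shapely.points(points[:, 0], points[:, 1])
    dist = shapely.distance(pts, ring)
    inside = shapely.contains_xy(poly, points[:, 0], points[:, 1])
    return np.where(inside, dist, -dist)


def compute_velocity_map(
    boundaries: BoundarySeries,
    masks: MaskSeries,
    pixel_size: float,
    frame_interval: float,
) -> VelocityMap:
    """Edge-velocity map (um/min) on the boundary parameterization.

    See the module docstring for the symmetrized signed-distance definition.
    ``masks`` must cover the same frames as ``boundaries``.
    """
    if boundaries.n_frames != masks.n_frames:
        raise DimensionError(
            f"{boundaries.n_frames} contour frames vs {masks.n_frames} mask frames"
        )
    if boundaries.n_frames < 2:
        raise DimensionError("velocity needs >= 2 frames")
    scale = pixel_size * 60.0 / frame_interval
    n_t = boundaries.n_frames - 1
    values = np.empty((boundaries.n_positions, n_t))
    dense = boundaries.dense_contours
    for t in range(n_t):
        d_next = _signed_distance(boundaries.contours[t], dense[t + 1])
        d_curr = _signed_distance(boundaries.contours[t + 1], dense[t])
        values[:, t] = 0.5 * (d_next - d_curr) * scale
    return VelocityMap(values=values, pixel_size=pixel_size,
                       frame_interval=frame_interval)


def compute_signal_map(
    movie: CellMovie,
    channel: str,
    masks: MaskSeries,
    boundaries: BoundarySeries,
    band_depth: float = 3.0,
) -> SignalMap:
    """Mean intensity in the inward edge band, per boundary position and frame.

    The band comprises mask pixels whose Euclidean distance to the background
    is at most ``round(band_depth / pixel_size)`` pixels; each band pixel is
    assigned to the nearest of the frame's resampled boundary points (a
    discrete Voronoi partition along the contour).  Positions left with no
    pixels are imputed by circular linear interpolation from the nearest
    populated neighbours and flagged in ``SignalMap.imputed``.
    """
    if band_depth <= 0:
        raise ParameterError("band_depth must be > 0")
    if boundaries.n_frames != masks.n_frames:
        raise DimensionError("boundaries and masks disagree on frame count")
    band_px = max(1, round(band_depth / movie.pixel_size))
    stack = movie.channel(channel)

    n_p = boundaries.n_positions
    n_t = masks.n_frames
    values = np.full((n_p, n_t), np.nan)
    imputed = np.zeros((n_p, n_t), dtype=bool)
    total = 0.0
    count = 0

    for t in range(n_t):
        mask = masks[t]
        frame = stack[t]
        total += float(frame[mask].sum())
        count += int(mask.sum())
        dist_in = ndimage.distance_transform_edt(mask)
        band = mask & (dist_in <= band_px)
        rows, cols = np.nonzero(band)
        if len(rows) == 0:
            imputed[:, t] = True
            continue
        tree = cKDTree(boundaries.contours[t])
        _, nearest = tree.query(np.column_stack([cols, rows]).astype(float))
        sums = np.bincount(nearest, weights=frame[rows, cols], minlength=n_p)
        npix = np.bincount(nearest, minlength=n_p)
        with np.errstate(invalid="ignore"):
            values[:, t] = sums / npix
        imputed[npix == 0, t] = True

    n_imputed = int(imputed.sum())
    if n_imputed:
        warnings.warn(
            f"{n_imputed} map entries had no band pixels; imputed from "
            "adjacent positions",
            EmptyRegionWarning,
            stacklevel=2,
        )
        for t in range(n_t):
            col = values[:, t]
            bad = np.isnan(col)
            if bad.all():
                continue
            if bad.any():
                # circular linear interpolation over position index
                idx = np.arange(n_p)
                good = ~bad
                values[bad, t] = np.interp(
                    idx[bad], idx[good], col[good], period=n_p
                )

    return SignalMap(
        values=values,
        band_depth=band_depth,
        whole_cell_mean=total / count if count else float("nan"),
        frame_interval=movie.frame_interval,
        imputed=imputed,
    )


@dataclasses.dataclass
class CentralPeripheralSplit:
    """Partition of each mask into an outer rim and the remaining interior."""

    peripheral: MaskSeries
    central: MaskSeries
    band_width_um: float


def split_central_peripheral(
    masks: MaskSeries, band_pixels: int = 5, pixel_size: float = 0.26
) -> CentralPeripheralSplit:
    """Split masks into a peripheral rim of ``band_pixels`` and a central rest.

    The rim is the set of mask pixels whose distance-map value (Euclidean
    distance to the background) is at most ``band_pixels``; at the default
    5 px and 0.26 um/px this is a 1.3 um band around the cell circumference.
    Peripheral and central regions partition the mask exactly.
    """
    if band_pixels < 1:
        raise ParameterError("band_pixels must be >= 1")
    periph = np.empty_like(masks.masks)
    for t in range(masks.n_frames):
        dist = ndimage.distance_transform_edt(masks[t])
        periph[t] = masks[t] & (dist <= band_pixels)
    central = masks.masks & ~periph
    return CentralPeripheralSplit(
        peripheral=MaskSeries(periph, source_channel=masks.source_channel),
        central=MaskSeries(central, source_channel=masks.source_channel),
        band_width_um=band_pixels * pixel_size,
    )


def rescale_map_positions(map_in: VelocityMap | SignalMap, n_out: int):
    """Resample a map's circular position axis to ``n_out`` rows.

    Linear interpolation on the periodic position coordinate ``p / n``; the
    time axis is untouched.  ``n_out`` equal to the current row count is an
    exact identity.
    """
    if n_out < 2:
        raise ParameterError("n_out must be >= 2")
    m = map_in.values
    n = m.shape[0]
    pos = np.arange(n_out) * n / n_out
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    i1 = (i0 + 1) % n
    out = (1.0 - frac)[:, None] * m[i0] + frac[:, None] * m[i1]
    kwargs = {"values": out}
    if isinstance(map_in, SignalMap) and map_in.imputed is not None:
        kwargs["imputed"] = map_in.imputed[i0] | map_in.imputed[i1]
    return dataclasses.replace(map_in, **kwargs)
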