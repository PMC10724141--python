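"""Background-, baseline- and control-corrected biosensor activity traces.

A translocation sensor's raw fluorescence at the membrane confounds GTPase
activity with cell-volume changes (shrinkage or spreading changes the local
protein concentration for *any* cytosolic protein).  Co-expressing a freely
diffusing control fluorophore lets that artifact be measured and removed:

    corrected activity
        A(t) = (I_s(t) - I_s_bg(t)) / (mean_0[I_s] - mean_0[I_s_bg])
             - (I_c(t) - I_c_bg(t)) / (mean_0[I_c] - mean_0[I_c_bg])

    simple normalized activity (no control subtraction)
        A(t) = (I(t) - I_bg(t)) / (mean_0[I] - mean_0[I_bg])

where ``mean_0`` averages over the pre-perturbation baseline frames.  By
construction the corrected trace averages 0 over the baseline and the simple
trace averages 1; both are invariant to rescaling a channel's gain.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from scipy import ndimage

from .containers import CellMovie, MaskSeries
from .errors import (
    DegenerateBaselineError,
    DimensionError,
    EmptyRegionWarning,
    ParameterError,
    WindowError,
)
import warnings

__all__ = [
    "IntensityTrace",
    "ActivityTrace",
    "corrected_activity",
    "normalized_activity",
    "background_trace",
    "window_response",
    "region_trace",
]


@dataclass
class IntensityTrace:
    """Raw per-frame mean intensity of one region (AU)."""

    values: np.ndarray
    region: str = ""
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DimensionError("an intensity trace is 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("intensity trace contains non-finite values")
        if np.any(self.values < 0):
            raise ParameterError("intensity trace contains negative values")


@dataclass
class ActivityTrace:
    """Dimensionless sensor activity per frame.

    ``kind`` is "corrected" (control-subtracted; baseline mean 0) or
    "simple" (baseline mean 1).
    """

    values: np.ndarray
    kind: str
    baseline_frames: slice
    frame_interval: float = 1.0


def _baseline_slice(baseline_frames, n: int) -> slice:
    if isinstance(baseline_frames, slice):
        sl = baseline_frames
    else:
        lo, hi = baseline_frames
        sl = slice(lo, hi)
    idx = range(*sl.indices(n))
    if len(idx) == 0:
        raise ParameterError("baseline_frames selects no frames")
    return sl

def _norm_term(trace: IntensityTrace, bg: IntensityTrace, sl: slice,
               label: str) -> np.ndarray:
    if trace.values.shape != bg.values.shape:
        raise DimensionError(f"{label}: trace and background lengths differ")
    denom = trace.values[sl].mean() - bg.values[sl].mean()
    if denom == 0:
        raise DegenerateBaselineError(
            f"{label}: baseline intensity equals baseline background"
        )
    return (trace.values - bg.values) / denom


def corrected_activity(
    sensor: IntensityTrace,
    sensor_bg: IntensityTrace,
    control: IntensityTrace,
    control_bg: IntensityTrace,
    baseline_frames,
) -> ActivityTrace:
    """Control-corrected sensor activity (baseline mean exactly 0).

    Subtracts the identically normalized control-fluorophore trace from the
    normalized sensor trace, cancelling volume/concentration artifacts common
    to both channels (including uniform photobleaching).
    """
    n = len(sensor.values)
    for other in (sensor_bg, control, control_bg):
        if len(other.values) != n:
            raise DimensionError("all four traces must have the same length")
    sl = _baseline_slice(baseline_frames, n)
    a = _norm_term(sensor, sensor_bg, sl, "sensor") - _norm_term(
        control, control_bg, sl, "control"
    )
    return ActivityTrace(values=a, kind="corrected", baseline_frames=sl,
                         frame_interval=sensor.frame_interval)


def normalized_activity(
    sensor: IntensityTrace, sensor_bg: IntensityTrace, baseline_frames
) -> ActivityTrace:
    """Background-subtracted, baseline-normalized activity (baseline mean 1)."""
    sl = _baseline_slice(baseline_frames, len(sensor.values))
    a = _norm_term(sensor, sensor_bg, sl, "sensor")
    return ActivityTrace(values=a, kind="simple", baseline_frames=sl,
                         frame_interval=sensor.frame_interval)


def background_trace(
    movie: CellMovie, channel: str, masks: MaskSeries, dilation: int = 10
) -> IntensityTrace:
    """Per-frame mean intensity outside the dilated cell mask.

    The mask is dilated by ``dilation`` pixels before taking the complement,
    keeping dim cell fringes out of the background estimate.
    """
    if dilation < 0:
        raise ParameterError("dilation must be >= 0")
    stack = movie.channel(channel)
    if stack.shape[0] != masks.n_frames:
        raise DimensionError("movie and masks disagree on frame count")
    vals = np.empty(masks.n_frames)
    for t in range(masks.n_frames):
        region = ~masks[t]
        if dilation > 0:
            region = ~ndimage.binary_dilation(masks[t], iterations=dilation)
        if not region.any():
            raise ParameterError(
                f"frame {t}: empty background region after dilation {dilation}"
            )
        vals[t] = float(stack[t][region].mean())
    return IntensityTrace(values=vals, region=f"background({channel})",
                          frame_interval=movie.frame_interval)


def region_trace(
    movie: CellMovie, channel: str, masks: MaskSeries, region: str = "cell"
) -> IntensityTrace:
    """Per-frame mean intensity over the mask (convenience for whole-cell traces)."""
    stack = movie.channel(channel)
    if stack.shape[0] != masks.n_frames:
        raise DimensionError("movie and masks disagree on frame count")
    vals = np.array([float(stack[t][masks[t]].mean()) for t in range(masks.n_frames)])
    return IntensityTrace(values=vals, region=region,
                          frame_interval=movie.frame_interval)


def window_response(
    activity: ActivityTrace, n_pre: int, n_post: int, onset: int
) -> float:
    """Mean activity over ``n_post`` frames from onset minus the ``n_pre``-frame
    pre-window; the standard before/after perturbation response measure."""
    v = activity.values
    if n_pre < 1 or n_post < 1:
        raise ParameterError("n_pre and n_post must be >= 1")
    if onset - n_pre < 0 or onset + n_post > len(v):
        raise WindowError(
            f"window [{onset - n_pre}, {onset + n_post}) outside trace of "
            f"length {len(v)}"
        )
    return float(v[onset:onset + n_post].mean() - v[onset - n_pre:onset].mean())
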