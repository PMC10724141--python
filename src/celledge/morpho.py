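"""Relating edge motion to near-edge signals: correlation, enrichment, cycles.

Given the shared-parameterization velocity and signal maps, this module
quantifies how a fluorescent signal organizes around edge motion:

* **Cross-correlation** — Pearson r between the signal map shifted by a lag
  and the velocity map, pooled over all (position, time) pairs; positive lag
  means the signal *follows* the velocity.
* **Protrusion/retraction labelling** — spatio-temporal regions with edge
  velocity above +0.075 um/min (protrusion) or below -0.075 um/min
  (retraction); strict inequalities.
* **Time-shifted enrichment functions** — percentage enrichment of the
  signal in protruding/retracting regions, relative to the whole-cell mean,
  after sliding the labelled regions along the time axis; the shift of the
  protrusion-enrichment peak estimates the delay between edge motion and
  signal recruitment.
* **Cycle durations** — per-position time from a protrusion onset to the
  next retraction onset, on a map rescaled to 100 circumference positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import SignalMap, VelocityMap
from .edgemap import rescale_map_positions
from .errors import (
    DegenerateControlError,
    DimensionError,
    EmptyRegionWarning,
    ParameterError,
)

__all__ = [
    "PROTRUSION_THRESHOLD",
    "RETRACTION_THRESHOLD",
    "RegionLabels",
    "CrossCorrelation",
    "EnrichmentFunction",
    "CycleDurationSet",
    "label_protrusion_retraction",
    "crosscorrelate_maps",
    "enrichment_at_shift",
    "enrichment_function",
    "normalize_enrichment_to_control",
    "cycle_durations",
]

#: Default edge-velocity thresholds (um/min) separating protrusion and
#: retraction from quiescent edge regions.
PROTRUSION_THRESHOLD = 0.075
RETRACTION_THRESHOLD = -0.075

PROTRUSION = 1
NEITHER = 0
RETRACTION = -1


@dataclass
class RegionLabels:
    """Per-(position, time) classification of edge motion.

    ``labels`` holds +1 (protrusion, v > v_protrusion), -1 (retraction,
    v < v_retraction) or 0 (neither); comparisons are strict, so a value
    exactly at a threshold is "neither".
    """

    labels: np.ndarray
    v_protrusion: float = PROTRUSION_THRESHOLD
    v_retraction: float = RETRACTION_THRESHOLD

    @property
    def protrusion(self) -> np.ndarray:
        return self.labels == PROTRUSION

    @property
    def retraction(self) -> np.ndarray:
        return self.labels == RETRACTION


@dataclass
class CrossCorrelation:
    """Pearson r between signal and velocity maps per time lag.

    Positive lag = signal delayed relative to velocity.  A lag where the
    overlap has zero variance in either map is reported as NaN (missing),
    never as 0.
    """

    lags: np.ndarray            # frames, symmetric around 0
    r: np.ndarray               # Pearson r per lag (NaN where undefined)
    n_pairs: np.ndarray         # pooled sample size per lag
    frame_interval: float

    @property
    def lags_seconds(self) -> np.ndarray:
        return self.lags * self.frame_interval

    @property
    def extremum_lag(self) -> int:
        """Lag (frames) of the correlation maximum, NaNs ignored.

        For a signal recruited during protrusion (positive coupling) the
        relevant extremum of the correlation function is its peak; a signal
        recruited during retraction anticorrelates with velocity, and
        :attr:`trough_lag` is the extremum to read instead.  With a
        periodically oscillating edge the anti-phase trough can rival the
        peak in magnitude, so the two are kept separate rather than merged
        into an argmax of ``|r|``.
        """
        if np.all(np.isnan(self.r)):
            raise ParameterError("cross-correlation undefined at every lag")
        return int(self.lags[np.nanargmax(self.r)])

    @property
    def trough_lag(self) -> int:
        """Lag (frames) of the correlation minimum, NaNs ignored."""
        if np.all(np.isnan(self.r)):
            raise ParameterError("cross-correlation undefined at every lag")
        return int(self.lags[np.nanargmin(self.r)])


@dataclass
class EnrichmentFunction:
    """% signal enrichment in protruding/retracting regions per time shift.

    Enrichment at a shift is ``(region mean / whole-cell mean - 1) * 100``,
    the region being the protrusion- (or retraction-) labelled map entries
    displaced ``shift`` frames along the time axis of the signal map.
    """

    shifts: np.ndarray                  # frames (signed)
    protrusion_enrichment: np.ndarray   # % per shift (NaN = empty overlap)
    retraction_enrichment: np.ndarray
    frame_interval: float
    normalized: bool = False

    @property
    def shifts_seconds(self) -> np.ndarray:
        return self.shifts * self.frame_interval

    @property
    def peak_shift(self) -> int:
        """Shift (frames) maximizing protrusion enrichment, NaNs ignored."""
        if np.all(np.isnan(self.protrusion_enrichment)):
            raise ParameterError("protrusion enrichment undefined at every shift")
        return int(self.shifts[np.nanargmax(self.protrusion_enrichment)])

    @property
    def peak_shift_seconds(self) -> float:
        return self.peak_shift * self.frame_interval


@dataclass
class CycleDurationSet:
    """Completed protrusion-onset -> retraction-onset durations, pooled over
    the circumference positions of one cell."""

    durations: np.ndarray  # seconds
    frame_interval: float

    @property
    def mean(self) -> float:
        return float(self.durations.mean()) if len(self.durations) else float("nan")

    @property
    def sem(self) -> float:
        n = len(self.durations)
        if n < 2:
            return float("nan")
        return float(self.durations.std(ddof=1) / np.sqrt(n))


def label_protrusion_retraction(
    velocity: VelocityMap,
    v_protrusion: float = PROTRUSION_THRESHOLD,
    v_retraction: float = RETRACTION_THRESHOLD,
) -> RegionLabels:
    """Threshold a velocity map into protrusion / retraction / neither."""
    if not v_retraction < v_protrusion:
        raise ParameterError(
            f"v_retraction ({v_retraction}) must be < v_protrusion "
            f"({v_protrusion})"
        )
    v = velocity.values
    labels = np.zeros(v.shape, dtype=np.int8)
    labels[v > v_protrusion] = PROTRUSION
    labels[v < v_retraction] = RETRACTION
    return RegionLabels(labels=labels, v_protrusion=v_protrusion,
                        v_retraction=v_retraction)


def crosscorrelate_maps(
    signal: SignalMap, velocity: VelocityMap, max_lag: int
) -> CrossCorrelation:
    """Pooled signal-velocity Pearson correlation over a symmetric lag range.

    For each lag ``l`` in ``[-max_lag, max_lag]``, r is computed over all
    (position, time) pairs where both ``signal[p, t + l]`` and
    ``velocity[p, t]`` exist.
    """
    if signal.n_positions != velocity.n_positions:
        raise DimensionError("signal and velocity maps disagree on position count")
    n_t = velocity.n_frames
    if not 0 <= max_lag < signal.n_frames / 2:
        raise ParameterError("max_lag must satisfy 0 <= max_lag < n_frames / 2")

    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(len(lags), np.nan)
    n_pairs = np.zeros(len(lags), dtype=int)
    undefined = []
    for i, lag in enumerate(lags):
        t0 = max(0, -lag)
        t1 = min(n_t, signal.n_frames - lag)
        if t1 <= t0:
            continue
        s = signal.values[:, t0 + lag:t1 + lag].ravel()
        v = velocity.values[:, t0:t1].ravel()
        ok = np.isfinite(s) & np.isfinite(v)
        s, v = s[ok], v[ok]
        n_pairs[i] = len(s)
        if len(s) < 2 or s.std() == 0 or v.std() == 0:
            undefined.append(int(lag))
            continue
        r[i] = float(np.corrcoef(s, v)[0, 1])
    if undefined:
        warnings.warn(
            f"correlation undefined (zero variance or empty overlap) at lags "
            f"{undefined}; reported as missing",
            EmptyRegionWarning,
            stacklevel=2,
        )
    return CrossCorrelation(lags=lags, r=r, n_pairs=n_pairs,
                            frame_interval=velocity.frame_interval)


def enrichment_at_shift(
    signal: SignalMap, labels: RegionLabels, shift: int
) -> tuple[float, float]:
    """% enrichment of the time-shifted signal in protrusion/retraction regions.

    Averages ``signal[p, t + shift]`` over the labelled (p, t) entries that
    remain inside the signal map, divides by the whole-cell mean, subtracts 1
    and scales to percent.  An empty overlap for a class yields NaN with a
    warning, never 0.
    """
    n_t_lab = labels.labels.shape[1]
    n_t_sig = signal.values.shape[1]
    if labels.labels.shape[0] != signal.n_positions:
        raise DimensionError("labels and signal map disagree on position count")
    t0 = max(0, -shift)
    t1 = min(n_t_lab, n_t_sig - shift)
    if t1 <= t0:
        raise ParameterError(
            f"shift {shift} leaves no overlap between labels and signal map"
        )
    sig = signal.values[:, t0 + shift:t1 + shift]
    lab = labels.labels[:, t0:t1]

    out = []
    for name, sel in (("protrusion", lab == PROTRUSION),
                      ("retraction", lab == RETRACTION)):
        vals = sig[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(
                f"no {name}-labelled entries in the valid overlap at shift "
                f"{shift}; enrichment missing",
                EmptyRegionWarning,
                stacklevel=2,
            )
            out.append(float("nan"))
        else:
            out.append((float(vals.mean()) / signal.whole_cell_mean - 1.0) * 100.0)
    return out[0], out[1]


def enrichment_function(
    signal: SignalMap,
    velocity: VelocityMap,
    shifts: np.ndarray | range,
    v_protrusion: float = PROTRUSION_THRESHOLD,
    v_retraction: float = RETRACTION_THRESHOLD,
) -> EnrichmentFunction:
    """Time-shifted enrichment of a signal in protrusion/retraction regions."""
    labels = label_protrusion_retraction(velocity, v_protrusion, v_retraction)
    shifts = np.asarray(list(shifts), dtype=int)
    prot = np.empty(len(shifts))
    retr = np.empty(len(shifts))
    for i, sh in enumerate(shifts):
        prot[i], retr[i] = enrichment_at_shift(signal, labels, int(sh))
    return EnrichmentFunction(
        shifts=shifts,
        protrusion_enrichment=prot,
        retraction_enrichment=retr,
        frame_interval=signal.frame_interval,
    )


def normalize_enrichment_to_control(
    sensor: EnrichmentFunction, control: EnrichmentFunction
) -> EnrichmentFunction:
    """Express sensor enrichment relative to a control construct's enrichment.

    Multiplicative normalization of the underlying region/whole-cell ratios:
    ``e' = ((1 + e_s/100) / (1 + e_c/100) - 1) * 100`` per shift and class,
    cancelling band-geometry biases common to both constructs.  A control
    ratio <= 0 (enrichment <= -100%) is degenerate.
    """
    if not np.array_equal(sensor.shifts, control.shifts):
        raise DimensionError("sensor and control enrichment shift grids differ")

    def norm(e_s: np.ndarray, e_c: np.ndarray) -> np.ndarray:
        ratio_c = 1.0 + e_c / 100.0
        if np.any(ratio_c[np.isfinite(ratio_c)] <= 0):
            raise DegenerateControlError(
                "control enrichment ratio <= 0; normalization undefined"
            )
        return ((1.0 + e_s / 100.0) / ratio_c - 1.0) * 100.0

    return EnrichmentFunction(
        shifts=sensor.shifts.copy(),
        protrusion_enrichment=norm(sensor.protrusion_enrichment,
                                   control.protrusion_enrichment),
        retraction_enrichment=norm(sensor.retraction_enrichment,
                                   control.retraction_enrichment),
        frame_interval=sensor.frame_interval,
        normalized=True,
    )


def cycle_durations(
    velocity: VelocityMap,
    frame_interval: float | None = None,
    n_positions: int = 100,
    v_protrusion: float = PROTRUSION_THRESHOLD,
    v_retraction: float = RETRACTION_THRESHOLD,
) -> CycleDurationSet:
    """Protrusion-retraction cycle durations pooled over circumference positions.

    The velocity map is first rescaled to ``n_positions`` rows (100 by
    default).  In each row, a protrusion onset is a protrusion-labelled frame
    whose predecessor is not protrusion-labelled (the first frame counts);
    the cycle closes at the first subsequent retraction-labelled frame, with
    intervening "neither" frames allowed.  A new protrusion onset before any
    retraction restarts the cycle; cycles still open at the end of the trace
    are discarded.  Durations are (closing index - onset index) *
    frame_interval seconds.
    """
    dt = velocity.frame_interval if frame_interval is None else frame_interval
    if velocity.n_positions != n_positions:
        velocity = rescale_map_positions(velocity, n_positions)
    labels = label_protrusion_retraction(velocity, v_protrusion, v_retraction).labels

    durations: list[float] = []
    for row in labels:
        onset: int | None = None
        prev = NEITHER
        for t, lab in enumerate(row):
            if lab == PROTRUSION and prev != PROTRUSION:
                onset = t  # new onset (re)starts the open cycle
            elif lab == RETRACTION and onset is not None:
                durations.append((t - onset) * dt)
                onset = None
            prev = lab
    return CycleDurationSet(durations=np.asarray(durations, dtype=float),
                            frame_interval=dt)
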