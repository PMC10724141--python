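"""Reading movies, writing result tables, and the result bundle.

Maps are written as CSV matrices (rows = positions, columns = frames, a
header comment carrying units); functions and per-track metrics as tidy CSV;
the manifest as JSON with provenance (config hash, seed, package version).
Numeric formatting is fixed (repr-stable %.12g) so re-running an identical
configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .containers import CellMovie, SignalMap, VelocityMap
from .errors import FormatError
from .kinetics import ActivityTrace
from .migration import MigrationMetrics, Track
from .morpho import CrossCorrelation, CycleDurationSet, EnrichmentFunction

__all__ = ["read_movie", "write_movie", "ResultBundle", "write_results"]

_FMT = "%.12g"


def read_movie(
    path: str | Path | list[str | Path],
    channel_names: list[str],
    pixel_size: float,
    frame_interval: float,
) -> CellMovie:
    """Load a multi-channel movie from TIFF.

    ``path`` may be a single multi-page TIFF whose pages are either
    ``(time, H, W)`` for one channel or ``(time, channel, H, W)``, or a list
    of single-channel stacks (one file per channel) of identical shape.
    Calibration comes from the caller's configuration; TIFF metadata is not
    trusted for physical units.
    """
    if isinstance(path, (list, tuple)):
        stacks = [np.asarray(tifffile.imread(str(p))) for p in path]
        shapes = {s.shape for s in stacks}
        if len(shapes) != 1:
            raise FormatError(f"channel stacks disagree in shape: {sorted(shapes)}")
        frames = np.stack(stacks, axis=0)
    else:
        arr = np.asarray(tifffile.imread(str(path)))
        if arr.ndim == 3:
            frames = arr[None, ...]
        elif arr.ndim == 4:
            # stored as (time, channel, H, W) by write_movie
            frames = np.moveaxis(arr, 1, 0)
        else:
            raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")
    if frames.shape[0] != len(channel_names):
        raise FormatError(
            f"{frames.shape[0]} channels in file(s) but "
            f"{len(channel_names)} channel names configured"
        )
    return CellMovie(
        frames=frames.astype(float),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=list(channel_names),
    )


def write_movie(movie: CellMovie, path: str | Path) -> None:
    """Write a movie as a ``(time, channel, H, W)`` float32 TIFF stack."""
    arr = np.moveaxis(movie.frames, 0, 1).astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


@dataclass
class ResultBundle:
    """Everything one pipeline run produces, plus provenance."""

    velocity_map: VelocityMap | None = None
    signal_map: SignalMap | None = None
    crosscorrelation: CrossCorrelation | None = None
    enrichment: EnrichmentFunction | None = None
    cycles: CycleDurationSet | None = None
    activity_traces: list[ActivityTrace] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)
    track_metrics: list[MigrationMetrics] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _write_map(values: np.ndarray, path: Path, unit: str) -> None:
    header = f"rows=positions cols=frames unit={unit}"
    np.savetxt(path, values, delimiter=",", fmt=_FMT, header=header)


def write_results(
    bundle: ResultBundle, out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Serialize a result bundle to CSV/JSON files; returns the manifest.

    Raises :class:`FileExistsError` on collision unless ``overwrite``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def target(name: str) -> Path:
        p = out / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
        written.append(name)
        return p

    if bundle.velocity_map is not None:
        _write_map(bundle.velocity_map.values, target("velocity_map.csv"), "um/min")
    if bundle.signal_map is not None:
        _write_map(bundle.signal_map.values, target("signal_map.csv"), "AU")

    if bundle.crosscorrelation is not None:
        cc = bundle.crosscorrelation
        pd.DataFrame(
            {
                "lag_frames": cc.lags,
                "lag_s": cc.lags_seconds,
                "pearson_r": cc.r,
                "n_pairs": cc.n_pairs,
            }
        ).to_csv(target("crosscorrelation.csv"), index=False, float_format=_FMT)

    if bundle.enrichment is not None:
        ef = bundle.enrichment
        rows = []
        for cls, vals in (
            ("protrusion", ef.protrusion_enrichment),
            ("retraction", ef.retraction_enrichment),
        ):
            for sh, sh_s, v in zip(ef.shifts, ef.shifts_seconds, vals):
                rows.append(
                    {"shift_frames": sh, "shift_s": sh_s, "class": cls,
                     "enrichment_pct": v, "normalized": ef.normalized}
                )
        pd.DataFrame(rows).to_csv(target("enrichment.csv"), index=False,
                                  float_format=_FMT)

    if bundle.cycles is not None:
        pd.DataFrame({"duration_s": bundle.cycles.durations}).to_csv(
            target("cycle_durations.csv"), index=False, float_format=_FMT
        )

    for i, tr in enumerate(bundle.activity_traces):
        pd.DataFrame(
            {
                "frame": np.arange(len(tr.values)),
                "time_s": np.arange(len(tr.values)) * tr.frame_interval,
                "activity": tr.values,
            }
        ).to_csv(target(f"activity_{tr.kind}_{i}.csv"), index=False,
                 float_format=_FMT)

    if bundle.track_metrics:
        pd.DataFrame(
            [
                {
                    "track": i,
                    "distance_um": m.distance,
                    "displacement_um": m.displacement,
                    "directionality": m.directionality,
                    "mean_speed_um_per_min": m.mean_speed,
                }
                for i, m in enumerate(bundle.track_metrics)
            ]
        ).to_csv(target("migration_metrics.csv"), index=False, float_format=_FMT)

    manifest = {
        "files": written,
        "provenance": bundle.provenance,
        "version": __version__,
    }
    with open(target("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
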