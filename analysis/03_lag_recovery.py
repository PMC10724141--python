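#!/usr/bin/env python
"""Recover the signal-velocity coupling delay from the reference movie.

Runs the full pipeline on the 160 s-lag reference movie and writes the
cross-correlation function, the time-shifted protrusion/retraction
enrichment functions, and the cycle durations to results/.  The delay
estimated by both readouts should match the generator's 160 s ground truth
within one frame interval (40 s).
"""

import argparse
from pathlib import Path

import numpy as np

import celledge as ce
from celledge.io import write_results
from celledge.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    params = ce.SyntheticParams(
        n_frames=100, coupling_lag=160.0, coupling_gain=0.5, noise_sd=2.0,
        seed=args.seed,
    )
    movie, _ = ce.generate_cell_movie(params)
    cfg = ce.PipelineConfig(simulate=True, seed=args.seed)
    bundle = run_pipeline(cfg, movie=movie)
    write_results(bundle, ROOT / "results" / "lag_recovery", overwrite=True)

    ef, cc = bundle.enrichment, bundle.crosscorrelation
    peak_idx = int(np.nanargmax(ef.protrusion_enrichment))
    print(f"true coupling lag: {params.coupling_lag:.0f} s")
    print(f"enrichment peak shift: {ef.peak_shift_seconds:+.0f} s "
          f"(protrusion {ef.protrusion_enrichment[peak_idx]:+.1f}%, "
          f"retraction {ef.retraction_enrichment[peak_idx]:+.1f}%)")
    print(f"cross-correlation extremum: "
          f"{cc.extremum_lag * movie.frame_interval:+.0f} s "
          f"(r = {np.nanmax(cc.r):.2f})")
    print(f"cycle durations: n={len(bundle.cycles.durations)}, mean "
          f"{bundle.cycles.mean:.0f} s, SEM {bundle.cycles.sem:.1f} s")


if __name__ == "__main__":
    main()
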