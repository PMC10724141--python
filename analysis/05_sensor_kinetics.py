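#!/usr/bin/env python
"""Why control correction matters: photobleaching and the two normalizations.

Generates a movie in which both channels bleach exponentially (a pure
artifact — there is no activity change), then compares the simple
background/baseline normalization against the control-corrected form.  The
simple trace drifts with the bleach; the corrected trace stays at zero.
Writes both traces and a windowed before/after response to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import celledge as ce

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    params = ce.SyntheticParams(n_frames=40, coupling_gain=0.0, noise_sd=0.5,
                                bleach_rate=2e-4, seed=args.seed + 4)
    movie, _ = ce.generate_cell_movie(params)
    masks = ce.segment_cell(movie, "volume")
    baseline = (0, 5)

    sensor = ce.region_trace(movie, "sensor", masks)
    control = ce.region_trace(movie, "volume", masks)
    sensor_bg = ce.background_trace(movie, "sensor", masks)
    control_bg = ce.background_trace(movie, "volume", masks)

    corrected = ce.corrected_activity(sensor, sensor_bg, control, control_bg,
                                      baseline)
    simple = ce.normalized_activity(sensor, sensor_bg, baseline)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame({
        "time_s": np.arange(params.n_frames) * params.frame_interval,
        "corrected_activity": corrected.values,
        "simple_activity": simple.values,
    }).to_csv(out / "kinetics_bleach_demo.csv", index=False)

    resp_corr = ce.window_response(corrected, n_pre=5, n_post=5, onset=20)
    resp_simple = ce.window_response(simple, n_pre=5, n_post=5, onset=20)
    print(f"bleach rate {params.bleach_rate:.0e}/s over "
          f"{params.n_frames * params.frame_interval:.0f} s")
    print(f"simple normalization drifts to {simple.values[-1]:.3f} "
          f"(artifactual apparent loss of activity)")
    print(f"control-corrected trace stays within "
          f"{np.abs(corrected.values).max():.4f} of 0")
    print(f"5-frame window responses at frame 20: corrected "
          f"{resp_corr:+.4f}, simple {resp_simple:+.4f}")


if __name__ == "__main__":
    main()
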