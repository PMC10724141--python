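# celledge

Quantitative cell-edge morphodynamics from fluorescence time-lapse movies.

Migrating and spreading cells show spontaneous, minutes-scale
protrusion–retraction cycles of their edge, driven by Rho-family GTPase
signalling at the plasma membrane.  `celledge` turns a two-channel movie (a
cytosolic volume marker delineating the cell plus one or more signal
channels, e.g. translocation biosensors of Rac/Rho activity or fluorescent
GEFs) into the standard quantitative readouts of that behaviour:

* **edge-velocity maps** `v(p, t)` — local boundary speed (μm/min, positive
  outward) over 100 matched circumference positions × time;
* **inward-band signal maps** — mean fluorescence within ~3 μm inside the
  edge, on the same parameterization, so membrane-proximal signal is not
  diluted by extracellular background;
* **time-shifted enrichment functions** — % enrichment of the signal in
  protruding (v > 0.075 μm/min) and retracting (v < −0.075 μm/min) regions
  relative to the whole-cell mean, as the labelled regions slide along the
  time axis: the peak shift estimates the delay between edge motion and
  signal recruitment;
* **signal–velocity cross-correlation functions** and
  **protrusion-retraction cycle durations** (protrusion onset to the next
  retraction onset, pooled over positions);
* **biosensor kinetics** with background, baseline, and control-sensor
  correction,

      A_corr(t) = (I_s − I_s,BG)/(Ī_s,0 − Ī_s,0,BG) − (I_c − I_c,BG)/(Ī_c,0 − Ī_c,0,BG)

  (baseline mean 0; the simple first term alone has baseline mean 1), plus
  a central/peripheral split of the attachment area (outer 5 px ≙ 1.3 μm at
  0.26 μm/px);
* **migration metrics** from labelled-nuclei movies: path distance, net
  displacement, directionality = displacement/distance, mean speed.

A seeded synthetic generator (star-convex oscillating cell, velocity-coupled
sensor with configurable lag/gain/noise, correlated-random-walk nuclei)
provides closed-form ground truth, so the whole pipeline is testable without
any external data.  See `docs/methods.md` for models, conventions and
numerical choices.

## Worked example

Recover a known signal-recruitment delay from a synthetic movie:

```python
import celledge as ce
from celledge.pipeline import run_pipeline

params = ce.SyntheticParams(n_frames=100, coupling_lag=160.0,
                            coupling_gain=0.5, noise_sd=2.0, seed=1)
movie, truth = ce.generate_cell_movie(params)
bundle = run_pipeline(ce.PipelineConfig(simulate=True, seed=1), movie=movie)
print("enrichment peak shift:", bundle.enrichment.peak_shift_seconds, "s")
print("cross-correlation extremum:",
      bundle.crosscorrelation.extremum_lag * movie.frame_interval, "s")
print("cycles:", len(bundle.cycles.durations), "mean", bundle.cycles.mean, "s")
```

```
enrichment peak shift: 160.0 s
cross-correlation extremum: 160.0 s
cycles: 660 mean 282.90909090909093 s
```

Both readouts recover the generator's 160 s lag exactly (one frame = 40 s);
the mean cycle duration sits near half the 600 s oscillation period, as
expected for a thresholded sinusoid.  The same chain is driven step by step
by the numbered scripts in `analysis/` (simulation, edge maps, lag
recovery, null control, kinetics, migration), each printing what it found
and writing tables under `results/`.

A `celledge` command-line interface wraps the library for shell use
(`celledge simulate|segment|maps|correlate|enrich|cycles|kinetics|migrate|all`),
driven by a single YAML config; run `celledge --help`.

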