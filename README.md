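# evfccs

Dual-color PIE-FCCS and coincident-burst quantification of labeled
extracellular vesicles (EVs) from two-channel photon time tags.

Extracellular vesicles are 30–200 nm membrane vesicles that carry protein and
nucleic-acid cargo between cells. When the cargo protein carries a green
fluorescent tag and the vesicle membrane a far-red one, a confocal microscope
with pulsed interleaved excitation (PIE) records, photon by photon, which
vesicles carry cargo as they diffuse through the focus. This package turns
those photon records (macrotime / TCSPC nanotime / detector) into the
quantities a single-vesicle experiment is after:

* the mean numbers of green-, red- and dual-labeled particles in the focal
  volume (N_g, N_r, N_rg) from fluorescence (cross-)correlation amplitudes,
* the **loading yield** N_rg/N_r — the fraction of labeled vesicles that
  actually carry cargo — by two independent routes (FCCS amplitudes and
  coincident two-color bursts),
* per-vesicle **hydrodynamic sizes** from single-transit burst durations via
  Stokes–Einstein, summarized with rescaled-gamma fits,
* per-vesicle **cargo-molecule counts** from burst brightness against an
  independently calibrated single-molecule brightness,
* condition-level statistics (subset splitting, Welch t-tests).

A Brownian-dynamics photon simulator with per-photon ground truth generates
fully controlled synthetic acquisitions, so every stage of the analysis is
testable against known truth. It is aimed at single-molecule biophysicists
building or validating FCCS/burst pipelines.

## The models in brief

Correlation curves are fit with the 3D diffusion model with background
correction,

    G_D(τ) = (1 − B/F)² / N · 1/(1 + τ/τ_D) · (1 + τ/(κ²τ_D))^(−1/2),

with occupancy N, diffusion time τ_D = ω_xy²/(4D), axial ratio
κ = ω_z/ω_xy, background B and mean rate F. Cross- and autocorrelation
amplitudes combine to N_rg = G_rg(0)·N_r·N_g/[(1−B_r/F_r)(1−B_g/F_g)],
with an effective-volume correction when the two channels' calibrated
volumes differ. Bursts are found with the sliding-window rule (m consecutive
photons at local rate ≥ K·B), calibrated so the median burst duration
matches the FCCS τ_D, and each burst duration converts to a diameter via

    d = 4 k_B T τ_burst / (3 π η ω₀²).

Coincident green/red bursts (center times within a tolerance window derived
from the burst-duration distributions) mark single loaded vesicles.
See `docs/methods.md` for the full account, including the deliberate design
choices and known limitations.

## Worked example

Simulate a 300 s acquisition of a mixture in which 30% of the vesicles carry
two green cargo molecules, then run the full pipeline:

```python
from evfccs import make_scenario, simulate_photon_stream, AnalysisConfig, run_pipeline
from evfccs.report import calibrate_brightness, summarize_condition

eps = calibrate_brightness(seed=2)          # free-cargo brightness, cps/molecule
cfg = make_scenario("mixture_dual30", duration=300.0, seed=1)
stream, _ = simulate_photon_stream(cfg)     # two-channel photon time tags
analysis = AnalysisConfig(
    condition="mixture_30pct_loaded",
    background_green=200.0, background_red=200.0,   # measured separately
    brightness_cps=eps, seed=1,
)
report = run_pipeline(stream, analysis)
print(f"calibrated brightness: {eps:.0f} cps/molecule")
print(summarize_condition(report))
```

Output:

```
calibrated brightness: 3989 cps/molecule
condition: mixture_30pct_loaded
duration: 300.0 s
occupancies: N_g=0.0198 N_r=0.129 N_rg=0.0262
loading yield (FCCS): 0.276
loading yield (bursts): 0.071
coincident rate: 26.80 events/min (134 events)
size (gamma mean): green 90 nm, red 87 nm
cargo median: 2 molecules
subsets: 6 x 20 events, rate 29.31 +- 5.71 events/min
```

Reading it: the FCCS amplitude route recovers the loading yield (0.28 vs the
simulated 0.30 within the run's sampling noise); the burst-coincidence route
is a *relative* metric that underestimates the absolute fraction (its
geometric biases are analyzed in `docs/methods.md`) but tracks differences
between conditions; the gamma-fit size means recover the simulated 100 nm
vesicles to within ~10%; and the median cargo count per coincident vesicle is
the simulated 2 molecules.

The same stages are scriptable from the shell:

```
evfccs simulate mixture_dual30 --duration 60 --seed 1 --out run.h5
evfccs gate run.h5 --out-green g.h5 --out-red r.h5
evfccs bursts r.h5 --background 200 --out red_bursts.tsv
evfccs run run.h5 --condition demo --brightness 4000 --out report.json
```

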