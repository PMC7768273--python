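# sleepswitch

Tools for quantifying **sleep-state bistability** in rodent EEG and in
spiking-network models of the NREM/REM "flip-flop" switch.

Sleep normally separates cleanly into NREM and REM states; epochs whose EEG
lies *between* the two — NREM/REM transitionary (NRt) sleep — are rare, and
their rate and duration measure how bistable the switching circuitry is.
This package implements three analyses around that idea:

1. **EEG state-space NRt scoring.** Each 5-s epoch is reduced to sixteen
   2-Hz band powers (1–33 Hz) and embedded in a 2-D state space,
   `x = log10 P(7–9 Hz)/P(1–9 Hz)` (theta ratio) and
   `y = log10 P(1–19 Hz)` (total low-frequency power), smoothed with a
   5-epoch moving average. NREM and REM cluster boundaries are convex
   envelopes of the points bounding trajectory self-intersections (bounded
   within-state trajectories loop; directed transitions do not); the NRt
   region is demarcated by the trajectories of complete NREM→REM
   transitions; six scoring rules then upgrade a manual 3-stage hypnogram
   (W/N/R) to 4 stages (W/N/R/t), with bout statistics (NRt densities per
   origin state, short/long REM bouts, % of total sleep time).
2. **Flip-flop circuit simulations.** Two mutually inhibitory pools of 25
   leaky integrate-and-fire neurons (dv/dt = −v + I_applied + Σ W·s, alpha
   synapses, Euler integration, Gaussian current noise, rest 0 / threshold
   1), driven by a linearly ramping REM drive through a 10-neuron input
   pool. Includes the 11×11 synaptic-weight and bias-current tuning grids,
   bimodality analysis of the pooled R-minus-N rate-difference histograms,
   and the inactivation experiments (R-pool, N-pool, both) with NRt density
   and latency-to-REM metrics.
3. **Focal drug-spread simulation.** 3-D muscimol diffusion from a point
   source on a 250³ grid by iterated Gaussian smoothing (size 3, SD 1.2; one
   iteration ≡ one minute), for pressure microinjection (307 mM source reset
   for 30 of 150 iterations) versus reverse microdialysis (0.085 mM reset
   throughout), with the cubic dose–response
   `PSI(c) = 4e-7·c³ − 0.0007·c² + 0.45·c` (c in nM) mapping concentration
   to percent spike inhibition and defining the 1%-PSI inhibition radius.

A synthetic-data generator produces labelled band-power recordings with the
cluster/corridor structure the scorer assumes (including a "drug" condition
that inflates REM-origin NRt), so the whole pipeline is testable without any
animal data. An estimation-statistics layer provides paired mean differences
with BCa bootstrap CIs (5000 resamples) and Cohen's d.

## Worked example

```python
from sleepswitch.synth import SyntheticConfig, generate_recording
from sleepswitch.pipeline import score_recording

rec = generate_recording(SyntheticConfig(seed=7), n_epochs=3000)
scored = score_recording(rec.band_powers, rec.labels3, control_range=(0, 1500))
print(scored.bouts.summary)
```

prints (abridged):

```
epoch_counts        {'W': 588, 'N': 1374, 'R': 634, 't': 404}
nrt_pct_tst         16.75
nrt_from_N_bouts    41     nrt_from_N_density_per_min  0.358
nrt_from_R_bouts    7      nrt_from_R_density_per_min  0.132
short_rem_bouts     20     long_rem_bouts              16
```

Boundaries were fit on the first 1500 epochs (the "control period") and
applied to the whole recording: 404 of 3000 epochs are scored as NRt
(16.8% of total sleep time), 41 NRt bouts exit from NREM (0.36 bouts per
minute of NREM) and 7 from REM. Against the generator's ground truth this
run recovers t epochs with sensitivity 0.954 and specificity 0.944, and the
wake epochs are untouched by construction.

The same steps are available from the shell:

```bash
sleepswitch synth --seed 1 --epochs 3000 --out run/synth
sleepswitch score --bandpower run/synth/bandpower.csv \
    --hypnogram run/synth/hypnogram3.csv --control-range 0:1500 --out run/score
sleepswitch flipflop experiment --seed 1 --networks 20 --out run/ff
sleepswitch diffusion --scenario both --out run/diff
```

Every output directory carries a `manifest.json` (config, seeds, file
hashes) sufficient to reproduce it bit-identically.

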