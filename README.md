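# mdephys

Intrinsic-electrophysiology analysis for thalamocortical projection neurons
recorded in whole-cell current clamp. Mediodorsal (MD) thalamic neurons that
project to medial prefrontal cortex fall into medial (MD-M) and lateral
(MD-L) populations with distinct membrane physiology: MD-L cells carry more
HCN-channel (I_h) conductance, which lowers their input resistance, deepens
their hyperpolarization-activated voltage sag and afterhyperpolarization,
and raises the current needed to drive tonic, burst, and rebound firing.
`mdephys` is for experimenters and modelers who want that entire analysis —
feature extraction, firing-mode classification, and estimation statistics —
as tested, scriptable code, together with a conductance-model neuron that
generates recordings with known ground truth so every estimator can be
validated end-to-end.

The package implements:

* **Subthreshold features** — resting membrane potential; membrane time
  constant τ from the averaged −10 pA × 1,000 ms response (1/e point,
  interpolated); input resistance R_N as the OLS slope of subthreshold
  steady-state voltage vs current over −60…+60 pA steps (mV/pA → MΩ);
  voltage sag (step minimum minus the mean of the last 25 ms), normalized by
  selecting the sweep peaking nearest −100 mV; afterhyperpolarization (the
  minimum within 250 ms of step offset, across steps), including the
  matched-time readout for drug comparisons.
* **Spike analysis** — peak detection (overshoot above 0 mV, ≥1 ms apart);
  spike threshold by the third-derivative criterion (earliest crossing above
  a configurable cutoff within 3 ms of the peak); the rule-based
  burst/tonic/rebound/total classifier built on interspike-interval ratios
  (burst: ISI < 4 ms and ratio within [0.50, 1.99] inside 500 ms of onset;
  tonic phase opens at the first ratio ≥ 2; >15 spikes pool as "total";
  rebound: within 1 s of a hyperpolarizing offset); per-mode rheobase,
  accommodation index, and F-I curves with the class-specific inclusion
  rules.
* **Estimation statistics** — Mann–Whitney (exact by full enumeration for
  small tie-free samples, tie/continuity-corrected normal approximation
  otherwise), Wilcoxon signed rank (signed-sum convention), order-statistic
  median CIs, seeded percentile-bootstrap median differences with the full
  bootstrap distribution retained, η² = z²/(N−1) effect sizes, Spearman
  correlation, and the two-sample sample-size formula
  n = ⌈2σ²(z₁₋α/₂+z_power)²/δ²⌉.
* **Synthetic neuron** — a single-compartment model (leak, I_h, T-type
  calcium, inward rectifier, exponential spike mechanism with adaptation)
  with MD-M-like and MD-L-like presets, population generators with
  controlled between-cell variability, and HCN-block (ZD7288) emulation as
  `g_h → (1−block)·g_h`. Simulation is vectorized across sweeps and cells,
  deterministic per seed.

See `docs/methods.md` for the model equations, parameter defaults, and known
limitations.

## Worked example

Simulate one lateral-type cell, run the full protocol battery
(−60…+60 pA in 5 pA steps; −250…+350 pA in 25 pA steps; 10 × −10 pA; a
zero-bias epoch), and extract its feature vector:

```python
from mdephys import synth, pipeline

p = synth.md_l_preset(seed=7)
fine   = synth.simulate_protocol(p, synth.fine_protocol(),   -65.0)
coarse = synth.simulate_protocol(p, synth.coarse_protocol(), -65.0)
tau    = synth.simulate_protocol(p, synth.tau_protocol(),    -65.0)
rest   = synth.simulate_protocol(p, synth.rest_protocol(),   None)
row = pipeline.extract_features(rec_fine=fine, rec_coarse=coarse,
                                rec_tau=tau, rec_rest=rest)
```

This prints (formatted):

```
RMP              -61.02 mV
tau               59.04 ms
R_N               397.3 MOhm
sag @ -100 mV     -7.32 mV
AHP              -68.03 mV
rheobase tonic     45.0 pA @ threshold -30.2 mV
rheobase burst     20.0 pA
rheobase reb.     -15.0 pA
spikes/burst        2.0
flags: {'accommodation_index': 'no sweep with >= 12 tonic spikes'}
```

Reading: the cell rests at −61 mV and charges with a 59 ms time constant;
its 397 MΩ input resistance and −7.3 mV sag at the −100 mV step are the
lateral-type signature (strong I_h); it needs +20 pA to fire a
depolarization-evoked burst, +45 pA before sustained tonic firing appears,
and −15 pA of hyperpolarization before release triggers a rebound burst. A
feature that cannot be measured is never silently zero — here no sweep
reached the 12 tonic spikes the accommodation index requires, and the flag
says so.

The same pipeline runs from the shell:

```bash
mdephys simulate --preset MD-L-like --protocol fine --n 5 --seed 1 --out sim/
mdephys extract sim/ --out features.csv
mdephys compare features.csv --out comparisons.csv
mdephys run --seed 1 --out full_run/       # simulate -> extract -> compare
```

`mdephys run` writes `features.csv`, `comparisons.csv` (per-feature test
statistic, p, medians with CIs, bootstrap median difference, η² where
significant) and `summary.json` mapping each expected group contrast to its
observed direction and p-value.

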