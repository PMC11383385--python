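# Methods

`mdephys` analyses episodic current-clamp recordings from thalamocortical
projection neurons: it extracts subthreshold membrane properties, classifies
action potentials into burst / tonic / rebound firing modes, compares cell
populations with nonparametric estimation statistics, and validates the whole
stack end-to-end against a single-compartment conductance model whose ground
truth is known. This note documents the science behind each layer, the
parameters that matter, and the places where the design was genuinely open.

## Units and conventions

Time in ms, voltage in mV, current in pA, conductance in nS, resistance in
MΩ, capacitance in pF — so `R[MΩ] = 1000/g[nS]` and `τ[ms] = C[pF]/g[nS]`.
Membrane potentials are stored uncorrected for the liquid junction
potential; a sidecar may carry an informational `ljp_mv` that no computation
applies. Sampling defaults to 20 kHz; square steps default to 250 ms
pre-step baseline, 1,000 ms step, and 1,250 ms post-step (the rebound
analysis window is 1 s, so the post-step epoch must exceed it).

## Feature estimators

* **Resting membrane potential (RMP)** — mean voltage over the first 100 ms
  of the first zero-bias sweep. Bias is recoverable from the command trace
  itself (the baseline current level), so a recording with no zero-bias
  segment yields a flagged missing value rather than a wrong one.
* **Membrane time constant (τ)** — the −10 pA, 1,000 ms step is repeated
  (10× by default) and averaged point-wise; τ is the time for the deflection
  to reach 1 − 1/e of its steady value at the step **onset**, by linear
  interpolation between samples. The post-offset decay mode is also
  implemented (`mode="offset"`), but the onset charging is the default
  because cells with low rebound rheobase fire rebound bursts after a −10 pA
  step, which contaminates the offset relaxation; the onset of a
  hyperpolarizing step is spike-free by construction. The two modes agree
  exactly for a passive membrane.
* **Input resistance (R_N)** — ordinary least-squares slope of steady-state
  voltage (mean of the last 100 ms of the step) against injected current
  over the −60…+60 pA family, excluding sweeps with spikes during the step;
  mV/pA is GΩ, reported ×1000 in MΩ. Because HCN and inward-rectifier
  conductances activate over the hyperpolarized limb, the fitted slope is a
  chord resistance, systematically below the small-signal resistance at the
  holding potential — true of the real measurement as well.
* **Voltage sag** — per hyperpolarizing sweep, the minimum voltage during
  the step minus the mean of its last 25 ms (signed ≤ 0 for sagging cells;
  comparisons use magnitude where a positive rendering is wanted). The
  normalized readout selects the sweep whose peak lands closest to −100 mV
  and flags selections more than 5 mV away; no interpolation across sweeps.
* **Afterhyperpolarization (AHP)** — minimum voltage in the 250 ms after
  step offset, minimized across all depolarizing sweeps. A 500 ms window is
  available by argument (the source protocols used both windows in different
  places). Drug comparisons use the matched-time readout: the post-drug
  voltage at exactly the sweep amplitude and latency where the pre-drug AHP
  was maximal, which cancels differences in spike-count-dependent
  adaptation.
* **Spike detection** — local maxima overshooting 0 mV with ≥ 1 ms
  separation (the higher peak wins); spike "time" is the peak time.
* **Spike threshold** — the trace is boxcar-smoothed (0.2 ms), the third
  time derivative is formed by central differences in mV/ms³, and the 3 ms
  before the peak are scanned for the earliest crossing above a cutoff. The
  published criterion constant (0.3) carries no units; in mV/ms³ a cutoff of
  0.3 fires on the foot of the low-threshold calcium spike for burst and
  rebound spikes, whereas the estimator is meant to report the sodium-spike
  kink. The default cutoff is therefore 30 mV/ms³ (configurable and recorded
  in outputs), which reads ≈ −30 mV for tonic spikes and ≈ −33 mV for burst
  spikes — close to the published medians. If no crossing exists the
  estimator falls back to 5% of the maximal rate of rise and flags it.

## Spike classification

The rule set, applied per sweep (all constants configurable):

* Hyperpolarizing sweeps: spikes within 1 s after offset are **rebound**;
  everything else is **other**.
* Depolarizing sweeps with more than 15 in-step spikes: all pooled as
  **total** (burst and tonic cannot be separated reliably at such rates).
* Otherwise, the ISI ratio of spike *k* is ISI(k−1,k)/ISI(k−2,k−1) —
  current interval over previous. The first spike whose ratio is ≥ 2 opens
  the **tonic** phase; every later spike is tonic. Before that point, a
  spike is **burst** if it lies within 500 ms of step onset, its ISI to the
  previous spike is < 4 ms, and its ratio is in [0.50, 1.99]; the second
  spike of a burst has no defined ratio and is admitted on the ISI criterion
  alone (otherwise two-spike bursts would be unclassifiable), and the spike
  that opens a qualifying burst is labelled burst as well.

Derived measures: **rheobase** per firing mode (smallest positive amplitude
with ≥ 1 tonic or burst spike; smallest-magnitude hyperpolarizing amplitude
whose sweep contains a rebound *burst*, i.e. ≥ 2 rebound spikes — single
rebound spikes do not qualify), with the threshold voltage of the first
spike of that mode and, for rebound, the steady-state voltage of the
rheobase sweep; the **accommodation index** (least-squares slope of ISI
against interval index over the tonic phase of the lowest-amplitude sweep
with ≥ 12 tonic spikes, in ms per interval); **F-I curves** per class, where
the tonic series includes zero-count sweeps but burst statistics exclude
sweeps without bursts; and **spikes per burst** averaged over burst-bearing
sweeps.

## Statistics

Two-group comparisons use the Mann–Whitney test with midranks; the p-value
is exact (full enumeration of rank assignments via a subset-sum recursion)
for tie-free samples with n₁+n₂ ≤ 16 and a tie- and continuity-corrected
normal approximation otherwise. U is reported as min(U₁, U₂). Paired
comparisons use the signed-rank test with the signed-sum convention
(W = Σ signed ranks, so ten uniformly negative changes give W = −55); zero
differences are dropped; exact for n ≤ 15. Medians carry distribution-free
order-statistic confidence intervals (the smallest symmetric order-statistic
pair with binomial coverage ≥ 95%; samples under n = 6 return the range with
an under-coverage flag). Median differences carry seeded percentile-bootstrap
intervals (5,000 resamples by default; the full bootstrap distribution is
retained for estimation plots; percentile rather than BCa for exact
reproducibility). The rank-test effect size is η² = z²/(N−1) — the standard
definition for rank tests, chosen because it reproduces the published effect
sizes from their (U, n) pairs — categorised small/medium/large at
0.01/0.06/0.14 and reported only where p < 0.05. Spearman correlations use
midrank Pearson with exact permutation p for n ≤ 9 and the t approximation
otherwise. The sample-size calculation is the two-sided normal-approximation
two-sample formula n = ⌈2σ²(z₁₋α/₂+z_power)²/δ²⌉ (δ=20 ms, σ=20 ms,
α=0.05, power=0.8 → 16 per group); an iterated noncentral-t variant (→ 17)
is available behind a flag.

## The synthetic neuron

A single compartment with leak, HCN (I_h), T-type calcium, inward-rectifier
K (Kir), an instantaneous delayed-rectifier K, a spike-triggered adaptation
conductance, and an exponential spike mechanism:

    C dV/dt = −g_L(V−E_L) − g_h·m_h·(V−E_h) − g_T·m∞²·h_T·(V−E_T)
              − g_Kir·k∞(V)·(V−E_K) − g_K·n∞(V)·(V−E_K) − g_w·(V−E_K)
              + g_spike·s·ΔT·exp((V−V_T)/ΔT) + I_inj + ξ(t)

* **HCN** — first-order gate, steady state 1/(1+exp((V+85)/25)), bell-shaped
  time constant capped at `h_taumax` (120 ms MD-M-like, 300 ms MD-L-like),
  E_h = −43 mV. The shallow activation slope is a deliberate functional fit:
  the source data constrain the ratio of sag to steady-state rectification to
  AHP depth, not channel-level gating, and a conventional steep sigmoid
  cannot satisfy all three at once. ZD7288 is modelled purely as scaling g_h
  by (1 − block fraction); no off-target effects.
* **T-type calcium** — instantaneous m∞² activation (V½ −49, slope 4) times
  a first-order inactivation gate (V½ −78, slope 4) whose clock is slow
  (300 ms) below ≈ −55 mV and fast (8 ms) at spike voltages, plus a 45%
  multiplicative depletion of h per action potential. The per-spike
  depletion is a lumped stand-in for inactivation accumulated during each
  spike's depolarized excursion; together with the fast spike-triggered
  adaptation it terminates bursts crisply after 2–3 spikes (rebound bursts,
  starting from larger h, run 3–5). Without it the decaying calcium spike
  leaks marginal late spikes whose ISI ratios spuriously trigger the tonic
  rule at burst rheobase.
* **Spiking** — exponential integrate-and-fire escape (ΔT = 1.5 mV) scaled
  by a slow availability gate s; when V reaches +20 mV the trace is pinned
  at +32 mV for 0.05 ms (so peaks overshoot 0 mV and survive decimation to
  20 kHz) then reset to −41 mV with a 0.8 ms refractory period. The
  adaptation conductance (1.8 nS per spike, τ = 12 ms) produces fast spike
  AHPs and burst termination while leaving the slow step-offset AHP to HCN.
* **Kir** — instantaneous, activating below ≈ −115 mV; bounds the response
  to the strongest hyperpolarizing steps the way real rectification does
  (without it a −250 pA step into 0.8 GΩ would pass −180 mV).
* **Integration** — forward Euler on V, exponential Euler on gates, fixed
  dt = 0.025 ms, decimated to the output rate; many sweeps and cells are
  integrated in lockstep as one vectorized batch. A guard raises if V leaves
  (−160, +100) mV outside the spike-pinned phase. Current noise is white,
  2 pA SD per step by default, with one reproducible stream per
  (cell seed, sweep index), so a sweep is bit-identical whether simulated
  alone or in a batch.
* **Holding** — the bias current for a target holding potential is solved
  from the steady-state I–V curve and the pre-step state starts exactly at
  the target; zero-bias recordings start at the resting fixed point nearest
  −65 mV.

### Presets and populations

Two presets emulate the medial and lateral phenotypes. MD-M-like: C 90 pF,
g_L 0.65 nS, g_h 0.7 nS, g_T 300 nS, V_T −32.5 mV. MD-L-like: C 140 pF,
g_L 0.9 nS, g_h 2.2 nS, g_T 400 nS, V_T −32.9 mV, slower HCN kinetics. The
leak reversal is solved per cell so the zero-bias rest sits at a per-cell
target drawn from N(−61, 1.2) mV. Extracted single-cell values: R_N 681 vs
397 MΩ, τ 78 vs 59 ms, sag at −100 mV −2.0 vs −7.3 mV, AHP −65.8 vs
−68.0 mV, rheobase tonic 30/45, burst 10/15, rebound −10/−15 pA, ≈ 2 spikes
per depolarization-evoked burst, group-equal spike thresholds near −31 mV.
The per-preset V_T offset expresses the empirical finding that spike
thresholds do not differ between the populations even though conductance
loads do.

Populations are drawn lognormally around a preset: a shared cell-size
factor (CV = 0.2 by default) scales all conductances and the capacitance
together — so resistance varies more than the time constant, as in real
populations — plus smaller independent per-parameter jitter (CV/2) and a
1.5 mV SD jitter on V_T. Calibration is to the published population
intervals rather than point values: at n = 20, CV = 0.2 the extracted
medians land inside the published 95% CIs for MD-M R_N ([641, 1021] MΩ),
MD-L sag at −100 mV ([−9, −6] mV), RMP ([−64, −59] mV) and tonic threshold
(−31.5 ± 4 mV). The published point medians (e.g. R_N 793 MΩ for MD-M) are
not reachable jointly with a realistic firing phenotype in one compartment:
pushing the leak low enough collapses rheobases and thresholds, so the
model sits inside the intervals instead. Absolute conductances are
implementation choices, flagged as such in the ground-truth JSON the
simulator writes.

### What the generator does and does not emulate

It reproduces: HCN sag and its abolition by channel block, the inverse
sag–R_N relation, sag-correlated AHPs, onset and rebound bursting with
burst/tonic/rebound rheobase ordering and direction differences between the
phenotypes, tonic firing with mild accommodation, group-equal RMP and spike
thresholds, and fully deterministic seeded noise. It does **not** reproduce:
depolarization block within a 1-s step (the bounded availability gate
cannot block without also silencing moderate steps); the published
*reduction* of rebound burst size and the more-negative rebound rheobase
after HCN block (in the model the resistance increase deepens
hyperpolarization and wins over the lost I_h tail, so rebound firing grows
slightly); channel-level gating realism (the HCN slope is a functional
lump); spatial structure, synaptic input, temperature effects, or
electrode/access-resistance artifacts. The rebound-spike threshold is also
systematically 1.5–3 mV apart between presets at any derivative cutoff,
because the first rebound spike rides a group-dependent calcium spike —
real recordings show no such difference, so passing tests on the other
contrasts say nothing about rebound thresholds in real data.

## Problem sizes and numerical choices

Default test/validation scales: 50 passive cells for ground-truth recovery
(R_N within 1%, τ within 2%); 1,000 random spike trains for classifier
equivalence with an independently written literal transcription of the
rules; 200 random small samples for exact-test enumeration checks; 20 cells
per group (CV 0.2) for the direction battery; 8 + 8 cells for the
channel-block emulation; 1,000 trials for the type-I error rate of the
group comparison (nominal 5%). Ties in rank tests use midranks; tie-broken
degenerate inputs (all-zero differences, constant samples) return flagged
degenerate results rather than raising. The OLS fits use `numpy.polyfit`;
root-finding uses bracketed Brent iterations on the steady-state I–V curve,
taking the root nearest the physiological operating point when the T-window
current makes the curve non-monotone.
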