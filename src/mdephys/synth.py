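"""Single-compartment conductance-model simulator for thalamic relay neurons.

The model reproduces the phenomenology that the feature extractors target:
HCN-mediated voltage sag and afterhyperpolarization, T-type-driven onset and
rebound bursts, tonic firing with accommodation, and depolarization block at
strong drive.  Membrane equation (units mV, ms, pA, nS, pF):

    C dV/dt = -g_L (V - E_L)
              - g_h m_h (V - E_h)                       (HCN, first-order gate)
              - g_T mT_inf(V)^2 h_T (V - E_T)           (T-type Ca, inst. act.)
              - g_K nK_inf(V) (V - E_K)                 (plateau-capping K)
              - g_w (V - E_K)                           (spike-triggered adapt.)
              + g_spike * s * dT * exp((V - V_T)/dT)    (exponential spike)
              + I_inj + noise

Spikes are emitted by threshold-crossing of the exponential escape: when V
reaches ``v_cut`` the trace is pinned at ``v_peak`` for 0.05 ms (so peaks
always overshoot 0 mV and survive decimation to 20 kHz) and then reset with
an absolute refractory period.  A slow availability gate ``s`` emulates
cumulative sodium-channel inactivation and produces depolarization block.

Integration is fixed-step (forward Euler on V, exponential Euler on gates)
at dt = 0.025 ms, decimated to the output sampling rate.  Many sweeps (and
cells) are integrated simultaneously as a batch, which is what makes
population-scale simulation cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NumericalError
from .types import ProtocolSpec, Recording, Sweep

__all__ = [
    "TGate",
    "SpikeParams",
    "SimParams",
    "GroundTruth",
    "StepDesc",
    "fine_protocol",
    "coarse_protocol",
    "tau_protocol",
    "rest_protocol",
    "md_m_preset",
    "md_l_preset",
    "passive_preset",
    "apply_zd7288",
    "solve_bias",
    "resting_potential",
    "simulate_sweep",
    "simulate_protocol",
    "simulate_population_protocol",
    "make_population",
    "ground_truth",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class TGate:
    """T-type calcium current gating: instantaneous m^2 activation times a
    first-order inactivation gate whose time constant interpolates between a
    slow de-inactivation limit (hyperpolarized) and a fast inactivation limit
    (depolarized)."""

    m_vhalf_mv: float = -49.0
    m_slope_mv: float = 4.0
    h_vhalf_mv: float = -78.0
    h_slope_mv: float = 4.0
    tau_h_slow_ms: float = 300.0    # de-inactivation / subthreshold decay
    tau_h_fast_ms: float = 8.0      # inactivation at spike voltages
    tau_h_vhalf_mv: float = -55.0   # where the clock switches fast
    tau_h_slope_mv: float = 3.0
    spike_depletion: float = 0.45   # fractional h loss per action potential
    e_rev_mv: float = 120.0


@dataclass(frozen=True)
class SpikeParams:
    """Exponential spike mechanism with reset, refractoriness, adaptation,
    a slow availability gate (depolarization block) and an instantaneous
    rectifying K conductance that caps the blocked plateau."""

    enabled: bool = True
    g_spike_ns: float = 60.0
    delta_t_mv: float = 1.5
    v_t_mv: float = -32.5
    v_cut_mv: float = 20.0
    v_peak_mv: float = 32.0
    v_reset_mv: float = -41.0
    t_ref_ms: float = 0.8
    adapt_inc_ns: float = 1.8
    adapt_tau_ms: float = 12.0
    avail_vhalf_mv: float = -45.0
    avail_slope_mv: float = 5.0
    avail_tau_ms: float = 500.0
    g_k_ns: float = 60.0
    k_vhalf_mv: float = -5.0
    k_slope_mv: float = 5.0
    e_k_mv: float = -95.0


@dataclass(frozen=True)
class SimParams:
    """Full parameter set for one model cell."""

    c_pf: float = 100.0
    g_leak_ns: float = 1.0
    e_leak_mv: float = -65.0
    g_h_ns: float = 0.0
    e_h_mv: float = -43.0
    h_vhalf_mv: float = -85.0
    h_slope_mv: float = 25.0
    h_taumax_ms: float = 250.0
    g_t_ns: float = 0.0
    t_gate: TGate = field(default_factory=TGate)
    g_kir_ns: float = 0.0
    kir_vhalf_mv: float = -115.0
    kir_slope_mv: float = 7.0
    e_k_mv: float = -95.0
    spike: SpikeParams = field(default_factory=SpikeParams)
    noise_pa: float = 2.0
    seed: int = 0
    dt_ms: float = 0.025

    def __post_init__(self) -> None:
        if self.c_pf <= 0 or self.g_leak_ns <= 0:
            raise DomainError("c_pf and g_leak_ns must be positive")
        if self.g_h_ns < 0 or self.g_t_ns < 0 or self.noise_pa < 0:
            raise DomainError("conductances and noise SD must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic recovery targets implied by a parameter set at the holding
    potential: small-signal passive resistance 1000/(g_L + g_h*m_h(V_hold)),
    the matching membrane time constant, and whether any sag is expected."""

    rn_true_mohm: float
    tau_true_ms: float
    sag_expected: bool


@dataclass(frozen=True)
class StepDesc:
    """Timing of a single square step, mirroring ProtocolSpec for one sweep."""

    amp: float
    step_on: float = 250.0
    step_off: float = 1250.0
    total_dur: float = 2500.0
    fs: float = 20000.0


# ---------------------------------------------------------------------------
# protocol factories


def fine_protocol() -> ProtocolSpec:
    """1,000-ms steps from -60 to +60 pA in 5 pA increments (25 sweeps)."""
    return ProtocolSpec("fine", tuple(float(a) for a in range(-60, 65, 5)))


def coarse_protocol() -> ProtocolSpec:
    """1,000-ms steps from -250 to +350 pA in 25 pA increments (25 sweeps)."""
    return ProtocolSpec("coarse", tuple(float(a) for a in range(-250, 375, 25)))


def tau_protocol(n_reps: int = 10) -> ProtocolSpec:
    """-10 pA, 1,000-ms step repeated (default 10x) for time-constant averaging."""
    return ProtocolSpec("tau", (-10.0,), n_reps=n_reps)


def rest_protocol(dur_ms: float = 1000.0) -> ProtocolSpec:
    """A single zero-current epoch used to read the resting potential."""
    return ProtocolSpec("rest", (0.0,), step_dur=dur_ms / 2, pre_dur=dur_ms / 4,
                        post_dur=dur_ms / 4)


# ---------------------------------------------------------------------------
# gating curves and steady state


def _sigmoid_down(v, vhalf, slope):
    """1 at very negative V, 0 at very positive V."""
    return 1.0 / (1.0 + np.exp((v - vhalf) / slope))


def _sigmoid_up(v, vhalf, slope):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / slope))


def m_h_inf(v, p: SimParams):
    """HCN steady-state activation (opens with hyperpolarization)."""
    return _sigmoid_down(v, p.h_vhalf_mv, p.h_slope_mv)


def tau_h(v, p: SimParams):
    """HCN activation time constant: bell-shaped, capped at h_taumax."""
    return p.h_taumax_ms / np.cosh((v - p.h_vhalf_mv) / (2.0 * p.h_slope_mv))


def t_m_inf(v, g: TGate):
    return _sigmoid_up(v, g.m_vhalf_mv, g.m_slope_mv)


def t_h_inf(v, g: TGate):
    return _sigmoid_down(v, g.h_vhalf_mv, g.h_slope_mv)


def t_tau_h(v, g: TGate):
    frac_slow = _sigmoid_down(v, g.tau_h_vhalf_mv, g.tau_h_slope_mv)
    return g.tau_h_fast_ms + (g.tau_h_slow_ms - g.tau_h_fast_ms) * frac_slow


def steady_state_current(v: float, p: SimParams) -> float:
    """Total ionic current at voltage ``v`` with all gates at steady state
    (spike and adaptation currents excluded).  The bias current that holds the
    cell at ``v`` equals this value."""
    g = p.t_gate
    i = p.g_leak_ns * (v - p.e_leak_mv)
    i += p.g_h_ns * m_h_inf(v, p) * (v - p.e_h_mv)
    i += p.g_t_ns * t_m_inf(v, g) ** 2 * t_h_inf(v, g) * (v - g.e_rev_mv)
    i += p.g_kir_ns * _sigmoid_down(v, p.kir_vhalf_mv, p.kir_slope_mv) * (v - p.e_k_mv)
    sp = p.spike
    if sp.enabled:
        i += sp.g_k_ns * _sigmoid_up(v, sp.k_vhalf_mv, sp.k_slope_mv) * (v - sp.e_k_mv)
    return float(i)


def solve_bias(p: SimParams, hold_mv: float) -> float:
    """Bias current (pA) that makes ``hold_mv`` the pre-step fixed point."""
    return steady_state_current(hold_mv, p)


def resting_potential(p: SimParams, bias_pa: float = 0.0,
                      bracket=(-130.0, -20.0), near_mv: float = -65.0) -> float:
    """Subthreshold fixed point for a given bias.

    The I-V curve can have several zeros when the T-type window current is
    strong; the root closest to ``near_mv`` is returned (that is the one an
    experimenter would call the resting/holding level)."""
    f = lambda v: steady_state_current(v, p) - bias_pa
    grid = np.arange(bracket[0], bracket[1] + 0.5, 0.5)
    vals = np.array([f(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)
    if sign_change.size == 0:
        raise NumericalError("no resting fixed point in bracket; check params")
    roots = [float(brentq(f, grid[k], grid[k + 1], xtol=1e-10))
             for k in sign_change]
    return min(roots, key=lambda r: abs(r - near_mv))


def ground_truth(p: SimParams, hold_mv: float = -65.0) -> GroundTruth:
    g_eff = p.g_leak_ns + p.g_h_ns * float(m_h_inf(hold_mv, p))
    return GroundTruth(
        rn_true_mohm=1000.0 / g_eff,
        tau_true_ms=p.c_pf / g_eff,
        sag_expected=p.g_h_ns > 0,
    )


# ---------------------------------------------------------------------------
# presets


def _solve_e_leak(p: SimParams, rest_target_mv: float) -> SimParams:
    """Adjust the leak reversal so the zero-bias fixed point hits the target."""

    def rest_given_el(el: float) -> float:
        return resting_potential(replace(p, e_leak_mv=el))

    el = brentq(lambda el: rest_given_el(el) - rest_target_mv, -120.0, -40.0,
                xtol=1e-9)
    return replace(p, e_leak_mv=float(el))


def md_m_preset(seed: int = 0) -> SimParams:
    """Medial-subnucleus-like cell: high input resistance, modest HCN."""
    p = SimParams(
        c_pf=90.0, g_leak_ns=0.65, g_h_ns=0.7, g_t_ns=300.0, g_kir_ns=3.5,
        h_taumax_ms=120.0, spike=SpikeParams(v_t_mv=-32.5),
        seed=seed,
    )
    return _solve_e_leak(p, -61.0)


def md_l_preset(seed: int = 0) -> SimParams:
    """Lateral-subnucleus-like cell: lower input resistance, strong HCN."""
    p = SimParams(
        c_pf=140.0, g_leak_ns=0.9, g_h_ns=2.2, g_t_ns=400.0, g_kir_ns=3.5,
        h_taumax_ms=300.0, spike=SpikeParams(v_t_mv=-32.9),
        seed=seed,
    )
    return _solve_e_leak(p, -61.0)


def passive_preset(c_pf: float = 100.0, g_leak_ns: float = 2.0,
                   e_leak_mv: float = -65.0, seed: int = 0,
                   noise_pa: float = 0.0) -> SimParams:
    """Pure RC membrane: no HCN, no T current, spiking disabled."""
    return SimParams(
        c_pf=c_pf, g_leak_ns=g_leak_ns, e_leak_mv=e_leak_mv,
        g_h_ns=0.0, g_t_ns=0.0,
        spike=SpikeParams(enabled=False),
        noise_pa=noise_pa, seed=seed,
    )


def apply_zd7288(p: SimParams, block_frac: float = 1.0) -> SimParams:
    """HCN-channel block: scales g_h by (1 - block_frac), all else unchanged."""
    if not (0.0 <= block_frac <= 1.0):
        raise DomainError(f"block_frac must be in [0, 1], got {block_frac}")
    return replace(p, g_h_ns=p.g_h_ns * (1.0 - block_frac))


# ---------------------------------------------------------------------------
# batched integrator


def _noise_rngs(params: Sequence[SimParams], stream_keys: Sequence[int]):
    """One independent, reproducible generator per (cell seed, sweep key)."""
    return [
        np.random.default_rng(np.random.SeedSequence((int(p.seed), int(k))))
        for p, k in zip(params, stream_keys)
    ]


def _integrate_batch(
    params: Sequence[SimParams],
    amps: np.ndarray,
    biases: np.ndarray,
    step: StepDesc,
    stream_keys: Sequence[int],
    v_init: np.ndarray,
    gate_trace: Optional[dict] = None,
) -> np.ndarray:
    """Integrate ``len(params)`` independent sweeps in lockstep.

    All sweeps must share dt, timing and output rate (they may differ in cell
    parameters, amplitude and bias).  Returns the decimated voltage array of
    shape (n_sweeps, n_out).
    """
    n = len(params)
    dt = params[0].dt_ms
    if any(p.dt_ms != dt for p in params):
        raise DomainError("batched sweeps must share dt")
    if step.fs < 10000.0:
        raise DomainError("output sampling rate must be >= 10 kHz")
    dt_out = 1000.0 / step.fs
    decim = int(round(dt_out / dt))
    if abs(decim * dt - dt_out) > 1e-9:
        raise DomainError(f"1/fs must be an integer multiple of dt={dt} ms")

    n_out = int(round(step.total_dur / dt_out))
    n_steps = n_out * decim
    k_on = int(round(step.step_on / dt))
    k_off = int(round(step.step_off / dt))

    # parameter arrays
    arr = lambda f: np.array([f(p) for p in params], dtype=np.float64)
    c = arr(lambda p: p.c_pf)
    gl = arr(lambda p: p.g_leak_ns)
    el = arr(lambda p: p.e_leak_mv)
    gh = arr(lambda p: p.g_h_ns)
    eh = arr(lambda p: p.e_h_mv)
    h_vh = arr(lambda p: p.h_vhalf_mv)
    h_sl = arr(lambda p: p.h_slope_mv)
    h_tmax = arr(lambda p: p.h_taumax_ms)
    gt = arr(lambda p: p.g_t_ns)
    tm_vh = arr(lambda p: p.t_gate.m_vhalf_mv)
    tm_sl = arr(lambda p: p.t_gate.m_slope_mv)
    th_vh = arr(lambda p: p.t_gate.h_vhalf_mv)
    th_sl = arr(lambda p: p.t_gate.h_slope_mv)
    th_tau_slow = arr(lambda p: p.t_gate.tau_h_slow_ms)
    th_tau_fast = arr(lambda p: p.t_gate.tau_h_fast_ms)
    th_tau_vh = arr(lambda p: p.t_gate.tau_h_vhalf_mv)
    th_tau_sl = arr(lambda p: p.t_gate.tau_h_slope_mv)
    et = arr(lambda p: p.t_gate.e_rev_mv)
    t_depl = arr(lambda p: 1.0 - p.t_gate.spike_depletion)
    gkir = arr(lambda p: p.g_kir_ns)
    kir_vh = arr(lambda p: p.kir_vhalf_mv)
    kir_sl = arr(lambda p: p.kir_slope_mv)
    ek_cell = arr(lambda p: p.e_k_mv)
    noise_sd = arr(lambda p: p.noise_pa)

    spike_on = np.array([p.spike.enabled for p in params])
    sp = params[0].spike
    gsp = arr(lambda p: p.spike.g_spike_ns) * spike_on
    dT = arr(lambda p: p.spike.delta_t_mv)
    vT = arr(lambda p: p.spike.v_t_mv)
    v_cut = arr(lambda p: p.spike.v_cut_mv)
    v_peak = arr(lambda p: p.spike.v_peak_mv)
    v_reset = arr(lambda p: p.spike.v_reset_mv)
    ref_steps = np.array([max(1, int(round(p.spike.t_ref_ms / dt))) for p in params])
    peak_steps = max(1, int(round(0.05 / dt)))  # hold peak for 0.05 ms
    w_inc = arr(lambda p: p.spike.adapt_inc_ns)
    w_decay = np.exp(-dt / arr(lambda p: p.spike.adapt_tau_ms))
    s_vh = arr(lambda p: p.spike.avail_vhalf_mv)
    s_sl = arr(lambda p: p.spike.avail_slope_mv)
    s_alpha = -np.expm1(-dt / arr(lambda p: p.spike.avail_tau_ms))
    gk = arr(lambda p: p.spike.g_k_ns) * spike_on
    k_vh = arr(lambda p: p.spike.k_vhalf_mv)
    k_sl = arr(lambda p: p.spike.k_slope_mv)
    ek = arr(lambda p: p.spike.e_k_mv)

    amps = np.asarray(amps, dtype=np.float64)
    biases = np.asarray(biases, dtype=np.float64)

    # state
    v = np.array(v_init, dtype=np.float64).copy()
    m_h = 1.0 / (1.0 + np.exp((v - h_vh) / h_sl))
    h_t = 1.0 / (1.0 + np.exp((v - th_vh) / th_sl))
    s = 1.0 / (1.0 + np.exp((v - s_vh) / s_sl))
    w = np.zeros(n)
    # spike phase: >0 while pinned at peak, <0 while refractory, 0 active
    peak_timer = np.zeros(n, dtype=np.int64)
    ref_timer = np.zeros(n, dtype=np.int64)

    rngs = _noise_rngs(params, stream_keys)
    any_noise = bool(np.any(noise_sd > 0))
    any_gh = bool(np.any(gh > 0))
    any_gt = bool(np.any(gt > 0))
    any_kir = bool(np.any(gkir > 0))
    any_spike = bool(np.any(spike_on))

    out = np.empty((n, n_out))
    chunk = 20000
    exp = np.exp
    max_exp_arg = 30.0  # caps the spike current to avoid overflow before reset

    k = 0
    while k < n_steps:
        m = min(chunk, n_steps - k)
        if any_noise:
            noise = np.empty((n, m))
            for j, rng in enumerate(rngs):
                if noise_sd[j] > 0:
                    noise[j] = rng.standard_normal(m) * noise_sd[j]
                else:
                    noise[j] = 0.0
        for kk in range(m):
            step_idx = k + kk
            i_inj = biases + amps * (k_on <= step_idx < k_off)

            # gates (exponential Euler; gates follow V even while pinned)
            i_ion = gl * (v - el)
            if any_kir:
                i_ion += gkir / (1.0 + exp((v - kir_vh) / kir_sl)) * (v - ek_cell)
            if any_gh:
                mh_inf = 1.0 / (1.0 + exp((v - h_vh) / h_sl))
                tauh = h_tmax / np.cosh((v - h_vh) / (2.0 * h_sl))
                m_h += (mh_inf - m_h) * -np.expm1(-dt / tauh)
                i_ion += gh * m_h * (v - eh)
            if any_gt:
                ht_inf = 1.0 / (1.0 + exp((v - th_vh) / th_sl))
                frac_slow = 1.0 / (1.0 + exp((v - th_tau_vh) / th_tau_sl))
                taut = th_tau_fast + (th_tau_slow - th_tau_fast) * frac_slow
                h_t += (ht_inf - h_t) * -np.expm1(-dt / taut)
                mt = 1.0 / (1.0 + exp(-(v - tm_vh) / tm_sl))
                i_ion += gt * mt * mt * h_t * (v - et)

            dv_scale = dt / c
            if any_spike:
                s_inf = 1.0 / (1.0 + exp((v - s_vh) / s_sl))
                s += (s_inf - s) * s_alpha
                w *= w_decay
                i_ion += gk / (1.0 + exp(-(v - k_vh) / k_sl)) * (v - ek)
                i_spk = gsp * s * dT * exp(np.minimum((v - vT) / dT, max_exp_arg))
                i_ion += w * (v - ek)   # spike-triggered adaptation conductance
                dv = dv_scale * (-i_ion + i_spk + i_inj)
            else:
                dv = dv_scale * (i_inj - i_ion)
            if any_noise:
                dv += dv_scale * noise[:, kk]

            if any_spike:
                active = (peak_timer == 0) & (ref_timer == 0)
                v = np.where(active, v + dv, v)

                # spike initiation
                fired = active & spike_on & (v >= v_cut)
                if fired.any():
                    v = np.where(fired, v_peak, v)
                    peak_timer = np.where(fired, peak_steps, peak_timer)
                    w = np.where(fired, w + w_inc, w)
                    # cumulative T-channel inactivation during each spike
                    h_t = np.where(fired, h_t * t_depl, h_t)

            else:
                v = v + dv

            if (step_idx + 1) % decim == 0:
                out[:, (step_idx + 1) // decim - 1] = v
                if gate_trace is not None:
                    j = (step_idx + 1) // decim - 1
                    gate_trace.setdefault("h_t", np.empty((n, n_out)))[:, j] = h_t
                    gate_trace.setdefault("m_h", np.empty((n, n_out)))[:, j] = m_h
                    gate_trace.setdefault("s", np.empty((n, n_out)))[:, j] = s
                    gate_trace.setdefault("w", np.empty((n, n_out)))[:, j] = w

            if any_spike:
                # end-of-peak reset and refractory countdown (after the
                # output sample is taken, so peaks are never overwritten)
                ending_peak = peak_timer == 1
                peak_timer = np.maximum(peak_timer - 1, 0)
                if ending_peak.any():
                    v = np.where(ending_peak, v_reset, v)
                    ref_timer = np.where(ending_peak, ref_steps, ref_timer)
                ref_timer = np.maximum(ref_timer - 1, 0)
        # instability guard: out-of-range voltage outside the pinned phase
        bad = ((v > 100.0) | (v < -160.0)) & (peak_timer == 0)
        if bad.any():
            raise NumericalError(
                f"integration instability (|V|>100 mV between spikes) at "
                f"dt={dt} ms"
            )
        k += m

    return out


# ---------------------------------------------------------------------------
# public simulation API


def _make_sweep(sweep_id: str, v: np.ndarray, amp: float, bias: float,
                step: StepDesc) -> Sweep:
    dt_out = 1000.0 / step.fs
    n_out = v.size
    t = np.arange(n_out) * dt_out
    i = np.full(n_out, bias)
    inside = (t >= step.step_on) & (t < step.step_off)
    i[inside] += amp
    return Sweep(
        sweep_id=sweep_id, t=t, v=v, i=i, fs=step.fs,
        step_on=step.step_on, step_off=step.step_off, amp=amp,
    )


def simulate_sweep(p: SimParams, step: StepDesc, bias_pa: float = 0.0,
                   stream_key: int = 0, sweep_id: str = "sw0") -> Sweep:
    """Simulate one square-step sweep.  Deterministic given (params, step,
    seed, stream_key); the pre-step state is the fixed point for the bias."""
    v0 = resting_potential(p, bias_pa)
    v = _integrate_batch([p], np.array([step.amp]), np.array([bias_pa]), step,
                         [stream_key], np.array([v0]))[0]
    return _make_sweep(sweep_id, v, step.amp, bias_pa, step)


def simulate_protocol(p: SimParams, spec: ProtocolSpec,
                      hold_mv: Optional[float] = -65.0,
                      cell_id: str = "cell0", group: str = "",
                      condition: str = "baseline") -> Recording:
    """Simulate a whole protocol for one cell, holding the pre-step voltage
    at ``hold_mv`` (bias auto-solved) or at rest if ``hold_mv`` is None."""
    return simulate_population_protocol(
        [p], spec, hold_mv=hold_mv, cell_ids=[cell_id], group=group,
        condition=condition,
    )[0]


def simulate_population_protocol(
    params: Sequence[SimParams],
    spec: ProtocolSpec,
    hold_mv: Optional[float] = -65.0,
    cell_ids: Optional[Sequence[str]] = None,
    group: str = "",
    condition: str = "baseline",
) -> list[Recording]:
    """Simulate one protocol for many cells in a single batched integration.

    Sweeps are emitted in ascending-amplitude order; per-sweep noise streams
    are keyed by (cell seed, amplitude index, repetition) so the same sweep is
    bit-identical whether simulated alone or in a batch.
    """
    params = list(params)
    n_cells = len(params)
    if cell_ids is None:
        cell_ids = [f"cell{j}" for j in range(n_cells)]
    amps_sorted = sorted(spec.amps)
    step = StepDesc(amp=0.0, step_on=spec.step_on, step_off=spec.step_off,
                    total_dur=spec.total_dur)

    flat_params: list[SimParams] = []
    flat_amps: list[float] = []
    flat_bias: list[float] = []
    flat_keys: list[int] = []
    flat_v0: list[float] = []
    for j, p in enumerate(params):
        if hold_mv is None:
            bias = 0.0
            v0 = resting_potential(p, bias)
        else:
            bias = solve_bias(p, hold_mv)
            v0 = hold_mv
        for a_idx, amp in enumerate(amps_sorted):
            for rep in range(spec.n_reps):
                flat_params.append(p)
                flat_amps.append(amp)
                flat_bias.append(bias)
                flat_keys.append(a_idx * spec.n_reps + rep)
                flat_v0.append(v0)

    v_out = _integrate_batch(
        flat_params, np.array(flat_amps), np.array(flat_bias), step,
        flat_keys, np.array(flat_v0),
    )

    recs: list[Recording] = []
    per_cell = len(amps_sorted) * spec.n_reps
    for j, p in enumerate(params):
        sweeps = []
        for local in range(per_cell):
            idx = j * per_cell + local
            a_idx, rep = divmod(local, spec.n_reps)
            sid = f"{spec.name}_{local:03d}"
            sweeps.append(_make_sweep(sid, v_out[idx], flat_amps[idx],
                                      flat_bias[idx], step))
        rec = Recording(
            cell_id=str(cell_ids[j]), sweeps=sweeps,
            holding_mv=hold_mv, group=group, condition=condition,
            protocol=spec.name,
        )
        rec.validate()
        recs.append(rec)
    return recs


# ---------------------------------------------------------------------------
# populations


def make_population(
    preset: str,
    n: int,
    cv: float = 0.2,
    seed: int = 0,
) -> list[tuple[SimParams, GroundTruth]]:
    """Draw ``n`` cells around a named preset ("MD-M-like" | "MD-L-like").

    Between-cell variability combines a shared lognormal cell-size factor
    (scaling all conductances and the capacitance together, so the time
    constant varies less than the resistance, as in real populations) with
    smaller independent lognormal jitter per parameter, plus a small normal
    jitter on the leak reversal so resting potentials spread realistically.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0.0 <= cv <= 0.5):
        raise DomainError("cv must be in [0, 0.5]")
    key = preset.lower().replace("_", "-")
    if key in ("md-m", "md-m-like"):
        base = md_m_preset()
    elif key in ("md-l", "md-l-like"):
        base = md_l_preset()
    else:
        raise DomainError(f"unknown preset {preset!r}")

    rng = np.random.default_rng(seed)
    out: list[tuple[SimParams, GroundTruth]] = []
    sig_size = math.sqrt(math.log(1.0 + cv**2))
    sig_ind = math.sqrt(math.log(1.0 + (cv / 2.0) ** 2))
    for j in range(n):
        size = rng.lognormal(0.0, sig_size) if cv > 0 else 1.0
        jit = lambda: rng.lognormal(0.0, sig_ind) if cv > 0 else 1.0
        rest_target = -61.0 + (rng.normal(0.0, 1.2) if cv > 0 else 0.0)
        d_vt = rng.normal(0.0, 1.5) if cv > 0 else 0.0
        cell_seed = int(rng.integers(2**31))
        p = replace(
            base,
            c_pf=base.c_pf * size * jit(),
            g_leak_ns=base.g_leak_ns * size * jit(),
            g_h_ns=base.g_h_ns * size * jit(),
            g_t_ns=base.g_t_ns * size * jit(),
            spike=replace(base.spike, v_t_mv=base.spike.v_t_mv + d_vt),
            seed=cell_seed,
        )
        # pin each cell's zero-bias rest to its own target so resting
        # potential spreads realistically but identically in every preset
        p = _solve_e_leak(p, rest_target)
        out.append((p, ground_truth(p)))
    return out
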