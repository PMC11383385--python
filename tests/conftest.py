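"""Shared fixtures: analytically constructed sweeps and small simulated cells."""

import numpy as np
import pytest

from mdephys.types import ProtocolSpec, Recording, Sweep


def make_step_sweep(v_fn, amp, fs=20000.0, step_on=250.0, step_off=1250.0,
                    total=2500.0, bias=0.0, sweep_id="sw0"):
    """Sweep whose voltage is ``v_fn(t)`` (vectorized, t in ms) under a
    square current step."""
    dt = 1000.0 / fs
    t = np.arange(int(round(total / dt))) * dt
    v = np.asarray(v_fn(t), dtype=float)
    i = np.full(t.size, bias)
    i[(t >= step_on) & (t < step_off)] += amp
    return Sweep(sweep_id=sweep_id, t=t, v=v, i=i, fs=fs,
                 step_on=step_on, step_off=step_off, amp=amp)


def rc_response(amp_pa, r_gohm, tau_ms, v_rest=-65.0,
                step_on=250.0, step_off=1250.0):
    """Analytic passive RC voltage response to a square step (mV)."""
    dv = amp_pa * r_gohm

    def v_fn(t):
        v = np.full(t.size, v_rest, dtype=float)
        rise = (t >= step_on) & (t < step_off)
        v[rise] += dv * (1.0 - np.exp(-(t[rise] - step_on) / tau_ms))
        decay = t >= step_off
        v_off = dv * (1.0 - np.exp(-(step_off - step_on) / tau_ms))
        v[decay] += v_off * np.exp(-(t[decay] - step_off) / tau_ms)
        return v

    return v_fn


def spike_template(dt_ms, peak_mv=30.0, base_mv=-60.0, rise_ms=0.5, fall_ms=0.8):
    """A small triangular action-potential template sampled at dt."""
    n_up = max(2, int(round(rise_ms / dt_ms)))
    n_dn = max(2, int(round(fall_ms / dt_ms)))
    up = np.linspace(base_mv, peak_mv, n_up, endpoint=False)
    dn = np.linspace(peak_mv, base_mv, n_dn + 1)
    return np.concatenate([up, dn])


def trace_with_spikes(spike_times_ms, amp=50.0, fs=20000.0, base_mv=-60.0,
                      step_on=250.0, step_off=1250.0, total=2500.0):
    """Sweep holding ``base_mv`` with AP templates pasted at given peak times."""
    dt = 1000.0 / fs
    n = int(round(total / dt))
    v = np.full(n, base_mv)
    tmpl = spike_template(dt, base_mv=base_mv)
    k_peak = int(np.argmax(tmpl))
    for st in spike_times_ms:
        k = int(round(st / dt)) - k_peak
        if k < 0 or k + tmpl.size > n:
            raise ValueError("spike template out of range")
        v[k:k + tmpl.size] = np.maximum(v[k:k + tmpl.size], tmpl)
    t = np.arange(n) * dt
    i = np.zeros(n)
    i[(t >= step_on) & (t < step_off)] += amp
    return Sweep(sweep_id="spiky", t=t, v=v, i=i, fs=fs,
                 step_on=step_on, step_off=step_off, amp=amp)


@pytest.fixture(scope="session")
def passive_cell():
    from mdephys import synth

    return synth.passive_preset(c_pf=100.0, g_leak_ns=2.0, seed=11)


@pytest.fixture(scope="session")
def md_m_cell():
    import dataclasses

    from mdephys import synth

    return dataclasses.replace(synth.md_m_preset(seed=3), noise_pa=0.0)


@pytest.fixture(scope="session")
def md_l_cell():
    import dataclasses

    from mdephys import synth

    return dataclasses.replace(synth.md_l_preset(seed=4), noise_pa=0.0)
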