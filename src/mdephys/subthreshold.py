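"""Subthreshold intrinsic-property estimators.

All estimators work on :class:`~mdephys.types.Sweep` / ``Recording`` objects
and follow fixed window conventions: resistance uses the mean of the last
100 ms of the step as the steady state, sag uses the mean of the last 25 ms,
the afterhyperpolarization is the minimum over a 250 ms (configurable)
post-offset window, and the time constant is the post-offset 1/e relaxation
time of the averaged -10 pA response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import AlignmentError, ContaminationError, DomainError, WindowError
from .spikes import detect_spikes
from .types import Recording, Sweep

#: steady-state window for the V-I resistance fit (ms before step offset)
RN_SS_WINDOW_MS = 100.0
#: steady-state window for sag (ms before step offset)
SAG_SS_WINDOW_MS = 25.0
#: default post-offset window for the afterhyperpolarization (ms)
AHP_WINDOW_MS = 250.0
#: default baseline window for the resting potential (ms from sweep start)
RMP_WINDOW_MS = 100.0


@dataclass(frozen=True)
class SagMeasure:
    """Voltage sag of one hyperpolarizing sweep: minimum during the step
    minus the mean of the last 25 ms of the step (<= 0 for sagging cells)."""

    peak_mv: float
    steady_mv: float
    sag_mv: float
    amp_pa: float
    peak_ok: bool = True   # set by sag_at_peak_target when near the target


@dataclass(frozen=True)
class VICurvePoint:
    amp_pa: float
    v_ss_mv: float
    has_spikes: bool


def estimate_rmp(rec: Recording, window_ms: float = RMP_WINDOW_MS) -> Optional[float]:
    """Resting membrane potential: mean voltage over the first ``window_ms``
    of the first zero-bias sweep.  Returns None when no zero-bias segment
    exists (the cell was biased throughout)."""
    for s in rec.sweeps:
        if abs(s.baseline_pa) < 0.5 and s.step_on >= 1e-9:
            seg = s.v[s.t < min(window_ms, s.step_on)]
            if seg.size:
                return float(np.mean(seg))
        if abs(s.baseline_pa) < 0.5 and abs(s.amp) < 1e-9:
            seg = s.v[s.t < window_ms]
            if seg.size:
                return float(np.mean(seg))
    return None


def estimate_time_constant(rec: Recording, mode: str = "onset") -> Optional[float]:
    """Membrane time constant from the averaged -10 pA response.

    The repetitions are averaged point-wise and the 1/e relaxation is timed
    at the chosen step edge.  The default is the onset charging (time until
    the deflection reaches 1 - 1/e of its steady value), which is guaranteed
    spike-free for a hyperpolarizing step; ``mode="offset"`` instead times
    the post-offset decay back to baseline, which is only valid for cells
    that do not fire rebound spikes at -10 pA.  Linear interpolation between
    samples; returns None when the crossing never occurs inside the window.
    """
    sweeps = [s for s in rec.sweeps if abs(s.amp + 10.0) < 1e-6]
    if len(sweeps) < 2:
        sweeps = [s for s in rec.sweeps if s.amp < 0]
    if len(sweeps) < 2:
        raise DomainError("time constant needs >= 2 repetitions of the -10 pA step")
    ref = sweeps[0]
    v_avg = np.mean([s.v for s in sweeps], axis=0)
    avg = Sweep("tau_avg", ref.t, v_avg, ref.i, ref.fs, ref.step_on,
                ref.step_off, ref.amp)
    spikes = detect_spikes(avg)
    if mode == "onset":
        spikes = spikes[spikes < ref.step_off]   # rebound firing is tolerable
    if spikes.size:
        raise ContaminationError("spikes detected in averaged trace")

    if mode == "offset":
        base = float(np.mean(v_avg[avg.mask(ref.step_off - RN_SS_WINDOW_MS,
                                            ref.step_off)]))
        # relaxation from the steady in-step level back to the pre-step level
        target_base = float(np.mean(v_avg[ref.t < ref.step_on]))
        t0 = ref.step_off
        seg = ref.t >= ref.step_off
    elif mode == "onset":
        target_base = float(np.mean(v_avg[ref.t < ref.step_on]))
        t0 = ref.step_on
        seg = ref.t >= ref.step_on
    else:
        raise DomainError(f"unknown tau mode {mode!r}")

    t_seg = ref.t[seg]
    d = v_avg[seg] - target_base
    if mode == "onset":
        # deflection grows toward the steady level; time to 1 - 1/e of final
        final = float(np.mean(v_avg[avg.mask(ref.step_off - RN_SS_WINDOW_MS,
                                             ref.step_off)])) - target_base
        crossing = np.abs(d) >= abs(final) * (1.0 - 1.0 / np.e)
    else:
        d0 = d[0]
        if abs(d0) < 1e-12:
            return None
        crossing = np.abs(d) <= abs(d0) / np.e
    idx = np.flatnonzero(crossing)
    idx = idx[idx > 0]
    if idx.size == 0:
        return None
    k = idx[0]
    if mode == "onset":
        y0, y1 = np.abs(d[k - 1]), np.abs(d[k])
        yc = abs(final) * (1.0 - 1.0 / np.e)
    else:
        y0, y1 = np.abs(d[k - 1]), np.abs(d[k])
        yc = abs(d[0]) / np.e
    frac = 0.0 if y1 == y0 else (y0 - yc) / (y0 - y1)
    t_cross = t_seg[k - 1] + frac * (t_seg[k] - t_seg[k - 1])
    return float(t_cross - t0)


def estimate_input_resistance(
    rec: Recording, ss_window_ms: float = RN_SS_WINDOW_MS
) -> tuple[Optional[float], list[VICurvePoint]]:
    """Input resistance as the OLS slope of subthreshold steady-state voltage
    vs injected current, in MOhm.  Sweeps with spikes during the step are
    flagged and excluded from the fit; returns (None, curve) when fewer than
    three usable sweeps remain."""
    curve: list[VICurvePoint] = []
    for s in rec.sweeps:
        spikes = detect_spikes(s)
        in_step = spikes[(spikes >= s.step_on) & (spikes < s.step_off)]
        v_ss = float(np.mean(s.v[s.mask(s.step_off - ss_window_ms, s.step_off)]))
        curve.append(VICurvePoint(s.amp, v_ss, bool(in_step.size)))
    usable = [p for p in curve if not p.has_spikes]
    if len(usable) < 3:
        return None, curve
    x = np.array([p.amp_pa for p in usable])
    y = np.array([p.v_ss_mv for p in usable])
    slope = np.polyfit(x, y, 1)[0]          # mV/pA == GOhm
    return float(slope * 1000.0), curve


def measure_sag(sweep: Sweep) -> SagMeasure:
    """Sag of one hyperpolarizing sweep (peak minus late-step steady state)."""
    if sweep.amp >= 0:
        raise DomainError("sag is defined on hyperpolarizing sweeps only")
    in_step = sweep.mask(sweep.step_on, sweep.step_off)
    peak = float(np.min(sweep.v[in_step]))
    steady = float(np.mean(sweep.v[sweep.mask(sweep.step_off - SAG_SS_WINDOW_MS,
                                              sweep.step_off)]))
    return SagMeasure(peak_mv=peak, steady_mv=steady, sag_mv=peak - steady,
                      amp_pa=sweep.amp)


def sag_at_peak_target(rec: Recording, target_mv: float = -100.0,
                       tol_mv: float = 5.0) -> SagMeasure:
    """Sag of the sweep whose peak hyperpolarization lands closest to the
    target voltage (default -100 mV).  ``peak_ok`` is False when no sweep
    peaks within ``tol_mv`` of the target."""
    hyper = [s for s in rec.sweeps if s.amp < 0]
    if not hyper:
        raise DomainError("no hyperpolarizing sweeps in recording")
    measures = [measure_sag(s) for s in hyper]
    best = min(measures, key=lambda m: abs(m.peak_mv - target_mv))
    ok = abs(best.peak_mv - target_mv) <= tol_mv
    return SagMeasure(best.peak_mv, best.steady_mv, best.sag_mv, best.amp_pa,
                      peak_ok=ok)


def measure_ahp(sweep: Sweep, window_ms: float = AHP_WINDOW_MS) -> tuple[float, float]:
    """Afterhyperpolarization of one depolarizing sweep: the minimum voltage
    in the ``window_ms`` after step offset, plus its latency from offset."""
    if sweep.amp <= 0:
        raise DomainError("AHP is measured after depolarizing steps")
    if sweep.step_off + window_ms > sweep.t[-1] + sweep.dt_ms:
        raise WindowError("AHP window extends past the end of the sweep")
    m = (sweep.t > sweep.step_off) & (sweep.t <= sweep.step_off + window_ms)
    seg_v = sweep.v[m]
    seg_t = sweep.t[m]
    k = int(np.argmin(seg_v))
    return float(seg_v[k]), float(seg_t[k] - sweep.step_off)


def ahp_minimum(rec: Recording, window_ms: float = AHP_WINDOW_MS) -> Optional[float]:
    """Per-recording AHP: the minimum post-offset voltage across all
    depolarizing sweeps (None when there are none)."""
    vals = [measure_ahp(s, window_ms)[0] for s in rec.sweeps if s.amp > 0]
    return min(vals) if vals else None


def measure_ahp_matched(pre_sweep: Sweep, post_sweep: Sweep,
                        window_ms: float = AHP_WINDOW_MS) -> tuple[float, float, float]:
    """Drug-condition AHP comparison at matched latency: the post-drug voltage
    is read at exactly the time point where the pre-drug AHP was maximal."""
    if (pre_sweep.step_on != post_sweep.step_on
            or pre_sweep.step_off != post_sweep.step_off
            or pre_sweep.fs != post_sweep.fs):
        raise AlignmentError("pre/post sweeps must share step timing and fs")
    pre_mv, t_match = measure_ahp(pre_sweep, window_ms)
    t_abs = post_sweep.step_off + t_match
    post_mv = float(np.interp(t_abs, post_sweep.t, post_sweep.v))
    return pre_mv, post_mv, t_match
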