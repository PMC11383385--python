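"""Spike detection, threshold criterion, and the ISI classification rules."""

import numpy as np
import pytest

from mdephys import spikes as sp
from mdephys.errors import DomainError
from mdephys.types import Recording, Sweep

from conftest import make_step_sweep, trace_with_spikes


# ---------------------------------------------------------------------------
# independent oracle: a literal, unoptimized transcription of the rules


def oracle_classify(times, amp, on, off, rules=sp.DEFAULT_RULES):
    """Literal rule evaluator, deliberately written without reference to the
    production implementation: every clause mirrors one sentence of the
    classification protocol."""
    times = list(times)
    n = len(times)
    labels = ["other"] * n

    if amp < 0:
        for k, t in enumerate(times):
            if off < t <= off + rules.rebound_window_ms:
                labels[k] = "rebound"
        return labels

    in_step = [on <= t < off for t in times]
    if sum(in_step) > rules.max_classifiable_spikes:
        return ["total" if s else "other" for s in in_step]

    def isi(k):
        return times[k] - times[k - 1] if k >= 1 else None

    def ratio(k):
        if k < 2:
            return None
        return isi(k) / isi(k - 1)

    # "the first spike to have an ISI ratio of >= 2 was classified as the
    # first tonic spike; the rest of the spikes ... were also tonic"
    first_tonic = None
    for k in range(n):
        r = ratio(k)
        if r is not None and r >= rules.tonic_isi_ratio_min:
            first_tonic = k
            break

    stop = n if first_tonic is None else first_tonic
    for k in range(stop):
        t = times[k]
        if not (on <= t <= on + rules.burst_onset_window_ms and t < off):
            continue
        gap = isi(k)
        if gap is None or gap >= rules.burst_isi_max_ms:
            continue
        r = ratio(k)
        if r is not None and not (rules.burst_isi_ratio_lo <= r
                                  <= rules.burst_isi_ratio_hi):
            continue
        labels[k] = "burst"
        # the spike that opens the burst counts as part of it
        prev_t = times[k - 1]
        if (labels[k - 1] == "other"
                and on <= prev_t <= on + rules.burst_onset_window_ms
                and prev_t < off):
            labels[k - 1] = "burst"
    if first_tonic is not None:
        for k in range(first_tonic, n):
            labels[k] = "tonic"
    return labels


def random_trains(n_trains, seed):
    """Mixture of uniform, bursty and composite spike trains with varied
    amplitudes, mimicking the range of firing patterns a step protocol
    produces."""
    rng = np.random.default_rng(seed)
    on, off = 250.0, 1250.0
    for _ in range(n_trains):
        kind = rng.integers(4)
        amp = float(rng.choice([-100, -25, 5, 25, 150, 350]))
        if kind == 0:  # sparse uniform
            n = int(rng.integers(0, 8))
            t = np.sort(rng.uniform(0.0, 2400.0, n))
        elif kind == 1:  # tonic-like regular train in the step
            n = int(rng.integers(2, 25))
            start = rng.uniform(on, on + 300)
            isi = rng.uniform(3.0, 80.0)
            t = start + np.arange(n) * isi * rng.uniform(0.8, 1.25, n).cumprod()
        elif kind == 2:  # burst then tonic
            b = rng.uniform(on, on + 400) + np.cumsum(
                rng.uniform(1.0, 5.0, int(rng.integers(2, 7))))
            tn = b[-1] + np.cumsum(rng.uniform(5.0, 120.0, int(rng.integers(0, 10))))
            t = np.concatenate([b, tn])
        else:  # rebound-like cluster after offset
            n = int(rng.integers(1, 8))
            t = off + rng.uniform(0.5, 1400.0, n)
            t = np.sort(t)
        t = np.unique(np.round(t, 3))
        t = t[(t > 0) & (t < 2500.0)]
        yield t, amp, on, off


class TestDetectSpikes:
    def test_subthreshold_sweep_empty(self):
        s = make_step_sweep(lambda t: np.full(t.size, -60.0) + np.sin(t / 50.0),
                            amp=20.0)
        assert sp.detect_spikes(s).size == 0

    def test_template_spikes_recovered(self):
        times = [300.0, 400.0, 405.0, 900.0, 1700.0]
        s = trace_with_spikes(times)
        found = sp.detect_spikes(s)
        assert found.size == 5
        assert np.all(np.abs(found - np.array(times)) <= s.dt_ms)

    def test_refractory_rule_keeps_higher_peak(self):
        dt = 0.05
        n = 10000
        v = np.full(n, -60.0)
        k1, k2 = 4000, 4008  # 0.4 ms apart
        v[k1 - 2:k1 + 3] = [-20, 10, 25, 10, -20]
        v[k2 - 2:k2 + 3] = [-15, 15, 30, 15, -15]  # higher
        t = np.arange(n) * dt
        i = np.zeros(n)
        s = Sweep("x", t, v, i, 20000.0, 100.0, 400.0, 0.0)
        found = sp.detect_spikes(s)
        assert found.size == 1
        assert found[0] == pytest.approx(k2 * dt)


class TestSpikeThreshold:
    @staticmethod
    def exponential_upstroke_sweep(delta_t=0.3, t0=500.0, a=0.5):
        """V(t) = base + a*exp((t-t0)/delta_t): the third derivative is
        (a/delta_t^3)*exp((t-t0)/delta_t), known in closed form."""
        fs = 20000.0
        dt = 1000.0 / fs
        n = 12000
        t = np.arange(n) * dt
        base = -65.0
        v = base + a * np.exp((t - t0) / delta_t)
        v = np.minimum(v, 30.0)  # clip into a flat peak
        i = np.zeros(n)
        i[(t >= 250.0) & (t < 550.0)] = 50.0
        return Sweep("exp", t, v, i, fs, 250.0, 550.0, 50.0)

    def test_matches_analytic_third_derivative(self):
        delta_t, a = 0.3, 0.5
        s = self.exponential_upstroke_sweep(delta_t=delta_t, a=a)
        peak_t = s.t[np.argmax(s.v)]
        v_th, t_th, fb = sp.spike_threshold(s, float(peak_t), cutoff=0.3,
                                            smooth_ms=0.0)
        assert not fb
        # analytic: d3V/dt3 = (a/dT^3) exp((t-t0)/dT) crosses 0.3 at
        # t* = t0 + dT*ln(0.3*dT^3/a)
        t_star = 500.0 + delta_t * np.log(0.3 * delta_t**3 / a)
        assert abs(t_th - t_star) <= 0.3  # within finite-difference error
        assert v_th == pytest.approx(-65.0 + a * np.exp((t_star - 500.0) / delta_t),
                                     abs=1.5)

    def test_halving_cutoff_gives_earlier_threshold(self):
        s = self.exponential_upstroke_sweep()
        peak_t = float(s.t[np.argmax(s.v)])
        v1, t1, _ = sp.spike_threshold(s, peak_t, cutoff=0.3, smooth_ms=0.0)
        v2, t2, _ = sp.spike_threshold(s, peak_t, cutoff=0.15, smooth_ms=0.0)
        assert t2 < t1
        assert v2 < v1


class TestClassifier:
    def test_worked_burst_then_tonic_example(self):
        # onset-relative times {5,7,9,120,260,420,600}: three-spike burst
        # (ratio at the 4th spike is 111/2 >= 2, opening the tonic phase)
        times = 250.0 + np.array([5, 7, 9, 120, 260, 420, 600.0])
        cs = sp.classify_step_spikes(times, 50.0, 250.0, 1250.0)
        assert cs.label == ["burst", "burst", "burst",
                            "tonic", "tonic", "tonic", "tonic"]

    def test_total_gate(self):
        times = 250.0 + np.linspace(5, 900, 22)
        cs = sp.classify_step_spikes(times, 300.0, 250.0, 1250.0)
        assert cs.label == ["total"] * 22

    def test_rebound_window(self):
        times = np.array([1270.0, 1274.0, 2249.0, 2251.0])
        cs = sp.classify_step_spikes(times, -100.0, 250.0, 1250.0)
        assert cs.label == ["rebound", "rebound", "rebound", "other"]

    def test_two_spike_burst_admitted_without_ratio(self):
        times = 250.0 + np.array([10.0, 12.5])
        cs = sp.classify_step_spikes(times, 20.0, 250.0, 1250.0)
        assert cs.label == ["burst", "burst"]

    def test_unsorted_input_rejected(self):
        with pytest.raises(DomainError):
            sp.classify_step_spikes(np.array([300.0, 280.0]), 50.0, 250.0, 1250.0)

    def test_every_spike_gets_exactly_one_label(self):
        for times, amp, on, off in random_trains(300, seed=5):
            cs = sp.classify_step_spikes(times, amp, on, off)
            assert len(cs.label) == times.size
            assert all(lab in ("burst", "tonic", "rebound", "total", "other")
                       for lab in cs.label)

    def test_matches_literal_oracle(self):
        """Spike-for-spike agreement with the independent transcription of
        the classification rules on randomized trains."""
        for times, amp, on, off in random_trains(500, seed=17):
            got = sp.classify_step_spikes(times, amp, on, off).label
            want = oracle_classify(times, amp, on, off)
            assert got == want, (times, amp)


def recording_from_trains(trains):
    """Recording whose sweeps carry template spikes at prescribed times."""
    sweeps = []
    for j, (amp, times) in enumerate(trains):
        s = trace_with_spikes(times, amp=amp)
        s.sweep_id = f"s{j}"
        sweeps.append(s)
    return Recording("synthetic", sweeps, holding_mv=-65.0)


class TestRheobaseAndFI:
    def make_rec(self):
        on = 250.0
        return recording_from_trains([
            (-20.0, []),
            (-10.0, [1270.0, 1273.0, 1276.0]),       # rebound burst
            (-5.0, [1300.0]),                          # single rebound spike
            (5.0, []),
            (10.0, [on + 5, on + 7]),                  # 2-spike burst
            (15.0, [on + 5, on + 7, on + 9, on + 120, on + 260, on + 420]),
            (20.0, [on + t for t in
                    [5, 7, 9, 40, 80, 130, 190, 260, 340, 430, 530, 640,
                     760, 890]]),                      # burst + 11 tonic
        ])

    def test_rheobase_per_mode(self):
        rec = self.make_rec()
        cls = sp.classify_recording(rec, with_thresholds=False)
        rt = sp.rheobase(rec, "tonic", cls)
        rb = sp.rheobase(rec, "burst_depol", cls)
        rr = sp.rheobase(rec, "rebound", cls)
        assert rb.amp_pa == 10.0
        assert rt.amp_pa == 15.0
        # -5 pA has only a single rebound spike: not a burst
        assert rr.amp_pa == -10.0
        assert rr.steady_state_mv is not None

    def test_missing_class_flagged(self):
        rec = recording_from_trains([(5.0, []), (-5.0, [])])
        assert sp.rheobase(rec, "rebound",
                           sp.classify_recording(rec, with_thresholds=False)) is None

    def test_fi_inclusion_rules(self):
        rec = self.make_rec()
        fic = sp.fi_curve(rec)
        amps, tonic = fic.series("tonic")
        assert amps.size == len(rec.sweeps)          # zero-count sweeps stay
        bamps, bcounts = fic.series("burst")
        assert np.all(bcounts > 0)                    # burstless sweeps drop

    def test_subthreshold_recording(self):
        rec = recording_from_trains([(5.0, []), (10.0, [])])
        fic = sp.fi_curve(rec)
        assert np.all(fic.counts["tonic"] == 0)
        assert fic.series("burst")[0].size == 0


class TestAccommodation:
    def on_times_from_isis(self, isis, start=300.0):
        return list(start + np.cumsum(np.concatenate([[0.0], isis])))

    def test_exact_linear_isi_growth(self):
        # a burst opens the sweep, then 13 tonic spikes with ISIs 10,12,...
        on = 250.0
        isis = np.arange(10.0, 34.0, 2.0)  # 12 intervals
        tonic = self.on_times_from_isis(isis, start=on + 100.0)
        times = [on + 5, on + 7] + tonic
        rec = recording_from_trains([(50.0, times)])
        res = sp.accommodation_index(rec)
        assert res is not None
        slope, amp = res
        assert slope == pytest.approx(2.0, abs=1e-9)
        assert amp == 50.0

    def test_constant_isis_give_zero_slope(self):
        on = 250.0
        tonic = self.on_times_from_isis(np.full(12, 20.0), start=on + 100.0)
        rec = recording_from_trains([(50.0, [on + 5, on + 7] + tonic)])
        slope, _ = sp.accommodation_index(rec)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_lowest_amplitude_sweep_selected(self):
        on = 250.0
        tonic = self.on_times_from_isis(np.full(12, 20.0), start=on + 100.0)
        train = [on + 5, on + 7] + tonic
        rec = recording_from_trains([(200.0, train), (150.0, train)])
        _, amp = sp.accommodation_index(rec)
        assert amp == 150.0

    def test_no_qualifying_sweep(self):
        rec = recording_from_trains([(50.0, [250.0 + 5, 250.0 + 7])])
        assert sp.accommodation_index(rec) is None
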