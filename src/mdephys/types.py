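"""Core domain types for episodic current-clamp data.

Units are fixed package-wide: time in ms, voltage in mV, current in pA,
resistance in MOhm, conductance in nS, capacitance in pF.  With these units
R[MOhm] = 1000 / g[nS] and tau[ms] = C[pF] / g[nS].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError

#: relative jitter tolerance on the uniform time base (parts per million)
TIME_JITTER_PPM = 1.0
#: absolute tolerance on the command-current step shape (pA)
CURRENT_TOL_PA = 1e-6
#: acceptable holding-potential band for held protocols (mV)
HOLDING_BAND_MV = (-68.0, -62.0)


@dataclass
class Sweep:
    """One stimulus episode: a square current step and the voltage response.

    ``i`` must equal a constant baseline outside ``[step_on, step_off)`` and
    ``baseline + amp`` inside it.  The baseline carries any holding bias, so
    the bias is always recoverable from the command trace itself.
    """

    sweep_id: str
    t: np.ndarray        # ms, uniform, starting at 0
    v: np.ndarray        # mV
    i: np.ndarray        # pA (command current, noise-free)
    fs: float            # Hz
    step_on: float       # ms
    step_off: float      # ms
    amp: float           # pA

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.i = np.asarray(self.i, dtype=np.float64)

    # -- derived quantities -------------------------------------------------

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1]) + self.dt_ms

    @property
    def baseline_pa(self) -> float:
        """Holding bias current (command level outside the step)."""
        pre = self.i[self.t < self.step_on]
        if pre.size == 0:
            pre = self.i[self.t >= self.step_off]
        return float(pre[0])

    def mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean mask selecting samples with ``lo_ms <= t < hi_ms``."""
        return (self.t >= lo_ms) & (self.t < hi_ms)

    def validate(self) -> None:
        n = self.t.size
        if not (self.v.size == n and self.i.size == n):
            raise ValidationError(
                f"sweep {self.sweep_id}: t/v/i lengths differ "
                f"({n}/{self.v.size}/{self.i.size})"
            )
        if n < 2:
            raise ValidationError(f"sweep {self.sweep_id}: too few samples")
        dt = np.diff(self.t)
        nominal = 1000.0 / self.fs
        if np.any(dt <= 0):
            raise ValidationError(f"sweep {self.sweep_id}: time not increasing")
        if np.max(np.abs(dt - nominal)) > nominal * TIME_JITTER_PPM * 1e-6:
            raise ValidationError(
                f"sweep {self.sweep_id}: time base jitter exceeds "
                f"{TIME_JITTER_PPM} ppm of 1/fs"
            )
        if not (self.step_on < self.step_off <= self.t[-1] + nominal):
            raise ValidationError(
                f"sweep {self.sweep_id}: step [{self.step_on}, {self.step_off}) "
                "outside the recorded window"
            )
        inside = (self.t >= self.step_on) & (self.t < self.step_off)
        base = self.baseline_pa
        if np.any(np.abs(self.i[~inside] - base) > CURRENT_TOL_PA):
            raise ValidationError(
                f"sweep {self.sweep_id}: command not constant outside the step"
            )
        if np.any(np.abs(self.i[inside] - (base + self.amp)) > CURRENT_TOL_PA):
            raise ValidationError(
                f"sweep {self.sweep_id}: in-step command != baseline + amp"
            )


@dataclass
class Recording:
    """Ordered sweeps from one cell plus acquisition metadata."""

    cell_id: str
    sweeps: list[Sweep]
    holding_mv: Optional[float] = None   # None => recorded at rest, no bias
    group: str = ""                      # e.g. "MD-M" | "MD-L"
    condition: str = "baseline"          # baseline | ZD7288 | custom
    protocol: str = "custom"             # fine | coarse | tau | rest | custom
    ljp_mv: Optional[float] = None       # informational only, never applied

    def __post_init__(self) -> None:
        self.sweeps = list(self.sweeps)

    @property
    def fs(self) -> float:
        return self.sweeps[0].fs

    @property
    def amps(self) -> np.ndarray:
        return np.array([s.amp for s in self.sweeps])

    def sort_by_amp(self) -> None:
        """Stable ascending-amplitude order (ties keep input order)."""
        self.sweeps.sort(key=lambda s: (s.amp, s.sweep_id))

    def validate(self) -> None:
        if not self.sweeps:
            raise ValidationError(f"recording {self.cell_id}: no sweeps")
        for s in self.sweeps:
            s.validate()
        ref = self.sweeps[0]
        for s in self.sweeps[1:]:
            if s.fs != ref.fs or s.step_on != ref.step_on or s.step_off != ref.step_off:
                raise ValidationError(
                    f"recording {self.cell_id}: sweeps disagree on fs or step timing"
                )
        if self.holding_mv is not None:
            lo, hi = HOLDING_BAND_MV
            if not (lo <= self.holding_mv <= hi):
                raise ValidationError(
                    f"recording {self.cell_id}: holding {self.holding_mv} mV "
                    f"outside [{lo}, {hi}] mV"
                )


@dataclass(frozen=True)
class ProtocolSpec:
    """A family of square current steps delivered from a common holding level."""

    name: str
    amps: tuple[float, ...]
    step_dur: float = 1000.0   # ms
    pre_dur: float = 250.0     # ms
    post_dur: float = 1250.0   # ms
    n_reps: int = 1

    def __post_init__(self) -> None:
        if not self.amps:
            raise ValidationError("protocol needs at least one amplitude")
        if self.step_dur <= 0 or self.pre_dur < 0 or self.post_dur < 0:
            raise ValidationError("protocol durations must be positive")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")

    @property
    def step_on(self) -> float:
        return self.pre_dur

    @property
    def step_off(self) -> float:
        return self.pre_dur + self.step_dur

    @property
    def total_dur(self) -> float:
        return self.pre_dur + self.step_dur + self.post_dur


# spike class labels
SPIKE_LABELS = ("burst", "tonic", "rebound", "total", "other")


@dataclass
class ClassifiedSpikes:
    """Per-spike times, thresholds and class labels for one sweep."""

    spike_t: np.ndarray               # peak times, ms
    label: list[str]                  # one of SPIKE_LABELS per spike
    thresh_v: Optional[np.ndarray] = None
    thresh_t: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.spike_t = np.asarray(self.spike_t, dtype=np.float64)
        if len(self.label) != self.spike_t.size:
            raise ValidationError("one label per spike required")
        if np.any(np.diff(self.spike_t) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        for lab in self.label:
            if lab not in SPIKE_LABELS:
                raise ValidationError(f"unknown spike label {lab!r}")

    @property
    def isi(self) -> np.ndarray:
        """Interspike intervals; isi[k] = spike_t[k+1] - spike_t[k]."""
        return np.diff(self.spike_t)

    @property
    def isi_ratio(self) -> np.ndarray:
        """Ratio of each ISI to the previous one, aligned to spikes.

        Entry ``k`` is ISI(k-1,k)/ISI(k-2,k-1); NaN for the first two spikes.
        """
        n = self.spike_t.size
        out = np.full(n, np.nan)
        if n >= 3:
            isi = self.isi
            out[2:] = isi[1:] / isi[:-1]
        return out

    def count(self, label: str) -> int:
        return sum(1 for lab in self.label if lab == label)


#: reason codes attached to FeatureRow fields that could not be measured
NOT_MEASURABLE = "not_measurable"

FEATURE_FIELDS = (
    "rmp_mv",
    "tau_ms",
    "rn_mohm",
    "sag_at_100_mv",
    "ahp_mv",
    "rheobase_tonic_pa",
    "rheobase_burst_pa",
    "rheobase_rebound_pa",
    "thresh_tonic_mv",
    "thresh_burst_mv",
    "thresh_rebound_mv",
    "accommodation_index",
    "steady_state_at_rebound_rheobase_mv",
    "spikes_per_burst",
)


@dataclass
class FeatureRow:
    """One cell's intrinsic-property vector.

    A feature that could not be measured stays ``None`` and carries a reason
    string in ``flags``; it is never silently zero.
    """

    cell_id: str
    group: str = ""
    condition: str = "baseline"
    rmp_mv: Optional[float] = None
    tau_ms: Optional[float] = None
    rn_mohm: Optional[float] = None
    sag_at_100_mv: Optional[float] = None
    ahp_mv: Optional[float] = None
    rheobase_tonic_pa: Optional[float] = None
    rheobase_burst_pa: Optional[float] = None
    rheobase_rebound_pa: Optional[float] = None
    thresh_tonic_mv: Optional[float] = None
    thresh_burst_mv: Optional[float] = None
    thresh_rebound_mv: Optional[float] = None
    accommodation_index: Optional[float] = None
    steady_state_at_rebound_rheobase_mv: Optional[float] = None
    spikes_per_burst: Optional[float] = None
    flags: dict = field(default_factory=dict)

    def mark(self, feature: str, reason: str) -> None:
        if feature not in FEATURE_FIELDS:
            raise ValidationError(f"unknown feature {feature!r}")
        self.flags[feature] = reason

    def validate(self) -> None:
        if self.rn_mohm is not None and self.rn_mohm <= 0:
            raise ValidationError("rn_mohm must be positive when defined")
        if self.tau_ms is not None and self.tau_ms <= 0:
            raise ValidationError("tau_ms must be positive when defined")
        for name in FEATURE_FIELDS:
            if getattr(self, name) is None and name not in self.flags:
                raise ValidationError(f"missing feature {name} has no reason flag")


def copy_with(obj, **kw):
    """dataclasses.replace re-exported under a friendlier name."""
    return replace(obj, **kw)
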