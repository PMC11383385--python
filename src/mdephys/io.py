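"""Sweep-table CSV + JSON sidecar reading/writing and protocol validation.

The canonical on-disk format is a long-form CSV with header
``sweep_id,t_ms,v_mV,i_pA`` plus a JSON sidecar carrying the sampling rate,
step timing, per-sweep amplitudes and labels.  Numbers are written with 17
significant digits so that write -> read round-trips float64 exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, SamplingError, ValidationError
from .types import CURRENT_TOL_PA, HOLDING_BAND_MV, Recording, ProtocolSpec, Sweep

_CSV_COLUMNS = ["sweep_id", "t_ms", "v_mV", "i_pA"]


def sidecar_path(path: str | Path) -> Path:
    """Default sidecar location for a sweep table: same stem, ``.json``."""
    p = Path(path)
    return p.with_suffix(".json")


def write_sweep_table(rec: Recording, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a Recording as sweep-table CSV plus JSON sidecar."""
    rec.validate()
    path = Path(path)
    sidecar = sidecar_path(path) if sidecar is None else Path(sidecar)
    frames = []
    for s in rec.sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": s.sweep_id,
                    "t_ms": s.t,
                    "v_mV": s.v,
                    "i_pA": s.i,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "cell_id": rec.cell_id,
        "fs_hz": rec.fs,
        "step_on_ms": rec.sweeps[0].step_on,
        "step_off_ms": rec.sweeps[0].step_off,
        "holding_mv": rec.holding_mv,
        "group": rec.group,
        "condition": rec.condition,
        "protocol": rec.protocol,
        "ljp_mv": rec.ljp_mv,
        "sweeps": {s.sweep_id: s.amp for s in rec.sweeps},
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_sweep_table(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a sweep-table CSV + sidecar back into a Recording.

    Sweeps are returned in stable ascending-amplitude order regardless of the
    row order in the file.
    """
    path = Path(path)
    sidecar = sidecar_path(path) if sidecar is None else Path(sidecar)
    try:
        meta = json.loads(Path(sidecar).read_text())
    except FileNotFoundError as e:
        raise FormatError(f"missing sidecar {sidecar}") from e
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    fs = float(meta["fs_hz"])
    step_on = float(meta["step_on_ms"])
    step_off = float(meta["step_off_ms"])
    amps = dict(meta["sweeps"])
    sweeps: list[Sweep] = []
    for sweep_id, block in df.groupby("sweep_id", sort=False):
        sid = str(sweep_id)
        if sid not in amps:
            raise ConsistencyError(f"sweep {sid} absent from sidecar")
        t = block["t_ms"].to_numpy(dtype=np.float64)
        v = block["v_mV"].to_numpy(dtype=np.float64)
        i = block["i_pA"].to_numpy(dtype=np.float64)
        nominal = 1000.0 / fs
        dt = np.diff(t)
        if np.any(dt <= 0) or np.max(np.abs(dt - nominal)) > nominal * 1e-6:
            raise SamplingError(f"sweep {sid}: non-uniform time base (>1 ppm jitter)")
        sw = Sweep(
            sweep_id=sid, t=t, v=v, i=i, fs=fs,
            step_on=step_on, step_off=step_off, amp=float(amps[sid]),
        )
        # cross-check the sidecar amplitude against the current column
        inside = (t >= step_on) & (t < step_off)
        if inside.any() and (~inside).any():
            measured = float(np.median(i[inside]) - np.median(i[~inside]))
            if abs(measured - sw.amp) > max(CURRENT_TOL_PA, 1e-9 * abs(sw.amp)):
                raise ConsistencyError(
                    f"sweep {sid}: sidecar amp {sw.amp} pA but current steps "
                    f"{measured:g} pA"
                )
        sweeps.append(sw)
    extra = set(amps) - {s.sweep_id for s in sweeps}
    if extra:
        raise ConsistencyError(f"sidecar lists sweeps absent from table: {sorted(extra)}")
    rec = Recording(
        cell_id=str(meta.get("cell_id", path.stem)),
        sweeps=sweeps,
        holding_mv=meta.get("holding_mv"),
        group=str(meta.get("group", "")),
        condition=str(meta.get("condition", "baseline")),
        protocol=str(meta.get("protocol", "custom")),
        ljp_mv=meta.get("ljp_mv"),
    )
    rec.sort_by_amp()
    rec.validate()
    return rec


@dataclass
class ProtocolReport:
    """Report-only outcome of checking a Recording against a ProtocolSpec."""

    missing_amps: list[float] = field(default_factory=list)
    timing_issues: list[str] = field(default_factory=list)
    holding_violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.missing_amps or self.timing_issues or self.holding_violations)


def validate_protocol(rec: Recording, spec: ProtocolSpec) -> ProtocolReport:
    """Check amplitude coverage, step timing and holding potential.

    The holding check compares the measured pre-step voltage of each sweep
    against the accepted band around -65 mV; it only applies to recordings
    that declare a holding potential (held protocols).
    """
    report = ProtocolReport()
    have = rec.amps
    for amp in spec.amps:
        n = int(np.sum(np.abs(have - amp) < 1e-6))
        if n < spec.n_reps:
            report.missing_amps.append(float(amp))
    for s in rec.sweeps:
        if abs(s.step_on - spec.step_on) > 1e-6 or abs(s.step_off - spec.step_off) > 1e-6:
            report.timing_issues.append(
                f"sweep {s.sweep_id}: step [{s.step_on}, {s.step_off}) != "
                f"spec [{spec.step_on}, {spec.step_off})"
            )
        if abs(s.duration_ms - spec.total_dur) > s.dt_ms:
            report.timing_issues.append(
                f"sweep {s.sweep_id}: duration {s.duration_ms:g} ms != {spec.total_dur:g} ms"
            )
    if rec.holding_mv is not None:
        lo, hi = HOLDING_BAND_MV
        for s in rec.sweeps:
            pre = s.v[s.t < s.step_on]
            if pre.size == 0:
                continue
            v0 = float(np.mean(pre))
            if not (lo <= v0 <= hi):
                report.holding_violations.append(
                    f"sweep {s.sweep_id}: pre-step voltage {v0:.2f} mV outside "
                    f"[{lo}, {hi}] mV"
                )
    return report
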