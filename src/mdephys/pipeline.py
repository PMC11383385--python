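"""End-to-end orchestration: simulate -> extract -> compare.

``extract_features`` turns one cell's protocol recordings into a FeatureRow;
``extract_population`` does it for many cells; ``compare_groups`` runs the
two-group estimation-statistics battery over a feature table; and
``run_pipeline`` wires the three stages together from a single config,
producing sweep tables, a feature CSV, a comparison report and a
machine-readable summary, all reproducible from one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mdio
from . import spikes as spk
from . import stats as st
from . import subthreshold as sub
from . import synth
from .errors import ContaminationError, DomainError, ValidationError
from .types import FEATURE_FIELDS, FeatureRow, Recording

log = logging.getLogger("mdephys")

#: features where the expected group contrast is directional; the value is
#: the sign of (MD-L minus MD-M) the study reports
EXPECTED_DIRECTIONS = {
    "rn_mohm": -1,                 # lower input resistance in MD-L
    "tau_ms": -1,                  # shorter time constant in MD-L
    "sag_at_100_mv": -1,           # more (more negative) sag in MD-L
    "ahp_mv": -1,                  # deeper afterhyperpolarization in MD-L
    "rheobase_tonic_pa": +1,       # more current needed in MD-L
    "rheobase_burst_pa": +1,
    "rheobase_rebound_pa": -1,     # more hyperpolarizing current in MD-L
}

#: features where the study reports no difference between the groups
NULL_FEATURES = (
    "rmp_mv",
    "thresh_tonic_mv",
    "thresh_burst_mv",
    "thresh_rebound_mv",
    "accommodation_index",
    "spikes_per_burst",
    "steady_state_at_rebound_rheobase_mv",
)


def extract_features(
    rec_fine: Optional[Recording] = None,
    rec_coarse: Optional[Recording] = None,
    rec_tau: Optional[Recording] = None,
    rec_rest: Optional[Recording] = None,
    rules: spk.ClassifierRules = spk.DEFAULT_RULES,
    ahp_window_ms: float = sub.AHP_WINDOW_MS,
    sag_target_mv: float = -100.0,
) -> FeatureRow:
    """One cell's intrinsic-property vector from its protocol recordings.

    Any missing protocol or unmeasurable quantity leaves the field None with
    a reason code in ``row.flags`` — nothing is silently zero.  Deterministic
    given its inputs.
    """
    any_rec = rec_fine or rec_coarse or rec_tau or rec_rest
    if any_rec is None:
        raise DomainError("at least one recording is required")
    row = FeatureRow(cell_id=any_rec.cell_id, group=any_rec.group,
                     condition=any_rec.condition)

    # resting potential: needs a zero-bias segment
    rmp_src = rec_rest or rec_fine
    if rmp_src is not None:
        rmp = sub.estimate_rmp(rmp_src)
        if rmp is None:
            row.mark("rmp_mv", "no zero-bias baseline segment")
        else:
            row.rmp_mv = rmp
    else:
        row.mark("rmp_mv", "missing rest recording")

    if rec_tau is not None:
        try:
            tau = sub.estimate_time_constant(rec_tau)
            if tau is None:
                row.mark("tau_ms", "deflection never reached 1/e")
            else:
                row.tau_ms = tau
        except ContaminationError:
            row.mark("tau_ms", "spikes contaminate averaged trace")
    else:
        row.mark("tau_ms", "missing tau protocol")

    if rec_fine is not None:
        rn, _ = sub.estimate_input_resistance(rec_fine)
        if rn is None:
            row.mark("rn_mohm", "fewer than 3 spike-free sweeps")
        else:
            row.rn_mohm = rn
    else:
        row.mark("rn_mohm", "missing fine protocol")

    if rec_coarse is not None:
        sag = sub.sag_at_peak_target(rec_coarse, target_mv=sag_target_mv)
        row.sag_at_100_mv = sag.sag_mv
        if not sag.peak_ok:
            row.flags["sag_at_100_mv"] = "no sweep peaks within 5 mV of target"
        ahp = sub.ahp_minimum(rec_coarse, window_ms=ahp_window_ms)
        if ahp is None:
            row.mark("ahp_mv", "no depolarizing sweeps")
        else:
            row.ahp_mv = ahp
    else:
        row.mark("sag_at_100_mv", "missing coarse protocol")
        row.mark("ahp_mv", "missing coarse protocol")

    if rec_fine is not None:
        classified = spk.classify_recording(rec_fine, rules)
        for mode, amp_field, thr_field in (
            ("tonic", "rheobase_tonic_pa", "thresh_tonic_mv"),
            ("burst_depol", "rheobase_burst_pa", "thresh_burst_mv"),
            ("rebound", "rheobase_rebound_pa", "thresh_rebound_mv"),
        ):
            res = spk.rheobase(rec_fine, mode, classified, rules)
            if res is None:
                row.mark(amp_field, f"no {mode} spikes at any amplitude")
                row.mark(thr_field, f"no {mode} spikes at any amplitude")
                if mode == "rebound":
                    row.mark("steady_state_at_rebound_rheobase_mv",
                             "no rebound burst at any amplitude")
            else:
                setattr(row, amp_field, res.amp_pa)
                setattr(row, thr_field, res.thresh_v_mv)
                if mode == "rebound":
                    row.steady_state_at_rebound_rheobase_mv = res.steady_state_mv
        spb = spk.spikes_per_burst(rec_fine, classified, rules)
        if spb is None:
            row.mark("spikes_per_burst", "no depolarization-evoked bursts")
        else:
            row.spikes_per_burst = spb
        acc = spk.accommodation_index(rec_fine, classified, rules)
        if acc is None and rec_coarse is not None:
            acc = spk.accommodation_index(rec_coarse, rules=rules)
        if acc is None:
            row.mark("accommodation_index",
                     f"no sweep with >= {rules.accommodation_min_tonic} tonic spikes")
        else:
            row.accommodation_index = acc[0]
    else:
        for f in ("rheobase_tonic_pa", "rheobase_burst_pa", "rheobase_rebound_pa",
                  "thresh_tonic_mv", "thresh_burst_mv", "thresh_rebound_mv",
                  "spikes_per_burst", "accommodation_index",
                  "steady_state_at_rebound_rheobase_mv"):
            row.mark(f, "missing fine protocol")

    row.validate()
    return row


def simulate_cell_recordings(
    p: synth.SimParams,
    cell_id: str,
    group: str = "",
    condition: str = "baseline",
    hold_mv: float = -65.0,
    tau_reps: int = 10,
) -> dict[str, Recording]:
    """All four protocols for one cell (fine, coarse, tau at the holding
    potential; rest at zero bias)."""
    recs = {}
    for name, spec, hold in (
        ("fine", synth.fine_protocol(), hold_mv),
        ("coarse", synth.coarse_protocol(), hold_mv),
        ("tau", synth.tau_protocol(tau_reps), hold_mv),
        ("rest", synth.rest_protocol(), None),
    ):
        recs[name] = synth.simulate_protocol(
            p, spec, hold, cell_id=cell_id, group=group, condition=condition)
    return recs


def extract_population(
    params: Sequence[synth.SimParams],
    group: str,
    condition: str = "baseline",
    hold_mv: float = -65.0,
    cell_prefix: str = "cell",
    tau_reps: int = 10,
) -> list[FeatureRow]:
    """Simulate the full protocol battery for a population and extract one
    FeatureRow per cell.  Simulation is batched per protocol across cells."""
    n = len(params)
    ids = [f"{cell_prefix}{j:02d}" for j in range(n)]
    recs = {}
    for name, spec, hold in (
        ("fine", synth.fine_protocol(), hold_mv),
        ("coarse", synth.coarse_protocol(), hold_mv),
        ("tau", synth.tau_protocol(tau_reps), hold_mv),
        ("rest", synth.rest_protocol(), None),
    ):
        recs[name] = synth.simulate_population_protocol(
            params, spec, hold, cell_ids=ids, group=group, condition=condition)
    rows = []
    for j in range(n):
        rows.append(extract_features(
            rec_fine=recs["fine"][j], rec_coarse=recs["coarse"][j],
            rec_tau=recs["tau"][j], rec_rest=recs["rest"][j]))
    return rows


def features_frame(rows: Sequence[FeatureRow]) -> pd.DataFrame:
    """FeatureRows as a tidy DataFrame (one row per cell); missing-value
    reasons are serialized into a ``flags`` JSON column."""
    recs = []
    for r in rows:
        d = {k: v for k, v in asdict(r).items() if k != "flags"}
        d["flags"] = json.dumps(r.flags, sort_keys=True)
        recs.append(d)
    return pd.DataFrame(recs)


@dataclass
class GroupComparison:
    """One feature's two-group result plus the direction bookkeeping."""

    result: st.ComparisonResult
    expected_direction: Optional[int]   # sign of (b - a) expected, or None
    observed_direction: int

    @property
    def direction_ok(self) -> Optional[bool]:
        if self.expected_direction is None:
            return None
        return self.observed_direction == self.expected_direction


def compare_groups(
    features: pd.DataFrame,
    group_col: str = "group",
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
    feature_cols: Optional[Sequence[str]] = None,
    n_boot: int = 5000,
    seed: int = 0,
) -> dict[str, GroupComparison]:
    """Per-feature Mann-Whitney battery between two groups.

    Group a is the reference (MD-M in the study design); the bootstrap median
    difference is b minus a.  eta^2 is attached only where p < 0.05.  Groups
    with fewer than 5 usable cells for a feature trigger a warning flag but
    are still compared.
    """
    groups = sorted(features[group_col].dropna().unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise DomainError(f"need exactly two groups, found {groups}")
        group_a, group_b = groups
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_FIELDS if c in features.columns]
    out: dict[str, GroupComparison] = {}
    for j, col in enumerate(feature_cols):
        a = features.loc[features[group_col] == group_a, col].dropna().to_numpy(float)
        b = features.loc[features[group_col] == group_b, col].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            log.warning("feature %s: too few cells (%d/%d), skipped",
                        col, a.size, b.size)
            continue
        if a.size < 5 or b.size < 5:
            log.warning("feature %s: under-powered (%d/%d cells)",
                        col, a.size, b.size)
        res = st.compare_two_groups(a, b, feature=col, n_boot=n_boot,
                                    seed=seed + j)
        diff = float(np.median(b) - np.median(a))
        out[col] = GroupComparison(
            result=res,
            expected_direction=EXPECTED_DIRECTIONS.get(col),
            observed_direction=int(np.sign(diff)),
        )
    return out


def comparison_frame(comparisons: dict[str, GroupComparison]) -> pd.DataFrame:
    rows = []
    for col, gc in comparisons.items():
        r = gc.result
        rows.append({
            "feature": col,
            "n_a": r.n_a, "n_b": r.n_b,
            "statistic": r.statistic, "p": r.p,
            "median_a": r.median_a.median,
            "ci_a_lo": r.median_a.lo, "ci_a_hi": r.median_a.hi,
            "median_b": r.median_b.median,
            "ci_b_lo": r.median_b.lo, "ci_b_hi": r.median_b.hi,
            "median_diff": r.diff.diff,
            "ci_diff_lo": r.diff.lo, "ci_diff_hi": r.diff.hi,
            "eta_sq": r.eta_sq, "eta_category": r.eta_category,
            "method": r.method, "exact": r.exact,
            "expected_direction": gc.expected_direction,
            "observed_direction": gc.observed_direction,
            "direction_ok": gc.direction_ok,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runner


_ALLOWED_KEYS = {
    "seed", "out_dir", "n_per_group", "cv", "hold_mv", "tau_reps",
    "n_boot", "zd_block", "write_sweep_tables", "log_level",
}


@dataclass
class PipelineConfig:
    """Configuration of a full simulate->extract->compare run."""

    seed: int = 0
    out_dir: str = "mdephys_out"
    n_per_group: int = 20
    cv: float = 0.2
    hold_mv: float = -65.0
    tau_reps: int = 10
    n_boot: int = 5000
    zd_block: Optional[float] = None     # also run a ZD7288 arm when set
    write_sweep_tables: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full battery and write the artifact set.

    Writes ``features.csv``, ``comparisons.csv`` and ``summary.json`` (the
    machine-readable map of each expected contrast to its observed direction
    and p-value) under ``config.out_dir``; optionally the raw sweep tables.
    Every artifact records the seed and the config hash.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log.info("pipeline start: seed=%d config=%s", config.seed, digest)

    pop_m = synth.make_population("MD-M-like", config.n_per_group, config.cv,
                                  seed=config.seed)
    pop_l = synth.make_population("MD-L-like", config.n_per_group, config.cv,
                                  seed=config.seed + 1)
    rows = extract_population([p for p, _ in pop_m], "MD-M",
                              hold_mv=config.hold_mv, cell_prefix="m",
                              tau_reps=config.tau_reps)
    rows += extract_population([p for p, _ in pop_l], "MD-L",
                               hold_mv=config.hold_mv, cell_prefix="l",
                               tau_reps=config.tau_reps)
    log.info("extracted %d feature rows", len(rows))

    feats = features_frame(rows)
    feats.insert(0, "seed", config.seed)
    feats.insert(1, "config", digest)
    feats.to_csv(out / "features.csv", index=False)

    # MD-M is the reference group: median differences read MD-L minus MD-M
    comps = compare_groups(feats, group_a="MD-M", group_b="MD-L",
                           n_boot=config.n_boot, seed=config.seed)
    cdf = comparison_frame(comps)
    cdf.insert(0, "seed", config.seed)
    cdf.insert(1, "config", digest)
    cdf.to_csv(out / "comparisons.csv", index=False)

    summary = {
        "seed": config.seed,
        "config": digest,
        "contrasts": {
            col: {
                "expected_direction": gc.expected_direction,
                "observed_direction": gc.observed_direction,
                "direction_ok": gc.direction_ok,
                "p": gc.result.p,
                "eta_sq": gc.result.eta_sq,
            }
            for col, gc in comps.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    if config.write_sweep_tables:
        tables = out / "sweep_tables"
        tables.mkdir(exist_ok=True)
        for j, (p, gt) in enumerate(pop_m + pop_l):
            grp = "MD-M" if j < config.n_per_group else "MD-L"
            cid = f"{'m' if grp == 'MD-M' else 'l'}{j % config.n_per_group:02d}"
            recs = simulate_cell_recordings(p, cid, grp,
                                            hold_mv=config.hold_mv,
                                            tau_reps=config.tau_reps)
            for name, rec in recs.items():
                mdio.write_sweep_table(rec, tables / f"{cid}_{name}.csv")
    log.info("pipeline done: artifacts in %s", out)
    return summary
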