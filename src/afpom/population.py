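"""Population generation and biomarker-constrained calibration.

Candidate profiles are drawn by Latin hypercube sampling over the nine
multipliers in [0.5, 2.0].  Each candidate is paced on a thin 8 x 256 strip
(15 beats at 1 Hz, 3 ms stimuli at twice diastolic threshold from the
left-edge band), action-potential biomarkers are read at three probe cells
along the strip (linear indices 500, 620, 748 by default, i.e. rows 1-2 away
from the stimulated edge), averaged over the last five beats, and the
candidate is accepted only if every probe cell satisfies every biomarker
bound.  Experimental constraint tables load from CSV
(columns: biomarker, min, max); a documented synthetic stand-in box ships in
``afpom.synthetic_data``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import cell_model as cm
from . import synthetic_data as sd
from . import tissue_sim as ts
from .cell_model import (MULTIPLIER_HIGH, MULTIPLIER_LOW, MULTIPLIER_NAMES,
                         BaselineParameters, IonicProfile)
from .errors import NoAPError, NumericalStateError, PropagationError, RangeError

BIOMARKER_NAMES = ("APD20", "APD50", "APD90", "APA", "RMP", "V20")


@dataclass(frozen=True)
class APBiomarkers:
    """Six AP biomarkers (ms / mV) at 1 Hz pacing."""

    APD20: float
    APD50: float
    APD90: float
    APA: float
    RMP: float
    V20: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in BIOMARKER_NAMES}


@dataclass(frozen=True)
class BiomarkerConstraints:
    """Per-biomarker (min, max) acceptance bounds."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in BIOMARKER_NAMES:
                raise RangeError(f"unknown biomarker {name!r}")
            if lo > hi:
                raise RangeError(f"{name}: min {lo} exceeds max {hi}")

    def contains(self, bm: APBiomarkers) -> bool:
        for name, (lo, hi) in self.bounds.items():
            v = getattr(bm, name)
            if math.isnan(v) or not (lo <= v <= hi):
                return False
        return True

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiomarkerConstraints":
        df = pd.read_csv(path)
        return cls({r.biomarker: (float(r.min), float(r.max))
                    for r in df.itertuples()})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"biomarker": k, "min": lo, "max": hi}
             for k, (lo, hi) in self.bounds.items()]
        ).to_csv(path, index=False)


@dataclass
class PopulationRecord:
    profile: IonicProfile
    biomarkers: dict[int, APBiomarkers]  # probe-cell linear index -> biomarkers
    accepted: bool
    reason: str | None = None  # 'constraints' | 'numerical' | 'no AP' when rejected


# ---------------------------------------------------------------------------
# Latin hypercube sampling
# ---------------------------------------------------------------------------

def lhs_sample(n: int, dims: int, seed: int) -> np.ndarray:
    """n x dims Latin hypercube over [0.5, 2.0]: one sample per stratum and
    dimension, reproducible by seed."""
    if n < 1 or dims < 1:
        raise RangeError("n and dims must both be >= 1")
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, MULTIPLIER_LOW, MULTIPLIER_HIGH)


def sample_profiles(n: int, seed: int, prefix: str = "p") -> list[IonicProfile]:
    mat = lhs_sample(n, len(MULTIPLIER_NAMES), seed)
    return [IonicProfile.from_array(f"{prefix}{k:04d}", mat[k]) for k in range(n)]


# ---------------------------------------------------------------------------
# biomarker extraction
# ---------------------------------------------------------------------------

def compute_biomarkers(t: np.ndarray, vm: np.ndarray, stim_times: Sequence[float],
                       n_last: int = 5, upstroke_mv: float = -40.0) -> APBiomarkers:
    """Per-beat biomarkers on the last ``n_last`` beats, averaged.

    The upstroke instant is the maximum-dV/dt sample of the beat; APDx is the
    time from the upstroke to x % repolarization of that beat's amplitude
    (crossings searched from the peak, linearly interpolated); APA is
    peak - RMP with RMP the diastolic minimum before the upstroke; V20 is the
    voltage at offset APD20 after the upstroke.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if n_last > len(stim_times):
        raise RangeError("n_last exceeds the number of stimuli")
    if t[-1] < stim_times[-1]:
        raise RangeError("trace does not cover all stimuli")
    per_beat: list[dict[str, float]] = []
    edges = list(stim_times) + [t[-1] + 1e-9]
    # each beat window starts shortly before its stimulus so the upstroke's
    # rising edge and a diastolic pre-upstroke sample are always inside it
    pre_roll = 10.0
    for b in range(len(stim_times) - n_last, len(stim_times)):
        start = edges[b] - pre_roll
        if b > 0:
            start = max(start, edges[b - 1])
        w = (t >= start) & (t < edges[b + 1] - pre_roll)
        tt, vv = t[w], vm[w]
        if len(vv) < 4 or vv.max() < upstroke_mv:
            raise NoAPError(f"no action potential detected in beat {b}")
        # maximum-upstroke instant: the sample at which the steepest rise
        # lands (diff[k] is the rise from sample k to k+1)
        k_up = int(np.argmax(np.diff(vv))) + 1
        t_up = tt[k_up]
        k_peak = k_up + int(np.argmax(vv[k_up:]))
        peak = float(vv[k_peak])
        # diastolic window: from beat onset up to the upstroke
        pre = vv[: max(k_up, 1)]
        rmp = float(pre.min())
        apa = peak - rmp
        apds = {}
        for x in (20, 50, 90):
            level = peak - x / 100.0 * apa
            seg = vv[k_peak:]
            below = np.nonzero(seg <= level)[0]
            if len(below) == 0:
                apds[x] = math.nan
                continue
            k = below[0]
            if k == 0:
                t_cross = tt[k_peak]
            else:
                v0, v1 = seg[k - 1], seg[k]
                frac = (v0 - level) / (v0 - v1) if v1 != v0 else 0.0
                t_cross = tt[k_peak + k - 1] + frac * (tt[k_peak + k] - tt[k_peak + k - 1])
            apds[x] = float(t_cross - t_up)
        v20 = (float(np.interp(t_up + apds[20], tt, vv))
               if not math.isnan(apds[20]) else math.nan)
        per_beat.append({"APD20": apds[20], "APD50": apds[50], "APD90": apds[90],
                         "APA": apa, "RMP": rmp, "V20": v20})
    mean = {k: float(np.mean([d[k] for d in per_beat])) for k in per_beat[0]}
    return APBiomarkers(**mean)


# ---------------------------------------------------------------------------
# calibration strip
# ---------------------------------------------------------------------------

STRIP_ROWS = 8
STRIP_COLS = 256
DEFAULT_PROBE_CELLS = (500, 620, 748)


def probe_rc(index: int, cols: int = STRIP_COLS) -> tuple[int, int]:
    """Strip node linear index -> (row, column); index = row * cols + column."""
    return index // cols, index % cols


def simulate_strip(profile: IonicProfile,
                   probe_cells: Sequence[int] = DEFAULT_PROBE_CELLS,
                   model: ts.ModelKind = "surrogate",
                   base_params: BaselineParameters | None = None,
                   base_sparams: sd.SurrogateParameters | None = None,
                   n_beats: int = 15, cl: float = 1000.0,
                   dx: float = 0.025, dt: float | None = None,
                   D_baseline: float = ts.D_BASELINE,
                   stim_duration: float = 3.0):
    """Pace the 8 x 256 strip and return (t, Vm-at-probes dict, stim_times)."""
    geometry = ts.TissueGeometry(STRIP_COLS, STRIP_ROWS, dx, "strip")
    for idx in probe_cells:
        r, c = probe_rc(idx)
        if not (0 <= r < STRIP_ROWS and 0 <= c < STRIP_COLS):
            raise RangeError(f"probe index {idx} outside the strip")
    D_eff = D_baseline * profile.m_D
    if model == "surrogate":
        sp0 = base_sparams if base_sparams is not None else sd.SurrogateParameters()
        sp = sd.surrogate_from_profile(sp0, profile)
        state = ts.init_tissue(geometry, "surrogate", sparams=sp)
        amp = 2.0 * ts.surrogate_threshold(sp)
    else:
        bp = base_params if base_params is not None else cm.apply_caf_remodeling(BaselineParameters())
        p = cm.scale_profile(bp, profile)
        state = ts.init_tissue(geometry, "ionic", params=p)
        amp = 2.0 * cm.diastolic_threshold(p)
    if dt is None:
        dt = min(0.7 * ts.stability_dt(D_eff, dx), 0.1 if model == "surrogate" else 0.02)
        if model == "surrogate":
            dt = min(dt, state.sparams.tau_in / 2.5)
    stim = ts.s1_mask(geometry) * amp
    zero = np.zeros_like(stim)
    stim_times = cl * np.arange(n_beats)
    t_end = cl * n_beats
    n_ms = int(round(t_end))
    sub = max(1, int(round(1.0 / dt)))
    dt_eff = 1.0 / sub
    t_out = np.arange(n_ms + 1, dtype=float)
    traces = {idx: np.empty(n_ms + 1) for idx in probe_cells}
    quiescent_mv = sd.V_REST_MV + 2.0
    ms = 0
    while ms <= n_ms:
        vmf = state.Vm
        for idx in probe_cells:
            r, c = probe_rc(idx)
            traces[idx][ms] = vmf[r, c]
        if ms == n_ms:
            break
        t = float(ms)
        # diastolic fast-forward: once the strip is quiescent, relax v and h
        # in closed form up to just before the next stimulus
        if (model == "surrogate" and ms % 20 == 0
                and not any(s - 1.0 <= t < s + stim_duration + 1.0 for s in stim_times)
                and float(vmf.max()) < quiescent_mv):
            upcoming = stim_times[stim_times >= t]
            target = float(upcoming.min()) - 5.0 if len(upcoming) else float(n_ms)
            if target > t + 25.0:
                gap = target - t
                sp = state.sparams
                state.v *= math.exp(-gap / sp.tau_out)
                state.h = 1.0 + (state.h - 1.0) * math.exp(-gap / sp.tau_open)
                rest = state.Vm
                rest_vals = {idx: rest[probe_rc(idx)] for idx in probe_cells}
                for fill in range(ms + 1, int(target)):
                    for idx in probe_cells:
                        traces[idx][fill] = rest_vals[idx]
                ms = int(target)
                state.t = float(ms)
                continue
        on = any(s <= t < s + stim_duration for s in stim_times)
        ts.advance(state, D_eff, dt_eff, sub, stim if on else zero)
        ms += 1
    return t_out, traces, stim_times


def calibrate_population(candidates: Sequence[IonicProfile],
                         constraints: BiomarkerConstraints,
                         probe_cells: Sequence[int] = DEFAULT_PROBE_CELLS,
                         model: ts.ModelKind = "surrogate",
                         base_params: BaselineParameters | None = None,
                         base_sparams: sd.SurrogateParameters | None = None,
                         n_beats: int = 15, cl: float = 1000.0,
                         n_last: int = 5, dx: float = 0.025,
                         D_baseline: float = ts.D_BASELINE) -> list[PopulationRecord]:
    """Accept candidates whose probe-cell biomarkers all fall within bounds.

    Candidate order is preserved; a candidate whose simulation diverges is
    rejected with reason 'numerical' and never aborts the batch.  Biomarkers
    are recorded per probe cell even for rejected candidates (NaN rows when a
    probe shows no AP).
    """
    for idx in probe_cells:
        r, c = probe_rc(idx)
        if not (0 <= r < STRIP_ROWS and 0 <= c < STRIP_COLS):
            raise RangeError(f"probe index {idx} outside the strip")
    records: list[PopulationRecord] = []
    nan_bm = APBiomarkers(*([math.nan] * 6))
    for prof in candidates:
        try:
            t, traces, stim_times = simulate_strip(
                prof, probe_cells, model, base_params, base_sparams,
                n_beats, cl, dx, D_baseline=D_baseline)
        except NumericalStateError:
            records.append(PopulationRecord(prof, {i: nan_bm for i in probe_cells},
                                            accepted=False, reason="numerical"))
            continue
        except PropagationError:
            # profile too weak to even fire a single cell
            records.append(PopulationRecord(prof, {i: nan_bm for i in probe_cells},
                                            accepted=False, reason="no AP"))
            continue
        bms: dict[int, APBiomarkers] = {}
        ok = True
        reason = None
        for idx in probe_cells:
            try:
                bm = compute_biomarkers(t, traces[idx], stim_times, n_last)
            except NoAPError:
                bm = nan_bm
                ok, reason = False, "no AP"
            bms[idx] = bm
            if ok and not constraints.contains(bm):
                ok, reason = False, "constraints"
        records.append(PopulationRecord(prof, bms, accepted=ok,
                                        reason=None if ok else reason))
    return records


def population_table(records: Sequence[PopulationRecord]) -> pd.DataFrame:
    """Flat CSV-ready view: id, nine multipliers, accepted, per-cell biomarkers."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"profile_id": rec.profile.profile_id}
        row.update({n: getattr(rec.profile, n) for n in MULTIPLIER_NAMES})
        row["accepted"] = rec.accepted
        row["reason"] = rec.reason or ""
        for idx, bm in rec.biomarkers.items():
            for name, val in bm.as_dict().items():
                row[f"cell{idx}_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def accepted_profiles(records: Sequence[PopulationRecord]) -> list[IonicProfile]:
    return [r.profile for r in records if r.accepted]
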