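"""Synthetic generators: fast surrogate cell, constraint stand-ins, closed-form
AP traces, spiral-wave movies, and rule-labeled outcome tables.

Every generator is seed-deterministic and returns its ground truth alongside
the data, so each downstream stage (biomarkers, PDE, phase analysis, ML) can
be validated against known answers without the full ionic model.

The surrogate is a two-variable Mitchell-Schaeffer excitable cell: it supports
planar waves and reentry on 2D planes, has an interpretable action-potential
duration (roughly ``tau_close * ln(tau_out / (4 tau_in))``), and integrates in
seconds where the ionic model takes minutes.  Population multipliers hook into
it as follows: ``m_gNa`` scales the inward-current rate ``1/tau_in``;
``m_gK1`` and ``m_gKur`` jointly scale the outward rate ``1/tau_out``;
``m_gCaL`` scales ``tau_close`` (more calcium current, longer plateau); the
remaining multipliers are electrophysiologically inert in the surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .cell_model import MULTIPLIER_NAMES, IonicProfile
from .drug_model import DrugSpec, drug_factors
from .errors import InvalidParameterError, RangeError

# ---------------------------------------------------------------------------
# surrogate cell model (Mitchell-Schaeffer)
# ---------------------------------------------------------------------------

#: affine map from normalized surrogate voltage to mV
V_REST_MV = -80.0
V_SPAN_MV = 110.0


@dataclass(frozen=True)
class SurrogateParameters:
    """Two-variable excitable-cell time scales (ms) and threshold."""

    tau_in: float = 0.3
    tau_out: float = 2.0
    tau_open: float = 60.0
    tau_close: float = 265.0
    v_gate: float = 0.13

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0.0 < self.v_gate < 1.0):
            raise InvalidParameterError("v_gate must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.tau_in, self.tau_out, self.tau_open,
                         self.tau_close, self.v_gate])


def surrogate_from_profile(base: SurrogateParameters,
                           profile: IonicProfile,
                           drug: DrugSpec | None = None) -> SurrogateParameters:
    """Apply the population-multiplier hooks (and optionally a drug).

    Drug factors reach the surrogate through the same hooks: Nav1.5 block
    scales ``1/tau_in`` with ``m_gNa``; Cav1.2 block/enhancement scales
    ``tau_close`` with ``m_gCaL``.  hERG has no surrogate correlate.
    """
    m_gNa, m_gK1, m_gCaL, m_gKur = (profile.m_gNa, profile.m_gK1,
                                    profile.m_gCaL, profile.m_gKur)
    if drug is not None:
        factors = drug_factors(drug)
        m_gNa *= factors.get("gNa", 1.0)
        m_gCaL *= factors.get("gCaL", 1.0)
    return replace(
        base,
        tau_in=base.tau_in / m_gNa,
        tau_out=base.tau_out / (m_gK1 * m_gKur),
        tau_close=base.tau_close * m_gCaL,
    )


def surrogate_cell(state: Sequence[float], params: SurrogateParameters,
                   i_stim: float = 0.0):
    """Right-hand side of the surrogate: ``(dv_dt, (h_inf, tau_h))``.

    The recovery gate ``h`` relaxes exponentially toward 1 below ``v_gate``
    (time constant ``tau_open``) and toward 0 above it (``tau_close``), so it
    admits an exact Rush-Larsen update like any Hodgkin-Huxley gate.
    """
    v, h = float(state[0]), float(state[1])
    dv = h * v * v * (1.0 - v) / params.tau_in - v / params.tau_out + i_stim
    if v < params.v_gate:
        h_inf, tau_h = 1.0, params.tau_open
    else:
        h_inf, tau_h = 0.0, params.tau_close
    return dv, (h_inf, tau_h)


@njit(cache=True, fastmath=True)
def ms_integrate_cell(v0, h0, tin, tout, topen, tclose, vgate,
                      t_end, dt, stim_starts, stim_dur, stim_amp,
                      out_dt, tt, vv):  # pragma: no cover - numba
    """Single surrogate cell, Euler voltage + exact gate; records every out_dt."""
    v = v0
    h = h0
    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(out_dt / dt)))
    n_rec = 0
    for step in range(n_steps + 1):
        if step % rec_every == 0 and n_rec < tt.shape[0]:
            tt[n_rec] = step * dt
            vv[n_rec] = V_REST_MV + V_SPAN_MV * v
            n_rec += 1
        if step == n_steps:
            break
        t = step * dt
        istim = 0.0
        for k in range(stim_starts.shape[0]):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                istim = stim_amp
        dv = h * v * v * (1.0 - v) / tin - v / tout + istim
        if v < vgate:
            h = 1.0 + (h - 1.0) * math.exp(-dt / topen)
        else:
            h = h * math.exp(-dt / tclose)
        v += dt * dv
        if v < -0.1:
            v = -0.1
    return v, h, n_rec


def run_paced_surrogate(params: SurrogateParameters, n_beats: int, cl: float,
                        stim_duration: float = 3.0, stim_amplitude: float = 0.3,
                        dt: float = 0.05, out_dt: float = 1.0):
    """Pace a surrogate cell; returns (t, Vm mV, stim_times)."""
    if n_beats < 1:
        raise RangeError("n_beats must be >= 1")
    stim_starts = 10.0 + cl * np.arange(n_beats, dtype=np.float64)
    t_end = stim_starts[-1] + cl
    n_max = int(t_end / out_dt) + 2
    tt = np.empty(n_max)
    vv = np.empty(n_max)
    _, _, n_rec = ms_integrate_cell(
        0.0, 1.0, params.tau_in, params.tau_out, params.tau_open,
        params.tau_close, params.v_gate, t_end, dt,
        stim_starts, stim_duration, stim_amplitude, out_dt, tt, vv)
    return tt[:n_rec], vv[:n_rec], stim_starts


# ---------------------------------------------------------------------------
# biomarker-constraint stand-ins
# ---------------------------------------------------------------------------

#: documented stand-in acceptance ranges for chronic-AF atrial APs at 1 Hz.
#: These are synthetic placeholders for unavailable patient-derived ranges;
#: replace via the CSV constraint interface when real ranges are available.
DEFAULT_CONSTRAINT_BOX = {
    "APD90": (150.0, 350.0),
    "APD50": (50.0, 250.0),
    "APD20": (5.0, 120.0),
    "APA": (80.0, 130.0),
    "RMP": (-85.0, -65.0),
    "V20": (-40.0, 30.0),
}

#: variant adapted to the surrogate's spike-free AP morphology: without a
#: sodium spike the propagated AP repolarizes its first 20 % slowly
#: (APD20 ~ 0.75 APD90), so the early-repolarization bounds are relaxed while
#: APD90/APA/RMP stay at the chronic-AF stand-in values.
SURROGATE_CONSTRAINT_BOX = {
    "APD90": (150.0, 350.0),
    "APD50": (50.0, 320.0),
    "APD20": (5.0, 280.0),
    "APA": (80.0, 130.0),
    "RMP": (-85.0, -65.0),
    "V20": (-40.0, 30.0),
}

CONSTRAINT_BOXES = {"caf": DEFAULT_CONSTRAINT_BOX,
                    "surrogate": SURROGATE_CONSTRAINT_BOX}


def gen_constraint_box(seed: int | None = None, jitter: float = 0.0,
                       variant: str = "caf"):
    """Stand-in biomarker constraint ranges (optionally jittered by seed).

    Returns a ``population.BiomarkerConstraints``.  ``variant`` selects the
    chronic-AF box ('caf', default) or the surrogate-morphology box
    ('surrogate').  With ``jitter > 0`` each bound is perturbed by a uniform
    fraction of the range width, keeping min <= max.
    """
    from .population import BiomarkerConstraints  # local import: no cycle at module load

    if variant not in CONSTRAINT_BOXES:
        raise RangeError(f"unknown constraint-box variant {variant!r}")
    bounds = {}
    rng = np.random.default_rng(seed)
    for name, (lo, hi) in CONSTRAINT_BOXES[variant].items():
        if jitter > 0.0:
            w = (hi - lo) * jitter
            lo = lo + rng.uniform(-w, w)
            hi = hi + rng.uniform(-w, w)
            lo, hi = min(lo, hi), max(lo, hi)
        bounds[name] = (lo, hi)
    return BiomarkerConstraints(bounds)


# ---------------------------------------------------------------------------
# closed-form AP traces
# ---------------------------------------------------------------------------

def gen_ap_trace(rest: float = -80.0, peak: float = 20.0, apd90: float = 270.0,
                 shape: str = "linear", n_beats: int = 1, cl: float = 1000.0,
                 fs: float = 1000.0):
    """Waveform with analytically known biomarkers.

    ``linear``: instantaneous upstroke then linear return to rest over
    ``T = apd90 / 0.9``; APDx = (x/100) T, V20 = peak - 0.2 APA.
    ``exponential``: V = rest + APA exp(-t/tau) with tau = apd90/ln(10);
    APDx = tau ln(100/(100-x)).

    Returns ``(t, Vm, stim_times, analytic)`` where ``analytic`` is a
    ``population.APBiomarkers``.
    """
    from .population import APBiomarkers

    if not peak > rest:
        raise RangeError("peak must exceed rest")
    if not apd90 > 0:
        raise RangeError("apd90 must be > 0")
    apa = peak - rest
    dt = 1000.0 / fs
    t = np.arange(0.0, n_beats * cl, dt)
    v = np.full_like(t, rest)
    t_up = 10.0
    stim_times = t_up + cl * np.arange(n_beats)
    if shape == "linear":
        T = apd90 / 0.9
        apd20, apd50 = 0.2 * T, 0.5 * T
        v20 = peak - 0.2 * apa
        for s in stim_times:
            tau_rel = t - s
            mask = (tau_rel >= 0) & (tau_rel < T)
            v[mask] = peak - apa * tau_rel[mask] / T
    elif shape == "exponential":
        tau = apd90 / math.log(10.0)
        apd20 = tau * math.log(100.0 / 80.0)
        apd50 = tau * math.log(2.0)
        v20 = rest + apa * math.exp(-apd20 / tau)  # = peak - 0.2 APA
        for s in stim_times:
            tau_rel = t - s
            mask = (tau_rel >= 0) & (tau_rel < cl - t_up)
            v[mask] = rest + apa * np.exp(-tau_rel[mask] / tau)
    else:
        raise RangeError(f"unknown shape {shape!r}")
    analytic = APBiomarkers(APD20=apd20, APD50=apd50, APD90=apd90,
                            APA=apa, RMP=rest, V20=v20)
    return t, v, stim_times, analytic


# ---------------------------------------------------------------------------
# spiral-wave phase movies
# ---------------------------------------------------------------------------

def gen_spiral_movie(nx: int, ny: int,
                     centers: Sequence[tuple[float, float, int]],
                     f: float, duration: float, fs: float = 1000.0):
    """Rotating-phase movie with known singularities.

    ``centers`` is a list of ``(x, y, chirality)`` with chirality +-1; ``f``
    is in rotations per second.  Returns ``(movie, truth)`` where ``movie``
    has shape (n_frames, ny, nx) in mV and ``truth`` is a dict with the SP
    trajectory (static centers), per-center chirality, and the rotation count
    ``f * duration / 1000``.
    """
    for (cx, cy, chir) in centers:
        if not (0 <= cx < nx and 0 <= cy < ny):
            raise RangeError(f"center {(cx, cy)} outside the {nx}x{ny} grid")
        if chir not in (-1, 1):
            raise RangeError("chirality must be +-1")
    dt = 1000.0 / fs
    n_frames = int(round(duration / dt))
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = np.zeros((ny, nx))
    # The analytic-signal phase of cos(theta - omega t) is (omega t - theta):
    # the recovered spatial field is -theta, so the angular field enters with
    # a minus sign to make detected charge equal the stated chirality.
    for (cx, cy, chir) in centers:
        theta -= chir * np.arctan2(yy - cy + 1e-9, xx - cx + 1e-9)
    omega = 2.0 * math.pi * f / 1000.0  # rad per ms
    tgrid = dt * np.arange(n_frames)
    movie = V_REST_MV + 0.5 * V_SPAN_MV * (
        1.0 + np.cos(theta[None, :, :] - omega * tgrid[:, None, None]))
    truth = {
        "centers": [(float(cx), float(cy)) for (cx, cy, _) in centers],
        "chirality": [int(c) for (_, _, c) in centers],
        "rotations": f * duration / 1000.0,
        "frame_dt": dt,
    }
    return movie, truth


# ---------------------------------------------------------------------------
# rule-labeled outcome tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleClause:
    feature: str
    threshold: float
    direction: str  # 'gt' or 'lt'

    def __post_init__(self) -> None:
        if self.direction not in ("gt", "lt"):
            raise RangeError("direction must be 'gt' or 'lt'")


@dataclass(frozen=True)
class GeneratorRule:
    """OR of AND-clauses over design-row features, plus a label-noise rate."""

    clauses: tuple[tuple[RuleClause, ...], ...]
    noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise < 0.5):
            raise RangeError("noise rate must lie in [0, 0.5)")

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        """Noise-free truth labels for the rows of ``table``."""
        result = np.zeros(len(table), dtype=bool)
        for clause in self.clauses:
            m = np.ones(len(table), dtype=bool)
            for c in clause:
                col = table[c.feature].to_numpy()
                m &= (col > c.threshold) if c.direction == "gt" else (col < c.threshold)
            result |= m
        return result


def single_feature_rule(feature: str = "m_gK1", threshold: float = 1.09,
                        direction: str = "gt", noise: float = 0.0) -> GeneratorRule:
    return GeneratorRule(((RuleClause(feature, threshold, direction),),), noise)


#: two induced-AF archetypes: (A) high gK1 / low diffusion / high [K]o /
#: high gNa / low gKur, and (B) low gK1 / low [K]o / high INaK / high gCaL /
#: high IKCa / high gNa.  Thresholds are the fixture's own design.
PAPER_CLUSTERS_RULE = GeneratorRule(
    clauses=(
        (RuleClause("m_gK1", 1.09, "gt"),
         RuleClause("m_D", 1.85, "lt"),
         RuleClause("m_K_o", 0.65, "gt"),
         RuleClause("m_gNa", 0.65, "gt"),
         RuleClause("m_gKur", 1.85, "lt")),
        (RuleClause("m_gK1", 1.09, "lt"),
         RuleClause("m_K_o", 1.25, "lt"),
         RuleClause("m_iNaK", 1.0, "gt"),
         RuleClause("m_gCaL", 1.0, "gt"),
         RuleClause("m_iKCa", 1.0, "gt"),
         RuleClause("m_gNa", 0.65, "gt")),
    ),
    noise=0.0,
)

PRESET_RULES = {
    "gk1_threshold": single_feature_rule(),
    "paper_clusters": PAPER_CLUSTERS_RULE,
}

#: plane areas (cm^2) attached to synthetic tables, matching the two sizes
SIZE_AREAS = {"normal": 16.0, "dilated": 20.25}


def gen_outcome_table(n: int, rule: GeneratorRule | str, seed: int = 0,
                      noise: float | None = None) -> pd.DataFrame:
    """Labeled design-table fixture for the ML stage.

    Multipliers are uniform on [0.5, 2.0]; tissue size and condition are
    uniform over their vocabularies; ``label`` follows ``rule`` with the
    rule's (or the overriding) noise rate.  Column ``label_truth`` carries the
    noise-free ground truth.  A degenerate rule (all rows one class before
    noise) sets ``table.attrs['degenerate_rule'] = True``.
    """
    if n < 10:
        raise RangeError("n must be >= 10")
    if isinstance(rule, str):
        rule = PRESET_RULES[rule]
    if noise is not None:
        rule = GeneratorRule(rule.clauses, noise)
    rng = np.random.default_rng(seed)
    data = {name: rng.uniform(0.5, 2.0, size=n) for name in MULTIPLIER_NAMES}
    table = pd.DataFrame(data)
    table.insert(0, "profile_id", [f"syn{idx:05d}" for idx in range(n)])
    table["tissue"] = rng.choice(["normal", "dilated"], size=n)
    table["tissue_area"] = table["tissue"].map(SIZE_AREAS)
    table["condition"] = rng.choice(
        ["basal", "flecainide", "verapamil", "isoproterenol"], size=n)
    truth = rule.evaluate(table)
    flips = rng.random(n) < rule.noise
    labels = truth ^ flips
    table["label_truth"] = np.where(truth, "induced", "non_inducible")
    table["label"] = np.where(labels, "induced", "non_inducible")
    table.attrs["degenerate_rule"] = bool(truth.all() or not truth.any())
    table.attrs["rule_noise"] = rule.noise
    return table
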