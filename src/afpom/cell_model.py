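"""Human atrial myocyte model with chronic-AF remodeling.

The membrane model is a compact Hodgkin-Huxley-type formulation of the human
atrial action potential authored for this package.  It carries the currents
that the population varies or that chronic-AF remodeling touches: fast sodium
(INa), inward rectifier (IK1), transient outward (Ito), ultrarapid delayed
rectifier (IKur), rapid delayed rectifier (IKr), small-conductance
calcium-activated potassium (IKCa/SK), L-type calcium (ICaL), sodium-potassium
pump (INaK), sodium-calcium exchanger (INCX), background sodium/calcium
currents and a sarcolemmal calcium pump, plus a two-compartment intracellular
calcium subsystem (cytosol + sarcoplasmic reticulum) whose uptake flux is
modulated by SERCA expression and its phospholamban/sarcolipin regulators.
Gating kinetics use standard published rate forms for INa (Luo-Rudy type) and
Boltzmann/bell-shaped rates adapted from the human atrial modeling literature
for the potassium and calcium channels.  Intracellular Na+ and K+ are clamped,
a common reduction that removes slow drift irrelevant on the minutes-long
protocols used here.

Chronic-AF electrical remodeling is a fixed set of multiplicative rescalings
applied on top of the baseline (ICaL down 55 %, Ito down 62 %, IKur down 38 %,
IK1 up 62 %, NCX up 50 %, SERCA down 16 %, phospholamban up 18 %, sarcolipin
down 40 %).  Population variability then scales nine quantities (gNa, INaK,
gK1, gCaL, gKur, IKCa, [Na]o, [K]o and the tissue diffusion coefficient)
between 0.5x and 2x.

All currents are in pA/pF, voltages in mV, time in ms, concentrations in mM.
A depolarizing stimulus is positive and ``dVm/dt = -(I_ion - I_stim)/Cm`` with
Cm normalized into the pA/pF convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Iterable

import numpy as np
from numba import njit

from .errors import InvalidParameterError, NumericalStateError, RangeError

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

#: order of the nine population multipliers everywhere in the package
MULTIPLIER_NAMES = (
    "m_gNa", "m_iNaK", "m_gK1", "m_gCaL", "m_gKur",
    "m_iKCa", "m_Na_o", "m_K_o", "m_D",
)

MULTIPLIER_LOW = 0.5
MULTIPLIER_HIGH = 2.0


@dataclass(frozen=True)
class BaselineParameters:
    """Maximal conductances/fluxes and extracellular milieu of the cell model.

    Conductances are in nS/pF except ``gKur`` which scales a voltage-dependent
    conductance profile and the dimensionless ``*_scale`` regulators.
    """

    gNa: float = 7.8
    gK1: float = 0.09
    gCaL: float = 0.40
    gKur: float = 1.0
    gKCa: float = 0.01
    iNaK_max: float = 0.60
    gto: float = 0.1652
    gKr: float = 0.015
    gNCX_scale: float = 1.0
    serca_scale: float = 1.0
    plb_scale: float = 1.0
    sln_scale: float = 1.0
    Na_o: float = 140.0
    K_o: float = 5.4
    Cm: float = 100.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0.0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"BaselineParameters.{name} must be strictly positive and finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """Pack into the flat float64 layout the numba kernels consume."""
        return np.array(
            [self.gNa, self.gK1, self.gCaL, self.gKur, self.gKCa,
             self.iNaK_max, self.gto, self.gKr, self.gNCX_scale,
             self.serca_scale, self.plb_scale, self.sln_scale,
             self.Na_o, self.K_o, self.Cm],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class IonicProfile:
    """One member of the population: nine dimensionless multipliers.

    ``m_D`` does not touch the cell model; it scales the tissue diffusion
    coefficient and is carried through to the tissue stage.
    """

    profile_id: str
    m_gNa: float = 1.0
    m_iNaK: float = 1.0
    m_gK1: float = 1.0
    m_gCaL: float = 1.0
    m_gKur: float = 1.0
    m_iKCa: float = 1.0
    m_Na_o: float = 1.0
    m_K_o: float = 1.0
    m_D: float = 1.0

    def __post_init__(self) -> None:
        for name in MULTIPLIER_NAMES:
            v = getattr(self, name)
            if not (MULTIPLIER_LOW <= v <= MULTIPLIER_HIGH):
                raise RangeError(
                    f"{name}={v!r} outside the admissible multiplier range "
                    f"[{MULTIPLIER_LOW}, {MULTIPLIER_HIGH}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MULTIPLIER_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, profile_id: str, values: Iterable[float]) -> "IonicProfile":
        vals = list(values)
        if len(vals) != len(MULTIPLIER_NAMES):
            raise RangeError(f"expected {len(MULTIPLIER_NAMES)} multipliers, got {len(vals)}")
        return cls(profile_id, **dict(zip(MULTIPLIER_NAMES, vals)))


# chronic-AF remodeling scalars (fraction of the non-AF baseline that remains)
CAF_REMODELING = {
    "gCaL": 0.45,        # L-type Ca2+ down 55 %
    "gto": 0.38,         # transient outward down 62 %
    "gKur": 0.62,        # ultrarapid K+ down 38 %
    "gK1": 1.62,         # inward rectifier up 62 %
    "gNCX_scale": 1.50,  # Na/Ca exchanger up 50 %
    "serca_scale": 0.84, # SERCA expression down 16 %
    "plb_scale": 1.18,   # phospholamban/SERCA up 18 %
    "sln_scale": 0.60,   # sarcolipin/SERCA down 40 %
}


def apply_caf_remodeling(base: BaselineParameters) -> BaselineParameters:
    """Return a copy of ``base`` with chronic-AF electrical remodeling applied."""
    updates = {k: getattr(base, k) * v for k, v in CAF_REMODELING.items()}
    return replace(base, **updates)


def scale_profile(base: BaselineParameters, profile: IonicProfile) -> BaselineParameters:
    """Apply a population member's multipliers to the (remodeled) baseline.

    ``m_D`` is intentionally not consumed here; tissue code reads it from the
    profile directly.
    """
    return replace(
        base,
        gNa=base.gNa * profile.m_gNa,
        iNaK_max=base.iNaK_max * profile.m_iNaK,
        gK1=base.gK1 * profile.m_gK1,
        gCaL=base.gCaL * profile.m_gCaL,
        gKur=base.gKur * profile.m_gKur,
        gKCa=base.gKCa * profile.m_iKCa,
        Na_o=base.Na_o * profile.m_Na_o,
        K_o=base.K_o * profile.m_K_o,
    )


# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "Vm", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "d", "f", "fca",
    "Ca_i", "Ca_sr",
)
N_STATES = len(STATE_NAMES)
GATE_SLICE = slice(1, 12)  # m..fca are Hodgkin-Huxley gates (Rush-Larsen)
N_GATES = 11

#: float mask, 1.0 on gate entries; used by the generic integrators
GATE_MASK = np.zeros(N_STATES, dtype=np.float64)
GATE_MASK[GATE_SLICE] = 1.0


@dataclass
class CellState:
    """Membrane potential plus gating and concentration variables."""

    Vm: float
    gates: np.ndarray        # 11 gating variables, each in [0, 1]
    concentrations: np.ndarray  # [Ca_i, Ca_sr] in mM

    def as_array(self) -> np.ndarray:
        out = np.empty(N_STATES)
        out[0] = self.Vm
        out[GATE_SLICE] = self.gates
        out[12:] = self.concentrations
        return out

    @classmethod
    def from_array(cls, s: np.ndarray) -> "CellState":
        return cls(Vm=float(s[0]), gates=np.array(s[GATE_SLICE]),
                   concentrations=np.array(s[12:]))


def default_initial_state() -> np.ndarray:
    """A quiescent starting point; equilibrate before quantitative use."""
    s = np.array([
        -81.2,       # Vm
        0.0029, 0.965, 0.978,   # m h j
        0.03, 0.999,            # oa oi
        0.005, 0.999,           # ua ui
        3e-5,                   # xr
        1.4e-4, 0.999, 0.77,    # d f fca
        1.0e-4, 1.2,            # Ca_i Ca_sr
    ])
    return s


# ---------------------------------------------------------------------------
# membrane kinetics (numba kernels)
# ---------------------------------------------------------------------------

_RTF = 8.3143 * 310.0 / 96.4867   # ~26.71 mV
_F = 96.4867                      # C/mmol
_NA_I = 11.2                      # mM, clamped
_K_I = 139.0                      # mM, clamped
_CA_O = 1.8                       # mM
_V_I = 13668.0                    # cytosolic volume, um^3
_V_SR = 1206.0                    # lumped SR volume, um^3
_CM_REF = 100.0                   # pF, reference capacitance for flux scaling


@njit(cache=True, fastmath=True)
def ionic_rates(s, p, istim, dout, winf, tau):  # pragma: no cover - numba
    """Fill derivative / gate-rate arrays for one node.

    ``dout`` receives plain time-derivatives for Vm and concentrations (gate
    entries are set to 0); ``winf``/``tau`` receive steady state and time
    constant for each gate so callers can take exact Rush-Larsen steps.
    """
    V = s[0]
    m = s[1]; h = s[2]; j = s[3]
    oa = s[4]; oi = s[5]; ua = s[6]; ui = s[7]
    xr = s[8]; d = s[9]; f = s[10]; fca = s[11]
    Ca = s[12]; Casr = s[13]

    gNa = p[0]; gK1 = p[1]; gCaL = p[2]; gKur = p[3]; gKCa = p[4]
    iNaK = p[5]; gto = p[6]; gKr = p[7]; gNCX = p[8]
    serca = p[9]; plb = p[10]; sln = p[11]
    Na_o = p[12]; K_o = p[13]

    ENa = _RTF * math.log(Na_o / _NA_I)
    EK = _RTF * math.log(K_o / _K_I)
    ECa = 0.5 * _RTF * math.log(_CA_O / max(Ca, 1e-8))

    INa = gNa * m * m * m * h * j * (V - ENa)
    IK1 = gK1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))
    Ito = gto * oa * oa * oa * oi * (V - EK)
    IKur = gKur * (0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))) \
        * ua * ua * ua * ui * (V - EK)
    IKr = gKr * xr * (V - EK) / (1.0 + math.exp((V + 15.0) / 22.4))
    ca2 = Ca * Ca
    IKCa = gKCa * ca2 / (ca2 + 0.0005 * 0.0005) * (V - EK)
    ICaL = gCaL * d * f * fca * (V - 65.0)

    sigma = (math.exp(Na_o / 67.3) - 1.0) / 7.0
    fNaK = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / _RTF)
                  + 0.0365 * sigma * math.exp(-V / _RTF))
    INaK = iNaK * fNaK * (1.0 / (1.0 + (10.0 / _NA_I) ** 1.5)) \
        * (K_o / (K_o + 1.5))

    expp = math.exp(0.35 * V / _RTF)
    expm = math.exp(-0.65 * V / _RTF)
    INCX = gNCX * 1600.0 * (expp * _NA_I ** 3 * _CA_O - expm * Na_o ** 3 * Ca) \
        / ((87.5 ** 3 + Na_o ** 3) * (1.38 + _CA_O) * (1.0 + 0.1 * expm))

    IbNa = 0.000674 * (V - ENa)
    IbCa = 0.00113 * (V - ECa)
    IpCa = 0.275 * Ca / (Ca + 0.0005)

    Iion = (INa + IK1 + Ito + IKur + IKr + IKCa + ICaL
            + INaK + INCX + IbNa + IbCa + IpCa)

    dout[0] = -Iion + istim

    # --- INa gates (Luo-Rudy type rates) ---
    dv = V + 47.13
    if abs(dv) < 1e-7:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-V / 11.0)
    tau[1] = 1.0 / (am + bm)
    winf[1] = am * tau[1]

    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp((V + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * math.exp((80.0 + V) / -6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = (-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V)) \
            * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23)))
        bj = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (ah + bh)
    winf[2] = ah * tau[2]
    tau[3] = 1.0 / (aj + bj)
    winf[3] = aj * tau[3]

    # --- Ito gates ---
    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau[4] = 1.0 / (3.0 * (a_oa + b_oa))
    winf[4] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    tau[5] = 1.0 / (3.0 * (a_oi + b_oi))
    winf[5] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

    # --- IKur gates (activation shares the Ito alpha/beta) ---
    tau[6] = tau[4]
    winf[6] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    tau[7] = 1.0 / (3.0 * (a_ui + b_ui))
    winf[7] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

    # --- IKr gate ---
    dv = V + 14.1
    if abs(dv) < 1e-7:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-7:
        b_xr = 3.7836e-4
    else:
        b_xr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    tau[8] = 1.0 / (a_xr + b_xr)
    winf[8] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

    # --- ICaL gates ---
    dv = V + 10.0
    if abs(dv) < 1e-7:
        tau[9] = 2.2894
    else:
        e = math.exp(-dv / 6.24)
        tau[9] = (1.0 - e) / (0.035 * dv * (1.0 + e))
    winf[9] = 1.0 / (1.0 + math.exp(-dv / 8.0))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 * 0.0337) * dv * dv) + 0.02)
    winf[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau[11] = 2.0
    winf[11] = 1.0 / (1.0 + Ca / 0.00035)

    # gate entries of dout stay zero; integrators use winf/tau
    for k in range(1, 12):
        dout[k] = 0.0

    # --- calcium subsystem ---
    Jup = serca * 0.005 * Ca / (Ca + 0.00092 * plb * sln)
    Jleak = 0.005 * Casr / 15.0
    Jrel = 0.06 * d * fca * (Casr - Ca)

    bcoef = 1.0 / (1.0
                   + 0.05 * 0.00238 / ((Ca + 0.00238) * (Ca + 0.00238))
                   + 0.07 * 0.0005 / ((Ca + 0.0005) * (Ca + 0.0005)))
    flux_scale = _CM_REF / (2.0 * _F * _V_I)
    dout[12] = bcoef * ((2.0 * INCX - ICaL - IbCa - IpCa) * flux_scale
                        + Jrel + Jleak - Jup)
    dout[13] = (Jup - Jleak - Jrel) * (_V_I / _V_SR)


@njit(cache=True, fastmath=True)
def _integrate_cell(s, p, t0, t_end, dt, stim_starts, stim_dur, stim_amp,
                    out_dt, trace_t, trace_v):  # pragma: no cover - numba
    """Fixed-step integrator: forward Euler + Rush-Larsen gates.

    Records Vm every ``out_dt`` ms into the preallocated trace arrays and
    returns the number of samples written.
    """
    dout = np.zeros(N_STATES)
    winf = np.zeros(N_STATES)
    tau = np.zeros(N_STATES)
    n_steps = int(round((t_end - t0) / dt))
    rec_every = max(1, int(round(out_dt / dt)))
    n_rec = 0
    t = t0
    for step in range(n_steps + 1):
        if step % rec_every == 0 and n_rec < trace_t.shape[0]:
            trace_t[n_rec] = t
            trace_v[n_rec] = s[0]
            n_rec += 1
        if step == n_steps:
            break
        istim = 0.0
        for k in range(stim_starts.shape[0]):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                istim = stim_amp
        ionic_rates(s, p, istim, dout, winf, tau)
        s[0] += dt * dout[0]
        for g in range(1, 12):
            s[g] = winf[g] + (s[g] - winf[g]) * math.exp(-dt / tau[g])
        s[12] += dt * dout[12]
        s[13] += dt * dout[13]
        if s[12] < 1e-9:
            s[12] = 1e-9
        if s[13] < 1e-9:
            s[13] = 1e-9
        t = t0 + (step + 1) * dt
    return n_rec


# ---------------------------------------------------------------------------
# python-facing API
# ---------------------------------------------------------------------------

DEFAULT_DT = 0.02       # ms, membrane integration step for cell-level runs
OUTPUT_DT = 1.0         # ms, storage/analysis sampling contract (1 kHz)


def cell_derivatives(state: CellState, params: BaselineParameters,
                     i_stim: float = 0.0):
    """Time-derivatives for non-gating states plus (w_inf, tau) per gate.

    Returns ``(dVm_dt, gate_rates, conc_derivs)`` where ``gate_rates`` is a
    list of ``(w_inf, tau)`` pairs in state order, enabling exact Rush-Larsen
    updates downstream.
    """
    s = state.as_array()
    if not np.all(np.isfinite(s)):
        bad = STATE_NAMES[int(np.argmin(np.isfinite(s)))]
        raise NumericalStateError(f"non-finite value in state variable '{bad}'")
    dout = np.zeros(N_STATES)
    winf = np.zeros(N_STATES)
    tau = np.zeros(N_STATES)
    ionic_rates(s, params.as_array(), float(i_stim), dout, winf, tau)
    gate_rates = [(float(winf[k]), float(tau[k])) for k in range(1, 12)]
    return float(dout[0]), gate_rates, dout[12:].copy()


def equilibrate(params: BaselineParameters, duration: float = 60_000.0,
                dt: float = DEFAULT_DT, state: np.ndarray | None = None) -> np.ndarray:
    """Integrate with no stimulus until the model sits at its own rest."""
    s = default_initial_state() if state is None else state.copy()
    n = int(duration / OUTPUT_DT) + 2
    tt = np.empty(n)
    vv = np.empty(n)
    _integrate_cell(s, params.as_array(), 0.0, duration, dt,
                    np.empty(0, dtype=np.float64), 0.0, 0.0,
                    OUTPUT_DT, tt, vv)
    return s


@dataclass
class PacedTrace:
    """1 kHz voltage trace from a paced single-cell run."""

    t: np.ndarray               # ms
    Vm: np.ndarray              # mV
    stim_times: np.ndarray      # S1 onset times, ms
    final_state: np.ndarray
    repolarization_failure: bool = False
    repol_threshold: float = -60.0


def run_paced_cell(params: BaselineParameters, n_beats: int, cl: float,
                   stim_duration: float = 3.0, stim_amplitude: float = 20.0,
                   dt: float = DEFAULT_DT,
                   initial_state: np.ndarray | None = None,
                   pre_equilibrate: float = 10_000.0,
                   tail: float | None = None,
                   repol_threshold: float = -60.0) -> PacedTrace:
    """Pace an isolated cell ``n_beats`` times at cycle length ``cl`` (ms).

    The trace is sampled at 1 kHz.  A failure to repolarize below
    ``repol_threshold`` before the next stimulus is flagged on the record,
    never raised.
    """
    if n_beats < 1:
        raise RangeError("n_beats must be >= 1")
    if cl <= stim_duration:
        raise RangeError("cycle length must exceed the stimulus duration")
    if initial_state is None:
        s = equilibrate(params, pre_equilibrate, dt)
    else:
        s = initial_state.copy()
    if tail is None:
        tail = cl
    stim_starts = 10.0 + cl * np.arange(n_beats)
    t_end = stim_starts[-1] + tail
    n_max = int(t_end / OUTPUT_DT) + 2
    tt = np.empty(n_max)
    vv = np.empty(n_max)
    n_rec = _integrate_cell(s, params.as_array(), 0.0, t_end, dt,
                            stim_starts, stim_duration, stim_amplitude,
                            OUTPUT_DT, tt, vv)
    t, v = tt[:n_rec], vv[:n_rec]
    failure = False
    for k in range(n_beats - 1):
        win = (t >= stim_starts[k] + stim_duration) & (t < stim_starts[k + 1])
        if win.any() and v[win].min() > repol_threshold:
            failure = True
            break
    return PacedTrace(t=t, Vm=v, stim_times=stim_starts, final_state=s,
                      repolarization_failure=failure,
                      repol_threshold=repol_threshold)


def save_trace(trace: "PacedTrace", path, csv: bool = False) -> None:
    """Write a paced trace as HDF5 (datasets ``time``/``Vm`` with units
    attributes) or, with ``csv=True``, as a two-column CSV."""
    if csv:
        import pandas as pd

        pd.DataFrame({"time_ms": trace.t, "Vm_mV": trace.Vm}).to_csv(
            path, index=False)
        return
    import h5py

    with h5py.File(path, "w") as f:
        d_t = f.create_dataset("time", data=trace.t)
        d_t.attrs["units"] = "ms"
        d_v = f.create_dataset("Vm", data=trace.Vm)
        d_v.attrs["units"] = "mV"
        f.attrs["stim_times_ms"] = trace.stim_times
        f.attrs["repolarization_failure"] = trace.repolarization_failure


def run_stimulus_sequence(params: BaselineParameters, stim_times,
                          stim_duration: float = 3.0,
                          stim_amplitude: float = 20.0,
                          t_end: float | None = None,
                          dt: float = DEFAULT_DT,
                          initial_state: np.ndarray | None = None):
    """Integrate an isolated cell under an arbitrary stimulus train.

    Returns ``(t, Vm, final_state)`` at 1 kHz.  Used for refractoriness
    probes (an extra stimulus at an arbitrary coupling interval).
    """
    stim_times = np.asarray(stim_times, dtype=np.float64)
    s = equilibrate(params, 10_000.0, dt) if initial_state is None else initial_state.copy()
    if t_end is None:
        t_end = float(stim_times.max()) + 500.0
    n_max = int(t_end / OUTPUT_DT) + 2
    tt = np.empty(n_max)
    vv = np.empty(n_max)
    n_rec = _integrate_cell(s, params.as_array(), 0.0, t_end, dt,
                            stim_times, stim_duration, stim_amplitude,
                            OUTPUT_DT, tt, vv)
    return tt[:n_rec], vv[:n_rec], s


def count_upstrokes(t: np.ndarray, v: np.ndarray, threshold: float = -40.0) -> int:
    """Number of positive-going crossings of ``threshold``."""
    above = v >= threshold
    return int(np.count_nonzero(~above[:-1] & above[1:]))


def diastolic_threshold(params: BaselineParameters, stim_duration: float = 3.0,
                        dt: float = DEFAULT_DT, tol_rel: float = 0.01,
                        lo: float = 0.0, hi: float = 64.0,
                        state: np.ndarray | None = None) -> float:
    """Bisect the minimal stimulus amplitude (pA/pF) that elicits an AP.

    Uses a single stimulus from the equilibrated resting state; 1 % relative
    tolerance.
    """
    rest = equilibrate(params, 10_000.0, dt) if state is None else state

    def fires(amp: float) -> bool:
        tr = run_paced_cell(params, 1, 500.0, stim_duration, amp, dt,
                            initial_state=rest, tail=300.0)
        return count_upstrokes(tr.t, tr.Vm) >= 1

    if not fires(hi):
        raise RangeError(f"no AP even at amplitude {hi} pA/pF")
    while (hi - lo) > tol_rel * hi:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
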