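"""2D monodomain tissue: geometries, Rush-Larsen stepping, S1-S2 protocol.

The tissue is a square sheet of nodes coupled by the monodomain
reaction-diffusion equation ``dVm/dt = D lap(Vm) - (I_ion - I_stim)/Cm`` with
no-flux (mirrored ghost node) borders: the planes are fully insulated, with no
openings such as pulmonary veins.  Voltage diffuses with an effective
coefficient ``D_eff = D_baseline * m_D`` taken from the profile.  Integration
is forward Euler for voltage and concentrations and exact exponential
(Rush-Larsen) relaxation for every gating variable; the explicit diffusion
step enforces ``dt <= 0.9 * dx^2 / (4 D_eff)``.

Two membrane models can populate the nodes: the full ionic model
(``afpom.cell_model``) and the fast two-variable surrogate
(``afpom.synthetic_data``), which honors the same protocol/analysis contracts
and is the default for desk-scale work.

The arrhythmia-induction protocol is cross-field S1-S2: planar S1 beats from a
left-edge band at 1 Hz, then a premature S2 over the inferior-left quadrant,
timed (by default) just past the strip-measured APD90 so it lands in the
vulnerable window.  Movies are stored at 1 kHz regardless of the integration
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from . import cell_model as cm
from . import synthetic_data as sd
from .cell_model import BaselineParameters, IonicProfile
from .drug_model import DrugSpec, apply_drug
from .errors import (NumericalStateError, PropagationError, RangeError,
                     StabilityError)

# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

#: baseline diffusion coefficient (cm^2/ms), calibrated once so that a planar
#: surrogate wave at the reference spacing runs at ~40 cm/s, the slowed
#: conduction of chronic-AF atrial tissue (healthy atrium is faster, but at
#: >= 150 ms APD a faster wave could never reenter a 4 cm sheet).
D_BASELINE = 0.0055

DX_REFERENCE = 0.01  # cm, node spacing of the full-scale planes


@dataclass(frozen=True)
class TissueGeometry:
    nx: int
    ny: int
    dx: float  # cm
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise RangeError("grids below 8x8 are not meaningful tissue")
        if not self.dx > 0:
            raise RangeError("dx must be > 0")

    @property
    def area(self) -> float:
        """Plane area in cm^2."""
        return (self.nx * self.dx) * (self.ny * self.dx)


def build_geometry(size_label: str | None = None, nx: int | None = None,
                   ny: int | None = None, dx: float | None = None) -> TissueGeometry:
    """'normal' -> 400x400 @ 0.01 cm (16 cm^2); 'dilated' -> 450x450 (20.25 cm^2).

    Custom geometries pass ``nx, ny, dx`` explicitly.
    """
    if size_label is not None:
        if size_label == "normal":
            return TissueGeometry(400, 400, DX_REFERENCE, "normal")
        if size_label == "dilated":
            return TissueGeometry(450, 450, DX_REFERENCE, "dilated")
        raise RangeError(f"unknown geometry label {size_label!r}")
    if nx is None or ny is None or dx is None:
        raise RangeError("custom geometry requires nx, ny and dx")
    return TissueGeometry(nx, ny, dx, "custom")


def desk_geometry(size_label: str, n: int = 100) -> TissueGeometry:
    """Reduced node-count version of a named plane, same physical area."""
    full = build_geometry(size_label)
    dx = full.nx * full.dx / n
    return TissueGeometry(n, n, dx, size_label)


# ---------------------------------------------------------------------------
# elementary updates
# ---------------------------------------------------------------------------

def rush_larsen_step(w: float, w_inf: float, tau: float, dt: float) -> float:
    """Exact relaxation of a gating variable over one step."""
    if not tau > 0:
        raise RangeError(f"tau must be > 0, got {tau!r}")
    if not dt > 0:
        raise RangeError(f"dt must be > 0, got {dt!r}")
    return w_inf + (w - w_inf) * math.exp(-dt / tau)


def stability_dt(D_eff: float, dx: float, safety: float = 0.9) -> float:
    """Largest admissible explicit-diffusion step for (D_eff, dx)."""
    if D_eff <= 0:
        return math.inf
    return safety * dx * dx / (4.0 * D_eff)


def check_stability(D_eff: float, dx: float, dt: float) -> None:
    bound = stability_dt(D_eff, dx)
    if dt > bound:
        raise StabilityError(
            f"dt={dt} ms violates the diffusion stability bound for "
            f"D_eff={D_eff}, dx={dx}; use dt <= {bound:.6g} ms")


@njit(cache=True, fastmath=True)
def _laplacian(V, out, inv_dx2):  # pragma: no cover - numba
    ny, nx = V.shape
    for j in range(ny):
        jm = j - 1 if j > 0 else 1
        jp = j + 1 if j < ny - 1 else ny - 2
        for i in range(nx):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < nx - 1 else nx - 2
            out[j, i] = (V[jm, i] + V[jp, i] + V[j, im] + V[j, ip]
                         - 4.0 * V[j, i]) * inv_dx2


@njit(cache=True, fastmath=True)
def _ms_tissue_advance(v, h, vbuf, tin, tout, topen, tclose, vgate,
                       D, dx, dt, n_steps, stim):  # pragma: no cover - numba
    """Advance the surrogate plane n_steps with a frozen stimulus field.

    Single fused pass per step: reads ``v``, writes ``vbuf`` (diffusion via
    mirrored neighbors inline), then swaps roles.  Returns 0 if the final
    field sits in ``v``, 1 if in ``vbuf`` (caller copies back when needed).
    """
    ny, nx = v.shape
    inv_dx2 = 1.0 / (dx * dx)
    a_open = math.exp(-dt / topen)
    a_close = math.exp(-dt / tclose)
    src, dst = v, vbuf
    for _ in range(n_steps):
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for i in range(nx):
                im = i - 1 if i > 0 else 1
                ip = i + 1 if i < nx - 1 else nx - 2
                vv = src[j, i]
                lap = (src[jm, i] + src[jp, i] + src[j, im] + src[j, ip]
                       - 4.0 * vv) * inv_dx2
                hh = h[j, i]
                dv = (hh * vv * vv * (1.0 - vv) / tin - vv / tout
                      + stim[j, i] + D * lap)
                if vv < vgate:
                    h[j, i] = 1.0 + (hh - 1.0) * a_open
                else:
                    h[j, i] = hh * a_close
                vv += dt * dv
                if vv < -0.1:
                    vv = -0.1
                dst[j, i] = vv
        src, dst = dst, src
    return 0 if src is v else 1


@njit(cache=True, fastmath=True)
def _ionic_tissue_advance(S, p, D, dx, dt, n_steps, stim):  # pragma: no cover
    """Advance the ionic-model plane n_steps with a frozen stimulus field.

    ``S`` has shape (ny, nx, N_STATES), C-order so per-node state is
    contiguous.
    """
    ny, nx, ns = S.shape
    V = np.empty((ny, nx))
    lap = np.empty((ny, nx))
    dout = np.zeros(ns)
    winf = np.zeros(ns)
    tau = np.zeros(ns)
    inv_dx2 = 1.0 / (dx * dx)
    for _ in range(n_steps):
        for j in range(ny):
            for i in range(nx):
                V[j, i] = S[j, i, 0]
        _laplacian(V, lap, inv_dx2)
        for j in range(ny):
            for i in range(nx):
                s = S[j, i]
                cm.ionic_rates(s, p, stim[j, i], dout, winf, tau)
                s[0] += dt * (dout[0] + D * lap[j, i])
                for g in range(1, 12):
                    s[g] = winf[g] + (s[g] - winf[g]) * math.exp(-dt / tau[g])
                s[12] += dt * dout[12]
                s[13] += dt * dout[13]
                if s[12] < 1e-9:
                    s[12] = 1e-9
                if s[13] < 1e-9:
                    s[13] = 1e-9


# ---------------------------------------------------------------------------
# tissue state
# ---------------------------------------------------------------------------

ModelKind = Literal["ionic", "surrogate"]


@dataclass
class TissueState:
    """Voltage field plus per-node membrane state at time ``t`` (ms)."""

    geometry: TissueGeometry
    model: ModelKind
    t: float = 0.0
    # ionic model storage
    S: np.ndarray | None = None            # (ny, nx, N_STATES)
    params: np.ndarray | None = None       # packed BaselineParameters
    # surrogate storage
    v: np.ndarray | None = None
    h: np.ndarray | None = None
    vbuf: np.ndarray | None = None
    sparams: sd.SurrogateParameters | None = None

    @property
    def Vm(self) -> np.ndarray:
        if self.model == "ionic":
            return self.S[:, :, 0]
        return sd.V_REST_MV + sd.V_SPAN_MV * self.v

    def check_finite(self) -> None:
        f = self.Vm
        if not np.all(np.isfinite(f)):
            j, i = np.argwhere(~np.isfinite(f))[0]
            raise NumericalStateError(
                f"numerical blow-up: non-finite Vm at node (row={j}, col={i}), t={self.t} ms")


def init_tissue(geometry: TissueGeometry, model: ModelKind,
                params: BaselineParameters | None = None,
                sparams: sd.SurrogateParameters | None = None,
                resting_state: np.ndarray | None = None) -> TissueState:
    """Uniform resting plane for either membrane model."""
    ny, nx = geometry.ny, geometry.nx
    if model == "ionic":
        if params is None:
            raise RangeError("ionic tissue needs BaselineParameters")
        rest = resting_state if resting_state is not None else cm.equilibrate(params, 20_000.0)
        S = np.tile(rest, (ny, nx, 1)).astype(np.float64)
        return TissueState(geometry, "ionic", S=S, params=params.as_array())
    if model == "surrogate":
        sp = sparams if sparams is not None else sd.SurrogateParameters()
        return TissueState(geometry, "surrogate",
                           v=np.zeros((ny, nx)), h=np.ones((ny, nx)), sparams=sp)
    raise RangeError(f"unknown model kind {model!r}")


def advance(state: TissueState, D_eff: float, dt: float, n_steps: int,
            stim: np.ndarray | None = None) -> TissueState:
    """Advance ``n_steps`` with a frozen stimulus field; mutates ``state``."""
    check_stability(D_eff, state.geometry.dx, dt)
    ny, nx = state.geometry.ny, state.geometry.nx
    if stim is None:
        stim = np.zeros((ny, nx))
    if state.model == "surrogate":
        sp = state.sparams
        if dt > sp.tau_in / 2:
            raise StabilityError(
                f"dt={dt} too large for surrogate kinetics; use dt <= {sp.tau_in / 2:.4g}")
        if state.vbuf is None or state.vbuf.shape != state.v.shape:
            state.vbuf = np.empty_like(state.v)
        where = _ms_tissue_advance(state.v, state.h, state.vbuf, sp.tau_in,
                                   sp.tau_out, sp.tau_open, sp.tau_close,
                                   sp.v_gate, D_eff, state.geometry.dx, dt,
                                   n_steps, stim)
        if where == 1:
            state.v, state.vbuf = state.vbuf, state.v
    else:
        _ionic_tissue_advance(state.S, state.params, D_eff,
                              state.geometry.dx, dt, n_steps, stim)
    state.t += n_steps * dt
    state.check_finite()
    return state


def step_monodomain(state: TissueState, D_eff: float, dt: float,
                    stim: np.ndarray | None = None) -> TissueState:
    """One forward-Euler/Rush-Larsen monodomain step (5-point Laplacian,
    mirrored no-flux borders)."""
    return advance(state, D_eff, dt, 1, stim)


# ---------------------------------------------------------------------------
# stimulus bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """S1-S2 cross-field induction protocol.

    ``s2_coupling`` of ``None`` selects the adaptive default: the profile's
    strip-measured APD90 plus ``s2_offset`` ms after the last S1 onset.  The
    offset places S2 just past the recovery of excitability (gate reopening
    lags repolarization), inside the vulnerable window.  ``amplitude`` is a
    multiple of the diastolic threshold.
    """

    n_s1: int = 3
    cl: float = 1000.0
    s2_coupling: float | None = None
    s2_offset: float = 60.0
    amplitude: float = 2.0
    duration: float = 3.0
    observation: float = 2000.0
    s1_band_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.s2_coupling is not None and self.s2_coupling <= 0:
            raise RangeError("s2_coupling must be > 0")
        if self.duration >= self.cl:
            raise RangeError("stimulus duration must be below the cycle length")


def s1_mask(geometry: TissueGeometry, band_cm: float = 0.5) -> np.ndarray:
    """Left-edge stimulation band of physical width ``band_cm`` (>= 2 columns).

    A fixed physical width keeps the stimulated volume-to-perimeter ratio
    roughly constant across grid resolutions, so a '2x diastolic threshold'
    amplitude excites the band interior despite diffusive loading.
    """
    cols = max(2, int(round(band_cm / geometry.dx)))
    m = np.zeros((geometry.ny, geometry.nx))
    m[:, :cols] = 1.0
    return m


def s2_mask(geometry: TissueGeometry) -> np.ndarray:
    """Inferior-left quadrant: rows >= ny/2, columns < nx/2."""
    m = np.zeros((geometry.ny, geometry.nx))
    m[geometry.ny // 2:, : geometry.nx // 2] = 1.0
    return m


def surrogate_threshold(sp: sd.SurrogateParameters, stim_duration: float = 3.0,
                        dt: float = 0.05, lo: float = 0.0, hi: float = 2.0,
                        tol_rel: float = 0.01) -> float:
    """Diastolic threshold (bisection) of the surrogate cell, in v-units/ms."""
    starts = np.array([10.0])

    def fires(amp: float) -> bool:
        n = 420
        tt = np.empty(n)
        vv = np.empty(n)
        _, _, n_rec = sd.ms_integrate_cell(
            0.0, 1.0, sp.tau_in, sp.tau_out, sp.tau_open, sp.tau_close,
            sp.v_gate, 400.0, dt, starts, stim_duration, amp, 1.0, tt, vv)
        return vv[:n_rec].max() > sd.V_REST_MV + 0.8 * sd.V_SPAN_MV

    if not fires(hi):
        raise PropagationError(f"surrogate refuses to fire at amplitude {hi}")
    while (hi - lo) > tol_rel * hi:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# conduction-velocity measurement
# ---------------------------------------------------------------------------

def measure_cv(geometry: TissueGeometry, D_eff: float,
               model: ModelKind = "surrogate",
               params: BaselineParameters | None = None,
               sparams: sd.SurrogateParameters | None = None,
               dt: float | None = None, activation_mv: float = -40.0) -> float:
    """Planar-wave conduction velocity (cm/s) between two probe columns.

    Stimulates the left-edge band once and times the activation (-40 mV
    upstroke crossing) at two columns >= 1 cm apart on the middle row.
    """
    if D_eff <= 0:
        raise PropagationError("no diffusion, no propagation (D_eff <= 0)")
    state = init_tissue(geometry, model, params=params, sparams=sparams)
    if dt is None:
        dt = min(0.5 * stability_dt(D_eff, geometry.dx), 0.05)
    col_a = int(0.2 * geometry.nx)
    sep_nodes = max(int(math.ceil(1.0 / geometry.dx)), 4)
    col_b = col_a + sep_nodes
    if col_b >= geometry.nx - 2:
        col_b = geometry.nx - 3
    if (col_b - col_a) * geometry.dx < 0.5:
        raise RangeError("strip too short to place probes >= 0.5 cm apart")
    row = geometry.ny // 2

    if model == "surrogate":
        amp = 2.0 * surrogate_threshold(state.sparams, dt=dt)
    else:
        amp = 2.0 * cm.diastolic_threshold(params)
    stim = s1_mask(geometry) * amp
    zero = np.zeros_like(stim)

    t_a = t_b = None
    sub = max(1, int(round(0.5 / dt)))  # check every ~0.5 ms
    t_max = 10.0 * geometry.nx * geometry.dx / 0.01  # generous: 1 cm/s floor
    stim_dur = 3.0
    while state.t < t_max:
        cur = stim if state.t < stim_dur else zero
        advance(state, D_eff, dt, sub, cur)
        vm = state.Vm
        if t_a is None and vm[row, col_a] >= activation_mv:
            t_a = state.t
        if vm[row, col_b] >= activation_mv:
            t_b = state.t
            break
    if t_a is None or t_b is None or t_b <= t_a:
        raise PropagationError("planar wave failed to reach the distal probe")
    dist_cm = (col_b - col_a) * geometry.dx
    return dist_cm / (t_b - t_a) * 1000.0


# ---------------------------------------------------------------------------
# S1-S2 simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Downsampled voltage movie plus protocol landmarks."""

    movie: np.ndarray          # (n_frames, ny, nx) float32, mV, 1 kHz
    movie_t0: float            # ms, absolute time of frame 0
    dt_out: float              # ms between frames (1.0)
    s2_time: float             # ms, S2 onset
    geometry: TissueGeometry
    profile_id: str
    condition: str = "basal"
    failed: bool = False
    failure_reason: str | None = None
    apd90_strip: float | None = None


def run_s1s2(profile: IonicProfile, geometry: TissueGeometry,
             drug: DrugSpec | None = None,
             protocol: StimulusProtocol | None = None,
             model: ModelKind = "surrogate",
             base_params: BaselineParameters | None = None,
             base_sparams: sd.SurrogateParameters | None = None,
             apd90_hint: float | None = None,
             dt: float | None = None,
             D_baseline: float = D_BASELINE,
             movie_margin: float = 50.0,
             fast_forward: bool = True) -> SimulationResult:
    """Cross-field S1-S2 run; the movie covers S2 minus ``movie_margin``
    through the end of the observation window, at 1 kHz.

    ``apd90_hint`` short-circuits the adaptive coupling (pass the calibration
    strip's APD90); without it a single-cell run estimates APD90.
    """
    protocol = protocol or StimulusProtocol()
    D_eff = D_baseline * profile.m_D

    if model == "surrogate":
        sp0 = base_sparams if base_sparams is not None else sd.SurrogateParameters()
        sp = sd.surrogate_from_profile(sp0, profile, drug)
        state = init_tissue(geometry, "surrogate", sparams=sp)
        thr = surrogate_threshold(sp)
        if apd90_hint is None:
            t, vm, stim_times = sd.run_paced_surrogate(sp, 3, protocol.cl,
                                                       stim_amplitude=2 * thr)
            apd90_hint = _quick_apd90(t, vm, stim_times[-1])
    else:
        bp = base_params if base_params is not None else cm.apply_caf_remodeling(BaselineParameters())
        p = cm.scale_profile(bp, profile)
        if drug is not None:
            p = apply_drug(p, drug)
        state = init_tissue(geometry, "ionic", params=p)
        thr = cm.diastolic_threshold(p)
        if apd90_hint is None:
            tr = cm.run_paced_cell(p, 3, protocol.cl, stim_amplitude=2 * thr)
            apd90_hint = _quick_apd90(tr.t, tr.Vm, tr.stim_times[-1])

    coupling = protocol.s2_coupling
    if coupling is None:
        coupling = (apd90_hint if apd90_hint is not None
                    else 0.75 * protocol.cl) + protocol.s2_offset

    dt_cap = 0.1 if model == "surrogate" else 0.02
    if model == "surrogate":
        # profiles with m_gNa > 1 shrink tau_in; stay under the kinetic bound
        dt_cap = min(dt_cap, state.sparams.tau_in / 2.5)
    if dt is None:
        dt = dt_cap
    # the requested dt is an upper bound; clamp to the stability limit
    dt = min(dt, 0.7 * stability_dt(D_eff, geometry.dx), dt_cap)

    amp = protocol.amplitude * thr
    m_s1 = s1_mask(geometry, protocol.s1_band_cm) * amp
    m_s2 = s2_mask(geometry) * amp
    zero = np.zeros_like(m_s1)

    last_s1 = protocol.cl * (protocol.n_s1 - 1)
    s2_time = last_s1 + coupling
    t_end = s2_time + protocol.observation
    movie_t0 = max(0.0, s2_time - movie_margin)
    n_frames = int(round(t_end - movie_t0)) + 1
    movie = np.empty((n_frames, geometry.ny, geometry.nx), dtype=np.float32)

    # stimulus schedule: (onset, offset, field)
    events = [(protocol.cl * k, protocol.cl * k + protocol.duration, m_s1)
              for k in range(protocol.n_s1)]
    events.append((s2_time, s2_time + protocol.duration, m_s2))

    def stim_at(t: float) -> np.ndarray:
        for on, off, fld in events:
            if on <= t < off:
                return fld
        return zero

    def next_onset(t: float) -> float:
        # inclusive: an event starting exactly now must not be jumped over
        upcoming = [on for on, _, _ in events if on >= t]
        return min(upcoming) if upcoming else math.inf

    def event_active(t: float) -> bool:
        return any(on - 1.0 <= t < off + 1.0 for on, off, _ in events)

    frame = 0
    result = SimulationResult(movie=movie, movie_t0=movie_t0, dt_out=1.0,
                              s2_time=s2_time, geometry=geometry,
                              profile_id=profile.profile_id,
                              apd90_strip=apd90_hint)
    # integrate in 1 ms blocks so stimuli (>= 3 ms) and recording stay aligned
    sub = max(1, int(round(1.0 / dt)))
    dt_eff = 1.0 / sub
    n_ms = int(round(t_end))
    quiescent_mv = sd.V_REST_MV + 2.0
    ms = 0
    try:
        while ms <= n_ms:
            t = float(ms)
            if t >= movie_t0 and frame < n_frames:
                movie[frame] = state.Vm
                frame += 1
            if ms == n_ms:
                break
            # diastolic fast-forward (surrogate only: gate relaxation is
            # closed-form at rest) once the plane is quiescent
            if (fast_forward and model == "surrogate" and ms % 20 == 0
                    and not event_active(t)
                    and float(state.Vm.max()) < quiescent_mv):
                target = min(next_onset(t) - 5.0, float(n_ms))
                if target > t + 25.0:
                    gap = target - t
                    sp = state.sparams
                    state.v *= math.exp(-gap / sp.tau_out)
                    state.h = 1.0 + (state.h - 1.0) * math.exp(-gap / sp.tau_open)
                    rest_field = state.Vm.copy()
                    for fill_ms in range(ms + 1, int(target)):
                        if float(fill_ms) >= movie_t0 and frame < n_frames:
                            movie[frame] = rest_field
                            frame += 1
                    ms = int(target)
                    state.t = float(ms)
                    if math.isinf(next_onset(float(ms))) and float(ms) > s2_time:
                        # post-S2 extinction: remaining frames are rest
                        while frame < n_frames:
                            movie[frame] = rest_field
                            frame += 1
                        ms = n_ms
                        continue
                    continue
            advance(state, D_eff, dt_eff, sub, stim_at(t))
            ms += 1
    except NumericalStateError as exc:
        result.failed = True
        result.failure_reason = str(exc)
        result.movie = movie[:frame]
    else:
        result.movie = movie[:frame]
    return result


def run_s1s2_induction(profile: IonicProfile, geometry: TissueGeometry,
                       drug: DrugSpec | None = None,
                       protocol: StimulusProtocol | None = None,
                       offsets: tuple[float, ...] = (60.0, 100.0),
                       **kwargs):
    """Programmed stimulation: try S2 at a short series of coupling offsets.

    The vulnerable window shifts with a profile's APD and recovery kinetics, so
    inducibility is assessed like clinical programmed stimulation: S2 is
    delivered at ``APD90 + offset`` for each offset in turn, and the run is
    labeled induced as soon as one coupling induces reentry.  Returns
    ``(result, outcome, tracks)`` for the inducing attempt, or for the last
    attempt when none induces.
    """
    from .reentry_analysis import analyze_simulation

    protocol = protocol or StimulusProtocol()
    last = None
    for off in offsets:
        proto = replace_protocol(protocol, s2_offset=off, s2_coupling=None)
        result = run_s1s2(profile, geometry, drug, proto, **kwargs)
        outcome, tracks = analyze_simulation(result)
        last = (result, outcome, tracks)
        if outcome.induced:
            return last
    return last


def replace_protocol(protocol: StimulusProtocol, **updates) -> StimulusProtocol:
    from dataclasses import replace as _replace

    return _replace(protocol, **updates)


def save_movie(result: SimulationResult, path) -> None:
    """Write a simulation movie as HDF5: dataset ``Vm[t, y, x]`` with dx,
    dt_out, timing landmarks and the geometry label as attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("Vm", data=result.movie, compression="gzip",
                             compression_opts=4)
        d.attrs["units"] = "mV"
        d.attrs["dx_cm"] = result.geometry.dx
        d.attrs["dt_out_ms"] = result.dt_out
        d.attrs["t0_ms"] = result.movie_t0
        d.attrs["s2_time_ms"] = result.s2_time
        d.attrs["geometry"] = result.geometry.label
        d.attrs["nx"] = result.geometry.nx
        d.attrs["ny"] = result.geometry.ny
        d.attrs["profile_id"] = result.profile_id
        d.attrs["condition"] = result.condition
        d.attrs["failed"] = result.failed


def load_movie(path) -> SimulationResult:
    """Read a movie written by :func:`save_movie`."""
    import h5py

    with h5py.File(path, "r") as f:
        d = f["Vm"]
        geometry = TissueGeometry(int(d.attrs["nx"]), int(d.attrs["ny"]),
                                  float(d.attrs["dx_cm"]),
                                  str(d.attrs["geometry"]))
        return SimulationResult(
            movie=d[...], movie_t0=float(d.attrs["t0_ms"]),
            dt_out=float(d.attrs["dt_out_ms"]),
            s2_time=float(d.attrs["s2_time_ms"]), geometry=geometry,
            profile_id=str(d.attrs["profile_id"]),
            condition=str(d.attrs["condition"]),
            failed=bool(d.attrs["failed"]))


def _quick_apd90(t: np.ndarray, vm: np.ndarray, last_stim: float) -> float | None:
    """APD90 of the beat at ``last_stim`` (peak-onward crossing), or None."""
    w = t >= last_stim
    tt, vv = t[w], vm[w]
    if len(vv) < 5 or vv.max() < -40.0:
        return None
    k_up = int(np.argmax(np.diff(vv)))
    k_peak = k_up + int(np.argmax(vv[k_up:]))
    rmp = vv.min()
    level = vv[k_peak] - 0.9 * (vv[k_peak] - rmp)
    below = np.nonzero(vv[k_peak:] <= level)[0]
    if len(below) == 0:
        return None
    return float(tt[k_peak + below[0]] - tt[k_up])
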