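"""Phase mapping, singularity detection, rotor tracking, outcome labeling.

Phase is the argument of the analytic signal (Hilbert transform) of each
node's mean-subtracted voltage over the analysis window.  A phase singularity
(SP) is a point surrounded by all phases 0..2pi, detected where the discrete
line integral of wrapped phase differences around a 2x2 plaquette is +-2pi;
the integral's sign is the chirality.  SPs are linked into rotor tracks by
greedy nearest-neighbor association (matching charge, bounded step, short
gaps tolerated), a track's rotation count is the unwrapped phase advance on a
small ring around its centroid divided by 2pi, and tracks persisting for less
than one full rotation are discarded.  A simulation is labeled *induced* when
at least one track survives that filter after S2, and *maintained* when, in
addition, the tissue is still active in the final stretch of the observation
window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .errors import RangeError

#: reserved marker for nodes whose signal is constant (phase undefined)
UNDEFINED_PHASE = np.nan


@dataclass
class PhaseFrame:
    phase: np.ndarray  # (ny, nx), values in (-pi, pi] or NaN where undefined
    t: float           # ms


@dataclass(frozen=True)
class SingularityPoint:
    x: float
    y: float
    t: float
    charge: int  # +-1


@dataclass
class RotorTrack:
    points: list[SingularityPoint]
    rotations: float = 0.0
    chirality: int = 0

    @property
    def t_start(self) -> float:
        return self.points[0].t

    @property
    def t_end(self) -> float:
        return self.points[-1].t


@dataclass(frozen=True)
class Outcome:
    induced: bool
    maintained: bool
    n_tracks: int

    def __post_init__(self) -> None:
        if self.maintained and not self.induced:
            raise RangeError("maintained implies induced")


# ---------------------------------------------------------------------------
# phase mapping
# ---------------------------------------------------------------------------

def phase_map(movie: np.ndarray, t0: float = 0.0, dt_out: float = 1.0,
              flat_tol: float = 1e-6, chunk: int = 4096) -> list[PhaseFrame]:
    """Analytic-signal phase of each node over the window.

    ``movie`` is (n_frames, ny, nx).  Constant nodes get the reserved
    undefined marker (NaN) and never contribute singularities.  Phase is
    invariant to any constant voltage offset because the signal is
    mean-subtracted per node.
    """
    nt, ny, nx = movie.shape
    flat = movie.reshape(nt, ny * nx).astype(np.float64)
    flat = flat - flat.mean(axis=0, keepdims=True)
    phases = np.empty((nt, ny * nx), dtype=np.float64)
    ptp = flat.max(axis=0) - flat.min(axis=0)
    dead = ptp < flat_tol
    for start in range(0, ny * nx, chunk):
        sl = slice(start, min(start + chunk, ny * nx))
        phases[:, sl] = np.angle(hilbert(flat[:, sl], axis=0))
    phases[:, dead] = UNDEFINED_PHASE
    phases = phases.reshape(nt, ny, nx)
    return [PhaseFrame(phases[k], t0 + k * dt_out) for k in range(nt)]


def _wrap(dp: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    return np.pi - np.mod(np.pi - dp, 2.0 * np.pi)


# ---------------------------------------------------------------------------
# singularity detection
# ---------------------------------------------------------------------------

def detect_singularities(frame: PhaseFrame, tol: float = 0.5) -> list[SingularityPoint]:
    """SPs where the winding number around a 2x2 plaquette is +-1.

    The reported position is the plaquette center; charge is the sign of the
    winding integral.  Plaquettes touching an undefined node are skipped.
    """
    P = frame.phase
    w = (_wrap(P[:-1, 1:] - P[:-1, :-1])     # top edge, left -> right
         + _wrap(P[1:, 1:] - P[:-1, 1:])     # right edge, down
         + _wrap(P[1:, :-1] - P[1:, 1:])     # bottom edge, right -> left
         + _wrap(P[:-1, :-1] - P[1:, :-1]))  # left edge, up
    with np.errstate(invalid="ignore"):
        pos = w > (2.0 * np.pi - tol)
        neg = w < -(2.0 * np.pi - tol)
    pts: list[SingularityPoint] = []
    for sign, mask in ((1, pos), (-1, neg)):
        jj, ii = np.nonzero(np.nan_to_num(mask, nan=False))
        for j, i in zip(jj, ii):
            pts.append(SingularityPoint(x=i + 0.5, y=j + 0.5, t=frame.t, charge=sign))
    return pts


# ---------------------------------------------------------------------------
# rotor tracking
# ---------------------------------------------------------------------------

def _ring_offsets(radius: int = 3) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            r = math.hypot(dx, dy)
            if radius - 0.5 <= r <= radius + 0.5:
                offs.append((dy, dx))
    return offs


def _track_rotations(track: "RotorTrack", frames: Sequence[PhaseFrame],
                     dt_out: float, t0: float, radius: int = 3) -> float:
    """|unwrapped phase advance| / 2pi on a ring around the track centroid."""
    cy = float(np.mean([p.y for p in track.points]))
    cx = float(np.mean([p.x for p in track.points]))
    k0 = int(round((track.t_start - t0) / dt_out))
    k1 = int(round((track.t_end - t0) / dt_out))
    if k1 <= k0:
        return 0.0
    # the analytic-signal phase is distorted near the window edges (spectral
    # leakage); measure the advance on the trimmed interior and rescale to
    # the full track duration
    span = k1 - k0
    trim = min(int(0.1 * span), max(2, int(0.1 * span)))
    a0, a1 = k0 + trim, k1 - trim
    if a1 - a0 < max(2, span // 2):
        a0, a1, trim = k0, k1, 0
    scale = span / (a1 - a0)
    ny, nx = frames[0].phase.shape
    advances = []
    for dy, dx in _ring_offsets(radius):
        j = int(round(cy + dy))
        i = int(round(cx + dx))
        if not (0 <= j < ny and 0 <= i < nx):
            continue
        series = np.array([frames[k].phase[j, i] for k in range(a0, a1 + 1)])
        if np.any(np.isnan(series)):
            continue
        unwrapped = np.unwrap(series)
        advances.append((unwrapped[-1] - unwrapped[0]) / (2.0 * np.pi))
    if not advances:
        return 0.0
    return float(abs(np.median(advances)) * scale)


def track_rotors(sp_frames: Sequence[Sequence[SingularityPoint]], dt_out: float,
                 link_radius: float = 10.0,
                 phase_frames: Sequence[PhaseFrame] | None = None,
                 t0: float | None = None, max_gap: int = 2,
                 min_rotations: float = 1.0,
                 ring_radius: int = 3) -> list[RotorTrack]:
    """Greedy nearest-neighbor linking of per-frame SPs into tracks.

    SPs link only to charge-matching track heads within ``link_radius`` nodes,
    with gaps up to ``max_gap`` frames tolerated.  When ``phase_frames`` is
    supplied, each track's rotation count is measured from the phase advance
    on a ring of ``ring_radius`` nodes around the track centroid, and tracks
    below ``min_rotations`` are discarded; without phase frames no rotation
    filter is applied and ``rotations`` stays 0.
    """
    open_tracks: list[RotorTrack] = []
    done: list[RotorTrack] = []
    for k, pts in enumerate(sp_frames):
        t = (t0 if t0 is not None else 0.0) + k * dt_out
        unmatched = list(pts)
        # close stale tracks
        still_open = []
        for tr in open_tracks:
            if (t - tr.t_end) / dt_out > max_gap + 0.5:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        # greedy association: nearest pair first
        pairs = []
        for ti, tr in enumerate(open_tracks):
            head = tr.points[-1]
            for pi, p in enumerate(unmatched):
                d = math.hypot(p.x - head.x, p.y - head.y)
                if d <= link_radius and p.charge == tr.chirality:
                    pairs.append((d, ti, pi))
        pairs.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for d, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            open_tracks[ti].points.append(unmatched[pi])
            used_t.add(ti)
            used_p.add(pi)
        for pi, p in enumerate(unmatched):
            if pi not in used_p:
                open_tracks.append(RotorTrack(points=[p], chirality=p.charge))
    done.extend(open_tracks)
    if phase_frames is not None:
        base_t = t0 if t0 is not None else 0.0
        kept = []
        for tr in done:
            tr.rotations = _track_rotations(tr, phase_frames, dt_out, base_t,
                                            ring_radius)
            if tr.rotations >= min_rotations:
                kept.append(tr)
        return kept
    return done


# ---------------------------------------------------------------------------
# outcome rule
# ---------------------------------------------------------------------------

def classify_outcome(tracks: Sequence[RotorTrack], movie_tail: np.ndarray,
                     quiescent_mv: float = -60.0) -> Outcome:
    """Induced iff a track survives the >=1-full-rotation filter; maintained
    iff induced and any node exceeds ``quiescent_mv`` in the tail window."""
    induced = len(tracks) > 0
    active_tail = bool(np.nanmax(movie_tail) > quiescent_mv) if movie_tail.size else False
    return Outcome(induced=induced, maintained=induced and active_tail,
                   n_tracks=len(tracks))


def analyze_simulation(result, link_radius: float = 10.0,
                       tail_ms: float = 200.0,
                       min_rotations: float = 1.0) -> tuple[Outcome, list[RotorTrack]]:
    """Full post-S2 analysis of a ``tissue_sim.SimulationResult``."""
    k_s2 = int(round((result.s2_time - result.movie_t0) / result.dt_out))
    window = result.movie[max(k_s2, 0):]
    if window.shape[0] < 8 or result.failed:
        return Outcome(False, False, 0), []
    n_tail = int(round(tail_ms / result.dt_out))
    # activity envelope: frames with any node above the quiescence level
    active = np.nonzero(window.max(axis=(1, 2)) > -60.0)[0]
    if len(active) == 0:
        return Outcome(False, False, 0), []
    # phase analysis only needs the active span (plus a short margin)
    k_hi = min(int(active[-1]) + int(100 / result.dt_out), window.shape[0])
    tail = window[-n_tail:]
    window = window[:k_hi]
    frames = phase_map(window, t0=result.s2_time, dt_out=result.dt_out)
    sp_frames = [detect_singularities(f) for f in frames]
    tracks = track_rotors(sp_frames, result.dt_out, link_radius,
                          phase_frames=frames, t0=result.s2_time,
                          min_rotations=min_rotations)
    outcome = classify_outcome(tracks, tail)
    return outcome, tracks


def tracks_table(tracks: Sequence[RotorTrack]):
    """CSV-ready flat view of SPs with track ids and rotation counts."""
    import pandas as pd

    rows = []
    for tid, tr in enumerate(tracks):
        for p in tr.points:
            rows.append({"track_id": tid, "t": p.t, "x": p.x, "y": p.y,
                         "charge": p.charge, "rotations": tr.rotations,
                         "chirality": tr.chirality})
    return pd.DataFrame(rows)
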