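"""Coupled segmental wall mechanics + circulation beat engine.

Each ventricle's cavity pressure is assembled from its wall-volume-weighted
mean segment tension T_mean(t) in tension-scaled elastance form,

    P = P_passive(V) + E_max * T_mean(t) * (V - V_d),

with an exponential end-diastolic P(V) (scaled by the same passive
stiffening factor as the segment passive element).  The linear systolic
P(V) relation stands in for the wall-geometry factor: without sarcomere
length feedback from the cavity a purely geometric (thick-walled-sphere)
gain grows as the cavity empties and has no stable end-systolic volume.  Segment afterload is
coupled back to the instantaneous cavity pressure (scaled by
``pressure_coupling``), and to the chamber's force imbalance (scaled by
``share_coupling``): a segment producing less tension than the chamber mean
is stretched by its neighbors, a segment producing more unloads into them.
Late-activated segments therefore undergo systolic pre-stretch and shorten
late against the pressure generated by early ones -- the mechanism by which
dyssynchrony prolongs the electromechanical delay, resynchronization
shortens it, and mechanical unloading (LVAD) shortens it further.

The engine advances all myofilament segments, the two cavity pressures and
the lumped circulation on a common fixed step (default 0.1 ms) inside one
JIT-compiled loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import rice
from .circulation import (CirculationParams, CirculationState, LVADParams,
                          _circ_step)
from .util import ConfigurationError, InstabilityError


@dataclass(frozen=True)
class WallParams:
    """Reduced-order cavity mechanics of one ventricle."""

    wall_volume: float             # mL, used for ATP wall weighting
    e_max: float                   # mmHg/mL, systolic elastance at T_mean = 1
    v_d: float                     # mL, zero-active-pressure volume
    pas_p0: float                  # mmHg, EDPVR scale (before HF stiffening)
    pas_k: float                   # 1/mL, EDPVR exponent
    v0: float                      # mL, unstressed cavity volume

    def vector(self) -> np.ndarray:
        return np.array([self.wall_volume, self.e_max, self.v_d,
                         self.pas_p0, self.pas_k, self.v0])


#: defaults tuned so the failing (x5-stiffened) sinus baseline lands near
#: EDV 88 mL, EF 38%, CO 3.4 L/min at BCL 600 ms; see docs/methods.md
LV_WALL_DEFAULT = WallParams(wall_volume=130.0, e_max=4.6, v_d=10.0,
                             pas_p0=0.3, pas_k=0.04, v0=40.0)
RV_WALL_DEFAULT = WallParams(wall_volume=45.0, e_max=1.6, v_d=10.0,
                             pas_p0=0.12, pas_k=0.035, v0=45.0)


@njit(cache=True)
def _wall_pressure(v, tension, wp, pscale):
    """Cavity pressure from volume and mean normalized wall tension."""
    vw, emax, vd, p0, k, v0 = wp[0], wp[1], wp[2], wp[3], wp[4], wp[5]
    if v > v0:
        pas = pscale * p0 * (np.exp(k * (v - v0)) - 1.0)
    else:
        pas = pscale * p0 * k * (v - v0)
    act = emax * tension * (v - vd)
    if act < 0.0:
        act = 0.0
    return pas + act


@njit(cache=True)
def _run_coupled(yseg, seg_p, delays, weights, chamber, ca_tab, ca_dt, bcl,
                 circ_p, vols, q_lvad, wp_lv, wp_rv, pscale, coupling,
                 share, dt, n_steps, stride, scal_out, seg_out):
    n_seg = yseg.shape[0]
    n_ca = ca_tab.shape[0]
    flows = np.empty(8)
    fprev = np.zeros(n_seg)
    p_lv = 0.0
    p_rv = 0.0
    t_lv = 0.0
    t_rv = 0.0
    n_out = 0
    for step in range(n_steps):
        t = step * dt
        t_lv_new = 0.0
        t_rv_new = 0.0
        rec = step % stride == 0
        for i in range(n_seg):
            tt = t - delays[i]
            if tt < 0.0:
                ca = ca_tab[0]
            else:
                u = (tt / ca_dt) % n_ca
                i0 = int(u)
                w = u - i0
                i1 = i0 + 1
                if i1 >= n_ca:
                    i1 = 0
                ca = ca_tab[i0] * (1.0 - w) + ca_tab[i1] * w
            if chamber[i] == 0:
                pcav = p_lv
                t_mean = t_lv
            else:
                pcav = p_rv
                t_mean = t_rv
            ext = coupling * (pcav if pcav > 0.0 else 0.0)
            # force sharing: weaker-than-average segments are stretched by
            # their neighbors (previous-step forces; explicit coupling)
            ext += share * (t_mean - fprev[i])
            fa, fp, faft, e, gxbt, sovf = rice._rice_step(
                yseg[i], ca, ext, seg_p, dt, 1)
            fprev[i] = fa
            if chamber[i] == 0:
                t_lv_new += weights[i] * fa
            else:
                t_rv_new += weights[i] * fa
            if rec:
                seg_out[0, i, n_out] = yseg[i, 7]     # SL
                seg_out[1, i, n_out] = fa
                seg_out[2, i, n_out] = e
        t_lv = t_lv_new
        t_rv = t_rv_new
        p_lv = _wall_pressure(vols[6], t_lv, wp_lv, pscale)
        p_rv = _wall_pressure(vols[7], t_rv, wp_rv, pscale)
        _circ_step(vols, circ_p, q_lvad, p_lv, p_rv, dt, flows)
        if rec:
            scal_out[0, n_out] = t
            scal_out[1, n_out] = p_lv
            scal_out[2, n_out] = p_rv
            scal_out[3, n_out] = vols[6]
            scal_out[4, n_out] = vols[7]
            scal_out[5, n_out] = (vols[3] - circ_p[17]) / circ_p[11]  # P_SA
            scal_out[6, n_out] = flows[1]                             # aortic
            scal_out[7, n_out] = q_lvad
            scal_out[8, n_out] = vols.sum()
            n_out += 1
        for k in range(8):
            if vols[k] < 0.0 or not np.isfinite(vols[k]):
                return -(step + 1)
    return n_out


@dataclass
class CoupledTraces:
    """Decimated traces of a coupled mechanics + circulation run."""

    t: np.ndarray
    p_lv: np.ndarray
    p_rv: np.ndarray
    v_lv: np.ndarray
    v_rv: np.ndarray
    p_sa: np.ndarray
    q_aortic: np.ndarray           # mL/ms
    q_lvad: np.ndarray             # mL/ms
    total_volume: np.ndarray
    seg_sl: np.ndarray             # (n_seg, n_samples)
    seg_tension: np.ndarray
    seg_atp: np.ndarray            # 1/s
    bcl: float
    final_circulation: CirculationState

    def beat_slice(self, index: int = -1) -> slice:
        n_beats = int(np.floor((self.t[-1] + (self.t[1] - self.t[0])) / self.bcl))
        idx = index if index >= 0 else n_beats + index
        lo = np.searchsorted(self.t, idx * self.bcl)
        hi = np.searchsorted(self.t, (idx + 1) * self.bcl)
        return slice(lo, hi)


def run_coupled(segments: list, myo_params: rice.MyofilamentParams,
                ca_time: np.ndarray, ca_value: np.ndarray,
                duration: float = 20000.0, bcl: float = 600.0,
                dt: float = 0.1, sample_dt: float = 1.0,
                circulation: CirculationParams | None = None,
                lvad: LVADParams | None = None,
                lv_wall: WallParams = LV_WALL_DEFAULT,
                rv_wall: WallParams = RV_WALL_DEFAULT,
                pressure_coupling: float = 0.0005,
                share_coupling: float = 2.0,
                initial: CirculationState | None = None) -> CoupledTraces:
    """Run the coupled ventricles + circulation for ``duration`` ms.

    ca_value is the steady-state cell transient (mM or uM; mM is converted),
    sampled uniformly over one cycle starting at the stimulus.
    """
    circ = circulation if circulation is not None else CirculationParams()
    dev = lvad if lvad is not None else LVADParams()
    if dt <= 0 or duration < bcl:
        raise ConfigurationError("need dt > 0 and at least one full beat")
    ca_value = np.asarray(ca_value, float)
    if ca_value.max() < 0.05:      # mM input: convert to uM
        ca_value = ca_value * 1000.0
    ca_dt = float(ca_time[1] - ca_time[0])

    active = [s for s in segments if s.activated]
    if not active:
        raise ConfigurationError("no electrically activated segments")
    n_seg = len(active)
    yseg = np.empty((n_seg, rice.N_STATE))
    init = rice.initial_state(myo_params, diastolic_ca=float(ca_value.min()))
    for i in range(n_seg):
        yseg[i] = init.vector()
    delays = np.array([s.delay for s in active])
    chamber = np.array([0 if s.chamber == "lv" else 1 for s in active],
                       dtype=np.int64)
    weights = np.array([s.wall_fraction for s in active])
    # renormalize per chamber over the activated subset
    for ch in (0, 1):
        m = chamber == ch
        if m.any():
            weights[m] = weights[m] / weights[m].sum()

    state = initial if initial is not None else CirculationState.from_params(circ)
    vols = state.volumes.astype(float).copy()
    stride = max(1, int(round(sample_dt / dt)))
    n_steps = int(round(duration / dt))
    n_samples = n_steps // stride + 1
    scal_out = np.zeros((9, n_samples))
    seg_out = np.zeros((3, n_seg, n_samples))

    n_out = _run_coupled(
        yseg, myo_params.vector(), delays, weights, chamber,
        ca_value, ca_dt, bcl, circ.vector(), vols, dev.flow_ml_per_ms,
        lv_wall.vector(), rv_wall.vector(), myo_params.passive_scale,
        pressure_coupling, share_coupling, dt, n_steps, stride, scal_out,
        seg_out)
    if n_out < 0:
        t_fail = (-n_out - 1) * dt
        raise InstabilityError(
            f"coupled run failed at t={t_fail:.1f} ms (negative or non-finite "
            "compartment volume)")

    scal_out = scal_out[:, :n_out]
    seg_out = seg_out[:, :, :n_out]
    final = CirculationState(volumes=vols, lvad_flow=dev.flow_ml_per_ms)
    tr = CoupledTraces(
        t=scal_out[0], p_lv=scal_out[1], p_rv=scal_out[2], v_lv=scal_out[3],
        v_rv=scal_out[4], p_sa=scal_out[5], q_aortic=scal_out[6],
        q_lvad=scal_out[7], total_volume=scal_out[8],
        seg_sl=seg_out[0], seg_tension=seg_out[1], seg_atp=seg_out[2],
        bcl=bcl, final_circulation=final)
    # attach traces back onto the segment models
    for i, seg in enumerate(active):
        seg.strain = (seg_out[0, i] - myo_params.SL0) / myo_params.SL0
        seg.tension = seg_out[1, i]
        seg.atp_rate = seg_out[2, i]
    return tr
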