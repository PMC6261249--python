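"""Closed-loop lumped-parameter circulation with a continuous-flow LVAD.

Eight compartments: LV and RV (volumes tracked here, pressures supplied by
the coupled ventricular wall model), left/right atria, systemic and
pulmonary arteries and veins.  Valves (mitral, aortic, tricuspid, pulmonary)
are ideal diodes in series with a resistance: flow = max(dP, 0)/R.  Atria
are passive compliance chambers.  All compartment pressures follow
P = (V - V_unstressed)/C.

The LVAD is a constant-flow generator drawing blood from the LV apex and
delivering it to the systemic artery (ascending aorta) at a configured mean
rate (default 3 L/min), continuously throughout the cycle; inflow is drawn
from the LV volume balance even in diastole, with no suction guard beyond
the negative-volume error.

Units: pressure mmHg, volume mL, time ms; resistances mmHg*ms/mL,
compliances mL/mmHg.  The default parameter set is tuned so that the
coupled failing baseline in sinus rhythm lands near EDV 88 mL, EF 38%,
CO 3.4 L/min at a 600 ms cycle (see the methods note for the procedure);
every value can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from numba import njit

from .util import ConfigurationError, InstabilityError

# state-vector layout (volumes, mL)
V_PA, V_PV, V_LA, V_SA, V_SV, V_RA, V_LV, V_RV = range(8)
N_COMP = 8
COMP_NAMES = ("pulmonary_artery", "pulmonary_vein", "left_atrium",
              "systemic_artery", "systemic_vein", "right_atrium",
              "left_ventricle", "right_ventricle")


@dataclass(frozen=True)
class CirculationParams:
    """Resistances (mmHg*ms/mL), compliances (mL/mmHg), unstressed volumes (mL)."""

    R_PA: float = 150.0
    R_PV: float = 25.0
    R_MI: float = 25.0
    R_AO: float = 32.0
    R_SA: float = 1700.0
    R_SV: float = 50.0
    R_TR: float = 20.0
    R_PU: float = 8.0
    C_PA: float = 5.0
    C_PV: float = 12.0
    C_LA: float = 12.0
    C_SA: float = 1.6
    C_SV: float = 60.0
    C_RA: float = 20.0
    V0_PA: float = 60.0
    V0_PV: float = 60.0
    V0_LA: float = 30.0
    V0_SA: float = 450.0
    V0_SV: float = 2800.0
    V0_RA: float = 30.0
    total_blood_volume: float = 4300.0

    def __post_init__(self):
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigurationError(f"{f_.name} must be positive")
        unstressed = (self.V0_PA + self.V0_PV + self.V0_LA + self.V0_SA
                      + self.V0_SV + self.V0_RA)
        if self.total_blood_volume <= unstressed:
            raise ConfigurationError(
                "total blood volume must exceed the sum of unstressed volumes")

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, f_.name) for f_ in fields(self)],
                        dtype=np.float64)


_PVEC = [f_.name for f_ in fields(CirculationParams)]
_CP = {name: i for i, name in enumerate(_PVEC)}


@dataclass(frozen=True)
class LVADParams:
    """Constant-flow assist device from the LV to the systemic artery."""

    enabled: bool = False
    mean_flow: float = 3.0        # L/min
    mode: str = "constant-flow"

    def __post_init__(self):
        if self.mean_flow < 0:
            raise ConfigurationError("LVAD flow rate must be non-negative")
        if self.mode != "constant-flow":
            raise ConfigurationError("only the constant-flow mode is modelled")

    @property
    def flow_ml_per_ms(self) -> float:
        return self.mean_flow * 1000.0 / 60000.0 if self.enabled else 0.0


def lvad_flow(lvad: LVADParams, t: float = 0.0) -> float:  # noqa: ARG001
    """Device flow (L/min) at time t: the configured constant rate, or 0."""
    return lvad.mean_flow if lvad.enabled else 0.0


@dataclass
class CirculationState:
    """Volumes (mL) of all compartments; pressures derived from compliances."""

    volumes: np.ndarray = field(
        default_factory=lambda: np.array(
            [110.0, 160.0, 90.0, 600.0, 3100.0, 90.0, 120.0, 120.0]))
    valve_open: dict = field(default_factory=lambda: {
        "mitral": False, "aortic": False, "tricuspid": False, "pulmonary": False})
    lvad_flow: float = 0.0        # instantaneous, mL/ms

    @classmethod
    def from_params(cls, params: CirculationParams) -> "CirculationState":
        """Initial volumes distributing the configured total blood volume
        (the remainder beyond the standard compartment fills goes to the
        systemic veins)."""
        base = np.array([110.0, 160.0, 90.0, 600.0, 0.0, 90.0, 100.0, 100.0])
        base[V_SV] = params.total_blood_volume - base.sum()
        if base[V_SV] <= params.V0_SV * 0.5:
            raise ConfigurationError("total blood volume too small to fill the veins")
        return cls(volumes=base)

    def pressures(self, params: CirculationParams) -> dict:
        p = params
        v = self.volumes
        return {
            "pulmonary_artery": (v[V_PA] - p.V0_PA) / p.C_PA,
            "pulmonary_vein": (v[V_PV] - p.V0_PV) / p.C_PV,
            "left_atrium": (v[V_LA] - p.V0_LA) / p.C_LA,
            "systemic_artery": (v[V_SA] - p.V0_SA) / p.C_SA,
            "systemic_vein": (v[V_SV] - p.V0_SV) / p.C_SV,
            "right_atrium": (v[V_RA] - p.V0_RA) / p.C_RA,
        }

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


def valve_flow(p_upstream: float, p_downstream: float, R: float) -> float:
    """Diode valve: (p_up - p_down)/R when positive, else 0 (mL/ms)."""
    if R <= 0:
        raise ConfigurationError("valve resistance must be positive")
    dp = p_upstream - p_downstream
    return dp / R if dp > 0.0 else 0.0


@njit(cache=True)
def _circ_derivs(v, p, q_lvad, p_lv, p_rv, out_flows):
    """Volume derivatives (mL/ms); fills out_flows with the 8 branch flows."""
    p_pa = (v[0] - p[14]) / p[8]
    p_pv = (v[1] - p[15]) / p[9]
    p_la = (v[2] - p[16]) / p[10]
    p_sa = (v[3] - p[17]) / p[11]
    p_sv = (v[4] - p[18]) / p[12]
    p_ra = (v[5] - p[19]) / p[13]

    q_mi = (p_la - p_lv) / p[2] if p_la > p_lv else 0.0
    q_ao = (p_lv - p_sa) / p[3] if p_lv > p_sa else 0.0
    q_sa = (p_sa - p_sv) / p[4]
    q_sv = (p_sv - p_ra) / p[5]
    q_tr = (p_ra - p_rv) / p[6] if p_ra > p_rv else 0.0
    q_pu = (p_rv - p_pa) / p[7] if p_rv > p_pa else 0.0
    q_pa = (p_pa - p_pv) / p[0]
    q_pv = (p_pv - p_la) / p[1]

    out_flows[0] = q_mi
    out_flows[1] = q_ao
    out_flows[2] = q_sa
    out_flows[3] = q_sv
    out_flows[4] = q_tr
    out_flows[5] = q_pu
    out_flows[6] = q_pa
    out_flows[7] = q_pv

    dv = np.empty(8)
    dv[0] = q_pu - q_pa                # pulmonary artery
    dv[1] = q_pa - q_pv                # pulmonary vein
    dv[2] = q_pv - q_mi                # left atrium
    dv[3] = q_ao + q_lvad - q_sa       # systemic artery
    dv[4] = q_sa - q_sv                # systemic vein
    dv[5] = q_sv - q_tr                # right atrium
    dv[6] = q_mi - q_ao - q_lvad       # left ventricle
    dv[7] = q_tr - q_pu                # right ventricle
    return dv


@njit(cache=True)
def _circ_step(v, p, q_lvad, p_lv, p_rv, dt, flows):
    """Heun (RK2) volume update; returns flows at the step start."""
    dv1 = _circ_derivs(v, p, q_lvad, p_lv, p_rv, flows)
    v2 = v + dt * dv1
    tmp = np.empty(8)
    dv2 = _circ_derivs(v2, p, q_lvad, p_lv, p_rv, tmp)
    for k in range(8):
        v[k] = v[k] + 0.5 * dt * (dv1[k] + dv2[k])


# indices of _circ_derivs' flow output
FLOW_NAMES = ("mitral", "aortic", "systemic", "venous_return",
              "tricuspid", "pulmonary_valve", "pulmonary", "pulmonary_venous")


def circulation_step(state: CirculationState, params: CirculationParams,
                     lvad: LVADParams, P_LV: float, P_RV: float,
                     dt: float) -> CirculationState:
    """Advance compartment volumes by dt given the ventricular pressures."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    v = state.volumes.astype(np.float64).copy()
    flows = np.empty(8)
    q_lvad = lvad.flow_ml_per_ms
    _circ_step(v, params.vector(), q_lvad, P_LV, P_RV, dt, flows)
    if np.any(v < 0.0):
        bad = COMP_NAMES[int(np.argmin(v))]
        raise InstabilityError(f"negative volume in compartment {bad!r}")
    new = CirculationState(volumes=v, lvad_flow=q_lvad)
    new.valve_open = {"mitral": flows[0] > 0, "aortic": flows[1] > 0,
                      "tricuspid": flows[4] > 0, "pulmonary": flows[5] > 0}
    return new


def rhs_for_oracle(params: CirculationParams, lvad: LVADParams,
                   p_lv_fun, p_rv_fun):
    """f(t, v) over compartment volumes for an independent stiff solver."""
    p = params.vector()
    q_lvad = lvad.flow_ml_per_ms

    def f(t, v):
        flows = np.empty(8)
        return _circ_derivs(v, p, q_lvad, p_lv_fun(t), p_rv_fun(t), flows)

    return f


@dataclass
class PVLoopMetrics:
    """Hemodynamic indices of one steady-state beat."""

    EDV: float
    ESV: float
    SV: float
    EF: float | None               # %, None when the LVAD is enabled
    CO: float                      # L/min
    peak_lv_pressure: float        # mmHg
    time_of_peak_pressure: float   # ms within the beat
    aortic_open_duration: float    # ms
    lvad_mean_flow: float = 0.0    # L/min over the beat

    def as_dict(self) -> dict:
        return {
            "EDV_mL": self.EDV, "ESV_mL": self.ESV, "SV_mL": self.SV,
            "EF_pct": self.EF, "CO_L_min": self.CO,
            "peak_LVP_mmHg": self.peak_lv_pressure,
            "t_peak_LVP_ms": self.time_of_peak_pressure,
            "AV_open_ms": self.aortic_open_duration,
            "LVAD_L_min": self.lvad_mean_flow,
        }


def pv_metrics(t: np.ndarray, lv_pressure: np.ndarray, lv_volume: np.ndarray,
               aortic_flow: np.ndarray, lvad: LVADParams,
               heart_rate: float, lvad_flow_trace: np.ndarray | None = None,
               ) -> PVLoopMetrics:
    """PV-loop indices from one analysis beat's traces.

    heart_rate in beats/min.  aortic_flow in mL/ms.  EF is reported only with
    the LVAD disabled (the device distorts the PV loop); CO counts forward
    aortic flow plus device flow when the LVAD is enabled, and SV x HR
    otherwise.
    """
    t = np.asarray(t, float)
    if len(t) < 2 or (t[-1] - t[0]) < 60000.0 / heart_rate - 1.0:
        raise ValueError("traces must cover at least one full beat")
    lv_volume = np.asarray(lv_volume, float)
    lv_pressure = np.asarray(lv_pressure, float)
    aortic_flow = np.asarray(aortic_flow, float)

    edv = float(lv_volume.max())
    esv = float(lv_volume.min())
    sv = edv - esv
    beat_ms = t[-1] - t[0]
    dt_samples = np.gradient(t)
    av_open = float(np.sum(dt_samples[aortic_flow > 0.0]))
    i_pk = int(np.argmax(lv_pressure))

    if lvad.enabled:
        q_fwd = float(np.trapezoid(aortic_flow, t) / beat_ms)      # mL/ms
        if lvad_flow_trace is not None:
            q_dev = float(np.trapezoid(lvad_flow_trace, t) / beat_ms)
        else:
            q_dev = lvad.flow_ml_per_ms
        co = (q_fwd + q_dev) * 60000.0 / 1000.0                    # L/min
        ef = None
        lvad_mean = q_dev * 60.0
    else:
        co = sv * heart_rate / 1000.0
        ef = 100.0 * sv / edv if edv > 0 else 0.0
        lvad_mean = 0.0

    return PVLoopMetrics(
        EDV=edv, ESV=esv, SV=sv, EF=ef, CO=co,
        peak_lv_pressure=float(lv_pressure[i_pk]),
        time_of_peak_pressure=float(t[i_pk] - t[0]),
        aortic_open_duration=av_open, lvad_mean_flow=lvad_mean)
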