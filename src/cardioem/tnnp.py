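"""Human ventricular myocyte electrophysiology.

Implements the ten Tusscher et al. human ventricular membrane model in its
2004 single-cell formulation, with endocardial / midmyocardial / epicardial
transmural variants.  The membrane equation is

    dV/dt = -(I_ion + I_stim) / C_m

where I_ion is the sum of twelve transmembrane currents (I_Na, I_K1, I_to,
I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa).  The calcium
subsystem couples the sarcoplasmic reticulum (SR) to the cytosol through

    I_leak = V_leak (Ca_sr - Ca_i)
    I_up   = Vmax_up / (1 + K_up^2 / Ca_i^2)
    I_rel  = (a_rel Ca_sr^2 / (b_rel^2 + Ca_sr^2) + c_rel) d g

with d the L-type activation gate reused as release activation and g the
calcium-dependent release inactivation gate; cytosolic and SR calcium use the
rapid-buffering approximation.

Units: time ms, voltage mV, concentrations mM, currents pA/pF.  Because the
currents are normalized per unit capacitance, the membrane equation uses the
normalization constant ``C_m`` (default 1); the total cell capacitance
``cap_total`` converts membrane currents to concentration fluxes, and the
per-area capacitance enters only the tissue diffusion coefficients.

Gates are advanced with exponential (Rush-Larsen) updates, concentrations and
voltage with a forward update; default dt = 0.02 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
import warnings

import numpy as np
from numba import njit

from .util import InstabilityError, InvalidStateError, check_finite

# ---------------------------------------------------------------------------
# state layout

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f_ca", "r", "s",
    "xr1", "xr2", "xs", "g", "ca_i", "ca_sr", "na_i", "k_i",
)
N_STATE = len(STATE_NAMES)
GATE_SLICE = slice(1, 13)          # m ... g
N_GATES = 12
IDX_FCA = 5                        # index within the gate block
IDX_G = 11

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bCa", "I_bNa",
)
N_CURRENTS = 12

CELL_TYPES = ("endo", "mid", "epi")

# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class CellParams:
    """Constants of the ventricular membrane model for one transmural variant.

    Conductances in nS/pF, permeabilities in cm^3/(uF s)-equivalent units of
    the reference formulation, volumes in uL, concentrations mM.
    """

    cell_type: str = "endo"
    # physical constants
    R: float = 8314.472            # mJ/(mol K)
    T: float = 310.0               # K
    F: float = 96485.3415          # C/mmol
    C_m: float = 1.0               # membrane-equation normalization (currents are pA/pF)
    cap_total: float = 0.185       # uF, converts currents to concentration fluxes
    C_m_area: float = 2.0          # uF/cm^2, used in tissue diffusion coefficients
    # external concentrations
    Ko: float = 5.4
    Nao: float = 140.0
    Cao: float = 2.0
    # maximal conductances / permeabilities
    G_Na: float = 14.838
    G_K1: float = 5.405
    G_to: float = 0.073            # endo default; 0.294 for mid/epi
    G_Kr: float = 0.096
    G_Ks: float = 0.245            # endo/epi default; 0.062 for mid
    G_CaL: float = 1.75e-4
    k_NaCa: float = 1000.0
    Km_Nai: float = 87.5
    Km_Ca: float = 1.38
    k_sat: float = 0.1
    gamma: float = 0.35
    alpha_NaCa: float = 2.5
    P_NaK: float = 1.362
    Km_K: float = 1.0
    Km_Na: float = 40.0
    G_pCa: float = 0.825
    K_pCa: float = 0.0005
    G_pK: float = 0.0146
    G_bNa: float = 0.00029
    G_bCa: float = 0.000592
    p_KNa: float = 0.03
    # calcium handling
    V_c: float = 0.016404
    V_sr: float = 0.001094
    Buf_c: float = 0.15
    K_bufc: float = 0.001
    Buf_sr: float = 10.0
    K_bufsr: float = 0.3
    Vmax_up: float = 4.25e-4
    K_up: float = 2.5e-4
    a_rel: float = 0.016464
    b_rel: float = 0.25
    c_rel: float = 0.008232
    V_leak: float = 8.0e-5
    tau_fca: float = 2.0
    tau_g: float = 2.0

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for f_ in fields(self):
            if f_.name == "cell_type":
                continue
            if getattr(self, f_.name) < 0:
                raise ValueError(f"parameter {f_.name} must be non-negative")

    @classmethod
    def for_cell_type(cls, cell_type: str, **overrides) -> "CellParams":
        variant = {
            "endo": dict(G_to=0.073, G_Ks=0.245),
            "epi": dict(G_to=0.294, G_Ks=0.245),
            "mid": dict(G_to=0.294, G_Ks=0.062),
        }[cell_type]
        variant.update(overrides)
        return cls(cell_type=cell_type, **variant)

    def vector(self) -> np.ndarray:
        vals = [getattr(self, f_.name) for f_ in fields(self) if f_.name != "cell_type"]
        vec = np.array(vals, dtype=np.float64)
        return np.append(vec, 1.0 if self.cell_type == "endo" else 0.0)


_PVEC_NAMES = [f_.name for f_ in fields(CellParams) if f_.name != "cell_type"] + ["endo_s"]
_PI = {name: i for i, name in enumerate(_PVEC_NAMES)}


def param_matrix(params_by_type: dict[str, CellParams]) -> np.ndarray:
    """Stack parameter vectors for the three variants (rows endo, mid, epi)."""
    return np.stack([params_by_type[ct].vector() for ct in CELL_TYPES])


def default_param_matrix(**overrides) -> np.ndarray:
    return param_matrix({ct: CellParams.for_cell_type(ct, **overrides) for ct in CELL_TYPES})


# ---------------------------------------------------------------------------
# state containers


@dataclass
class CellState:
    """Full ionic state of one myocyte."""

    V: float = -86.2
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    d: float = 0.0
    f: float = 1.0
    f_ca: float = 1.0
    r: float = 0.0
    s: float = 1.0
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    g: float = 1.0
    ca_i: float = 2.0e-4
    ca_sr: float = 0.2
    na_i: float = 11.6
    k_i: float = 138.3

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CellState":
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        check_finite((n, getattr(self, n)) for n in STATE_NAMES)
        for n in STATE_NAMES[GATE_SLICE]:
            v = getattr(self, n)
            # f_ca is a scaling gate whose steady-state expression tops out
            # at 1.047 in the reference formulation; all true probability
            # gates stay in [0, 1]
            hi = 1.05 if n == "f_ca" else 1.0
            if not 0.0 <= v <= hi:
                raise InvalidStateError(f"gate {n}={v} outside [0, {hi}]")
        for n in ("ca_i", "ca_sr", "na_i", "k_i"):
            if getattr(self, n) <= 0:
                raise InvalidStateError(f"concentration {n} must be positive")


def resting_state(cell_type: str = "endo") -> CellState:  # noqa: ARG001 - same rest state
    """Quiescent initial state of the reference formulation."""
    return CellState()


@dataclass
class CurrentSet:
    """One value per membrane current (pA/pF); I_ion is their sum."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bCa: float
    I_bNa: float
    I_stim: float = 0.0

    @property
    def I_ion(self) -> float:
        return (self.I_Na + self.I_K1 + self.I_to + self.I_Kr + self.I_Ks
                + self.I_CaL + self.I_NaCa + self.I_NaK + self.I_pCa
                + self.I_pK + self.I_bCa + self.I_bNa)


@dataclass
class CalciumFluxes:
    """SR flux rates (mM/ms) and total-calcium derivatives."""

    I_leak: float
    I_up: float
    I_rel: float
    dca_i_total_dt: float
    dca_sr_total_dt: float
    ca_i_bufc: float
    ca_sr_bufsr: float


@dataclass
class PacingProtocol:
    """Periodic stimulation protocol for a single cell."""

    bcl: float = 600.0             # ms
    stim_amplitude: float = -52.0  # pA/pF, inward
    stim_duration: float = 1.0     # ms
    n_beats: int = 20
    dt: float = 0.02               # ms
    sample_dt: float = 0.1         # ms, trace resolution

    def __post_init__(self):
        if not self.bcl > self.stim_duration > 0:
            raise ValueError("require cycle length > stimulus duration > 0")
        if self.dt <= 0 or self.n_beats < 0:
            raise ValueError("dt must be positive and n_beats non-negative")


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _currents(y, p, out):
    """Fill out[:12] with the twelve membrane currents for state y."""
    (R, T, F) = (p[0], p[1], p[2])
    Ko, Nao, Cao = p[6], p[7], p[8]
    V = y[0]
    m, h, j, d, f, fca = y[1], y[2], y[3], y[4], y[5], y[6]
    r, s, xr1, xr2, xs = y[7], y[8], y[9], y[10], y[11]
    cai, nai, ki = y[13], y[15], y[16]

    rtf = R * T / F
    ena = rtf * np.log(Nao / nai)
    ek = rtf * np.log(Ko / ki)
    eks = rtf * np.log((Ko + p[_PK_KNA] * Nao) / (ki + p[_PK_KNA] * nai))
    eca = 0.5 * rtf * np.log(Cao / cai)

    i_na = p[_PG_NA] * m ** 3 * h * j * (V - ena)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0))
           + np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    i_k1 = p[_PG_K1] * (ak1 / (ak1 + bk1)) * (V - ek)

    i_to = p[_PG_TO] * r * s * (V - ek)
    i_kr = p[_PG_KR] * np.sqrt(Ko / 5.4) * xr1 * xr2 * (V - ek)
    i_ks = p[_PG_KS] * xs * xs * (V - eks)

    vf_rt = V * F / (R * T)
    ex2 = np.exp(2.0 * vf_rt)
    if abs(V) < 1.0e-6:
        # limit of the GHK-type driving term as V -> 0
        i_cal = p[_PG_CAL] * d * f * fca * 2.0 * F * (cai - 0.341 * Cao)
    else:
        i_cal = (p[_PG_CAL] * d * f * fca * 4.0 * V * F * F / (R * T)
                 * (cai * ex2 - 0.341 * Cao) / (ex2 - 1.0))

    exg = np.exp(p[_PGAMMA] * vf_rt)
    exg1 = np.exp((p[_PGAMMA] - 1.0) * vf_rt)
    i_naca = (p[_PK_NACA]
              * (exg * nai ** 3 * Cao - exg1 * Nao ** 3 * cai * p[_PALPHA])
              / ((p[_PKM_NAI] ** 3 + Nao ** 3) * (p[_PKM_CA] + Cao)
                 * (1.0 + p[_PK_SAT] * exg1)))

    i_nak = (p[_PP_NAK] * (Ko / (Ko + p[_PKM_K])) * (nai / (nai + p[_PKM_NA]))
             / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0353 * np.exp(-vf_rt)))

    i_pca = p[_PG_PCA] * cai / (cai + p[_PK_PCA])
    i_pk = p[_PG_PK] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    i_bca = p[_PG_BCA] * (V - eca)
    i_bna = p[_PG_BNA] * (V - ena)

    out[0] = i_na
    out[1] = i_k1
    out[2] = i_to
    out[3] = i_kr
    out[4] = i_ks
    out[5] = i_cal
    out[6] = i_naca
    out[7] = i_nak
    out[8] = i_pca
    out[9] = i_pk
    out[10] = i_bca
    out[11] = i_bna


# parameter-vector indices used inside kernels
_PG_NA = _PI["G_Na"]
_PG_K1 = _PI["G_K1"]
_PG_TO = _PI["G_to"]
_PG_KR = _PI["G_Kr"]
_PG_KS = _PI["G_Ks"]
_PG_CAL = _PI["G_CaL"]
_PK_NACA = _PI["k_NaCa"]
_PKM_NAI = _PI["Km_Nai"]
_PKM_CA = _PI["Km_Ca"]
_PK_SAT = _PI["k_sat"]
_PGAMMA = _PI["gamma"]
_PALPHA = _PI["alpha_NaCa"]
_PP_NAK = _PI["P_NaK"]
_PKM_K = _PI["Km_K"]
_PKM_NA = _PI["Km_Na"]
_PG_PCA = _PI["G_pCa"]
_PK_PCA = _PI["K_pCa"]
_PG_PK = _PI["G_pK"]
_PG_BNA = _PI["G_bNa"]
_PG_BCA = _PI["G_bCa"]
_PK_KNA = _PI["p_KNa"]
_PCM = _PI["C_m"]
_PCAP = _PI["cap_total"]
_PV_C = _PI["V_c"]
_PV_SR = _PI["V_sr"]
_PBUF_C = _PI["Buf_c"]
_PK_BUFC = _PI["K_bufc"]
_PBUF_SR = _PI["Buf_sr"]
_PK_BUFSR = _PI["K_bufsr"]
_PVMAX_UP = _PI["Vmax_up"]
_PK_UP = _PI["K_up"]
_PA_REL = _PI["a_rel"]
_PB_REL = _PI["b_rel"]
_PC_REL = _PI["c_rel"]
_PV_LEAK = _PI["V_leak"]
_PTAU_FCA = _PI["tau_fca"]
_PTAU_G = _PI["tau_g"]
_PFARADAY = _PI["F"]
_PENDO_S = len(_PVEC_NAMES) - 1


@njit(cache=True)
def _ca_fluxes(y, p):
    """Return (I_leak, I_up, I_rel) in mM/ms."""
    d, g = y[4], y[12]
    cai, casr = y[13], y[14]
    i_leak = p[_PV_LEAK] * (casr - cai)
    i_up = p[_PVMAX_UP] / (1.0 + (p[_PK_UP] * p[_PK_UP]) / (cai * cai))
    i_rel = (p[_PA_REL] * casr * casr / (p[_PB_REL] * p[_PB_REL] + casr * casr)
             + p[_PC_REL]) * d * g
    return i_leak, i_up, i_rel


@njit(cache=True)
def _gate_rates(V, cai, p, inf, tau):
    """Steady states and time constants for the 12 gates (order m..g)."""

    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    tau[0] = am * bm

    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    inf[1] = hinf
    tau[1] = 1.0 / (ah + bh)
    inf[2] = hinf
    tau[2] = 1.0 / (aj + bj)

    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    inf[3] = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    tau[3] = ad * bd + cd

    inf[4] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau[4] = (1125.0 * np.exp(-(V + 27.0) ** 2 / 240.0) + 80.0
              + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0)))

    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    cfca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    inf[5] = (afca + bfca + cfca + 0.23) / 1.46
    tau[5] = p[_PTAU_FCA]

    inf[6] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau[6] = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8

    if p[_PENDO_S] > 0.5:
        inf[7] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau[7] = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        inf[7] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau[7] = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
                  + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)

    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    inf[8] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tau[8] = axr1 * bxr1

    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    inf[9] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tau[9] = axr2 * bxr2

    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    inf[10] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tau[10] = axs * bxs

    if cai < 0.00035:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    tau[11] = p[_PTAU_G]


# largest voltage change allowed in one (sub)step; steps are subdivided when
# the membrane is depolarizing faster than this, which confines the extra work
# to the ~1.5 ms upstroke while keeping the production dt elsewhere
DV_MAX = 0.5  # mV


@njit(cache=True)
def _step_one(y, p, istim, dt, cbuf, infbuf, taubuf):
    """Advance one cell state in place by dt (Rush-Larsen gates).

    The step is internally subdivided so that no substep moves V by more than
    DV_MAX, bounding the first-order error of the forward voltage update
    during the fast sodium upstroke.
    """
    remaining = dt
    h_min = dt / 256.0
    while remaining > 1.0e-12:
        _currents(y, p, cbuf)
        i_ion = 0.0
        for k in range(12):
            i_ion += cbuf[k]
        dvdt = abs(i_ion + istim) / p[_PCM]
        if dvdt * remaining <= DV_MAX:
            _substep(y, p, istim, remaining, cbuf, i_ion, infbuf, taubuf)
            break
        h = DV_MAX / dvdt
        if h < h_min:
            h = h_min
        v0 = y[0]
        _substep(y, p, istim, h, cbuf, i_ion, infbuf, taubuf)
        # Heun correction on the voltage: re-evaluate I_ion at the predicted
        # state and average, giving second-order accuracy on the upstroke
        _currents(y, p, cbuf)
        i_ion2 = 0.0
        for k in range(12):
            i_ion2 += cbuf[k]
        y[0] = v0 - h * 0.5 * (i_ion + i_ion2 + 2.0 * istim) / p[_PCM]
        remaining -= h


@njit(cache=True)
def _substep(y, p, istim, dt, cbuf, i_ion, infbuf, taubuf):
    """Single forward/Rush-Larsen update using precomputed currents.

    Gate rates are evaluated at the predicted midpoint voltage, which centers
    the Rush-Larsen update and removes the first-order gate lag on upstrokes.
    """
    v_mid = y[0] - 0.5 * dt * (i_ion + istim) / p[_PCM]
    i_leak, i_up, i_rel = _ca_fluxes(y, p)
    _gate_rates(v_mid, y[13], p, infbuf, taubuf)

    V = y[0]
    cap = p[_PCAP]
    vcf = p[_PV_C] * p[_PFARADAY]

    # concentrations (rapid buffering)
    cai, casr = y[13], y[14]
    bc = 1.0 / (1.0 + p[_PBUF_C] * p[_PK_BUFC] / (cai + p[_PK_BUFC]) ** 2)
    dcai_tot = (-(cbuf[5] + cbuf[10] + cbuf[8] - 2.0 * cbuf[6]) * cap / (2.0 * vcf)
                + i_leak - i_up + i_rel)
    bsr = 1.0 / (1.0 + p[_PBUF_SR] * p[_PK_BUFSR] / (casr + p[_PK_BUFSR]) ** 2)
    dcasr_tot = (p[_PV_C] / p[_PV_SR]) * (i_up - i_leak - i_rel)
    y[13] = cai + dt * bc * dcai_tot
    y[14] = casr + dt * bsr * dcasr_tot
    y[15] = y[15] - dt * (cbuf[0] + cbuf[11] + 3.0 * cbuf[7] + 3.0 * cbuf[6]) * cap / vcf
    y[16] = y[16] - dt * (cbuf[1] + cbuf[2] + cbuf[3] + cbuf[4]
                          - 2.0 * cbuf[7] + cbuf[9] + istim) * cap / vcf

    # gates: exponential update with the fCa / g depolarized locks
    for k in range(12):
        old = y[1 + k]
        new = infbuf[k] + (old - infbuf[k]) * np.exp(-dt / taubuf[k])
        if (k == 5 or k == 11) and new > old and V > -60.0:
            new = old
        y[1 + k] = new

    y[0] = V - dt * (i_ion + istim) / p[_PCM]


@njit(cache=True)
def _derivatives(y, p, istim, dy):
    """Plain ODE right-hand side (same physics as _step_one) for oracles."""
    cbuf = np.empty(12)
    infbuf = np.empty(12)
    taubuf = np.empty(12)
    _currents(y, p, cbuf)
    i_ion = 0.0
    for k in range(12):
        i_ion += cbuf[k]
    i_leak, i_up, i_rel = _ca_fluxes(y, p)
    _gate_rates(y[0], y[13], p, infbuf, taubuf)

    V = y[0]
    cap = p[_PCAP]
    vcf = p[_PV_C] * p[_PFARADAY]
    cai, casr = y[13], y[14]

    dy[0] = -(i_ion + istim) / p[_PCM]
    for k in range(12):
        d = (infbuf[k] - y[1 + k]) / taubuf[k]
        if (k == 5 or k == 11) and d > 0.0 and V > -60.0:
            d = 0.0
        dy[1 + k] = d
    bc = 1.0 / (1.0 + p[_PBUF_C] * p[_PK_BUFC] / (cai + p[_PK_BUFC]) ** 2)
    dy[13] = bc * (-(cbuf[5] + cbuf[10] + cbuf[8] - 2.0 * cbuf[6]) * cap / (2.0 * vcf)
                   + i_leak - i_up + i_rel)
    bsr = 1.0 / (1.0 + p[_PBUF_SR] * p[_PK_BUFSR] / (casr + p[_PK_BUFSR]) ** 2)
    dy[14] = bsr * (p[_PV_C] / p[_PV_SR]) * (i_up - i_leak - i_rel)
    dy[15] = -(cbuf[0] + cbuf[11] + 3.0 * cbuf[7] + 3.0 * cbuf[6]) * cap / vcf
    dy[16] = -(cbuf[1] + cbuf[2] + cbuf[3] + cbuf[4] - 2.0 * cbuf[7]
               + cbuf[9] + istim) * cap / vcf


@njit(cache=True)
def _step_states(Y, pmat, ctype, istim, dt):
    """Reaction step for an array of cells (tissue nodes).

    Y is (n, N_STATE); pmat rows are the endo/mid/epi parameter vectors and
    ctype indexes into them per node.
    """
    cbuf = np.empty(12)
    infbuf = np.empty(12)
    taubuf = np.empty(12)
    for i in range(Y.shape[0]):
        _step_one(Y[i], pmat[ctype[i]], istim[i], dt, cbuf, infbuf, taubuf)


@njit(cache=True)
def _run_cell(y, p, n_steps, dt, stim_amp, stim_dur, bcl, stride, t0, out):
    """Paced single-cell run; out rows: t, V, Ca_i, I_leak, I_up, I_rel."""
    cbuf = np.empty(12)
    infbuf = np.empty(12)
    taubuf = np.empty(12)
    n_out = 0
    for step in range(n_steps):
        t = t0 + step * dt
        phase = t % bcl
        istim = stim_amp if phase < stim_dur else 0.0
        if step % stride == 0:
            i_leak, i_up, i_rel = _ca_fluxes(y, p)
            out[0, n_out] = t
            out[1, n_out] = y[0]
            out[2, n_out] = y[13]
            out[3, n_out] = i_leak
            out[4, n_out] = i_up
            out[5, n_out] = i_rel
            n_out += 1
        _step_one(y, p, istim, dt, cbuf, infbuf, taubuf)
    return n_out


# ---------------------------------------------------------------------------
# public API


def ionic_currents(state: CellState, params: CellParams, i_stim: float = 0.0) -> CurrentSet:
    """Compute the twelve membrane currents for the given cell variant."""
    state.validate()
    out = np.empty(N_CURRENTS)
    _currents(state.vector(), params.vector(), out)
    return CurrentSet(*[float(v) for v in out], I_stim=i_stim)


def calcium_fluxes(state: CellState, params: CellParams) -> CalciumFluxes:
    """SR calcium fluxes and the total-calcium balance derivatives."""
    if state.ca_i <= 0 or state.ca_sr <= 0:
        raise InvalidStateError("calcium concentrations must be positive")
    state.validate()
    y = state.vector()
    p = params.vector()
    i_leak, i_up, i_rel = (float(v) for v in _ca_fluxes(y, p))
    out = np.empty(N_CURRENTS)
    _currents(y, p, out)
    cap = params.cap_total
    vcf = params.V_c * params.F
    dcai = (-(out[5] + out[10] + out[8] - 2.0 * out[6]) * cap / (2.0 * vcf)
            + i_leak - i_up + i_rel)
    dcasr = (params.V_c / params.V_sr) * (i_up - i_leak - i_rel)
    bufc = state.ca_i * params.Buf_c / (state.ca_i + params.K_bufc)
    bufsr = state.ca_sr * params.Buf_sr / (state.ca_sr + params.K_bufsr)
    return CalciumFluxes(i_leak, i_up, i_rel, float(dcai), float(dcasr), bufc, bufsr)


def step_cell(state: CellState, params: CellParams, i_stim: float, dt: float) -> CellState:
    """Advance the cell by dt; gates via Rush-Larsen, concentrations forward."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    y = state.vector()
    _step_one(y, params.vector(), i_stim, dt,
              np.empty(12), np.empty(12), np.empty(12))
    new = CellState.from_vector(y)
    try:
        new.validate()
    except InvalidStateError as err:
        raise InstabilityError(f"invalid state after step of dt={dt}: {err}") from err
    return new


@dataclass
class CellTrace:
    """Sampled traces of a paced single-cell run."""

    t: np.ndarray
    V: np.ndarray
    ca_i: np.ndarray
    I_leak: np.ndarray
    I_up: np.ndarray
    I_rel: np.ndarray
    bcl: float
    n_beats: int
    final_state: CellState
    captured: bool = True
    steady_state: bool = False
    warnings: list = field(default_factory=list)

    def beat(self, index: int = -1):
        """Return the trace slice of one beat (default: the analysis beat)."""
        if self.n_beats == 0:
            raise ValueError("trace contains no beats")
        idx = index if index >= 0 else self.n_beats + index
        lo = np.searchsorted(self.t, idx * self.bcl)
        hi = np.searchsorted(self.t, (idx + 1) * self.bcl)
        return slice(lo, hi)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.t, "V_mV": self.V, "Ca_i_mM": self.ca_i,
            "I_leak": self.I_leak, "I_up": self.I_up, "I_rel": self.I_rel,
        })


def run_paced_cell(params: CellParams, protocol: PacingProtocol,
                   initial: CellState | None = None) -> CellTrace:
    """Pace a single cell for protocol.n_beats beats at the configured BCL.

    The final beat is the analysis beat.  A run in which the stimulus fails to
    elicit an upstroke (no sample above 0 mV in the final beat) is flagged with
    a warning recorded on the result.  Steady state is declared when the peak
    Ca_i of the last two beats differs by less than 1% (same rule for APD is
    applied by callers that need it).
    """
    state = initial if initial is not None else resting_state(params.cell_type)
    y = state.vector()
    p = params.vector()
    stride = max(1, int(round(protocol.sample_dt / protocol.dt)))
    n_steps = int(round(protocol.n_beats * protocol.bcl / protocol.dt))
    out = np.zeros((6, n_steps // stride + 1))
    n_out = _run_cell(y, p, n_steps, protocol.dt, protocol.stim_amplitude,
                      protocol.stim_duration, protocol.bcl, stride, 0.0, out)
    out = out[:, :n_out]
    trace = CellTrace(t=out[0], V=out[1], ca_i=out[2], I_leak=out[3],
                      I_up=out[4], I_rel=out[5], bcl=protocol.bcl,
                      n_beats=protocol.n_beats,
                      final_state=CellState.from_vector(y))
    if protocol.n_beats == 0:
        return trace
    last = trace.beat(-1)
    if not np.any(trace.V[last] > 0.0):
        msg = "failure to capture: no upstroke in the analysis beat"
        trace.captured = False
        trace.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    if protocol.n_beats >= 2:
        prev = trace.beat(-2)
        pk_last = trace.ca_i[last].max()
        pk_prev = trace.ca_i[prev].max()
        trace.steady_state = abs(pk_last - pk_prev) < 0.01 * pk_prev
    return trace


def apd(t: np.ndarray, v: np.ndarray, repol_fraction: float = 0.9) -> float:
    """Action-potential duration at the given repolarization fraction.

    Measured from the maximum-dV/dt upstroke to the downward crossing of
    V_rest + (1-repol_fraction)*(V_peak - V_rest).
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    i_up = int(np.argmax(np.gradient(v, t)))
    v_rest = v[0]
    v_peak = v.max()
    level = v_rest + (1.0 - repol_fraction) * (v_peak - v_rest)
    below = np.nonzero(v[i_up:] < level)[0]
    after_peak = below[below > int(np.argmax(v[i_up:]))]
    if len(after_peak) == 0:
        return float("nan")
    k = i_up + after_peak[0]
    # linear interpolation of the crossing
    t_cross = np.interp(level, [v[k], v[k - 1]], [t[k], t[k - 1]])
    return float(t_cross - t[i_up])


def rhs_for_oracle(p: np.ndarray, stim_fun=None):
    """Return f(t, y) suitable for scipy.integrate.solve_ivp on the same RHS."""

    def f(t, y):
        dy = np.empty(N_STATE)
        istim = stim_fun(t) if stim_fun is not None else 0.0
        _derivatives(y, p, istim, dy)
        return dy

    return f
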