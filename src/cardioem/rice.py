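"""Cross-bridge myofilament contraction (Rice-type approximate model).

A calcium transient drives Ca2+ binding to low- and high-affinity troponin
regulatory sites; a cooperative nonpermissive/permissive tropomyosin switch
(N <-> P) gates a three-state cross-bridge cycle

    P --fapp--> XB_prer --hf--> XB_postr --gxb--> P
      <-gapp--           <-hb--

with mean cross-bridge distortions x_prer, x_postr carried as ODEs.  Active
tension is the single-overlap-weighted sum of occupancy x distortion,
normalized so that maximal isometric tension at full activation is 1.

Sarcomere length follows the second-order dynamics

    mass * SL'' + viscosity * SL' = F_net,

integrated in the equivalent integral form

    dSL/dt = (IF + (SL0 - SL) * viscosity) / mass,

where IF accumulates the net normalized force with the convention

    dIF/dt = F_preload - F_active - F_passive - F_afterload + F_ext,

so that active tension shortens the sarcomere, the series-elastic afterload
F_afterload = K_SE (SL - SL0) restores it, and an external load F_ext
(e.g. scaled cavity pressure) opposes shortening.  :func:`integral_force`
separately reports the bracketed sum in its printed textbook form.
``integral_force`` and cycle ATP use trapezoidal quadrature on the solver
grid.

The ATP consumption rate is E = g_xbT * SOVF_thick (reported in 1/s), the
product of the strain-dependent cross-bridge detachment rate and the
single-overlap fraction of the thick filament.

Units: time ms, lengths um, [Ca] uM, forces normalized.  Rate constants are
the reference formulation's body-temperature set; none are restated by the
study this package mirrors, so every constant is exposed in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
from numba import njit

from .util import InvalidStateError, trapezoid_cumulative

STATE_NAMES = (
    "trpn_ca_l", "trpn_ca_h", "n_nop", "xb_prer", "xb_postr",
    "x_prer", "x_postr", "sl", "intf",
)
N_STATE = len(STATE_NAMES)

ISOMETRIC, ISOTONIC = 0, 1
_MODES = {"isometric": ISOMETRIC, "isotonic": ISOTONIC}


@dataclass(frozen=True)
class MyofilamentParams:
    """Rate constants, sarcomere geometry and mechanical constants."""

    # sarcomere geometry (um)
    SL_max: float = 2.4
    SL_min: float = 1.4
    len_thin: float = 1.2
    len_thick: float = 1.65
    len_hbare: float = 0.1
    # Ca binding to troponin (1/ms; kon per uM)
    kon: float = 50.0e-3
    koff_l: float = 250.0e-3
    koff_h: float = 25.0e-3
    # tropomyosin switch and cooperativity
    perm50: float = 0.5
    nperm: float = 15.0
    kn_p: float = 500.0e-3
    kp_n: float = 50.0e-3
    # cross-bridge cycling (1/ms)
    fapp: float = 500.0e-3
    gapp: float = 70.0e-3
    hf: float = 2000.0e-3
    hb: float = 400.0e-3
    gxb: float = 70.0e-3
    gslmod: float = 6.0
    hfmdc: float = 5.0
    sigma_p: float = 8.0
    sigma_n: float = 1.0
    x_0: float = 0.007            # um, power-stroke size
    x_psi: float = 2.0
    # passive element (normalized force)
    SL_rest: float = 1.9
    PCon_titin: float = 0.002
    PExp_titin: float = 10.0
    SL_collagen: float = 2.25
    PCon_collagen: float = 0.02
    PExp_collagen: float = 70.0
    passive_scale: float = 1.0    # x5 models the failing, stiffened myocardium
    # mechanics of the SL equation
    SL0: float = 2.2              # um, initial / preload sarcomere length
    K_SE: float = 5.0             # normalized force per um (series elastic)
    viscosity: float = 25.0       # normalized force * ms / um
    mass: float = 50.0            # normalized force * ms^2 / um

    def __post_init__(self):
        if self.SL0 <= 0:
            raise ValueError("SL0 must be positive")
        if self.viscosity <= 0 or self.mass <= 0:
            raise ValueError("viscosity and mass must be positive")
        if self.passive_scale < 1.0:
            raise ValueError("passive scaling is a stiffening multiplier >= 1")

    def vector(self) -> np.ndarray:
        vec = np.array([getattr(self, f_.name) for f_ in fields(self)], dtype=np.float64)
        ssprer, sspostr = _xb_steady_state(self.fapp, self.gapp, self.hf,
                                           self.hb, self.gxb)
        return np.concatenate([vec, [ssprer, sspostr]])


def _xb_steady_state(fapp, gapp, hf, hb, gxb):
    """Steady-state duty fractions of the cycle at full activation."""
    # solve fapp*P = (gapp+hf)*A - hb*B ; hf*A = (hb+gxb)*B ; P+A+B = 1
    a_over_b = (hb + gxb) / hf
    p_over_b = (gapp * a_over_b + gxb) / fapp
    b = 1.0 / (1.0 + a_over_b + p_over_b)
    return a_over_b * b, b


_PVEC_NAMES = [f_.name for f_ in fields(MyofilamentParams)] + ["ss_prer", "ss_postr"]
_P = {name: i for i, name in enumerate(_PVEC_NAMES)}

_I_SLMAX = _P["SL_max"]
_I_SLMIN = _P["SL_min"]
_I_LTHIN = _P["len_thin"]
_I_LTHICK = _P["len_thick"]
_I_LHBARE = _P["len_hbare"]
_I_KON = _P["kon"]
_I_KOFFL = _P["koff_l"]
_I_KOFFH = _P["koff_h"]
_I_PERM50 = _P["perm50"]
_I_NPERM = _P["nperm"]
_I_KNP = _P["kn_p"]
_I_KPN = _P["kp_n"]
_I_FAPP = _P["fapp"]
_I_GAPP = _P["gapp"]
_I_HF = _P["hf"]
_I_HB = _P["hb"]
_I_GXB = _P["gxb"]
_I_GSLMOD = _P["gslmod"]
_I_HFMDC = _P["hfmdc"]
_I_SIGP = _P["sigma_p"]
_I_SIGN = _P["sigma_n"]
_I_X0 = _P["x_0"]
_I_XPSI = _P["x_psi"]
_I_SLREST = _P["SL_rest"]
_I_PCONT = _P["PCon_titin"]
_I_PEXPT = _P["PExp_titin"]
_I_SLC = _P["SL_collagen"]
_I_PCONC = _P["PCon_collagen"]
_I_PEXPC = _P["PExp_collagen"]
_I_PSCALE = _P["passive_scale"]
_I_SL0 = _P["SL0"]
_I_KSE = _P["K_SE"]
_I_VISC = _P["viscosity"]
_I_MASS = _P["mass"]
_I_SSPRER = _P["ss_prer"]
_I_SSPOSTR = _P["ss_postr"]


@njit(cache=True)
def _overlap(sl, p):
    """Single-overlap fractions of the thick and thin filaments."""
    sovr_ze = min(p[_I_LTHICK] / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - p[_I_LTHIN]), p[_I_LHBARE] / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = 2.0 * len_sovr / (p[_I_LTHICK] - p[_I_LHBARE])
    sovf_thin = len_sovr / p[_I_LTHIN]
    return sovf_thick, sovf_thin


@njit(cache=True)
def _passive(sl, p):
    """Passive (titin + collagen) normalized force, stiffening-scaled."""
    d = sl - p[_I_SLREST]
    if d >= 0.0:
        f_titin = p[_I_PCONT] * (np.exp(p[_I_PEXPT] * d) - 1.0)
    else:
        f_titin = -p[_I_PCONT] * (np.exp(p[_I_PEXPT] * (-d)) - 1.0)
    f_coll = 0.0
    if sl > p[_I_SLC]:
        f_coll = p[_I_PCONC] * (np.exp(p[_I_PEXPC] * (sl - p[_I_SLC])) - 1.0)
    return p[_I_PSCALE] * (f_titin + f_coll)


@njit(cache=True)
def _gxbT(x_postr, p):
    """Strain-dependent detachment rate of the post-rotated state (1/ms)."""
    x0 = p[_I_X0]
    if x_postr < x0:
        md = np.exp(p[_I_SIGP] * ((x0 - x_postr) / x0) ** 2)
    else:
        md = np.exp(p[_I_SIGN] * ((x_postr - x0) / x0) ** 2)
    if md < 1.0:
        md = 1.0
    return p[_I_GXB] * md


@njit(cache=True)
def _rice_step(y, ca, ext_load, p, dt, mode):
    """Advance one myofilament unit by dt (forward update).

    ca in uM; ext_load is an extra normalized afterload (e.g. scaled cavity
    pressure) opposing shortening.  Returns (F_active, F_passive,
    F_afterload, E [1/s], gxbT [1/ms], SOVF_thick).
    """
    trpnl, trpnh, n_nop = y[0], y[1], y[2]
    a_prer, a_postr = y[3], y[4]
    x_prer, x_postr = y[5], y[6]
    sl, intf = y[7], y[8]

    sovf_thick, sovf_thin = _overlap(sl, p)

    # troponin and tropomyosin regulation
    perm = (1.0 - sovf_thin) * trpnl + sovf_thin * trpnh
    if perm < 1.0e-12:
        perm = 1.0e-12
    permtot = np.sqrt(1.0 / (1.0 + (p[_I_PERM50] / perm) ** p[_I_NPERM]))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0

    d_trpnl = p[_I_KON] * ca * (1.0 - trpnl) - p[_I_KOFFL] * trpnl
    d_trpnh = p[_I_KON] * ca * (1.0 - trpnh) - p[_I_KOFFH] * trpnh

    p_perm = 1.0 - n_nop - a_prer - a_postr
    d_n = -p[_I_KNP] * permtot * n_nop + p[_I_KPN] * inprmt * p_perm

    # cross-bridge cycling with strain- and overlap-dependent rates
    gapp_t = p[_I_GAPP] * (1.0 + (1.0 - sovf_thick) * p[_I_GSLMOD])
    x0 = p[_I_X0]
    sgn = 1.0 if x_prer >= 0.0 else -1.0
    hf_t = p[_I_HF] * np.exp(-sgn * p[_I_HFMDC] * (x_prer / x0) ** 2)
    hb_t = p[_I_HB]
    gxb_t = _gxbT(x_postr, p)

    d_prer = p[_I_FAPP] * p_perm - gapp_t * a_prer - hf_t * a_prer + hb_t * a_postr
    d_postr = hf_t * a_prer - hb_t * a_postr - gxb_t * a_postr

    # forces
    f_active = sovf_thick * (a_prer * x_prer + a_postr * x_postr) / (x0 * p[_I_SSPOSTR])
    f_passive = _passive(sl, p)
    f_preload = _passive(p[_I_SL0], p)
    f_after = p[_I_KSE] * (sl - p[_I_SL0])

    # SL dynamics (integral form of mass*SL'' + visc*SL' = F_net, with the
    # sign convention that active tension shortens and the series-elastic
    # element restores toward SL0)
    if mode == 1:
        dsl = (intf + (p[_I_SL0] - sl) * p[_I_VISC]) / p[_I_MASS]
    else:
        dsl = 0.0
    d_intf = f_preload - f_active - f_passive - f_after + ext_load

    # mean distortions
    d_xprer = 0.5 * dsl + (p[_I_XPSI] / p[_I_SSPRER]) * (
        -p[_I_FAPP] * x_prer + hb_t * (x_postr - x0 - x_prer))
    d_xpostr = 0.5 * dsl + (p[_I_XPSI] / p[_I_SSPOSTR]) * hf_t * (x_prer + x0 - x_postr)

    y[0] = trpnl + dt * d_trpnl
    y[1] = trpnh + dt * d_trpnh
    y[2] = n_nop + dt * d_n
    y[3] = a_prer + dt * d_prer
    y[4] = a_postr + dt * d_postr
    y[5] = x_prer + dt * d_xprer
    y[6] = x_postr + dt * d_xpostr
    new_sl = sl + dt * dsl
    # hard stop at the physical sarcomere range
    if new_sl < p[_I_SLMIN]:
        new_sl = p[_I_SLMIN]
    elif new_sl > p[_I_SLMAX]:
        new_sl = p[_I_SLMAX]
    y[7] = new_sl
    y[8] = intf + dt * d_intf

    e_rate = gxb_t * sovf_thick * 1000.0  # 1/s
    return f_active, f_passive, f_after, e_rate, gxb_t, sovf_thick


@njit(cache=True)
def _run_twitch(y, ca_tab, ca_dt, p, dt, mode, n_steps, stride, out):
    n_ca = ca_tab.shape[0]
    n_out = 0
    for step in range(n_steps):
        t = step * dt
        # linear interpolation in the periodic Ca table
        u = (t / ca_dt) % n_ca
        i0 = int(u)
        w = u - i0
        i1 = i0 + 1
        if i1 >= n_ca:
            i1 = 0
        ca = ca_tab[i0] * (1.0 - w) + ca_tab[i1] * w
        if step % stride == 0:
            out[0, n_out] = t
            out[6, n_out] = y[7]          # SL before the step
            out[7, n_out] = y[8]          # force integral (model convention)
            n_out += 1
        fa, fp, faft, e, gxbt, sovf = _rice_step(y, ca, 0.0, p, dt, mode)
        if step % stride == 0:
            k = n_out - 1
            out[1, k] = fa
            out[2, k] = fp
            out[3, k] = faft
            out[4, k] = e
            out[5, k] = ca
    return n_out


# ---------------------------------------------------------------------------
# public containers and API


@dataclass
class MyofilamentState:
    """Cross-bridge state of one myofilament unit."""

    trpn_ca_l: float = 0.0147
    trpn_ca_h: float = 0.13
    n_nop: float = 0.99           # nonpermissive tropomyosin fraction
    xb_prer: float = 1.0e-4
    xb_postr: float = 1.0e-4
    x_prer: float = 0.0
    x_postr: float = 0.007
    sl: float = 2.2
    intf: float = 0.0             # internal-convention force integral

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, y) -> "MyofilamentState":
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self, params: MyofilamentParams) -> None:
        for n in ("trpn_ca_l", "trpn_ca_h", "n_nop", "xb_prer", "xb_postr"):
            v = getattr(self, n)
            if not -1.0e-9 <= v <= 1.0 + 1.0e-9:
                raise InvalidStateError(f"occupancy {n}={v} outside [0, 1]")
        if not params.SL_min <= self.sl <= params.SL_max:
            raise InvalidStateError(
                f"SL={self.sl} outside physical range "
                f"[{params.SL_min}, {params.SL_max}]")

    def sovf_thick(self, params: MyofilamentParams) -> float:
        return float(_overlap(self.sl, params.vector())[0])

    def g_xbT(self, params: MyofilamentParams) -> float:
        """Strain-dependent cross-bridge detachment rate, 1/s."""
        return float(_gxbT(self.x_postr, params.vector())) * 1000.0


def initial_state(params: MyofilamentParams, diastolic_ca: float = 0.1) -> MyofilamentState:
    """Myofilament state equilibrated with a diastolic Ca level (uM)."""
    kl = params.kon * diastolic_ca
    return MyofilamentState(
        trpn_ca_l=kl / (kl + params.koff_l),
        trpn_ca_h=kl / (kl + params.koff_h),
        n_nop=0.99, xb_prer=1.0e-4, xb_postr=1.0e-4,
        x_prer=0.0, x_postr=params.x_0, sl=params.SL0, intf=0.0)


@dataclass
class ForceBalance:
    """Normalized force components and the printed-form force integral."""

    F_active: float = 0.0
    F_passive: float = 0.0
    F_preload: float = 0.0
    F_afterload: float = 0.0
    Integral_Force: float = 0.0


def afterload_force(x: float, SL0: float, K_SE: float) -> float:
    """Series-elastic afterload K_SE * (x - SL0)."""
    if K_SE < 0:
        raise ValueError("K_SE must be non-negative")
    return K_SE * (x - SL0)


def passive_force(sl, params: MyofilamentParams):
    """Passive force (titin + collagen), multiplied by the passive scaling."""
    p = params.vector()
    sl_arr = np.atleast_1d(np.asarray(sl, dtype=float))
    out = np.array([_passive(s, p) for s in sl_arr])
    return float(out[0]) if np.isscalar(sl) else out


def integral_force(balance: dict | ForceBalance, t: np.ndarray | float,
                   *, traces: dict | None = None) -> np.ndarray:
    """Time integral of (F_active + F_passive - F_preload - F_afterload).

    Accepts a dict of force traces (arrays over the monotone time grid t) and
    returns the cumulative integral sampled on t.
    """
    tr = traces if traces is not None else balance
    if isinstance(tr, ForceBalance):
        raise TypeError("pass force traces as a mapping of arrays")
    t = np.asarray(t, dtype=float)
    integrand = (np.asarray(tr["F_active"], float) + np.asarray(tr["F_passive"], float)
                 - np.asarray(tr["F_preload"], float) - np.asarray(tr["F_afterload"], float))
    return trapezoid_cumulative(integrand, t)


def sl_step(state: MyofilamentState, balance: ForceBalance,
            params: MyofilamentParams, dt: float, mode: str = "isotonic") -> MyofilamentState:
    """Advance the sarcomere length by one step of the SL equation.

    Isometric mode holds dSL/dt = 0; isotonic mode advances SL by
    (Integral_Force + (SL0 - SL) * viscosity) / mass * dt, with the
    Integral_Force taken from the supplied balance.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    new = replace(state)
    if mode == "isotonic":
        dsl = (balance.Integral_Force
               + (params.SL0 - state.sl) * params.viscosity) / params.mass
        new.sl = state.sl + dt * dsl
    if not params.SL_min <= new.sl <= params.SL_max:
        raise InvalidStateError(f"SL={new.sl} left the physical range")
    return new


def atp_rate(state: MyofilamentState | None, params: MyofilamentParams | None = None,
             g_xbT: float | None = None, sovf_thick: float | None = None) -> float:
    """ATP consumption rate E = g_xbT * SOVF_thick (units of g_xbT, 1/s)."""
    if g_xbT is None:
        g_xbT = state.g_xbT(params)
    if sovf_thick is None:
        sovf_thick = state.sovf_thick(params)
    return g_xbT * sovf_thick


@dataclass
class TwitchResult:
    """Sampled traces and summary indices of a myofilament twitch run."""

    t: np.ndarray
    F_active: np.ndarray
    F_passive: np.ndarray
    F_afterload: np.ndarray
    E: np.ndarray                  # ATP consumption rate, 1/s
    ca: np.ndarray                 # uM
    sl: np.ndarray
    integral_force: np.ndarray     # model convention (see module docstring)
    params: MyofilamentParams
    final_state: MyofilamentState

    @property
    def strain(self) -> np.ndarray:
        """Segment strain (SL - SL0) / SL0."""
        return (self.sl - self.params.SL0) / self.params.SL0

    @property
    def peak_tension(self) -> float:
        return float(self.F_active.max())

    @property
    def time_to_peak(self) -> float:
        return float(self.t[int(np.argmax(self.F_active))])

    @property
    def cycle_atp(self) -> float:
        """Cycle integral of E over the run (dimensionless, E in 1/s, t in ms)."""
        return float(np.trapezoid(self.E, self.t) * 1.0e-3)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.t, "F_active": self.F_active,
            "F_passive": self.F_passive, "F_afterload": self.F_afterload,
            "E_per_s": self.E, "Ca_uM": self.ca, "SL_um": self.sl,
            "strain": self.strain,
        })


def run_twitch(ca_time: np.ndarray, ca_value: np.ndarray,
               params: MyofilamentParams, mode: str = "isotonic",
               n_cycles: int = 1, dt: float = 0.1,
               sample_dt: float = 0.5) -> TwitchResult:
    """Run the myofilament unit driven by a periodic Ca transient (uM).

    ca_time must be a uniform grid covering one cycle; the transient repeats
    with that period for n_cycles.
    """
    ca_time = np.asarray(ca_time, float)
    ca_value = np.asarray(ca_value, float)
    if np.any(ca_value <= 0.0):
        raise ValueError("Ca transient must be strictly positive")
    steps = np.diff(ca_time)
    if len(steps) == 0 or np.any(steps <= 0) or np.ptp(steps) > 1.0e-9 * steps[0]:
        raise ValueError("Ca transient requires a uniform, increasing time grid")
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ca_dt = float(steps[0])
    period = ca_time[-1] - ca_time[0] + ca_dt
    y = initial_state(params, diastolic_ca=float(ca_value.min())).vector()
    p = params.vector()
    stride = max(1, int(round(sample_dt / dt)))
    n_steps = int(round(n_cycles * period / dt))
    out = np.zeros((8, n_steps // stride + 1))
    n_out = _run_twitch(y, ca_value, ca_dt, p, dt,
                        _MODES[mode], n_steps, stride, out)
    out = out[:, :n_out]
    return TwitchResult(t=out[0], F_active=out[1], F_passive=out[2],
                        F_afterload=out[3], E=out[4], ca=out[5], sl=out[6],
                        integral_force=out[7], params=params,
                        final_state=MyofilamentState.from_vector(y))


def apply_passive_scaling(params: MyofilamentParams, factor: float) -> MyofilamentParams:
    """Multiply the passive scaling constant (heart-failure stiffening)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return replace(params, passive_scale=params.passive_scale * factor)
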