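"""Lumped circulation: valves, conservation, LVAD contract, PV metrics,
agreement with an independent stiff-solver integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardioem import circulation as circ
from cardioem.util import ConfigurationError, InstabilityError


@pytest.fixture()
def params():
    return circ.CirculationParams()


@pytest.mark.parametrize("up, down, r, expected", [
    (5.0, 10.0, 5.0, 0.0),     # closed valve
    (20.0, 10.0, 5.0, 2.0),    # Ohmic conduction
    (10.0, 10.0, 5.0, 0.0),    # zero gradient
])
def test_valve_flow_diode(up, down, r, expected):
    assert circ.valve_flow(up, down, r) == pytest.approx(expected)


def test_valve_flow_rejects_bad_resistance():
    with pytest.raises(ConfigurationError):
        circ.valve_flow(10.0, 0.0, 0.0)


def equilibrium_state(params, pressure=10.0):
    vols = np.array([
        params.V0_PA + params.C_PA * pressure,
        params.V0_PV + params.C_PV * pressure,
        params.V0_LA + params.C_LA * pressure,
        params.V0_SA + params.C_SA * pressure,
        params.V0_SV + params.C_SV * pressure,
        params.V0_RA + params.C_RA * pressure,
        100.0, 100.0])
    return circ.CirculationState(volumes=vols)


def test_equilibrium_is_stationary(params):
    """All pressures equal and LVAD off: every flow is zero."""
    state = equilibrium_state(params, 10.0)
    new = circ.circulation_step(state, params, circ.LVADParams(), 10.0, 10.0,
                                dt=1.0)
    np.testing.assert_allclose(new.volumes, state.volumes, rtol=0, atol=1e-12)
    assert not any(new.valve_open.values())


@pytest.mark.parametrize("lvad_on", [False, True])
def test_volume_conservation_each_step(params, lvad_on):
    """The closed loop conserves blood volume exactly; the LVAD only moves
    volume between compartments."""
    state = circ.CirculationState.from_params(params)
    lvad = circ.LVADParams(enabled=lvad_on)
    total0 = state.total_volume
    for k in range(200):
        state = circ.circulation_step(state, params, lvad,
                                      P_LV=60.0 if k % 10 < 5 else 5.0,
                                      P_RV=20.0 if k % 10 < 5 else 2.0,
                                      dt=0.5)
    assert state.total_volume == pytest.approx(total0, abs=1e-9)


def test_negative_volume_aborts_with_compartment_name(params):
    state = circ.CirculationState.from_params(params)
    state.volumes[circ.V_LV] = 0.05
    lvad = circ.LVADParams(enabled=True, mean_flow=6.0)
    with pytest.raises(InstabilityError, match="left_ventricle"):
        for _ in range(100):
            state = circ.circulation_step(state, params, lvad, 5.0, 5.0, dt=1.0)


def test_lvad_flow_contract():
    on = circ.LVADParams(enabled=True, mean_flow=3.0)
    off = circ.LVADParams(enabled=False, mean_flow=3.0)
    for t in (0.0, 123.4, 599.9):
        assert circ.lvad_flow(on, t) == 3.0
    assert circ.lvad_flow(off, 0.0) == 0.0
    assert circ.lvad_flow(circ.LVADParams(enabled=True, mean_flow=0.0)) == 0.0
    # time-average of a constant equals the constant
    ts = np.linspace(0.0, 600.0, 601)
    flows = np.array([circ.lvad_flow(on, t) for t in ts])
    assert np.trapezoid(flows, ts) / 600.0 == pytest.approx(3.0)
    with pytest.raises(ConfigurationError):
        circ.LVADParams(enabled=True, mean_flow=-1.0)


def synthetic_beat(edv, esv, bcl=600.0):
    t = np.linspace(0.0, bcl, 601)
    vol = esv + (edv - esv) * 0.5 * (1.0 + np.cos(2 * np.pi * t / bcl))
    pres = 120.0 * np.sin(np.pi * t / bcl) ** 2
    q_ao = np.where((t > 100) & (t < 196), 0.3, 0.0)
    return t, pres, vol, q_ao


@pytest.mark.parametrize("edv, esv, sv, ef_int", [
    (90.0, 60.0, 30.0, 33),      # dyssynchronous-failure row
    (88.0, 54.5, 33.5, 38),      # failing baseline row
])
def test_pv_metrics_sv_and_ef_from_printed_volumes(edv, esv, sv, ef_int):
    t, pres, vol, q_ao = synthetic_beat(edv, esv)
    pv = circ.pv_metrics(t, pres, vol, q_ao, circ.LVADParams(), 100.0)
    assert pv.SV == pytest.approx(sv, abs=1e-9)
    assert round(pv.EF) == ef_int
    assert pv.CO == pytest.approx(sv * 100.0 / 1000.0, abs=1e-9)


def test_pv_metrics_degenerate_equal_volumes():
    t, pres, vol, q_ao = synthetic_beat(80.0, 80.0)
    pv = circ.pv_metrics(t, pres, vol, q_ao, circ.LVADParams(), 100.0)
    assert pv.SV == 0.0
    assert pv.EF == 0.0


def test_pv_metrics_lvad_mode_omits_ef_and_counts_device_flow():
    t, pres, vol, q_ao = synthetic_beat(80.0, 60.0)
    lvad = circ.LVADParams(enabled=True, mean_flow=3.0)
    pv = circ.pv_metrics(t, pres, vol, q_ao, lvad, 100.0)
    assert pv.EF is None
    q_fwd = np.trapezoid(q_ao, t) / 600.0 * 60.0    # L/min
    assert pv.CO == pytest.approx(q_fwd + 3.0, rel=1e-6)
    assert pv.aortic_open_duration == pytest.approx(96.0, abs=2.0)


def test_pv_metrics_rejects_short_traces():
    t = np.linspace(0.0, 100.0, 50)
    with pytest.raises(ValueError):
        circ.pv_metrics(t, np.zeros(50), np.ones(50), np.zeros(50),
                        circ.LVADParams(), 100.0)


def test_circulation_matches_stiff_solver_oracle(params):
    """One beat with prescribed ventricular pressure forcing: the Heun
    updates track an LSODA reference on the same network within 1%."""

    def p_lv(t):
        return 8.0 + 110.0 * np.sin(np.pi * ((t % 600.0) / 350.0)) ** 2 \
            if (t % 600.0) < 350.0 else 8.0

    def p_rv(t):
        return 4.0 + 24.0 * np.sin(np.pi * ((t % 600.0) / 350.0)) ** 2 \
            if (t % 600.0) < 350.0 else 4.0

    lvad = circ.LVADParams(enabled=True, mean_flow=3.0)
    state = circ.CirculationState.from_params(params)
    v0 = state.volumes.copy()
    dt = 0.05
    t_end = 600.0
    t = 0.0
    while t < t_end - 1e-9:
        state = circ.circulation_step(state, params, lvad, p_lv(t), p_rv(t), dt)
        t += dt
    ref = solve_ivp(circ.rhs_for_oracle(params, lvad, p_lv, p_rv),
                    (0.0, t_end), v0, method="LSODA",
                    rtol=1e-8, atol=1e-8, max_step=1.0)
    scale = np.abs(ref.y[:, -1]).max()
    np.testing.assert_allclose(state.volumes, ref.y[:, -1],
                               atol=0.01 * scale, rtol=0.01)
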