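"""Cross-bridge myofilament model: forces, SL dynamics, ATP rate, twitches."""

import numpy as np
import pytest

from cardioem import rice
from cardioem.fixtures import make_ca_transient


@pytest.fixture(scope="module")
def params():
    return rice.MyofilamentParams()


@pytest.fixture(scope="module")
def twitch(params, ca_transient):
    t, ca = ca_transient
    return rice.run_twitch(t, ca, params, mode="isotonic", n_cycles=3)


@pytest.mark.parametrize("x, sl0, kse, expected", [
    (2.2, 2.2, 7.0, 0.0),          # at rest length
    (2.3, 2.2, 2.0, 0.2),          # direct product
    (2.5, 2.2, 0.0, 0.0),          # unloaded limit
])
def test_afterload_force(x, sl0, kse, expected):
    assert rice.afterload_force(x, sl0, kse) == pytest.approx(expected)


def test_afterload_rejects_negative_stiffness():
    with pytest.raises(ValueError):
        rice.afterload_force(2.2, 2.2, -1.0)


def test_integral_force_zero_and_constant_cases():
    t = np.linspace(0.0, 100.0, 201)
    zeros = np.zeros_like(t)
    traces = {"F_active": zeros, "F_passive": zeros,
              "F_preload": zeros, "F_afterload": zeros}
    assert np.all(rice.integral_force(traces, t) == 0.0)
    c = 0.37
    traces = {"F_active": np.full_like(t, c), "F_passive": zeros,
              "F_preload": zeros, "F_afterload": zeros}
    out = rice.integral_force(traces, t)
    assert out[-1] == pytest.approx(c * t[-1], rel=1e-12)


def test_integral_force_matches_refined_quadrature():
    """Coarse-grid quadrature of smooth traces agrees with a 100x refined
    trapezoid oracle to 0.1%."""
    t_fine = np.linspace(0.0, 200.0, 20001)
    t_coarse = t_fine[::100]

    def traces(t):
        return {"F_active": 0.5 * np.sin(t / 30.0) ** 2,
                "F_passive": 0.05 + 0.01 * np.cos(t / 50.0),
                "F_preload": np.full_like(t, 0.05),
                "F_afterload": 0.1 * np.sin(t / 80.0)}

    ref = rice.integral_force(traces(t_fine), t_fine)[-1]
    got = rice.integral_force(traces(t_coarse), t_coarse)[-1]
    assert got == pytest.approx(ref, rel=1e-3)


def test_integral_force_rejects_nonmonotone_grid():
    t = np.array([0.0, 1.0, 0.5])
    z = np.zeros_like(t)
    with pytest.raises(ValueError):
        rice.integral_force({"F_active": z, "F_passive": z,
                             "F_preload": z, "F_afterload": z}, t)


def test_sl_step_isometric_holds_length(params):
    state = rice.initial_state(params)
    balance = rice.ForceBalance(F_active=0.8, Integral_Force=-5.0)
    new = rice.sl_step(state, balance, params, dt=0.1, mode="isometric")
    assert new.sl == state.sl


def test_sl_step_equilibrium(params):
    state = rice.initial_state(params)         # SL = SL0
    balance = rice.ForceBalance(Integral_Force=0.0)
    new = rice.sl_step(state, balance, params, dt=0.1, mode="isotonic")
    assert new.sl == pytest.approx(state.sl)


def test_sl_step_matches_linear_ode_solution(params):
    """Constant force integral: SL relaxes exponentially to
    SL0 + IF/viscosity with time constant mass/viscosity."""
    if_const = -0.5
    dt = 0.01
    state = rice.initial_state(params)
    t_end = 120.0
    for _ in range(int(t_end / dt)):
        state = rice.sl_step(state, rice.ForceBalance(Integral_Force=if_const),
                             params, dt=dt, mode="isotonic")
    tau = params.mass / params.viscosity
    expected = params.SL0 + (if_const / params.viscosity) * (1.0 - np.exp(-t_end / tau))
    assert state.sl == pytest.approx(expected, rel=1e-3)


def test_atp_rate_product_identity(params):
    assert rice.atp_rate(None, g_xbT=0.0, sovf_thick=0.9) == 0.0
    assert rice.atp_rate(None, g_xbT=5.0, sovf_thick=0.4) == pytest.approx(2.0)
    state = rice.initial_state(params)
    expected = state.g_xbT(params) * state.sovf_thick(params)
    assert rice.atp_rate(state, params) == pytest.approx(expected)


def test_cycle_atp_matches_refined_sampling(params, ca_transient):
    """Cycle ATP integral is insensitive to the trace sampling (quadrature
    error < 0.1% against a 5x denser sampling of the same solution)."""
    t, ca = ca_transient
    coarse = rice.run_twitch(t, ca, params, n_cycles=1, dt=0.1, sample_dt=0.5)
    dense = rice.run_twitch(t, ca, params, n_cycles=1, dt=0.1, sample_dt=0.1)
    assert coarse.cycle_atp == pytest.approx(dense.cycle_atp, rel=1e-3)


def test_twitch_requires_positive_calcium(params):
    t = np.arange(0.0, 600.0, 0.5)
    ca = np.full_like(t, 0.1)
    ca[10] = 0.0
    with pytest.raises(ValueError):
        rice.run_twitch(t, ca, params)


def test_diastolic_calcium_produces_no_twitch(params, ca_transient):
    t, ca = ca_transient
    flat = np.full_like(ca, ca.min())
    quiet = rice.run_twitch(t, flat, params, mode="isometric", n_cycles=1)
    active = rice.run_twitch(t, ca, params, mode="isometric", n_cycles=1)
    assert quiet.peak_tension < 0.05 * active.peak_tension


def test_passive_scaling_does_not_change_isometric_active_peak(params, ca_transient):
    t, ca = ca_transient
    base = rice.run_twitch(t, ca, params, mode="isometric", n_cycles=1)
    stiff = rice.run_twitch(t, ca, rice.apply_passive_scaling(params, 2.0),
                            mode="isometric", n_cycles=1)
    assert stiff.peak_tension == pytest.approx(base.peak_tension, rel=1e-9)


def test_peak_tension_monotone_in_calcium_amplitude(params):
    peaks = []
    for peak_ca in (0.6, 1.0, 1.4):
        t, ca = make_ca_transient(peak=peak_ca, diastolic=0.1, bcl=600.0)
        tw = rice.run_twitch(t, ca, params, mode="isometric", n_cycles=1)
        peaks.append(tw.peak_tension)
    assert peaks[0] < peaks[1] < peaks[2]


def test_occupancies_bounded_and_atp_nonnegative(twitch, params):
    final = twitch.final_state
    final.validate(params)
    assert np.all(twitch.E >= 0.0)
    assert np.all(twitch.F_active >= -1e-9)


def test_isometric_twitch_relaxes_by_cycle_end(params, ca_transient):
    """Tension returns to within 2% of its diastolic value by the end of a
    600 ms cycle at steady pacing."""
    t, ca = ca_transient
    tw = rice.run_twitch(t, ca, params, mode="isometric", n_cycles=3)
    last_cycle = tw.t >= 2 * 600.0
    f = tw.F_active[last_cycle]
    assert f[-1] - f[0] < 0.02 * f.max()


def test_passive_force_scales_linearly_with_stiffening(params):
    sl = np.linspace(1.6, 2.35, 12)
    base = rice.passive_force(sl, params)
    for factor in (2.0, 5.0):
        scaled = rice.passive_force(sl, rice.apply_passive_scaling(params, factor))
        np.testing.assert_allclose(scaled, factor * base, rtol=1e-12)


def test_apply_passive_scaling_identity_and_validation(params):
    assert rice.apply_passive_scaling(params, 1.0).passive_scale == params.passive_scale
    with pytest.raises(ValueError):
        rice.apply_passive_scaling(params, 0.0)
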