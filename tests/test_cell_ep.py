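"""Single-myocyte electrophysiology: current decomposition, calcium fluxes,
stepping, pacing, and agreement with an independent stiff solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from cardioem import tnnp
from cardioem.util import InstabilityError, InvalidStateError

ZERO_CONDUCTANCES = dict(G_Na=0.0, G_K1=0.0, G_to=0.0, G_Kr=0.0, G_Ks=0.0,
                         G_CaL=0.0, k_NaCa=0.0, P_NaK=0.0, G_pCa=0.0,
                         G_pK=0.0, G_bCa=0.0, G_bNa=0.0)


def stim(t):
    return -52.0 if (t % 600.0) < 1.0 else 0.0


@pytest.fixture(scope="module")
def bdf_reference():
    """One beat of the same RHS integrated by an independent stiff solver."""
    p = tnnp.CellParams.for_cell_type("endo").vector()
    y0 = tnnp.resting_state().vector()
    return solve_ivp(tnnp.rhs_for_oracle(p, stim), (0.0, 600.0), y0,
                     method="BDF", max_step=0.5, rtol=1e-9, atol=1e-11,
                     dense_output=True)


def test_zero_conductances_zero_all_currents():
    params = tnnp.CellParams(**ZERO_CONDUCTANCES)
    cur = tnnp.ionic_currents(tnnp.resting_state(), params)
    for name in tnnp.CURRENT_NAMES:
        assert getattr(cur, name) == 0.0
    assert cur.I_ion == 0.0


@settings(max_examples=50, deadline=None)
@given(v=st.floats(-90.0, 40.0), cai=st.floats(1e-5, 2e-3),
       nai=st.floats(5.0, 20.0), ki=st.floats(120.0, 150.0),
       gate=st.floats(0.0, 1.0))
def test_current_sum_identity(v, cai, nai, ki, gate):
    """I_ion equals the sum of the twelve components for arbitrary states."""
    state = tnnp.CellState(V=v, m=gate, h=gate, j=gate, d=gate, f=gate,
                           ca_i=cai, na_i=nai, k_i=ki)
    cur = tnnp.ionic_currents(state, tnnp.CellParams.for_cell_type("mid"))
    parts = sum(getattr(cur, n) for n in tnnp.CURRENT_NAMES)
    assert cur.I_ion == pytest.approx(parts, abs=1e-12)


def test_nonfinite_state_rejected_with_field_name():
    state = tnnp.resting_state()
    state.ca_i = float("nan")
    with pytest.raises(InvalidStateError, match="ca_i"):
        tnnp.ionic_currents(state, tnnp.CellParams())


def test_resting_cell_is_stable_unpaced():
    """Unpaced for 600 ms, the resting potential drifts less than 1 mV."""
    params = tnnp.CellParams.for_cell_type("endo")
    proto = tnnp.PacingProtocol(n_beats=1, stim_amplitude=0.0)
    with pytest.warns(UserWarning, match="capture"):
        trace = tnnp.run_paced_cell(params, proto)
    assert abs(trace.V[-1] - trace.V[0]) < 1.0


def test_calcium_flux_identities():
    params = tnnp.CellParams()
    state = tnnp.resting_state()
    state.ca_sr = state.ca_i          # no gradient -> no leak
    fl = tnnp.calcium_fluxes(state, params)
    assert fl.I_leak == 0.0
    state = tnnp.resting_state()
    state.ca_i = params.K_up          # half-saturation of the uptake pump
    fl = tnnp.calcium_fluxes(state, params)
    assert fl.I_up == pytest.approx(params.Vmax_up / 2.0, rel=1e-12)
    # invariants: bounded uptake, leak sign follows the SR gradient
    state = tnnp.resting_state()
    fl = tnnp.calcium_fluxes(state, params)
    assert 0.0 <= fl.I_up <= params.Vmax_up
    assert np.sign(fl.I_leak) == np.sign(state.ca_sr - state.ca_i)
    with pytest.raises(InvalidStateError):
        bad = tnnp.resting_state()
        bad.ca_i = -1e-4
        tnnp.calcium_fluxes(bad, params)


def test_sr_flux_balance_over_one_beat():
    """Integral of (I_up - I_leak - I_rel) matches the SR total-calcium change
    scaled by the volume ratio of the calcium balance equations."""
    params = tnnp.CellParams.for_cell_type("endo")
    proto = tnnp.PacingProtocol(n_beats=1, sample_dt=0.02)
    trace = tnnp.run_paced_cell(params, proto)
    net = np.trapezoid(trace.I_up - trace.I_leak - trace.I_rel, trace.t)

    def sr_total(ca_sr):
        return ca_sr + ca_sr * params.Buf_sr / (ca_sr + params.K_bufsr)

    d_sr_total = sr_total(trace.final_state.ca_sr) - sr_total(tnnp.resting_state().ca_sr)
    expected = d_sr_total * params.V_sr / params.V_c
    assert net == pytest.approx(expected, rel=0.02, abs=1e-6)


def test_step_cell_zero_rhs_keeps_voltage():
    params = tnnp.CellParams(**ZERO_CONDUCTANCES)
    state = tnnp.resting_state()
    new = tnnp.step_cell(state, params, i_stim=0.0, dt=0.02)
    assert new.V == state.V


def test_step_cell_rejects_bad_dt():
    with pytest.raises(ValueError):
        tnnp.step_cell(tnnp.resting_state(), tnnp.CellParams(), 0.0, dt=-0.1)


def test_step_convergence_under_dt_halving():
    """Richardson-style check: halving dt changes the one-beat voltage trace
    by a bounded amount, consistent with a convergent scheme."""
    params = tnnp.CellParams.for_cell_type("endo")
    traces = {}
    for dt in (0.02, 0.01, 0.005):
        proto = tnnp.PacingProtocol(n_beats=1, dt=dt, sample_dt=0.1)
        traces[dt] = tnnp.run_paced_cell(params, proto).V
    d_coarse = np.abs(traces[0.02] - traces[0.01]).max()
    d_fine = np.abs(traces[0.01] - traces[0.005]).max()
    assert d_coarse < 1.0
    assert d_fine < 1.0


def test_suprathreshold_stimulus_elicits_action_potential():
    params = tnnp.CellParams.for_cell_type("endo")
    trace = tnnp.run_paced_cell(params, tnnp.PacingProtocol(n_beats=1))
    assert trace.V.max() > 10.0
    assert trace.captured


def test_zero_beats_gives_empty_traces():
    trace = tnnp.run_paced_cell(tnnp.CellParams(), tnnp.PacingProtocol(n_beats=0))
    assert len(trace.t) == 0
    assert len(trace.V) == 0


def test_paced_cell_reaches_steady_state(paced_cell_trace):
    """At BCL 600 ms, 20 beats suffice: last two beats' peak Ca_i agree to
    <1%, and the 20-beat peak is close to a 100-beat long run."""
    trace = paced_cell_trace
    assert trace.steady_state
    last = trace.beat(-1)
    prev = trace.beat(-2)
    pk_last = trace.ca_i[last].max()
    pk_prev = trace.ca_i[prev].max()
    assert abs(pk_last - pk_prev) < 0.01 * pk_prev
    # long-run oracle: by 100 beats the beat-to-beat drift has shrunk
    # further and the 20-beat transient is within the slow ionic
    # equilibration band of the long-run peak
    long_run = tnnp.run_paced_cell(
        tnnp.CellParams.for_cell_type("endo"),
        tnnp.PacingProtocol(n_beats=100, sample_dt=1.0))
    pk_100 = long_run.ca_i[long_run.beat(-1)].max()
    pk_99 = long_run.ca_i[long_run.beat(-2)].max()
    assert abs(pk_100 - pk_99) / pk_100 < abs(pk_last - pk_prev) / pk_last + 1e-3
    assert pk_last == pytest.approx(pk_100, rel=0.2)


def test_transmural_apd_ordering():
    """Midmyocardial cells have a longer APD than epicardial cells."""
    apds = {}
    for ct in ("mid", "epi"):
        params = tnnp.CellParams.for_cell_type(ct)
        trace = tnnp.run_paced_cell(params, tnnp.PacingProtocol(n_beats=5))
        b = trace.beat(-1)
        apds[ct] = tnnp.apd(trace.t[b], trace.V[b])
    assert apds["mid"] > apds["epi"]


def test_gates_and_concentrations_stay_physical(paced_cell_trace):
    trace = paced_cell_trace
    trace.final_state.validate()          # gates in [0,1], concentrations > 0
    assert trace.ca_i.min() > 0.0
    assert np.isfinite(trace.V).all()


def test_rush_larsen_matches_stiff_solver(bdf_reference):
    """Production step size agrees with the BDF oracle within 1 mV."""
    params = tnnp.CellParams.for_cell_type("endo")
    trace = tnnp.run_paced_cell(params, tnnp.PacingProtocol(n_beats=1))
    v_ref = bdf_reference.sol(trace.t)[0]
    assert np.abs(v_ref - trace.V).max() < 1.0
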