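"""Purkinje activation, monodomain propagation, CV calibration, stimuli."""

import numpy as np
import networkx as nx
import pytest

from cardioem import fixtures, monodomain, purkinje, scenario
from cardioem.util import ConfigurationError


@pytest.fixture(scope="module")
def toy_tree():
    """Root -> waypoint (1 cm) -> two terminals (2 cm each branch leg)."""
    g = nx.DiGraph()
    g.add_node(0, branch="his", terminal=-1)
    g.add_node(1, branch="left", terminal=-1)
    g.add_node(2, branch="left", terminal=7)
    g.add_node(3, branch="right", terminal=9)
    g.add_edge(0, 1, length=1.0)
    g.add_edge(1, 2, length=2.0)
    g.add_edge(0, 3, length=3.0)
    coords = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0], [0, 3, 0.0]])
    return purkinje.PurkinjeTree(graph=g, coords=coords, root=0,
                                 conduction_velocity=60.0)


def test_terminal_time_is_path_length_over_cv(toy_tree):
    act = purkinje.purkinje_activation(toy_tree, root_time=0.0)
    by_node = dict(zip(act.terminal_nodes, act.times))
    # 3 cm at 60 cm/s -> 50 ms, on both branches
    assert by_node[7] == pytest.approx(50.0)
    assert by_node[9] == pytest.approx(50.0)


def test_root_activates_at_root_time(toy_tree):
    assert toy_tree.path_length(toy_tree.root) == 0.0
    act = purkinje.purkinje_activation(toy_tree, root_time=12.5)
    assert np.nanmin(act.times) >= 12.5


def test_left_block_marks_left_terminals_unactivated(toy_tree):
    act = purkinje.purkinje_activation(toy_tree.with_block("left"))
    for node, time, branch in zip(act.terminal_nodes, act.times, act.branch):
        if branch == "left":
            assert np.isnan(time)
        else:
            assert time == pytest.approx(50.0)


def test_block_validation(toy_tree):
    with pytest.raises(ConfigurationError):
        toy_tree.with_block("middle")


def test_disconnected_terminal_rejected(toy_tree):
    g = toy_tree.graph.copy()
    g.add_node(9, branch="left", terminal=11)   # never connected
    bad = purkinje.PurkinjeTree(graph=g, coords=toy_tree.coords, root=0)
    with pytest.raises(ConfigurationError):
        purkinje.purkinje_activation(bad)


def test_monodomain_without_stimuli_never_activates():
    cable = fixtures.make_cable(length=1.0, n_nodes=51)
    res = monodomain.monodomain_simulate(cable, [], duration=50.0,
                                         diffusivity=1e-3)
    assert not res.eat.activated.any()
    assert np.isnan(res.eat.longest)


@pytest.fixture(scope="module")
def cable_run(calibrated_fine_cable):
    cable, d = calibrated_fine_cable
    stim = monodomain.Stimulus(nodes=np.arange(3), time=0.0)
    res = monodomain.monodomain_simulate(cable, [stim], duration=80.0,
                                         diffusivity=d)
    return cable, d, res


def test_cable_activation_linear_in_distance(cable_run):
    """EAT(x) along the cable is linear with slope 1/CV within 5%, away
    from the ends."""
    cable, d, res = cable_run
    n = cable.n_nodes
    sel = slice(int(0.2 * n), int(0.8 * n))
    x = cable.nodes[sel, 0]
    t = res.eat.times[sel]
    slope = np.polyfit(x, t, 1)[0]            # ms/cm
    cv = 1000.0 / slope                        # cm/s
    assert cv == pytest.approx(60.0, rel=0.05)


def test_cable_eat_monotone_with_distance(cable_run):
    cable, d, res = cable_run
    t = res.eat.times[: cable.n_nodes - 2]
    assert np.all(np.diff(t) > -1e-9)


def test_wave_collision_at_midpoint(calibrated_fine_cable):
    """Stimuli at both ends collide in the middle: the longest EAT is about
    half the single-end traversal time."""
    cable, d = calibrated_fine_cable
    both = [monodomain.Stimulus(nodes=np.arange(3), time=0.0),
            monodomain.Stimulus(nodes=np.arange(cable.n_nodes - 3,
                                                cable.n_nodes), time=0.0)]
    res2 = monodomain.monodomain_simulate(cable, both, duration=80.0,
                                          diffusivity=d)
    one = [monodomain.Stimulus(nodes=np.arange(3), time=0.0)]
    res1 = monodomain.monodomain_simulate(cable, one, duration=80.0,
                                          diffusivity=d)
    assert res2.eat.longest == pytest.approx(res1.eat.longest / 2.0, rel=0.10)
    mid = cable.n_nodes // 2
    assert res2.eat.times[mid] == pytest.approx(res2.eat.longest, abs=1.0)


def test_cv_calibration_hits_target(calibrated_fine_cable):
    cable, d = calibrated_fine_cable
    cv = monodomain.measure_cv(cable, d)
    assert abs(cv - 60.0) <= 1.2


def test_cv_calibration_idempotent(calibrated_fine_cable):
    """Starting from an already-calibrated coefficient returns it within
    tolerance."""
    cable, d = calibrated_fine_cable
    d2 = monodomain.calibrate_cv(cable, 60.0, d0=d)
    assert d2 == pytest.approx(d, rel=0.05)


def test_cv_scales_as_sqrt_of_diffusivity(calibrated_fine_cable):
    cable, d = calibrated_fine_cable
    cv1 = monodomain.measure_cv(cable, d)
    cv2 = monodomain.measure_cv(cable, 2.0 * d)
    assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.05)


def test_diffusion_operator_symmetric_zero_row_sums(small_mesh):
    lap = monodomain.build_diffusion(small_mesh, 1e-3)
    asym = abs(lap - lap.T).max()
    assert asym < 1e-12
    row_sums = np.asarray(lap.sum(axis=1)).ravel()
    assert np.abs(row_sums).max() < 1e-10


def test_scenario_stimuli_sinus_covers_all_terminals(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh)
    stims = scenario.build_scenario_stimuli(scenario.study_scenario("sinus"),
                                            tree, small_mesh)
    assert len(stims) == len(tree.terminal_graph_nodes())


def test_scenario_stimuli_lbbb_crt(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh)
    sc = scenario.study_scenario("lbbb_crt")
    stims = scenario.build_scenario_stimuli(sc, tree, small_mesh)
    act = purkinje.purkinje_activation(tree.with_block("left"))
    n_right = int(act.activated.sum())
    assert len(stims) == n_right + 1          # right terminals + CRT site
    assert stims[-1].time == pytest.approx(sc.crt_delay)
    crt_nodes = stims[-1].nodes
    assert np.all(small_mesh.region[crt_nodes] == 0)   # LV free wall
    # epicardial lead: the stimulated ball sits on the outer wall
    assert np.all(small_mesh.cell_type[crt_nodes] >= 1)
    assert np.any(small_mesh.cell_type[crt_nodes] == 2)


def test_rbbb_crt_site_options(small_mesh):
    default = scenario.study_scenario("rbbb_crt")
    assert default.crt_site == "rv_apex_endo"
    nodes = scenario.crt_site_nodes(small_mesh, "rv_apex_endo", 0.3)
    assert np.all(small_mesh.region[nodes] == 2)       # RV free wall
    alt = scenario.crt_site_nodes(small_mesh, "rv_septal_base", 0.3)
    assert len(alt) > 0


def test_fully_blocked_scenario_warns_and_is_empty(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh).with_block("left", "right")
    sc = scenario.Scenario(rhythm="sinus", crt_enabled=False)
    with pytest.warns(UserWarning, match="no stimuli"):
        stims = scenario.build_scenario_stimuli(sc, tree, small_mesh)
    assert stims == []
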