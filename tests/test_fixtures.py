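"""Synthetic-data generators: determinism, labelling rules, Purkinje
topology, cables and Ca transients."""

import numpy as np
import pytest

from cardioem import fixtures, monodomain, purkinje
from cardioem.mesh import RV_FREE
from cardioem.util import ConfigurationError


def test_mesh_generation_is_deterministic():
    cfg = fixtures.GeometryConfig(target_nodes=1200, seed=5)
    a = fixtures.make_biventricular_mesh(cfg)
    b = fixtures.make_biventricular_mesh(cfg)
    assert a.content_hash() == b.content_hash()
    np.testing.assert_array_equal(a.nodes, b.nodes)


def test_different_seed_changes_jitter():
    a = fixtures.make_biventricular_mesh(fixtures.GeometryConfig(target_nodes=1200, seed=0))
    b = fixtures.make_biventricular_mesh(fixtures.GeometryConfig(target_nodes=1200, seed=1))
    assert a.content_hash() != b.content_hash()


def test_layer_fractions_near_equal_thirds(default_mesh):
    """At the default resolution the equal-thirds layer rule holds to 5%."""
    counts = np.bincount(default_mesh.cell_type, minlength=3) / default_mesh.n_nodes
    np.testing.assert_allclose(counts, 1.0 / 3.0, atol=0.05)


@pytest.mark.parametrize("mesh_fixture", ["small_mesh", "default_mesh"])
def test_no_element_mixes_endo_and_epi(mesh_fixture, request):
    mesh = request.getfixturevalue(mesh_fixture)
    span = mesh.cell_type[mesh.elements]
    assert int((span.max(axis=1) - span.min(axis=1)).max()) <= 1


def test_mesh_passes_activation_validity_checks(small_mesh):
    small_mesh.validate()
    lap = monodomain.build_diffusion(small_mesh, 1e-3)
    assert lap.shape == (small_mesh.n_nodes, small_mesh.n_nodes)


def test_mesh_has_all_labels(small_mesh):
    assert set(np.unique(small_mesh.cell_type)) == {0, 1, 2}
    assert set(np.unique(small_mesh.region)) == {0, 1, 2}
    assert set(np.unique(small_mesh.longitudinal)) == {0, 1, 2}


def test_infeasible_geometry_rejected():
    with pytest.raises(ConfigurationError):
        fixtures.GeometryConfig(lv_wall=5.0)
    with pytest.raises(ConfigurationError):
        fixtures.GeometryConfig(layer_fractions=(0.5, 0.5, 0.5))


def test_purkinje_same_seed_identical(small_mesh):
    cfg = fixtures.PurkinjeConfig(seed=3)
    a = fixtures.make_purkinje_tree(small_mesh, cfg)
    b = fixtures.make_purkinje_tree(small_mesh, cfg)
    assert a.to_frame().equals(b.to_frame())


def test_purkinje_terminals_are_endocardial(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh)
    tree.validate()
    for n in tree.terminal_graph_nodes():
        tissue = tree.graph.nodes[n]["terminal"]
        assert small_mesh.cell_type[tissue] == 0          # endo layer
        branch = tree.graph.nodes[n]["branch"]
        if branch == "left":
            assert small_mesh.region[tissue] != RV_FREE
        else:
            assert small_mesh.region[tissue] == RV_FREE


def test_purkinje_path_lengths_positive_finite(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh)
    for n in tree.terminal_graph_nodes():
        length = tree.path_length(n)
        assert np.isfinite(length) and length > 0.0


def test_left_block_covers_all_lv_terminals(small_mesh):
    tree = fixtures.make_purkinje_tree(small_mesh).with_block("left")
    act = purkinje.purkinje_activation(tree)
    lv_terminal = small_mesh.region[act.terminal_nodes] != RV_FREE
    assert np.isnan(act.times[lv_terminal]).all()
    assert np.isfinite(act.times[~lv_terminal]).all()


def test_cable_spacing_and_probes():
    cable = fixtures.make_cable(length=2.0, n_nodes=201)
    assert cable.n_nodes == 201
    assert cable.spacing == pytest.approx(0.01)
    i1, i2 = int(0.25 * 200), int(0.75 * 200)
    assert 0 < i1 < i2 < 200                    # interior probes
    with pytest.raises(ConfigurationError):
        fixtures.make_cable(n_nodes=2)


def test_ca_transient_peak_and_constant_cases():
    t, ca = fixtures.make_ca_transient(peak=1.2, diastolic=0.1)
    assert ca.max() == pytest.approx(1.2)
    assert ca.min() >= 0.1 - 1e-12
    t, flat = fixtures.make_ca_transient(peak=0.1, diastolic=0.1)
    np.testing.assert_allclose(flat, 0.1)
    with pytest.raises(ValueError):
        fixtures.make_ca_transient(peak=0.05, diastolic=0.1)


def test_ca_transient_area_matches_refined_grid():
    t1, ca1 = fixtures.make_ca_transient(dt=0.5)
    t2, ca2 = fixtures.make_ca_transient(dt=0.01)
    a1 = np.trapezoid(ca1, t1)
    a2 = np.trapezoid(ca2, t2)
    assert a1 == pytest.approx(a2, rel=1e-3)
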