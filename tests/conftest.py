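"""Shared fixtures: small meshes for unit tests, the full default study
(expensive; session-scoped) for scenario-level and acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from cardioem import fixtures, monodomain, study as study_mod, tnnp


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse biventricular mesh for structural tests."""
    cfg = fixtures.GeometryConfig(target_nodes=1500)
    return fixtures.make_biventricular_mesh(cfg)


@pytest.fixture(scope="session")
def default_mesh():
    """Biventricular mesh at the generator's default resolution."""
    return fixtures.make_biventricular_mesh()


@pytest.fixture(scope="session")
def fine_cable():
    """The 2 cm / 201-node calibration cable."""
    return fixtures.make_cable(length=2.0, n_nodes=201)


@pytest.fixture(scope="session")
def calibrated_fine_cable(fine_cable):
    """(cable, diffusivity) calibrated to 60 cm/s."""
    d = monodomain.calibrate_cv(fine_cable, 60.0)
    return fine_cable, d


@pytest.fixture(scope="session")
def ca_transient():
    """Synthetic single-peak Ca transient (uM), one 600 ms cycle."""
    return fixtures.make_ca_transient(peak=1.0, diastolic=0.1, bcl=600.0)


@pytest.fixture(scope="session")
def paced_cell_trace():
    """20-beat paced endocardial cell at BCL 600 ms."""
    params = tnnp.CellParams.for_cell_type("endo")
    return tnnp.run_paced_cell(params, tnnp.PacingProtocol(n_beats=20))


@pytest.fixture(scope="session")
def default_study():
    return study_mod.Study()


@pytest.fixture(scope="session")
def study_results(default_study):
    """All seven conditions on the default synthetic geometry (seed-fixed)."""
    results = default_study.run_all()
    return results, study_mod.results_table(results)
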