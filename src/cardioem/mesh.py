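"""Tissue mesh container: nodes, lattice connectivity, labels, conduction.

The mesh is a regular-lattice sampling of the ventricular walls (or a 1-D
cable).  Nodes carry a transmural cell type (endo/mid/epi), a wall region
(LV free wall / septum / RV free wall) and a longitudinal band (apex / mid /
base).  Edges are axis-tagged lattice links used to assemble the monodomain
diffusion operator; tetrahedral elements are kept for interchange/export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import ConfigurationError

# cell types
ENDO, MIDW, EPI = 0, 1, 2
CELL_TYPE_NAMES = ("endo", "mid", "epi")
# wall regions
LV_FREE, SEPTUM, RV_FREE = 0, 1, 2
REGION_NAMES = ("lv_free_wall", "septum", "rv_free_wall")
# longitudinal bands
APEX, MID_LONG, BASE = 0, 1, 2
LONGITUDINAL_NAMES = ("apex", "mid", "base")


def diffusion_from_resistivity(rho, S, C_m_area) -> np.ndarray:
    """Axis-wise diffusion coefficients 1/(rho_i S_i C_m).

    rho in kOhm*cm, S in 1/cm, C_m_area in uF/cm^2 gives D in cm^2/ms.
    """
    rho = np.broadcast_to(np.asarray(rho, float), (3,))
    S = np.broadcast_to(np.asarray(S, float), (3,))
    if np.any(rho <= 0) or np.any(S <= 0) or C_m_area <= 0:
        raise ConfigurationError("resistivity, S and C_m must be positive")
    return 1.0 / (rho * S * C_m_area)


@dataclass
class TissueMesh:
    """Labelled lattice mesh of the ventricular walls."""

    nodes: np.ndarray              # (N, 3) cm
    elements: np.ndarray           # (M, 4) tetrahedra (may be empty for 1-D)
    spacing: float                 # lattice spacing h, cm
    edges: np.ndarray              # (E, 3): node_i, node_j, axis
    cell_type: np.ndarray          # (N,) int8 in {ENDO, MIDW, EPI}
    region: np.ndarray             # (N,) int8 in {LV_FREE, SEPTUM, RV_FREE}
    longitudinal: np.ndarray       # (N,) int8 in {APEX, MID_LONG, BASE}
    ndepth: np.ndarray             # (N,) normalized transmural depth
    seed: int = 0
    diffusivity: np.ndarray | None = None   # (3,) cm^2/ms, set by calibration
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        n = self.n_nodes
        if self.spacing <= 0:
            raise ConfigurationError("spacing must be positive")
        for name in ("cell_type", "region", "longitudinal", "ndepth"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"label array {name} does not cover the mesh")
        if self.elements.size and (self.elements.min() < 0 or self.elements.max() >= n):
            raise ConfigurationError("element connectivity references unknown nodes")
        if self.edges.size and (self.edges[:, :2].min() < 0 or self.edges[:, :2].max() >= n):
            raise ConfigurationError("edge connectivity references unknown nodes")
        if self.diffusivity is not None and np.any(np.asarray(self.diffusivity) <= 0):
            raise ConfigurationError("conduction coefficients must be positive")

    def select(self, *, cell_type=None, region=None, longitudinal=None) -> np.ndarray:
        """Node indices matching all given label criteria."""
        mask = np.ones(self.n_nodes, dtype=bool)
        if cell_type is not None:
            mask &= self.cell_type == CELL_TYPE_NAMES.index(cell_type)
        if region is not None:
            mask &= self.region == REGION_NAMES.index(region)
        if longitudinal is not None:
            mask &= self.longitudinal == LONGITUDINAL_NAMES.index(longitudinal)
        return np.nonzero(mask)[0]

    def content_hash(self) -> str:
        """Deterministic digest of geometry and labels."""
        import hashlib

        hsh = hashlib.sha256()
        for arr in (self.nodes, self.elements, self.edges, self.cell_type,
                    self.region, self.longitudinal):
            hsh.update(np.ascontiguousarray(arr).tobytes())
        return hsh.hexdigest()
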