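"""Deterministic synthetic fixtures: geometry, Purkinje trees, Ca transients.

No anatomical imaging data ships with this package.  Everything the coupled
pipeline needs is generated here as a pure function of (config, seed):

* an idealized two-ellipsoid biventricular wall mesh on a regular lattice,
  with transmural endo/mid/epi layering, free-wall/septum and apex/mid/base
  region labels;
* left/right Purkinje trees rooted at a common His-like node with terminals
  restricted to endocardial nodes;
* 1-D calibration cables for conduction-velocity measurement;
* a smooth single-peak Ca2+ transient for stand-alone myofilament runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mesh import TissueMesh, LV_FREE, SEPTUM, RV_FREE, APEX, MID_LONG, BASE
from .purkinje import PurkinjeTree
from .util import ConfigurationError


@dataclass(frozen=True)
class GeometryConfig:
    """Idealized biventricular geometry (all lengths in cm).

    The LV is the wall between two concentric ellipsoids; the RV is a thinner
    crescent-shaped wall attached on the +x side; both are truncated at a
    basal plane.  ``target_nodes`` controls the lattice spacing.
    """

    lv_outer: tuple = (2.2, 2.2, 3.1)     # semi-axes (x, y, z)
    lv_wall: float = 1.0                  # LV free-wall thickness
    rv_outer: tuple = (2.7, 2.1, 2.8)     # RV outer ellipsoid semi-axes
    rv_center_x: float = 1.6              # RV ellipsoid shift along +x
    rv_wall: float = 0.9
    base_fraction: float = 0.55           # basal truncation at z = f * c_lv
    layer_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)   # endo / mid / epi
    apex_fraction: float = 0.35           # lowest fraction of z-extent = apex
    base_band: float = 0.2                # top fraction of z-extent = base
    target_nodes: int = 6500
    jitter: float = 0.1                   # coordinate jitter, fraction of h
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("layer fractions must sum to 1")
        if self.lv_wall >= min(self.lv_outer):
            raise ConfigurationError("LV wall thicker than its semi-axes")
        if self.rv_wall >= min(self.rv_outer):
            raise ConfigurationError("RV wall thicker than its semi-axes")
        if self.target_nodes < 100:
            raise ConfigurationError("target_nodes too small for a wall mesh")


def _ellipsoid_u(pts: np.ndarray, semi: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Scaled radius sqrt(sum ((p-c)/a)^2): 1 on the surface, <1 inside."""
    q = (pts - center) / semi
    return np.sqrt((q * q).sum(axis=1))


def _harmonic_depth(n, edges, endo, epi):
    """Laplace transmural depth: 0 on endocardium, 1 on epicardium."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    i, j = edges[:, 0], edges[:, 1]
    ones = np.ones(len(i))
    adj = sp.coo_matrix((np.concatenate([ones, ones]),
                         (np.concatenate([i, j]), np.concatenate([j, i]))),
                        shape=(n, n)).tocsr()
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    fixed = endo | epi
    vals = np.where(epi, 1.0, 0.0)
    free = ~fixed
    if not free.any():
        return vals
    lap = lap.tocsr()
    a_ff = lap[free][:, free]
    a_fb = lap[free][:, fixed]
    x = spla.spsolve(a_ff.tocsc(), -a_fb @ vals[fixed])
    out = vals.copy()
    out[free] = x
    return np.clip(out, 0.0, 1.0)


def _build_masks(cfg: GeometryConfig, h: float):
    a_lv_o = np.array(cfg.lv_outer)
    a_lv_i = a_lv_o - cfg.lv_wall
    a_rv_o = np.array(cfg.rv_outer)
    a_rv_i = a_rv_o - cfg.rv_wall
    c_lv = np.zeros(3)
    c_rv = np.array([cfg.rv_center_x, 0.0, 0.0])
    z_base = cfg.base_fraction * cfg.lv_outer[2]

    lim = np.maximum(a_lv_o, a_rv_o + np.abs(c_rv)) + 2 * h
    nx_ = np.arange(-lim[0], lim[0] + h, h)
    ny_ = np.arange(-lim[1], lim[1] + h, h)
    nz_ = np.arange(-lim[2], z_base + h, h)
    gx, gy, gz = np.meshgrid(nx_, ny_, nz_, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    u_lv_o = _ellipsoid_u(pts, a_lv_o, c_lv)
    u_lv_i = _ellipsoid_u(pts, a_lv_i, c_lv)
    u_rv_o = _ellipsoid_u(pts, a_rv_o, c_rv)
    u_rv_i = _ellipsoid_u(pts, a_rv_i, c_rv)
    below_base = pts[:, 2] <= z_base

    lv_wall = (u_lv_o <= 1.0) & (u_lv_i >= 1.0) & below_base
    rv_cav = (u_rv_i < 1.0) & (u_lv_o > 1.0) & below_base
    rv_wall = ((u_rv_o <= 1.0) & (u_rv_i >= 1.0) & (u_lv_o > 1.0)
               & below_base & (pts[:, 0] > 0.0))
    wall = lv_wall | rv_wall
    return (pts, (gx.shape, wall), lv_wall, rv_wall, rv_cav,
            u_lv_o, u_lv_i, u_rv_o, u_rv_i, z_base)


def make_biventricular_mesh(config: GeometryConfig | None = None) -> TissueMesh:
    """Generate the idealized biventricular wall mesh (deterministic per seed)."""
    cfg = config if config is not None else GeometryConfig()

    # two-pass spacing selection toward the target node count
    h = 0.25
    for _ in range(2):
        res = _build_masks(cfg, h)
        n = int(res[1][1].sum())
        h = h * (n / cfg.target_nodes) ** (1.0 / 3.0)
        h = float(min(max(h, 0.05), 0.5))
    (pts, (shape, wall), lv_wall, rv_wall, rv_cav,
     u_lv_o, u_lv_i, u_rv_o, u_rv_i, z_base) = _build_masks(cfg, h)

    idx = np.nonzero(wall)[0]
    if len(idx) == 0:
        raise ConfigurationError("geometry produced an empty wall")
    order = np.full(wall.shape[0], -1, dtype=np.int64)
    order[idx] = np.arange(len(idx))
    nodes = pts[idx]

    in_lv = lv_wall[idx]
    in_rv = rv_wall[idx] & ~in_lv
    lv_cav = (u_lv_i < 1.0) & (pts[:, 2] <= z_base)
    cavity = lv_cav | rv_cav

    # lattice connectivity: 6-neighbor edges between wall nodes, plus
    # boundary classification of wall nodes facing a cavity (endocardium) or
    # the exterior (epicardium); basal cut faces are left natural
    lin = np.arange(wall.shape[0]).reshape(shape)
    edges = []
    is_endo_surf = np.zeros(len(idx), dtype=bool)
    is_epi_surf = np.zeros(len(idx), dtype=bool)
    for axis in range(3):
        a = lin.take(np.arange(0, shape[axis] - 1), axis=axis).ravel()
        b = lin.take(np.arange(1, shape[axis]), axis=axis).ravel()
        m = wall[a] & wall[b]
        edges.append(np.column_stack([order[a[m]], order[b[m]], np.full(m.sum(), axis)]))
        for w_side, o_side in ((a, b), (b, a)):
            mb = wall[w_side] & ~wall[o_side]
            wn = order[w_side[mb]]
            outside = o_side[mb]
            is_endo_surf[wn[cavity[outside]]] = True
            not_cut = ~cavity[outside] & (pts[outside, 2] <= z_base)
            is_epi_surf[wn[not_cut]] = True
    edges = np.concatenate(edges, axis=0)

    # transmural depth: harmonic (Laplace) field, 0 at the endocardial
    # surfaces, 1 at the epicardium -- smooth across the LV/RV junction
    ndepth = _harmonic_depth(len(idx), edges, is_endo_surf,
                             is_epi_surf & ~is_endo_surf)

    # layer thresholds are per-ventricle depth quantiles, so the configured
    # fractions are node-count (wall-volume) fractions
    f_endo, f_mid, _ = cfg.layer_fractions
    layer = np.zeros(len(idx), dtype=np.int64)
    for sel in (in_lv, in_rv):
        if not sel.any():
            continue
        q1, q2 = np.quantile(ndepth[sel], [f_endo, f_endo + f_mid])
        layer[sel] = np.where(ndepth[sel] <= q1, 0,
                              np.where(ndepth[sel] <= q2, 1, 2))

    # wall region: septum = LV-wall nodes inside the RV outer ellipsoid
    region = np.where(in_rv, RV_FREE, LV_FREE)
    region[in_lv & (u_rv_o[idx] <= 1.0)] = SEPTUM

    z = nodes[:, 2]
    z_lo, z_hi = z.min(), z.max()
    zn = (z - z_lo) / max(z_hi - z_lo, 1e-12)
    longitudinal = np.where(zn < cfg.apex_fraction, APEX,
                            np.where(zn > 1.0 - cfg.base_band, BASE, MID_LONG))

    # tetrahedral elements: split every fully-interior lattice cube into 5 tets
    nxn, nyn, nzn = shape
    base_idx = lin[:-1, :-1, :-1].ravel()
    offs = [0, 1, nzn, nzn + 1, nyn * nzn, nyn * nzn + 1, nyn * nzn + nzn,
            nyn * nzn + nzn + 1]
    cube = np.column_stack([base_idx + o for o in offs])
    full = wall[cube].all(axis=1)
    cube = cube[full]
    # corner order: (x,y,z) bit pattern c000,c001,c010,c011,c100,c101,c110,c111
    t5 = np.array([[0, 1, 4, 2], [1, 3, 7, 2], [1, 4, 7, 5], [2, 4, 6, 7],
                   [1, 2, 7, 4]])
    tets = order[cube[:, t5].reshape(-1, 4)]

    # construction rule: no element may contain both endo and epi nodes; the
    # few violations left in thin-wall / junction cells (cube diagonals) are
    # resolved by demoting the epicardial member to mid
    for _ in range(8):
        span = layer[tets]
        bad = (span.max(axis=1) - span.min(axis=1)) >= 2
        if not bad.any():
            break
        demote = np.unique(tets[bad][span[bad] == 2])
        layer[demote] = 1

    rng = np.random.default_rng(cfg.seed)
    coords = nodes + (rng.uniform(-0.5, 0.5, nodes.shape) * cfg.jitter * h)

    return TissueMesh(
        nodes=coords, elements=tets, spacing=h, edges=edges,
        cell_type=layer.astype(np.int8), region=region.astype(np.int8),
        longitudinal=longitudinal.astype(np.int8),
        ndepth=ndepth, seed=cfg.seed,
        meta={"kind": "biventricular", "target_nodes": cfg.target_nodes},
    )


def make_cable(length: float = 2.0, n_nodes: int = 201) -> TissueMesh:
    """Uniform 1-D cable of endocardial cells (length in cm)."""
    if n_nodes < 3:
        raise ConfigurationError("a cable needs at least 3 nodes")
    h = length / (n_nodes - 1)
    x = np.linspace(0.0, length, n_nodes)
    nodes = np.column_stack([x, np.zeros(n_nodes), np.zeros(n_nodes)])
    edges = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes),
                             np.zeros(n_nodes - 1, dtype=np.int64)])
    zero = np.zeros(n_nodes, dtype=np.int8)
    return TissueMesh(nodes=nodes, elements=np.empty((0, 4), dtype=np.int64),
                      spacing=h, edges=edges, cell_type=zero.copy(),
                      region=zero.copy(), longitudinal=zero.copy(),
                      ndepth=np.zeros(n_nodes), seed=0,
                      meta={"kind": "cable", "length": length})


@dataclass(frozen=True)
class PurkinjeConfig:
    """Construction parameters of the two-branch conduction tree."""

    n_terminals_left: int = 16
    n_terminals_right: int = 12
    branch_depth: int = 4          # recursive bisection depth
    conduction_velocity: float = 60.0   # cm/s along the tree
    seed: int = 0

    def __post_init__(self):
        if self.n_terminals_left < 1 or self.n_terminals_right < 1:
            raise ConfigurationError("both branches need at least one terminal")


def _bisect_route(graph, coords, parent, targets, target_nodes, depth, branch, rng):
    """Recursively split targets in two and route edges toward centroids."""
    if len(targets) == 0:
        return
    if len(targets) == 1 or depth == 0:
        for t_xyz, t_node in zip(targets, target_nodes):
            nid = len(coords)
            coords.append(t_xyz)
            graph.add_edge(parent, nid,
                           length=float(np.linalg.norm(t_xyz - coords[parent])))
            graph.nodes[nid]["branch"] = branch
            graph.nodes[nid]["terminal"] = int(t_node)
        return
    # split along the direction of largest spread
    pts = np.asarray(targets)
    axis = int(np.argmax(pts.std(axis=0)))
    med = np.median(pts[:, axis])
    left_sel = pts[:, axis] <= med
    if left_sel.all() or not left_sel.any():
        left_sel = np.zeros(len(pts), dtype=bool)
        left_sel[: len(pts) // 2] = True
    for sel in (left_sel, ~left_sel):
        sub = pts[sel]
        sub_nodes = [n for n, s in zip(target_nodes, sel) if s]
        centroid = sub.mean(axis=0)
        p_xyz = coords[parent]
        mid = p_xyz + 0.55 * (centroid - p_xyz)
        mid = mid + rng.normal(0.0, 0.03, 3)
        nid = len(coords)
        coords.append(mid)
        graph.add_edge(parent, nid, length=float(np.linalg.norm(mid - p_xyz)))
        graph.nodes[nid]["branch"] = branch
        graph.nodes[nid]["terminal"] = -1
        _bisect_route(graph, coords, nid, list(sub), sub_nodes,
                      depth - 1, branch, rng)


def make_purkinje_tree(mesh: TissueMesh, config: PurkinjeConfig | None = None) -> PurkinjeTree:
    """Build the left/right conduction tree on the mesh endocardium.

    The His-like root sits at the basal septal endocardium; each bundle runs
    to an apical waypoint and fans out by recursive bisection to seeded
    endocardial target nodes of its ventricle.
    """
    cfg = config if config is not None else PurkinjeConfig()
    rng = np.random.default_rng(cfg.seed)

    endo = mesh.cell_type == 0
    lv_endo = np.nonzero(endo & (mesh.region != RV_FREE))[0]
    rv_endo = np.nonzero(endo & (mesh.region == RV_FREE))[0]
    if len(lv_endo) == 0 or len(rv_endo) == 0:
        raise ConfigurationError("mesh lacks endocardial nodes in one ventricle")

    sept = np.nonzero((mesh.region == SEPTUM) & endo)[0]
    pool = sept if len(sept) else lv_endo
    root_node = int(pool[np.argmax(mesh.nodes[pool, 2])])
    root_xyz = mesh.nodes[root_node].copy()

    graph = nx.DiGraph()
    coords = [root_xyz]
    graph.add_node(0, branch="his", terminal=-1)

    for branch, endo_ids, n_term in (("left", lv_endo, cfg.n_terminals_left),
                                     ("right", rv_endo, cfg.n_terminals_right)):
        pick = rng.choice(endo_ids, size=min(n_term, len(endo_ids)), replace=False)
        pick = np.sort(pick)
        # bundle waypoint: descend toward the apex of this ventricle first
        apex_node = endo_ids[np.argmin(mesh.nodes[endo_ids, 2])]
        way = root_xyz + 0.7 * (mesh.nodes[apex_node] - root_xyz)
        nid = len(coords)
        coords.append(way)
        graph.add_edge(0, nid, length=float(np.linalg.norm(way - root_xyz)))
        graph.nodes[nid]["branch"] = branch
        graph.nodes[nid]["terminal"] = -1
        _bisect_route(graph, coords, nid, list(mesh.nodes[pick]), list(pick),
                      cfg.branch_depth, branch, rng)

    return PurkinjeTree(graph=graph, coords=np.asarray(coords), root=0,
                        conduction_velocity=cfg.conduction_velocity,
                        seed=cfg.seed)


def make_ca_transient(peak: float = 1.0, diastolic: float = 0.1,
                      time_to_peak: float = 40.0, decay: float = 60.0,
                      bcl: float = 600.0, dt: float = 0.5):
    """Smooth single-peak Ca transient (uM), repeating at the cycle length.

    Shape: (t/tp)^2 exp(2(1 - t/tp)) rise normalized to 1 at t = tp, times an
    exponential decay envelope; qualitatively matches a paced myocyte
    transient with deactivation complete by ~250 ms.
    """
    if not peak >= diastolic > 0:
        raise ValueError("require peak >= diastolic > 0")
    t = np.arange(0.0, bcl, dt)
    x = t / time_to_peak
    shape = (x ** 2) * np.exp(2.0 * (1.0 - x)) * np.exp(-np.maximum(t - time_to_peak, 0.0) / decay)
    shape /= shape.max()
    return t, diastolic + (peak - diastolic) * shape
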