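"""Reduced-order segmental ventricular mechanics: mapping and timing metrics.

The 3-D electrical activation field is reduced to N wall segments per
ventricle (default 18 = 3 longitudinal x 6 circumferential).  Each segment
is one myofilament unit whose Ca2+ input is the steady-state single-cell
transient delayed by the segment's mean electrical activation time (EAT);
its wall-volume fraction is its node-count share of the ventricle.

Timing metrics: mechanical activation time (MAT) is the first instant local
shortening reaches 10% of its eventual maximum (linearly interpolated);
the electromechanical delay is EMD = MAT - EAT at every site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TissueMesh, RV_FREE
from .monodomain import EATMap
from .rice import MyofilamentParams, apply_passive_scaling
from .util import ConfigurationError


@dataclass
class SegmentModel:
    """One wall segment: region membership, activation delay, traces."""

    segment_id: int
    chamber: str                   # 'lv' (incl. septum) or 'rv'
    node_ids: np.ndarray
    wall_fraction: float           # of its ventricle's wall volume
    delay: float                   # ms, mean EAT of member nodes (NaN: never activated)
    region_label: str = ""
    tension: np.ndarray | None = None
    strain: np.ndarray | None = None
    atp_rate: np.ndarray | None = None

    @property
    def activated(self) -> bool:
        return np.isfinite(self.delay)


def map_activation_to_segments(eat: EATMap, mesh: TissueMesh,
                               n_long: int = 3, n_circ: int = 6) -> list:
    """Partition the walls into segments and attach mean-EAT delays.

    LV segments cover the LV free wall plus septum; RV segments the RV free
    wall.  Segments with no electrically activated node are flagged
    (delay = NaN) and excluded from averages downstream.
    """
    if n_long < 1 or n_circ < 1:
        raise ConfigurationError("need at least one segment per direction")
    if len(eat.times) != mesh.n_nodes:
        raise ConfigurationError("EAT map does not cover the mesh")
    segments = []
    sid = 0
    for chamber, mask in (("lv", mesh.region != RV_FREE),
                          ("rv", mesh.region == RV_FREE)):
        ids = np.nonzero(mask)[0]
        if len(ids) == 0:
            continue
        z = mesh.nodes[ids, 2]
        theta = np.arctan2(mesh.nodes[ids, 1], mesh.nodes[ids, 0])
        z_edges = np.quantile(z, np.linspace(0, 1, n_long + 1))
        z_edges[-1] += 1e-9
        t_edges = np.linspace(-np.pi, np.pi + 1e-9, n_circ + 1)
        zi = np.clip(np.searchsorted(z_edges, z, side="right") - 1, 0, n_long - 1)
        ti = np.clip(np.searchsorted(t_edges, theta, side="right") - 1, 0, n_circ - 1)
        n_wall = len(ids)
        for a in range(n_long):
            for b in range(n_circ):
                members = ids[(zi == a) & (ti == b)]
                if len(members) == 0:
                    continue
                times = eat.times[members]
                act = np.isfinite(times)
                delay = float(np.mean(times[act])) if act.any() else float("nan")
                segments.append(SegmentModel(
                    segment_id=sid, chamber=chamber, node_ids=members,
                    wall_fraction=len(members) / n_wall, delay=delay,
                    region_label=f"{chamber}_z{a}_c{b}"))
                sid += 1
    return segments


def compute_mat(strain_trace: np.ndarray, time_grid: np.ndarray,
                fraction: float = 0.1) -> float:
    """Mechanical activation time: shortening first reaches ``fraction`` of
    its eventual maximum, linearly interpolated.  NaN for a flat trace."""
    t = np.asarray(time_grid, float)
    s = np.asarray(strain_trace, float)
    if len(t) != len(s) or len(t) < 2:
        raise ValueError("strain trace and time grid must match (length >= 2)")
    shortening = -(s - s[0])
    peak = shortening.max()
    if peak <= 1.0e-12:
        return float("nan")     # mechanically unactivated
    level = fraction * peak
    above = np.nonzero(shortening >= level)[0]
    k = above[0]
    if k == 0:
        return float(t[0])
    return float(np.interp(level, [shortening[k - 1], shortening[k]],
                           [t[k - 1], t[k]]))


@dataclass
class TimingMaps:
    """Per-segment EAT/MAT/EMD with activated-site averages."""

    segment_ids: np.ndarray
    eat: np.ndarray
    mat: np.ndarray
    emd: np.ndarray
    n_excluded: int = 0

    @property
    def avg_mat(self) -> float:
        return float(np.nanmean(self.mat))

    @property
    def avg_emd(self) -> float:
        return float(np.nanmean(self.emd))

    @property
    def avg_eat(self) -> float:
        return float(np.nanmean(self.eat))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"segment": self.segment_ids, "eat_ms": self.eat,
                             "mat_ms": self.mat, "emd_ms": self.emd})


def compute_emd(mat: dict | np.ndarray, eat: dict | np.ndarray,
                segment_ids=None) -> TimingMaps:
    """Element-wise EMD = MAT - EAT over the common site set.

    Accepts aligned arrays (with segment_ids) or {site: value} mappings;
    sites present in only one map are excluded and counted.
    """
    if isinstance(mat, dict) or isinstance(eat, dict):
        common = sorted(set(mat) & set(eat))
        excluded = len(set(mat) ^ set(eat))
        ids = np.asarray(common)
        mat_a = np.array([mat[k] for k in common], dtype=float)
        eat_a = np.array([eat[k] for k in common], dtype=float)
    else:
        mat_a = np.asarray(mat, dtype=float)
        eat_a = np.asarray(eat, dtype=float)
        if mat_a.shape != eat_a.shape:
            raise ValueError("MAT and EAT maps are not aligned")
        ids = (np.arange(len(mat_a)) if segment_ids is None
               else np.asarray(segment_ids))
        excluded = 0
    return TimingMaps(segment_ids=ids, eat=eat_a, mat=mat_a,
                      emd=mat_a - eat_a, n_excluded=excluded)


def apply_hf_stiffening(params: MyofilamentParams,
                        factor: float = 5.0) -> MyofilamentParams:
    """Stiffen the passive element by ``factor`` (heart-failure myocardium).

    Every condition of the study, including sinus rhythm, uses factor 5:
    the baseline is a failing ventricle.
    """
    return apply_passive_scaling(params, factor)


def total_atp(segments: list, t: np.ndarray, beat: slice | None = None,
              chamber_weights: dict | None = None) -> float:
    """Wall-volume-weighted cycle ATP: sum_i w_i * integral E_i dt (E in 1/s,
    t in ms -> dimensionless cycles of turnover)."""
    if beat is None:
        beat = slice(0, len(t))
    weights = chamber_weights or {"lv": 0.75, "rv": 0.25}
    total = 0.0
    for seg in segments:
        if seg.atp_rate is None:
            raise ConfigurationError(f"segment {seg.segment_id} has no ATP trace")
        w = seg.wall_fraction * weights[seg.chamber]
        total += w * np.trapezoid(seg.atp_rate[beat], t[beat]) * 1.0e-3
    return float(total)
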