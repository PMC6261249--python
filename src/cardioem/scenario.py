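"""Study scenarios: rhythm, bundle branch block, CRT pacing, LVAD flag.

A scenario fixes the electrical setup (which Purkinje branch conducts, and
where/when CRT pacing stimulates) and whether the assist device is enabled in
the mechanical stage.  The same electrical setup is reused for the +LVAD
variants: the device enters only the mechanical computation.

CRT sites: for LBBB the pacing lead is on the LV free wall (epicardial,
mid-level, lateral); for RBBB at the RV endocardial apex, with the RV-side
bottom-of-septum position available as a named alternative.  The CRT
stimulus fires a configurable delay after Purkinje root activation; the
default (60 ms) is comparable to the bundle transit time, so pacing
coincides with intrinsic endocardial breakthrough rather than pre-exciting
its region, which would add dispersion instead of removing it.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .mesh import TissueMesh
from .monodomain import Stimulus
from .purkinje import PurkinjeTree, purkinje_activation
from .util import ConfigurationError

RHYTHMS = ("sinus", "lbbb", "rbbb")
CRT_SITES = ("lv_free_wall", "rv_apex_endo", "rv_septal_base")

#: the seven study conditions
STUDY_SCENARIOS = (
    "sinus", "lbbb", "lbbb_crt", "lbbb_crt_lvad",
    "rbbb", "rbbb_crt", "rbbb_crt_lvad",
)


@dataclass(frozen=True)
class Scenario:
    """One of the rhythm/therapy conditions of the study."""

    rhythm: str = "sinus"
    crt_enabled: bool = False
    crt_site: str | None = None          # default chosen from the rhythm
    crt_delay: float = 60.0              # ms after Purkinje root activation
    lvad_enabled: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.rhythm not in RHYTHMS:
            raise ConfigurationError(f"unknown rhythm {self.rhythm!r}")
        if self.crt_site is not None and self.crt_site not in CRT_SITES:
            raise ConfigurationError(f"unknown CRT site {self.crt_site!r}")
        if self.crt_enabled and self.crt_site is None:
            site = "lv_free_wall" if self.rhythm == "lbbb" else "rv_apex_endo"
            object.__setattr__(self, "crt_site", site)
        if self.name is None:
            label = self.rhythm
            if self.crt_enabled:
                label += "_crt"
            if self.lvad_enabled:
                label += "_lvad"
            object.__setattr__(self, "name", label)

    @property
    def blocked_branches(self) -> tuple:
        return {"sinus": (), "lbbb": ("left",), "rbbb": ("right",)}[self.rhythm]


def study_scenario(name: str) -> Scenario:
    """The named condition of the seven-scenario study."""
    if name not in STUDY_SCENARIOS:
        raise ConfigurationError(f"unknown study scenario {name!r}")
    rhythm = name.split("_")[0]
    return Scenario(rhythm=rhythm, crt_enabled="crt" in name,
                    lvad_enabled="lvad" in name, name=name)


def crt_site_nodes(mesh: TissueMesh, site: str, radius: float) -> np.ndarray:
    """Tissue nodes of the named pacing site (a ball around the lead tip)."""
    from scipy.spatial import cKDTree

    if site == "lv_free_wall":
        cand = mesh.select(region="lv_free_wall", longitudinal="mid",
                           cell_type="epi")
        if len(cand) == 0:
            raise ConfigurationError("mesh has no LV free-wall mid epicardium")
        tip = cand[np.argmin(mesh.nodes[cand, 0])]     # most lateral (-x)
    elif site == "rv_apex_endo":
        cand = mesh.select(region="rv_free_wall", longitudinal="apex",
                           cell_type="endo")
        if len(cand) == 0:
            raise ConfigurationError("mesh has no RV apical endocardium")
        tip = cand[np.argmin(mesh.nodes[cand, 2])]     # lowest
    elif site == "rv_septal_base":
        cand = mesh.select(region="septum", longitudinal="apex")
        if len(cand) == 0:
            raise ConfigurationError("mesh has no apical septum")
        # RV-facing (deep) side of the septum, at its bottom
        depth_rank = mesh.ndepth[cand] - mesh.nodes[cand, 2]
        tip = cand[np.argmax(depth_rank)]
    else:
        raise ConfigurationError(f"unknown CRT site {site!r}")
    ball = cKDTree(mesh.nodes).query_ball_point(mesh.nodes[tip], radius)
    return np.asarray(sorted(ball), dtype=np.int64)


def build_scenario_stimuli(scenario: Scenario, tree: PurkinjeTree,
                           mesh: TissueMesh, root_time: float = 0.0,
                           stim_radius: float | None = None,
                           amplitude: float = -80.0,
                           duration: float = 2.0) -> list:
    """Tissue stimuli for one beat of the scenario.

    Each unblocked Purkinje terminal injects a suprathreshold current in a
    small ball around its junction node at its arrival time (zero junction
    delay); CRT adds one pacing-site stimulus at root_time + crt_delay.
    """
    from scipy.spatial import cKDTree

    if stim_radius is None:
        stim_radius = max(0.25, 1.3 * mesh.spacing)
    blocked = set(tree.blocked) | set(scenario.blocked_branches)
    act = purkinje_activation(tree.with_block(*blocked), root_time=root_time)
    kt = cKDTree(mesh.nodes)
    stimuli = []
    for node, t in zip(act.terminal_nodes[act.activated],
                       act.times[act.activated]):
        ball = np.asarray(kt.query_ball_point(mesh.nodes[node], stim_radius),
                          dtype=np.int64)
        stimuli.append(Stimulus(nodes=ball, time=float(t),
                                amplitude=amplitude, duration=duration))
    if scenario.crt_enabled:
        nodes = crt_site_nodes(mesh, scenario.crt_site, stim_radius)
        stimuli.append(Stimulus(nodes=nodes, time=root_time + scenario.crt_delay,
                                amplitude=amplitude, duration=duration))
    if not stimuli:
        warnings.warn(f"scenario {scenario.name!r} produces no stimuli "
                      "(all branches blocked, CRT disabled)", stacklevel=2)
    return stimuli
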