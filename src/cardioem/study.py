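"""End-to-end scenario runner and seven-condition study.

One scenario run chains: Purkinje activation + CRT stimuli -> monodomain
tissue solve -> EAT map -> segmental reduction -> steady-state cell Ca
transient, delayed per segment -> coupled wall mechanics + circulation
(+/- LVAD) for 20 simulated seconds at BCL 600 ms -> metrics of the final
(steady-state) beat: longest EAT, average MAT/EMD, PV-loop indices,
cycle ATP, end-systolic/end-diastolic snapshot fields.

The expensive shared artifacts (mesh, conduction calibration, Purkinje tree,
electrical activation per rhythm/CRT setup, single-cell transient) are cached
on the Study object, and the same electrical setup is reused for the +LVAD
variant of a condition (the device enters only the mechanics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging
import time

import numpy as np
import pandas as pd

from . import coupled, fixtures, monodomain, tnnp
from .circulation import CirculationParams, LVADParams, PVLoopMetrics, pv_metrics
from .rice import MyofilamentParams
from .scenario import STUDY_SCENARIOS, Scenario, build_scenario_stimuli, study_scenario
from .segments import (TimingMaps, apply_hf_stiffening, compute_emd,
                       compute_mat, map_activation_to_segments, total_atp)
from .util import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the desk-scale study."""

    geometry: fixtures.GeometryConfig = field(default_factory=fixtures.GeometryConfig)
    purkinje: fixtures.PurkinjeConfig = field(default_factory=fixtures.PurkinjeConfig)
    target_cv: float = 60.0            # cm/s, tissue and Purkinje
    bcl: float = 600.0                 # ms
    ep_duration: float = 400.0         # ms, tissue solve window
    dt_ep: float = 0.02                # ms
    cell_beats: int = 20               # pacing to cell steady state
    mech_duration: float = 20000.0     # ms
    dt_mech: float = 0.1               # ms
    n_long: int = 3                    # segments per ventricle: n_long x n_circ
    n_circ: int = 6
    hf_stiffening: float = 5.0         # passive scaling, all scenarios
    lvad_rate: float = 3.0             # L/min
    pressure_coupling: float = 0.0005  # normalized force per mmHg
    share_coupling: float = 2.0        # force-imbalance stretch coupling
    seed: int = 0

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, seed=seed,
                       geometry=replace(self.geometry, seed=seed),
                       purkinje=replace(self.purkinje, seed=seed))


@dataclass
class ScenarioResult:
    """Metrics of one condition, all from the steady-state analysis beat."""

    scenario: Scenario
    longest_eat: float             # ms
    avg_mat: float                 # ms
    avg_emd: float                 # ms
    pv: PVLoopMetrics
    atp_rate_mean: float           # 1/s, wall-weighted cycle average
    atp_cycle_total: float         # dimensionless turnover per cycle
    timing: TimingMaps
    tension_end_systole: np.ndarray
    atp_end_systole: np.ndarray
    strain_end_diastole: np.ndarray
    n_segments_excluded: int
    seed: int

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "EDV_mL": self.pv.EDV if not self.scenario.lvad_enabled else np.nan,
            "ESV_mL": self.pv.ESV if not self.scenario.lvad_enabled else np.nan,
            "CO_L_min": self.pv.CO,
            "EF_pct": self.pv.EF if self.pv.EF is not None else np.nan,
            "longest_EAT_ms": self.longest_eat,
            "avg_MAT_ms": self.avg_mat,
            "avg_EMD_ms": self.avg_emd,
            "ATP_per_s": self.atp_rate_mean,
            "peak_LVP_mmHg": self.pv.peak_lv_pressure,
            "AV_open_ms": self.pv.aortic_open_duration,
            "LVAD_L_min": self.pv.lvad_mean_flow,
        }


class Study:
    """Shared-artifact cache and runner for the seven-condition study."""

    def __init__(self, config: StudyConfig | None = None,
                 circulation: CirculationParams | None = None,
                 myofilament: MyofilamentParams | None = None,
                 lv_wall: coupled.WallParams = coupled.LV_WALL_DEFAULT,
                 rv_wall: coupled.WallParams = coupled.RV_WALL_DEFAULT):
        self.config = config if config is not None else StudyConfig()
        self.circulation = circulation if circulation is not None else CirculationParams()
        base_myo = myofilament if myofilament is not None else MyofilamentParams()
        self.myofilament = apply_hf_stiffening(base_myo, self.config.hf_stiffening)
        self.lv_wall = lv_wall
        self.rv_wall = rv_wall
        self._mesh = None
        self._tree = None
        self._diffusivity = None
        self._ca = None
        self._eat_cache: dict = {}

    # -- shared artifacts ---------------------------------------------------

    @property
    def mesh(self):
        if self._mesh is None:
            t0 = time.perf_counter()
            self._mesh = fixtures.make_biventricular_mesh(self.config.geometry)
            self._mesh.diffusivity = np.full(3, self.diffusivity)
            log.info("mesh: %d nodes (%.1fs)", self._mesh.n_nodes,
                     time.perf_counter() - t0)
        return self._mesh

    @property
    def diffusivity(self) -> float:
        if self._diffusivity is None:
            t0 = time.perf_counter()
            probe = fixtures.make_biventricular_mesh(self.config.geometry) \
                if self._mesh is None else self._mesh
            cable = fixtures.make_cable(length=40 * probe.spacing, n_nodes=41)
            self._diffusivity = monodomain.calibrate_cv(
                cable, self.config.target_cv, dt=self.config.dt_ep)
            log.info("CV calibration: D=%.4g cm^2/ms (%.1fs)",
                     self._diffusivity, time.perf_counter() - t0)
        return self._diffusivity

    @property
    def tree(self):
        if self._tree is None:
            cfg = replace(self.config.purkinje,
                          conduction_velocity=self.config.target_cv)
            self._tree = fixtures.make_purkinje_tree(self.mesh, cfg)
        return self._tree

    @property
    def ca_transient(self):
        """Steady-state Ca_i transient of one paced beat (t from stimulus, mM)."""
        if self._ca is None:
            t0 = time.perf_counter()
            params = tnnp.CellParams.for_cell_type("endo")
            proto = tnnp.PacingProtocol(bcl=self.config.bcl,
                                        n_beats=self.config.cell_beats,
                                        dt=self.config.dt_ep)
            trace = tnnp.run_paced_cell(params, proto)
            if not trace.steady_state:
                log.warning("cell transient not at steady state after %d beats",
                            self.config.cell_beats)
            b = trace.beat(-1)
            self._ca = (trace.t[b] - trace.t[b][0], trace.ca_i[b])
            log.info("cell transient: peak %.3g mM (%.1fs)",
                     self._ca[1].max(), time.perf_counter() - t0)
        return self._ca

    def electrical_activation(self, scenario: Scenario) -> monodomain.EATMap:
        """EAT map of the scenario's electrical setup (cached; LVAD-independent)."""
        key = (scenario.rhythm, scenario.crt_enabled, scenario.crt_site,
               scenario.crt_delay)
        if key not in self._eat_cache:
            t0 = time.perf_counter()
            stimuli = build_scenario_stimuli(scenario, self.tree, self.mesh)
            res = monodomain.monodomain_simulate(
                self.mesh, stimuli, duration=self.config.ep_duration,
                dt=self.config.dt_ep)
            self._eat_cache[key] = res.eat
            log.info("EP %s: longest EAT %.1f ms (%.1fs)", scenario.name,
                     res.eat.longest, time.perf_counter() - t0)
        return self._eat_cache[key]

    # -- scenario execution -------------------------------------------------

    def run(self, scenario: Scenario | str) -> ScenarioResult:
        if isinstance(scenario, str):
            scenario = study_scenario(scenario)
        cfg = self.config
        eat = self.electrical_activation(scenario)
        segs = map_activation_to_segments(eat, self.mesh,
                                          n_long=cfg.n_long, n_circ=cfg.n_circ)
        n_excluded = sum(1 for s in segs if not s.activated)
        ca_t, ca_v = self.ca_transient
        lvad = LVADParams(enabled=scenario.lvad_enabled, mean_flow=cfg.lvad_rate)

        t0 = time.perf_counter()
        traces = coupled.run_coupled(
            segs, self.myofilament, ca_t, ca_v,
            duration=cfg.mech_duration, bcl=cfg.bcl, dt=cfg.dt_mech,
            circulation=self.circulation, lvad=lvad,
            lv_wall=self.lv_wall, rv_wall=self.rv_wall,
            pressure_coupling=cfg.pressure_coupling,
            share_coupling=cfg.share_coupling)
        log.info("mechanics %s: %.1fs", scenario.name, time.perf_counter() - t0)

        beat = traces.beat_slice(-1)
        t_beat = traces.t[beat] - traces.t[beat][0]
        hr = 60000.0 / cfg.bcl
        pv = pv_metrics(traces.t[beat], traces.p_lv[beat], traces.v_lv[beat],
                        traces.q_aortic[beat], lvad, hr, traces.q_lvad[beat])

        active = [s for s in segs if s.activated]
        mats = np.array([compute_mat(s.strain[beat], t_beat) for s in active])
        eats = np.array([s.delay for s in active])
        timing = compute_emd(mats, eats,
                             segment_ids=np.array([s.segment_id for s in active]))

        wall_tot = self.lv_wall.wall_volume + self.rv_wall.wall_volume
        weights = {"lv": self.lv_wall.wall_volume / wall_tot,
                   "rv": self.rv_wall.wall_volume / wall_tot}
        atp_cycle = total_atp(active, traces.t, beat, chamber_weights=weights)
        atp_mean = atp_cycle * 1000.0 / (traces.t[beat][-1] - traces.t[beat][0])

        i_es = beat.start + int(np.argmin(traces.v_lv[beat]))
        i_ed = beat.start + int(np.argmax(traces.v_lv[beat]))
        return ScenarioResult(
            scenario=scenario, longest_eat=eat.longest,
            avg_mat=timing.avg_mat, avg_emd=timing.avg_emd, pv=pv,
            atp_rate_mean=float(atp_mean), atp_cycle_total=float(atp_cycle),
            timing=timing,
            tension_end_systole=traces.seg_tension[:, i_es].copy(),
            atp_end_systole=traces.seg_atp[:, i_es].copy(),
            strain_end_diastole=traces.seg_sl[:, i_ed] / self.myofilament.SL0 - 1.0,
            n_segments_excluded=n_excluded, seed=cfg.seed)

    def run_all(self, scenarios=STUDY_SCENARIOS) -> dict:
        results = {}
        for name in scenarios:
            t0 = time.perf_counter()
            results[name] = self.run(name)
            log.info("scenario %s done in %.1fs", name, time.perf_counter() - t0)
        return results


def results_table(results: dict) -> pd.DataFrame:
    """Per-condition summary frame (one row per scenario)."""
    rows = [r.as_row() for r in results.values()]
    return pd.DataFrame(rows).set_index("scenario")


def run_study(config: StudyConfig | None = None, **study_kwargs):
    """Run all seven conditions; returns (results dict, summary frame)."""
    study = Study(config, **study_kwargs)
    results = study.run_all()
    return results, results_table(results)


# ---------------------------------------------------------------------------
# effect summaries


_PAIRS = (
    ("lbbb", "lbbb_crt"),
    ("lbbb", "lbbb_crt_lvad"),
    ("rbbb", "rbbb_crt"),
    ("rbbb", "rbbb_crt_lvad"),
)
_PCT_METRICS = ("longest_EAT_ms", "avg_MAT_ms", "avg_EMD_ms", "ATP_per_s")


def percent_reduction(reference: float, treated: float) -> float:
    """100 * (reference - treated) / reference, rounded to one decimal."""
    if reference == 0:
        raise ZeroDivisionError("reference value is zero")
    return round(100.0 * (reference - treated) / reference, 1)


def summarize_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Effect sizes between untreated and treated conditions.

    Reductions are percentages with the untreated scenario as denominator;
    cardiac-output effects are absolute deltas (L/min).  Input: a frame
    indexed by scenario with the study's summary columns (as produced by
    :func:`results_table` or :func:`cardioem.reference.published_summary`).
    """
    rows = []
    for ref_name, trt_name in _PAIRS:
        for name in (ref_name, trt_name):
            if name not in table.index:
                raise ConfigurationError(f"scenario {name!r} missing from table")
        ref = table.loc[ref_name]
        trt = table.loc[trt_name]
        for metric in _PCT_METRICS:
            if metric not in table.columns:
                continue
            rows.append({
                "comparison": f"{ref_name} -> {trt_name}", "metric": metric,
                "reference": ref[metric], "treated": trt[metric],
                "effect": "percent_reduction",
                "value": percent_reduction(ref[metric], trt[metric])})
        if "CO_L_min" in table.columns:
            rows.append({
                "comparison": f"{ref_name} -> {trt_name}", "metric": "CO_L_min",
                "reference": ref["CO_L_min"], "treated": trt["CO_L_min"],
                "effect": "delta",
                "value": round(trt["CO_L_min"] - ref["CO_L_min"], 1)})
    return pd.DataFrame(rows)
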