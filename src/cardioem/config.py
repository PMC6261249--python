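"""Structured-text (YAML) configuration for all model parameter sets."""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .circulation import CirculationParams
from .coupled import LV_WALL_DEFAULT, RV_WALL_DEFAULT, WallParams
from .fixtures import GeometryConfig, PurkinjeConfig
from .rice import MyofilamentParams
from .study import StudyConfig
from .tnnp import CellParams
from .util import ConfigurationError


def _build(cls, data: dict, **nested):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    clean = dict(data)
    for key, val in clean.items():
        if isinstance(val, list):
            clean[key] = tuple(val)
    return cls(**clean, **nested)


def study_config_to_dict(cfg: StudyConfig,
                         circulation: CirculationParams | None = None,
                         myofilament: MyofilamentParams | None = None,
                         lv_wall: WallParams = LV_WALL_DEFAULT,
                         rv_wall: WallParams = RV_WALL_DEFAULT) -> dict:
    return {
        "study": {k: v for k, v in asdict(cfg).items()
                  if k not in ("geometry", "purkinje")},
        "geometry": asdict(cfg.geometry),
        "purkinje": asdict(cfg.purkinje),
        "circulation": asdict(circulation or CirculationParams()),
        "myofilament": asdict(myofilament or MyofilamentParams()),
        "lv_wall": asdict(lv_wall),
        "rv_wall": asdict(rv_wall),
    }


def save_config(path, cfg: StudyConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write("# cardioem study configuration (units in field docstrings)\n")
        yaml.safe_dump(study_config_to_dict(cfg, **kwargs), fh,
                       default_flow_style=False, sort_keys=False)


def load_config(path) -> dict:
    """Load a study configuration file.

    Returns a dict with keys: study (StudyConfig), circulation, myofilament,
    lv_wall, rv_wall -- each an instantiated parameter object.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geometry = _build(GeometryConfig, raw.get("geometry", {}))
    purkinje = _build(PurkinjeConfig, raw.get("purkinje", {}))
    study = _build(StudyConfig, raw.get("study", {}),
                   geometry=geometry, purkinje=purkinje)
    return {
        "study": study,
        "circulation": _build(CirculationParams, raw.get("circulation", {})),
        "myofilament": _build(MyofilamentParams, raw.get("myofilament", {})),
        "lv_wall": _build(WallParams, raw.get("lv_wall", {})) if raw.get("lv_wall")
        else LV_WALL_DEFAULT,
        "rv_wall": _build(WallParams, raw.get("rv_wall", {})) if raw.get("rv_wall")
        else RV_WALL_DEFAULT,
    }


def cell_params_to_yaml(params: CellParams, path) -> None:
    """Write a cell parameter set as key-value YAML with a units comment."""
    with open(path, "w") as fh:
        fh.write("# ventricular cell parameters: conductances nS/pF, "
                 "volumes uL, concentrations mM, time ms\n")
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def cell_params_from_yaml(path) -> CellParams:
    with open(path) as fh:
        return _build(CellParams, yaml.safe_load(fh) or {})
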