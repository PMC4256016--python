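"""YAML parameter configs: flat key-value sections mirroring the parameter
dataclasses, with units documented in comments of the shipped default file
(``fimsim/data/default_params.yaml``)."""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .bond_kinetics import BondParams
from .fimbria_mechanics import FimbriaParams
from .hydrodynamics import DEFAULT_GAP_UM, DEFAULT_RADIUS_UM

__all__ = ["load_params", "save_params", "default_params",
           "default_config_path"]

_CELL_DEFAULTS = {"radius_um": DEFAULT_RADIUS_UM, "gap_um": DEFAULT_GAP_UM,
                  "viscosity_Pa_s": 1.0e-3}
_SIM_DEFAULTS = {"dt_s": 1.0e-4, "output_dt_s": 0.01,
                 "grace_window_s": 0.1, "k_wall_pN_nm": 50.0}


def default_params() -> dict:
    """Default parameter blocks: fimbria, bond, cell, simulation."""
    return {"fimbria": FimbriaParams(), "bond": BondParams(),
            "cell": dict(_CELL_DEFAULTS), "simulation": dict(_SIM_DEFAULTS)}


def default_config_path() -> Path:
    return Path(str(resources.files("fimsim") / "data" /
                    "default_params.yaml"))


def load_params(path=None) -> dict:
    """Load a config file; missing keys fall back to the defaults."""
    blocks = default_params()
    if path is None:
        return blocks
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "fimbria" in raw:
        blocks["fimbria"] = dataclasses.replace(blocks["fimbria"],
                                                **raw["fimbria"])
    if "bond" in raw:
        blocks["bond"] = dataclasses.replace(blocks["bond"], **raw["bond"])
    for sec in ("cell", "simulation"):
        if sec in raw:
            unknown = set(raw[sec]) - set(blocks[sec])
            if unknown:
                raise ValueError(f"unknown {sec} keys: {sorted(unknown)}")
            blocks[sec].update(raw[sec])
    return blocks


def save_params(path, blocks: dict) -> None:
    out = {}
    for sec, val in blocks.items():
        out[sec] = dataclasses.asdict(val) if dataclasses.is_dataclass(val) \
            else dict(val)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
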