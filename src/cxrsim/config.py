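"""YAML run configuration: loading, defaults, and provenance echoes."""

from __future__ import annotations

import json
import os
from importlib import resources

import yaml

from .errors import ValidationError
from .nodule_model import NoduleIntensityModel
from .preprocess import AttenuationModel, hu_to_mu
from .simulate import SimConfig, StudyConfig


def default_config() -> dict:
    """The shipped default study configuration as a plain dict."""
    with resources.files("cxrsim.data").joinpath("paper_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    """Load a YAML config, filling unset sections from the defaults."""
    cfg = default_config()
    if path is not None:
        with open(str(path)) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def build_study_config(cfg: dict) -> StudyConfig:
    """Turn a config dict into a StudyConfig with attenuation/intensity set."""
    att_cfg = cfg.get("attenuation", {})
    att = AttenuationModel(
        mu_water=float(att_cfg.get("mu_water", 0.2059)),
        mu_air=float(att_cfg.get("mu_air", 0.0)),
        S=int(att_cfg.get("S", 1000)),
    )
    nod_cfg = cfg.get("nodules", {})
    intensity = NoduleIntensityModel(
        mu_soft=hu_to_mu(float(nod_cfg.get("soft_tissue_hu", 50.0)), att)
    )
    study = cfg.get("study", {})
    sim = SimConfig(
        attenuation=att,
        intensity=intensity,
        output_size=int(study.get("output_size", 512)),
    )
    return StudyConfig(
        composition={int(k): int(v) for k, v in study.get("composition", {}).items()},
        size_counts={float(k): int(v) for k, v in study.get("size_counts", {}).items()},
        sim=sim,
        extent_range_mm=tuple(study.get("extent_range_mm", (8.0, 20.0))),
        unique_healthy_per_volume=bool(study.get("unique_healthy_per_volume", True)),
    )


def echo_config(cfg: dict, directory, seed: int | None = None) -> None:
    """Write the fully-resolved config (and seed) next to the outputs."""
    os.makedirs(str(directory), exist_ok=True)
    out = dict(cfg)
    if seed is not None:
        out["seed"] = int(seed)
    with open(os.path.join(str(directory), "config_echo.yaml"), "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(out)), fh)
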