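"""YAML configuration loading.

A config file holds one block per parameter group; every key is optional and
falls back to the documented default.  Example::

    experiment: {replicates: 20, base_seed: 7, horizon_hours: 2520}
    slide: {n_cancer: 1000, n_effector: 50, n_regulatory: 25, clustering: 0.5}
    dynamics: {p_a: 3.0e-3, p_m: 0.9, eta_directed: 0.19}
    recruitment: {zeta_apoptosis: 0.2, zeta_effector: 0.4, mu: 0.5,
                  zeta_regulatory: 0.2, zeta_tx: 0.1}
    radiation: {sf2_cancer: 0.49, sf2_effector: 0.60, sf2_regulatory: 0.77}
    schedule: {kind: wtrt, weeks: 7, peak_dose: 2.0}
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import yaml

from .dynamics import CycleParams, MotionParams
from .experiment import SimulationConfig, SlideConfig, TreatmentConfig
from .radiation import RadiosensitivityParams
from .recruitment import RecruitmentRates

__all__ = ["load_config", "config_from_dict", "config_to_dict"]

_BLOCKS = {
    "slide": ("slide", SlideConfig),
    "dynamics": ("motion", MotionParams),
    "cycle": ("cycle", CycleParams),
    "recruitment": ("rates", RecruitmentRates),
    "radiation": ("radio", RadiosensitivityParams),
    "schedule": ("treatment", TreatmentConfig),
}
_EXPERIMENT_KEYS = ("width", "height", "node_pitch", "kappa", "dt_hours",
                    "horizon_hours", "replicates", "base_seed")


def _build(cls, block: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in block {where!r}")
    if cls is TreatmentConfig and "custom_fractions" in block and \
            block["custom_fractions"] is not None:
        block = dict(block)
        block["custom_fractions"] = [tuple(p) for p in block["custom_fractions"]]
    return cls(**block)


def config_from_dict(data: Optional[dict]) -> SimulationConfig:
    data = dict(data or {})
    kwargs = {}
    exp = data.pop("experiment", {}) or {}
    unknown = set(exp) - set(_EXPERIMENT_KEYS)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in block 'experiment'")
    kwargs.update(exp)
    for block_name, (attr, cls) in _BLOCKS.items():
        block = data.pop(block_name, None)
        if block:
            kwargs[attr] = _build(cls, block, block_name)
    if data:
        raise ValueError(f"unknown config block(s): {sorted(data)}")
    return SimulationConfig(**kwargs)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_to_dict(config: SimulationConfig) -> dict:
    out = {"experiment": {k: getattr(config, k) for k in _EXPERIMENT_KEYS}}
    for block_name, (attr, _) in _BLOCKS.items():
        out[block_name] = dataclasses.asdict(getattr(config, attr))
    return out
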