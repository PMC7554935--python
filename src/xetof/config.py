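"""YAML configuration loading with strict schema validation.

A run configuration is a YAML mapping with optional sections ``kinetics``,
``calibration``, ``acquisition``, ``phantom`` and ``flow``.  Unknown
sections or keys are rejected before any computation so that a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .exceptions import ValidationError
from .kinetics import CalibrationParams, KineticsParams
from .phantom import AcquisitionParams, FlowPhantomSpec
from .presets import TOF_DELAY_PRESETS

_SCHEMAS: dict[str, set[str]] = {
    "kinetics": {
        "f", "lambda", "t1_blood_s", "t1_tissue_s", "transit_delay_s", "m_a0",
    },
    "calibration": {"s_arterial", "time_unit_factor"},
    "acquisition": {
        "tof_delays_s", "delays_preset", "flip_angle_deg", "matrix",
        "zero_pad_to", "noise_sd", "phase_order", "seed",
    },
    "phantom": {"grid", "fov_mm", "activation"},
    "flow": {
        "flow_rates_ml_min", "tube_id_mm", "sensitive_length_mm", "profile",
        "s_max", "noise_sd", "tau_grid_s",
    },
}


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(cfg) - set(_SCHEMAS)
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    for section, keys in cfg.items():
        if keys is None:
            continue
        if not isinstance(keys, dict):
            raise ValidationError(f"section '{section}' must be a mapping")
        bad = set(keys) - _SCHEMAS[section]
        if bad:
            raise ValidationError(
                f"unknown keys in '{section}': {sorted(bad)}"
            )
    return cfg


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    return validate_config(cfg)


def kinetics_from_config(cfg: dict) -> KineticsParams:
    d = cfg.get("kinetics") or {}
    return KineticsParams(
        f=d.get("f", 0.55),
        lam=d.get("lambda", 0.9),
        t1_blood=d.get("t1_blood_s", 8.0),
        t1_tissue=d.get("t1_tissue_s", 16.0),
        transit_delay=d.get("transit_delay_s", 0.0),
        m_a0=d.get("m_a0", 100.0),
    )


def calibration_from_config(cfg: dict) -> CalibrationParams | None:
    d = cfg.get("calibration") or {}
    if "s_arterial" not in d:
        return None
    kwargs = {"s_arterial": float(d["s_arterial"])}
    if "time_unit_factor" in d:
        kwargs["time_unit_factor"] = float(d["time_unit_factor"])
    return CalibrationParams(**kwargs)


def acquisition_from_config(
    cfg: dict, seed: int | None = None
) -> AcquisitionParams:
    d = dict(cfg.get("acquisition") or {})
    if "delays_preset" in d:
        name = d.pop("delays_preset")
        if name not in TOF_DELAY_PRESETS:
            raise ValidationError(
                f"unknown delays preset {name!r}; "
                f"choices: {sorted(TOF_DELAY_PRESETS)}"
            )
        delays = TOF_DELAY_PRESETS[name]
    else:
        delays = tuple(d.pop("tof_delays_s", TOF_DELAY_PRESETS["invivo_axial"]))
    return AcquisitionParams(
        tof_delays=tuple(float(t) for t in np.atleast_1d(delays)),
        flip_angle=float(d.pop("flip_angle_deg", 20.0)),
        matrix=tuple(d.pop("matrix", (20, 20))),
        zero_pad_to=tuple(d.pop("zero_pad_to", (32, 32))),
        noise_sd=float(d.pop("noise_sd", 0.0)),
        phase_order=d.pop("phase_order", "linear"),
        seed=seed if seed is not None else d.pop("seed", None),
    )


def flow_specs_from_config(cfg: dict) -> tuple[list[FlowPhantomSpec], list[float]]:
    """Flow-phantom specs (one per pump rate) and the tau sampling grid."""
    from .presets import FLOW_RATES_ML_MIN, FLOW_TAU_GRID_S

    d = cfg.get("flow") or {}
    rates = [float(q) for q in d.get("flow_rates_ml_min", FLOW_RATES_ML_MIN)]
    tau = [float(t) for t in d.get("tau_grid_s", FLOW_TAU_GRID_S)]
    kwargs = {}
    if "tube_id_mm" in d:
        kwargs["tube_id"] = float(d["tube_id_mm"])
    if "sensitive_length_mm" in d:
        kwargs["sensitive_length"] = float(d["sensitive_length_mm"])
    for key in ("profile", "s_max", "noise_sd"):
        if key in d:
            kwargs[key] = d[key]
    return [FlowPhantomSpec(flow_rate=q, **kwargs) for q in rates], tau
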