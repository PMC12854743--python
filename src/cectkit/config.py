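"""Run configuration: a fully serializable description of an analysis run.

Every pipeline run is reproducible from a YAML config plus its seed alone.
The file is validated field by field against the schema implied by
``DEFAULTS``; unknown or missing fields raise :class:`ConfigError` naming
the dotted field path.  ``analysis.bath_hu`` has no default — the bath
attenuation is a measured per-experiment scalar the partition definition
cannot do without.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

from .biomechanics import IndentationGeometry
from .phantom import CohortSpec, PhantomSpec, UptakeTruth, ViscoTruth

__all__ = ["ConfigError", "RunConfig", "load_config"]

_REQUIRED = object()

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "sample_id": "demo",
    "output_dir": "cectkit_out",
    "bath_mg_per_ml": 30.0,
    "times_h": [0.0, 1.0, 3.0, 6.0, 10.0, 24.0, 48.0, 72.0],
    "phantom": {
        "plug_diameter_mm": 4.0,
        "cartilage_thickness_mm": 2.0,
        "bone_thickness_mm": 1.0,
        "voxel_size_um": 80.0,
        "surface_tilt_deg": [2.0, -1.0],
        "hu_air": -1000.0,
        "hu_fluid": 0.0,
        "hu_cartilage": 100.0,
        "hu_bone": 2000.0,
        "noise_sd_hu": 10.0,
    },
    "uptake": {"p_max_pct": 56.49, "tau_h": 62.85, "bath_hu_gain": 12.0},
    "analysis": {
        "bath_hu": _REQUIRED,
        "threshold_background_hu": -500.0,
        "threshold_bone_hu": 1000.0,
        "surface_threshold_hu": None,
        "roi_diameter_mm": 1.2,
        "align": True,
    },
    "mechanics": {
        "e_eq_mpa": 0.5,
        "e_inst0_mpa": 5.0,
        "e_inst_slope_mpa": 10.0,
        "alpha_s": 60.0,
        "beta": 0.8,
        "eta_over_k_s": 0.05,
        "cartilage_thickness_mm": 2.0,
        "indenter_diameter_mm": 0.55,
        "noise_sd_mn": 0.0,
    },
    "densitometry": {
        "od_surface": 0.6,
        "od_deep": 1.8,
        "gray_intercept": 250.0,
        "gray_slope": -70.0,
        "noise_sd": 1.0,
    },
    "cohort": {
        "n_samples": 27,
        "pg_mean": 1.2,
        "pg_sd": 0.25,
        "partition_noise_pct": 1.5,
    },
}


class ConfigError(ValueError):
    """A config file does not match the expected schema."""


def _merge(defaults: Any, user: Any, path: str) -> Any:
    if isinstance(defaults, dict):
        if not isinstance(user, dict):
            raise ConfigError(f"config field '{path}' must be a mapping")
        out = {}
        for key, dval in defaults.items():
            sub = f"{path}.{key}" if path else key
            if key in user:
                out[key] = _merge(dval, user[key], sub)
            elif dval is _REQUIRED:
                raise ConfigError(f"missing required config field '{sub}'")
            else:
                out[key] = copy.deepcopy(dval)
        unknown = set(user) - set(defaults)
        if unknown:
            where = path or "top level"
            raise ConfigError(f"unknown config field(s) {sorted(unknown)} at {where}")
        return out
    if defaults is not None and user is not None and isinstance(defaults, (int, float)):
        if not isinstance(user, (int, float)) or isinstance(user, bool) != isinstance(defaults, bool):
            raise ConfigError(f"config field '{path}' must be a number, got {user!r}")
    return user


@dataclass
class RunConfig:
    """Validated run configuration with typed accessors for each stage."""

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(raw=_merge(DEFAULTS, d or {}, ""))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def times_h(self) -> list[float]:
        return [float(t) for t in self.raw["times_h"]]

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        p = self.raw["phantom"]
        return PhantomSpec(
            plug_diameter_mm=p["plug_diameter_mm"],
            cartilage_thickness_mm=p["cartilage_thickness_mm"],
            bone_thickness_mm=p["bone_thickness_mm"],
            voxel_size_um=p["voxel_size_um"],
            surface_tilt_deg=tuple(p["surface_tilt_deg"]),
            hu_air=p["hu_air"],
            hu_fluid=p["hu_fluid"],
            hu_cartilage=p["hu_cartilage"],
            hu_bone=p["hu_bone"],
            noise_sd_hu=p["noise_sd_hu"],
            seed=self.seed if seed is None else seed,
        )

    def uptake_truth(self) -> UptakeTruth:
        u = self.raw["uptake"]
        return UptakeTruth(
            p_max_pct=u["p_max_pct"], tau_h=u["tau_h"], bath_hu_gain=u["bath_hu_gain"]
        )

    def visco_truth(self) -> ViscoTruth:
        m = self.raw["mechanics"]
        return ViscoTruth(
            e_eq_mpa=m["e_eq_mpa"],
            e_inst0_mpa=m["e_inst0_mpa"],
            e_inst_slope_mpa=m["e_inst_slope_mpa"],
            alpha_s=m["alpha_s"],
            beta=m["beta"],
            eta_over_k_s=m["eta_over_k_s"],
        )

    def geometry(self) -> IndentationGeometry:
        m = self.raw["mechanics"]
        return IndentationGeometry(
            cartilage_thickness_mm=m["cartilage_thickness_mm"],
            indenter_diameter_mm=m["indenter_diameter_mm"],
        )

    def cohort_spec(self) -> CohortSpec:
        c = self.raw["cohort"]
        return CohortSpec(
            n_samples=int(c["n_samples"]),
            pg_mean=c["pg_mean"],
            pg_sd=c["pg_sd"],
            seed=self.seed + 1,
        )

    @property
    def analysis(self) -> dict:
        return self.raw["analysis"]

    @property
    def thresholds(self) -> tuple[float, float]:
        a = self.raw["analysis"]
        return (a["threshold_background_hu"], a["threshold_bone_hu"])


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return RunConfig.from_dict(data)
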