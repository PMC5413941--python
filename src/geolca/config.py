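"""Layered run configuration: a single YAML file, schema-validated.

The config describes one region/feedstock run end to end: the landscape
source (synthetic parameters or a directory of grids), the demand
scenarios and conversion chain, the allocator, the standard-branch
factors, the spatial-model knobs and the sensitivity ranges.  Validation
is strict — an unknown key is an error naming the key — and happens
before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .demand import ConversionChain, DEFAULT_VOLUMES
from .impacts import EdgeParams, FragTable, IntensificationResponse
from .lca import ImpactModelConfig, ParamRange, StandardFactors
from .synth import LandscapeParams

__all__ = ["RunConfig", "load_config", "validate_config", "config_hash"]

_SCHEMA: dict[str, dict[str, type | tuple[type, ...]]] = {
    "landscape": {
        "synthetic": dict, "files": str,
    },
    "scenarios": {
        "volumes": list, "chain": dict, "closure_fraction": (int, float),
        "feedstock_label": str,
    },
    "standard_factors": {
        "luc_gwp_factor": (int, float), "land_occupation": (int, float),
        "pnv_msa": (int, float), "current_msa": (int, float),
        "erosion_per_ha": (int, float), "water_per_tonne": (int, float),
        "eutroph_per_tonne": (int, float), "non_ag_stage_impacts": dict,
    },
    "impact_models": {
        "edge": dict, "frag": dict, "response": dict,
        "amortization_years": (int, float), "fert_gwp_per_kg_n": (int, float),
        "erosivity_per_mm": (int, float), "effective_precip_fraction": (int, float),
        "irrigate_new_agriculture": bool, "stream_threshold": int,
        "non_ag_stage_impacts": dict,
    },
    "sensitivity": None,  # list of {parameter, low, central, high}
}
_TOP_KEYS = {
    "landscape", "scenarios", "allocator", "standard_factors",
    "impact_models", "sensitivity", "seed", "output_dir",
}
_SYNTH_KEYS = {
    "shape", "cell_size", "correlation_length", "class_proportions",
    "true_beta", "predictor_names", "riparian_width", "stream_threshold",
    "relief", "tilt", "base_yield", "yield_gap_mean", "seed",
}


class ConfigError(ValueError):
    pass


def _check_keys(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown config key {key!r} in {where}")


@dataclass
class RunConfig:
    """Validated, materialized run configuration."""

    landscape_params: LandscapeParams | None
    landscape_dir: str | None
    volumes: list[float]
    chain: ConversionChain
    closure_fraction: float
    feedstock_label: str
    allocator: str
    standard_factors: StandardFactors
    impact_config: ImpactModelConfig
    sensitivity: list[ParamRange]
    seed: int
    output_dir: str
    raw: dict = field(default_factory=dict, repr=False)


def validate_config(data: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed config mapping and materialize typed objects."""
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, _TOP_KEYS, "top level")

    land = data.get("landscape", {"synthetic": {}})
    _check_keys(land, {"synthetic", "files"}, "landscape")
    if ("synthetic" in land) == ("files" in land):
        raise ConfigError("landscape must define exactly one of 'synthetic' or 'files'")
    params = None
    landscape_dir = None
    if "synthetic" in land:
        synth = dict(land["synthetic"] or {})
        _check_keys(synth, _SYNTH_KEYS, "landscape.synthetic")
        if "shape" in synth:
            synth["shape"] = tuple(synth["shape"])
        if "true_beta" in synth:
            synth["true_beta"] = tuple(synth["true_beta"])
        if "predictor_names" in synth:
            synth["predictor_names"] = tuple(synth["predictor_names"])
        params = LandscapeParams(**synth)
    else:
        landscape_dir = str(land["files"])

    scen = data.get("scenarios", {})
    _check_keys(scen, set(_SCHEMA["scenarios"]), "scenarios")
    volumes = [float(v) for v in scen.get("volumes", DEFAULT_VOLUMES)]
    chain = ConversionChain(**(scen.get("chain") or {}))
    closure = float(scen.get("closure_fraction", 0.2))
    feedstock = str(scen.get("feedstock_label", "maize"))

    allocator = str(data.get("allocator", "logistic"))
    if allocator not in {"logistic", "proximity", "observed"}:
        raise ConfigError(f"unknown allocator {allocator!r}")

    std = dict(data.get("standard_factors") or {})
    _check_keys(std, set(_SCHEMA["standard_factors"]), "standard_factors")
    factors = StandardFactors(**std)

    imp = dict(data.get("impact_models") or {})
    _check_keys(imp, set(_SCHEMA["impact_models"]), "impact_models")
    if "edge" in imp:
        imp["edge"] = EdgeParams(**imp["edge"])
    if "frag" in imp:
        frag = imp["frag"]
        imp["frag"] = FragTable(
            thresholds=tuple(frag.get("thresholds", FragTable().thresholds)),
            multipliers=tuple(frag.get("multipliers", FragTable().multipliers)),
        )
    if "response" in imp:
        imp["response"] = IntensificationResponse(**imp["response"])
    impact_config = ImpactModelConfig(**imp)

    ranges = []
    for entry in data.get("sensitivity") or []:
        _check_keys(entry, {"parameter", "low", "central", "high"}, "sensitivity")
        ranges.append(ParamRange(
            parameter=str(entry["parameter"]), low=float(entry["low"]),
            central=float(entry["central"]), high=float(entry["high"]),
        ))

    return RunConfig(
        landscape_params=params,
        landscape_dir=landscape_dir,
        volumes=volumes,
        chain=chain,
        closure_fraction=closure,
        feedstock_label=feedstock,
        allocator=allocator,
        standard_factors=factors,
        impact_config=impact_config,
        sensitivity=ranges,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "geolca_run")),
        raw=dict(data),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the raw config, recorded in every manifest."""
    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
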