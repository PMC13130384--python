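"""Configuration documents: YAML/JSON loading, validation, canonical form.

A run configuration bundles the dose grid, the prior, and a design (either a
named preset, optionally with overrides, or a fully spelled-out design with
its utility block).  Dose levels in configuration files are 1-based
(``start_dose_level: 1`` is the lowest dose); internally indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import DoseGrid, PriorSpec, center_log_dose
from .policy import DesignConfig
from .presets import default_prior, get_preset
from .utility import JointUtilitySpec, MarginalUtilitySpec, UtilityFunction

__all__ = ["RunConfig", "load_config", "loads_config", "canonical_json", "config_hash"]

_TOP_KEYS = {"doses", "prior", "design", "utility"}
_DESIGN_KEYS = {
    "preset",
    "rule_variant",
    "cohort_size",
    "max_n",
    "start_dose_level",
    "adm_eff",
    "adm_tox",
    "stop_contour",
    "name",
}
_MARGINAL_KEYS = {"reference", "loss_aversion", "exp_gain", "exp_loss"}
_JOINT_KEYS = {"k_eff", "k_tox"}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of grid, prior and design."""

    grid: DoseGrid
    prior: PriorSpec
    design: DesignConfig

    def canonical(self) -> dict:
        """Fully expanded, preset-free dictionary form (idempotent)."""
        d = self.design
        u = d.utility
        return {
            "doses": list(self.grid.doses),
            "prior": {"mean": list(self.prior.mean), "sd": list(self.prior.sd)},
            "design": {
                "name": d.name,
                "rule_variant": d.rule_variant,
                "cohort_size": d.cohort_size,
                "max_n": d.max_n,
                "start_dose_level": d.start_dose_index + 1,
                "adm_eff": list(d.adm_eff),
                "adm_tox": list(d.adm_tox),
                "stop_contour": None if d.stop_contour is None else list(d.stop_contour),
            },
            "utility": {
                "efficacy": _marginal_dict(u.efficacy),
                "toxicity": _marginal_dict(u.toxicity),
                "joint": {"k_eff": u.joint.k_eff, "k_tox": u.joint.k_tox},
            },
        }


def _marginal_dict(m: MarginalUtilitySpec) -> dict:
    return {
        "reference": m.reference,
        "loss_aversion": m.loss_aversion,
        "exp_gain": m.exp_gain,
        "exp_loss": m.exp_loss,
    }


def _check_keys(doc: dict, allowed: set, where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_utility(doc: dict) -> UtilityFunction:
    _check_keys(doc, {"efficacy", "toxicity", "joint"}, "utility")
    for part in ("efficacy", "toxicity", "joint"):
        if part not in doc:
            raise ConfigError(f"utility: missing block {part!r}")
    _check_keys(doc["efficacy"], _MARGINAL_KEYS, "utility.efficacy")
    _check_keys(doc["toxicity"], _MARGINAL_KEYS, "utility.toxicity")
    _check_keys(doc["joint"], _JOINT_KEYS, "utility.joint")
    return UtilityFunction(
        efficacy=MarginalUtilitySpec(orientation="efficacy", **doc["efficacy"]),
        toxicity=MarginalUtilitySpec(orientation="toxicity", **doc["toxicity"]),
        joint=JointUtilitySpec(**doc["joint"]),
    )


def _parse_design(doc: dict, utility: UtilityFunction | None) -> DesignConfig:
    _check_keys(doc, _DESIGN_KEYS, "design")
    overrides = {k: v for k, v in doc.items() if k != "preset"}
    if "start_dose_level" in overrides:
        lvl = overrides.pop("start_dose_level")
        if lvl < 1:
            raise ConfigError(f"design.start_dose_level is 1-based, got {lvl}")
        overrides["start_dose_index"] = lvl - 1
    for key in ("adm_eff", "adm_tox", "stop_contour"):
        if overrides.get(key) is not None:
            overrides[key] = tuple(overrides[key])
    if "preset" in doc:
        base = get_preset(doc["preset"])
        if utility is not None:
            overrides["utility"] = utility
        return dataclasses.replace(base, **overrides)
    if utility is None:
        raise ConfigError("design without a preset requires a utility block")
    return DesignConfig(utility=utility, **overrides)


def loads_config(doc: dict) -> RunConfig:
    """Validate a parsed configuration dictionary."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping at the top level")
    _check_keys(doc, _TOP_KEYS, "configuration")
    if "design" not in doc:
        raise ConfigError("configuration: missing block 'design'")
    grid = center_log_dose(doc.get("doses", (20.0, 30.0, 40.0, 50.0)))
    if "prior" in doc:
        _check_keys(doc["prior"], {"mean", "sd"}, "prior")
        prior = PriorSpec(mean=tuple(doc["prior"]["mean"]), sd=tuple(doc["prior"]["sd"]))
    else:
        prior = default_prior()
    utility = _parse_utility(doc["utility"]) if "utility" in doc else None
    design = _parse_design(doc["design"], utility)
    return RunConfig(grid=grid, prior=prior, design=design)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # yaml errors carry line/column marks
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return loads_config(doc)


def canonical_json(cfg: RunConfig) -> str:
    return json.dumps(cfg.canonical(), sort_keys=True, indent=2)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(canonical_json(cfg).encode()).hexdigest()[:16]
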