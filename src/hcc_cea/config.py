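"""Base-case model configuration and the single entry point to run it.

The configuration is a plain nested dict (YAML-serializable) mirroring the
published input table field for field: every uncertain entry carries
``value``, ``low``, ``high`` and ``dist`` (its sensitivity-analysis
distribution family).  :func:`default_config` returns the base case for the
atezolizumab+bevacizumab (atezo-beva) versus atezolizumab+cabozantinib
(atezo-cabo) comparison; :func:`run_model` evaluates both arms and their
incremental results for any (possibly perturbed) configuration.

Baseline survival comes from the comparator (atezo-cabo) arm — Weibull OS,
log-normal PFS, fitted to reconstructed trial data, time in months — and
the intervention arm is obtained by applying indirect-comparison hazard
ratios to those baselines.
"""

from __future__ import annotations

import copy
import dataclasses
from pathlib import Path
from typing import Any, Iterable

import yaml

from .markov_cea import (
    ArmResult,
    ArmSpec,
    CEResult,
    CostInputs,
    ModelSettings,
    UtilityInputs,
    icer,
    run_arm,
)
from .survival_models import ParametricSurvival

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "run_model",
    "param_specs",
    "apply_overrides",
    "ModelOutput",
    "ParamSpec",
    "BEVA",
    "CABO",
]

BEVA = "atezo-beva"
CABO = "atezo-cabo"

AVERAGE_BODY_WEIGHT_KG = 70.0


def _u(value: float, low: float, high: float, dist: str) -> dict:
    return {"value": value, "low": low, "high": high, "dist": dist}


def default_config() -> dict:
    """The base-case configuration (2023 USD, time in months)."""
    return {
        "settings": {
            "cycle_length_days": 21.0,
            "discount": _u(0.03, 0.00, 0.05, "beta"),
            "max_horizon_years": 40.0,
            "half_cycle_correction": False,
            "wtp": 150_000.0,
        },
        "survival": {
            # comparator-arm baselines; S(t)=exp(-lam t^gamma), lognormal on log-time
            "os": {"family": "weibull", "params": [0.01546928, 1.385069]},
            "pfs": {"family": "lognormal", "params": [1.908634, 0.9985375]},
        },
        "hazard_ratios": {
            # atezo-beva vs atezo-cabo, from the anchored indirect comparison
            "os": _u(0.64, 0.42, 0.97, "lognormal"),
            "pfs": _u(0.95, 0.61, 1.46, "lognormal"),
        },
        "arms": {
            BEVA: {
                "adjusted": True,  # uses the hazard-ratio-adjusted curves
                "dosing": {
                    "atezolizumab_mg_per_cycle": 1200.0,
                    "bevacizumab_mg_per_kg": 15.0,
                },
                "p_subsequent_active": _u(0.21, 0.168, 0.252, "beta"),
                "ae_incidence": {
                    "ast_increase": _u(0.07, 0.056, 0.084, "beta"),
                    "alt_increase": _u(0.036, 0.029, 0.043, "beta"),
                    "hypertension": _u(0.152, 0.122, 0.182, "beta"),
                },
            },
            CABO: {
                "adjusted": False,
                "dosing": {
                    "atezolizumab_mg_per_cycle": 1200.0,
                    "cabozantinib_mg_per_day": 40.0,
                },
                "p_subsequent_active": _u(0.20, 0.16, 0.24, "beta"),
                "ae_incidence": {
                    "ast_increase": _u(0.09, 0.072, 0.108, "beta"),
                    "alt_increase": _u(0.08, 0.064, 0.096, "beta"),
                    "hypertension": _u(0.09, 0.072, 0.108, "beta"),
                },
            },
        },
        "utilities": {
            "pfs": _u(0.76, 0.61, 0.91, "beta"),
            "pd": _u(0.68, 0.54, 0.82, "beta"),
            "ae_disutility": _u(0.160, 0.110, 0.204, "beta"),
        },
        "costs": {
            "atezolizumab_per_10mg": _u(82.678, 66.142, 99.214, "gamma"),
            "bevacizumab_per_10mg": _u(73.579, 58.863, 88.295, "gamma"),
            "cabozantinib_per_mg": _u(9.44, 7.552, 11.328, "gamma"),
            "testing_per_cycle": _u(797.33, 637.864, 956.796, "gamma"),
            "subsequent_active_per_patient": _u(108_336.0, 81_252.0, 135_420.0, "gamma"),
            "subsequent_bsc_per_patient": _u(37_084.0, 27_813.0, 46_355.0, "gamma"),
            "ae_event_costs": {
                "ast_increase": _u(59.0, 47.2, 70.8, "gamma"),
                "alt_increase": _u(59.0, 47.2, 70.8, "gamma"),
                "hypertension": _u(1701.0, 1276.0, 2127.0, "gamma"),
            },
            "post_progression_cost_mode": "per_cycle",
        },
        "body_weight_kg": AVERAGE_BODY_WEIGHT_KG,
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Building model objects from a configuration
# --------------------------------------------------------------------------


def _settings_from(cfg: dict) -> ModelSettings:
    s = cfg["settings"]
    return ModelSettings(
        cycle_length_months=float(s["cycle_length_days"]) / 30.4375,
        discount_rate=float(s["discount"]["value"]),
        max_horizon_years=float(s["max_horizon_years"]),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        wtp=float(s["wtp"]),
    )


def _utilities_from(cfg: dict) -> UtilityInputs:
    u = cfg["utilities"]
    return UtilityInputs(
        u_pfs=float(u["pfs"]["value"]),
        u_pd=float(u["pd"]["value"]),
        ae_disutility=float(u["ae_disutility"]["value"]),
    )


def _costs_from(cfg: dict) -> CostInputs:
    c = cfg["costs"]
    return CostInputs(
        atezolizumab_per_10mg=float(c["atezolizumab_per_10mg"]["value"]),
        bevacizumab_per_10mg=float(c["bevacizumab_per_10mg"]["value"]),
        cabozantinib_per_mg=float(c["cabozantinib_per_mg"]["value"]),
        testing_per_cycle=float(c["testing_per_cycle"]["value"]),
        subsequent_active_per_patient=float(c["subsequent_active_per_patient"]["value"]),
        subsequent_bsc_per_patient=float(c["subsequent_bsc_per_patient"]["value"]),
        ae_event_costs={k: float(v["value"]) for k, v in c["ae_event_costs"].items()},
        post_progression_cost_mode=c.get("post_progression_cost_mode", "per_cycle"),
    )


def _dosing_mg_per_cycle(arm_cfg: dict, cfg: dict) -> dict[str, float]:
    cycle_days = float(cfg["settings"]["cycle_length_days"])
    dosing: dict[str, float] = {}
    d = arm_cfg["dosing"]
    if "atezolizumab_mg_per_cycle" in d:
        dosing["atezolizumab"] = float(d["atezolizumab_mg_per_cycle"])
    if "bevacizumab_mg_per_kg" in d:
        dosing["bevacizumab"] = float(d["bevacizumab_mg_per_kg"]) * float(
            cfg.get("body_weight_kg", AVERAGE_BODY_WEIGHT_KG)
        )
    if "cabozantinib_mg_per_day" in d:
        dosing["cabozantinib"] = float(d["cabozantinib_mg_per_day"]) * cycle_days
    return dosing


def _arm_from(cfg: dict, name: str) -> ArmSpec:
    arm_cfg = cfg["arms"][name]
    surv = cfg["survival"]
    pfs = ParametricSurvival(surv["pfs"]["family"], tuple(surv["pfs"]["params"]))
    os_ = ParametricSurvival(surv["os"]["family"], tuple(surv["os"]["params"]))
    adjusted = bool(arm_cfg.get("adjusted", False))
    return ArmSpec(
        name=name,
        pfs_model=pfs,
        os_model=os_,
        dosing_mg_per_cycle=_dosing_mg_per_cycle(arm_cfg, cfg),
        ae_incidences={k: float(v["value"]) for k, v in arm_cfg["ae_incidence"].items()},
        p_subsequent_active=float(arm_cfg["p_subsequent_active"]["value"]),
        hr_pfs=float(cfg["hazard_ratios"]["pfs"]["value"]) if adjusted else None,
        hr_os=float(cfg["hazard_ratios"]["os"]["value"]) if adjusted else None,
    )


@dataclasses.dataclass(frozen=True)
class ModelOutput:
    arms: dict[str, ArmResult]
    ce: CEResult  # intervention (atezo-beva) vs comparator (atezo-cabo)

    def summary(self) -> dict:
        out: dict[str, Any] = {}
        for name, res in self.arms.items():
            out[name] = {
                "life_years": res.life_years,
                "qalys": res.qalys,
                "total_cost": res.total_cost,
                "cost_breakdown": dataclasses.asdict(res.cost_breakdown),
            }
        out["incremental"] = {
            k: v
            for k, v in dataclasses.asdict(self.ce).items()
            if k not in ("intervention", "comparator")
        }
        return out


def run_model(cfg: dict | None = None, overrides: dict[str, float] | None = None) -> ModelOutput:
    """Evaluate both arms and their incremental comparison.

    ``overrides`` maps flat parameter names (see :func:`param_specs`) to
    values; the configuration itself is not mutated.
    """
    cfg = copy.deepcopy(cfg) if cfg is not None else default_config()
    if overrides:
        apply_overrides(cfg, overrides)
    settings = _settings_from(cfg)
    utilities = _utilities_from(cfg)
    costs = _costs_from(cfg)
    results = {
        name: run_arm(_arm_from(cfg, name), settings, utilities, costs) for name in cfg["arms"]
    }
    ce = icer(results[BEVA], results[CABO], settings)
    return ModelOutput(arms=results, ce=ce)


# --------------------------------------------------------------------------
# Flat parameter registry for sensitivity analyses
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range, sampling family, location.

    ``path`` locates the entry's ``value`` field inside the nested config;
    ``scale`` rescales a beta draw onto [0, scale] (used for the discount
    rate, whose natural support is [0, 0.05]).
    """

    name: str
    base: float
    low: float
    high: float
    dist: str
    path: tuple[str, ...]
    scale: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: range ({self.low}, {self.high}) must bracket {self.base}")


def _walk_uncertain(cfg: dict) -> Iterable[tuple[tuple[str, ...], dict]]:
    def rec(node: Any, path: tuple[str, ...]):
        if isinstance(node, dict):
            if {"value", "low", "high", "dist"} <= set(node):
                yield path, node
            else:
                for k, v in node.items():
                    yield from rec(v, path + (k,))

    yield from rec(cfg, ())


def param_specs(cfg: dict | None = None, include_discount: bool = True) -> list[ParamSpec]:
    """Flatten every uncertain configuration entry into a ParamSpec list."""
    cfg = cfg if cfg is not None else default_config()
    specs = []
    for path, node in _walk_uncertain(cfg):
        name = ".".join(path)
        if name == "settings.discount":
            if not include_discount:
                continue
            scale = 0.05
        else:
            scale = None
        specs.append(
            ParamSpec(
                name=name,
                base=float(node["value"]),
                low=float(node["low"]),
                high=float(node["high"]),
                dist=str(node["dist"]),
                path=path + ("value",),
                scale=scale,
            )
        )
    return specs


def apply_overrides(cfg: dict, overrides: dict[str, float]) -> dict:
    """Set flat ``a.b.c``-named values inside the nested config (in place)."""
    for name, value in overrides.items():
        node = cfg
        parts = name.split(".")
        for part in parts[:-1]:
            node = node[part]
        leaf = parts[-1]
        if isinstance(node.get(leaf), dict) and "value" in node[leaf]:
            node[leaf]["value"] = float(value)
        elif leaf in node:
            node[leaf] = float(value)
        else:
            raise KeyError(f"unknown configuration entry {name!r}")
    return cfg
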