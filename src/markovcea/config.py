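"""Analysis configuration: YAML schema, validation, defaults, round-trip IO.

A configuration file defines the strategy arms (either clinical summary
statistics to derive probabilities from, or direct annual transition
probabilities), the shared utilities, the cost structure, run settings
(horizon, discount rate, half-cycle flag), decision thresholds and PSA
settings.  Validation is eager and names the offending key; every default
that gets applied is recorded on the returned object and logged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .econ import DEFAULT_WTP_CEAC, DEFAULT_WTP_NMB
from .engine import STATES
from .errors import ConfigError
from .model import ArmDefinition, CEModel
from .params import (ClinicalSummary, DerivedProbabilities, RoundingMode,
                     build_arm_matrix)

log = logging.getLogger(__name__)

_PROB_KEYS = ("ss", "sr", "sp", "rr", "rp", "pp", "pd")


@dataclass(frozen=True)
class ArmConfig:
    """One strategy arm as configured.

    Exactly one of ``summary`` (clinical summary statistics; probabilities
    are derived) or ``probabilities`` (direct annual transition
    probabilities, keys ss/sr/sp/rr/rp/pp/pd) must be given.
    """

    label: str
    state_costs: dict
    intervention_cost: float
    summary: dict | None = None
    probabilities: dict | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    arms: tuple[ArmConfig, ...]
    utilities: dict
    discount_rate: float = 0.05
    n_cycles: int = 5
    cycle_length: float = 1.0
    half_cycle: bool = True
    rounding_mode: RoundingMode = "printed_precision"
    nmb_wtp: float = DEFAULT_WTP_NMB
    ceac_grid: tuple = tuple(float(x) for x in range(0, 100_001, 5_000))
    psa_n_sims: int = 1000
    psa_seed: int | None = None
    psa_fraction: float = 0.2
    applied_defaults: tuple = field(default_factory=tuple, compare=False)


_DEFAULTS = {
    "discount_rate": 0.05,
    "n_cycles": 5,
    "cycle_length": 1.0,
    "half_cycle": True,
    "rounding_mode": "printed_precision",
    "nmb_wtp": DEFAULT_WTP_NMB,
    "ceac_grid": [float(x) for x in range(0, 100_001, 5_000)],
    "psa_n_sims": 1000,
    "psa_seed": None,
    "psa_fraction": 0.2,
}


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key {key!r}: {msg}")


def _validate_arm(raw: dict, idx: int) -> ArmConfig:
    where = f"arms[{idx}]"
    _require(isinstance(raw, dict), where, "must be a mapping")
    _require("label" in raw, f"{where}.label", "is required")
    label = str(raw["label"])
    summary = raw.get("summary")
    probabilities = raw.get("probabilities")
    _require((summary is None) != (probabilities is None), where,
             "exactly one of 'summary' or 'probabilities' must be given")
    if summary is not None:
        for k in ("rr", "os_median", "ttp_median", "dor_median"):
            _require(k in summary, f"{where}.summary.{k}", "is required")
            _require(isinstance(summary[k], (int, float)), f"{where}.summary.{k}",
                     "must be numeric")
    if probabilities is not None:
        for k in _PROB_KEYS:
            _require(k in probabilities, f"{where}.probabilities.{k}", "is required")
            v = probabilities[k]
            _require(isinstance(v, (int, float)) and 0.0 <= v <= 1.0,
                     f"{where}.probabilities.{k}", "must be a probability in [0, 1]")
    costs = raw.get("state_costs")
    _require(isinstance(costs, dict), f"{where}.state_costs", "must be a mapping")
    for state, v in costs.items():
        _require(state in STATES, f"{where}.state_costs.{state}",
                 f"unknown state (expected one of {STATES})")
        _require(isinstance(v, (int, float)) and v >= 0,
                 f"{where}.state_costs.{state}", "must be a non-negative number")
    for state in STATES:
        _require(state in costs, f"{where}.state_costs.{state}", "is required")
    interv = raw.get("intervention_cost", 0.0)
    _require(isinstance(interv, (int, float)) and interv >= 0,
             f"{where}.intervention_cost", "must be a non-negative number")
    return ArmConfig(label=label, summary=dict(summary) if summary else None,
                     probabilities=dict(probabilities) if probabilities else None,
                     state_costs=dict(costs), intervention_cost=float(interv))


def parse_config(raw: dict) -> AnalysisConfig:
    """Validate a raw mapping into an :class:`AnalysisConfig`."""
    if not isinstance(raw, dict) or not raw:
        raise ConfigError("config must be a non-empty mapping")
    _require("arms" in raw, "arms", "is required")
    _require(isinstance(raw["arms"], list) and len(raw["arms"]) == 2, "arms",
             "must list exactly two strategy arms")
    arms = tuple(_validate_arm(a, i) for i, a in enumerate(raw["arms"]))
    _require(arms[0].label != arms[1].label, "arms", "labels must differ")

    _require("utilities" in raw, "utilities", "is required")
    utilities = raw["utilities"]
    _require(isinstance(utilities, dict), "utilities", "must be a mapping")
    for state in STATES:
        _require(state in utilities, f"utilities.{state}", "is required")
        v = utilities[state]
        _require(isinstance(v, (int, float)) and 0.0 <= v <= 1.0,
                 f"utilities.{state}", "must be in [0, 1]")

    applied = []
    values = {}
    for key, default in _DEFAULTS.items():
        if key in raw:
            values[key] = raw[key]
        else:
            values[key] = default
            applied.append(key)
            log.info("config default applied: %s = %r", key, default)

    _require(isinstance(values["discount_rate"], (int, float))
             and values["discount_rate"] >= 0, "discount_rate", "must be >= 0")
    _require(isinstance(values["n_cycles"], int) and values["n_cycles"] >= 1,
             "n_cycles", "must be an integer >= 1")
    _require(values["cycle_length"] > 0, "cycle_length", "must be > 0")
    _require(values["rounding_mode"] in ("printed_precision", "full_precision"),
             "rounding_mode", "must be 'printed_precision' or 'full_precision'")
    _require(values["nmb_wtp"] >= 0, "nmb_wtp", "must be >= 0")
    _require(isinstance(values["psa_n_sims"], int) and values["psa_n_sims"] >= 0,
             "psa_n_sims", "must be an integer >= 0")
    _require(0.0 < values["psa_fraction"] < 1.0, "psa_fraction",
             "must be in (0, 1)")
    grid = values["ceac_grid"]
    _require(isinstance(grid, (list, tuple)) and len(grid) >= 1
             and all(isinstance(x, (int, float)) and x >= 0 for x in grid),
             "ceac_grid", "must be a non-empty list of non-negative thresholds")

    return AnalysisConfig(
        arms=arms, utilities=dict(utilities),
        discount_rate=float(values["discount_rate"]),
        n_cycles=values["n_cycles"], cycle_length=float(values["cycle_length"]),
        half_cycle=bool(values["half_cycle"]),
        rounding_mode=values["rounding_mode"],
        nmb_wtp=float(values["nmb_wtp"]),
        ceac_grid=tuple(float(x) for x in grid),
        psa_n_sims=values["psa_n_sims"], psa_seed=values["psa_seed"],
        psa_fraction=float(values["psa_fraction"]),
        applied_defaults=tuple(applied),
    )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raise ConfigError(f"{path}: empty configuration file")
    return parse_config(raw)


def config_to_dict(config: AnalysisConfig) -> dict:
    """Canonical plain-dict form (defaults materialised, metadata dropped)."""
    d = asdict(config)
    d.pop("applied_defaults")
    d["arms"] = [
        {k: v for k, v in asdict(a).items() if v is not None} for a in config.arms
    ]
    d["ceac_grid"] = list(config.ceac_grid)
    return d


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    """Serialise back to YAML; ``load_config`` round-trips to equality."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def config_hash(config: AnalysisConfig) -> str:
    """Stable sha256 over the canonical YAML form."""
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def build_model(config: AnalysisConfig) -> CEModel:
    """Materialise the paired cost-effectiveness model from a config."""
    arms = []
    for ac in config.arms:
        if ac.summary is not None:
            kwargs = {k: ac.summary[k] for k in
                      ("rr", "os_median", "ttp_median", "dor_median")}
            if "rp_decimals" in ac.summary:
                kwargs["rp_decimals"] = ac.summary["rp_decimals"]
            summ = ClinicalSummary(arm_label=ac.label, **kwargs)
            probs = build_arm_matrix(summ, rounding_mode=config.rounding_mode)
        else:
            p = ac.probabilities
            probs = DerivedProbabilities(
                arm_label=ac.label, p_ss=p["ss"], p_sr=p["sr"], p_sp=p["sp"],
                p_rr=p["rr"], p_rp=p["rp"], p_pp=p["pp"], p_pd=p["pd"],
                rounding_mode="full_precision",
            )
        arms.append(ArmDefinition(probs=probs, state_costs=dict(ac.state_costs),
                                  intervention_cost=ac.intervention_cost))
    return CEModel(
        arm_a=arms[0], arm_b=arms[1], utilities=dict(config.utilities),
        discount_rate=config.discount_rate, n_cycles=config.n_cycles,
        cycle_length=config.cycle_length, half_cycle=config.half_cycle,
        wtp=config.nmb_wtp,
    )


def bundled_config_path() -> Path:
    """Path of the packaged AC-TH vs TCH fixture configuration."""
    return Path(resources.files("markovcea").joinpath("data/acth_tch.yaml"))


def load_default_config() -> AnalysisConfig:
    return load_config(bundled_config_path())
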