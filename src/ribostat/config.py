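"""Scenario configuration: packaged parameter fixtures, validation, overrides.

Three named fixtures ship with the package and load without a file:
``table1`` (well-mixed chemistry with jump noise), ``table2`` (the
self-replication scenario) and ``table3`` (the spatial multi-agent
scenario).  Any flat YAML mapping with the same keys works as a file-based
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError
from .kinetics import RateConstants, Totals
from .mas import MASParams

__all__ = ["ScenarioConfig", "load_config", "FIXTURES"]

#: fixture name -> default scenario kind
FIXTURES = {
    "table1": "spreadsheet",
    "table2": "replication",
    "table3": "mas",
}

_CHEMISTRY_KEYS = {"dt", "k1", "k2", "k3", "k4", "cA", "cX", "cY"}
_VALID_KEYS = {
    "spreadsheet": _CHEMISTRY_KEYS,
    "noise": _CHEMISTRY_KEYS | {"s"},
    "replication": _CHEMISTRY_KEYS | {"A0", "kRR", "dR"},
    "mas": {
        "sizeX", "sizeY", "init_R", "init_P", "agent_size", "Nmax", "d",
        "aR", "aP", "lP", "D", "Dprime", "delta", "dt", "K_repl",
        "k1", "k2", "k3", "k4", "n_inhibitors", "n_anti_inhibitors",
        "target_mode",
    },
}


def _load_fixture(name: str) -> dict[str, Any]:
    text = resources.files("ribostat.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def _validate_keys(mapping: Mapping[str, Any], scenario: str, origin: str) -> None:
    valid = _VALID_KEYS[scenario]
    unknown = sorted(set(mapping) - valid)
    if unknown:
        raise ConfigError(
            f"unknown parameter key(s) {unknown} in {origin} for scenario "
            f"{scenario!r}; valid keys: {sorted(valid)}"
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated, reproducible description of one simulation run."""

    scenario: str                      # spreadsheet | noise | replication | mas
    source: str                        # fixture name or file path
    params: dict[str, Any]
    overrides: dict[str, Any] = field(default_factory=dict)
    seed: Optional[int] = None
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in _VALID_KEYS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"valid scenarios: {sorted(_VALID_KEYS)}"
            )
        _validate_keys(self.params, self.scenario, f"parameter set {self.source!r}")
        _validate_keys(self.overrides, self.scenario, "overrides")

    def effective_params(self) -> dict[str, Any]:
        """Parameter set with overrides applied; echoed into run metadata."""
        merged = dict(self.params)
        merged.update(self.overrides)
        return merged

    def metadata(self) -> dict[str, Any]:
        return {
            "scenario": self.scenario,
            "source": self.source,
            "params": self.effective_params(),
            "seed": self.seed,
        }

    # -- typed views ----------------------------------------------------
    def rates(self) -> RateConstants:
        p = self.effective_params()
        return RateConstants(k1=p["k1"], k2=p["k2"], k3=p["k3"], k4=p["k4"])

    def totals(self) -> Totals:
        p = self.effective_params()
        cA = p.get("cA", p.get("A0"))
        if cA is None:
            raise ConfigError("parameter set defines neither cA nor A0")
        return Totals(cA=cA, cX=p.get("cX", 0.0), cY=p.get("cY", 0.0))

    def mas_params(self) -> MASParams:
        if self.scenario != "mas":
            raise ConfigError(f"scenario {self.scenario!r} has no agent parameters")
        return MASParams(**self.effective_params())


def load_config(
    source: str | Path,
    *,
    scenario: Optional[str] = None,
    overrides: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
    out: Optional[str] = None,
) -> ScenarioConfig:
    """Load a fixture by name or a flat YAML parameter file.

    ``scenario`` defaults to the fixture's natural scenario (table1 ->
    spreadsheet, table2 -> replication, table3 -> mas) and must be given
    for arbitrary files unless the file provides a ``scenario`` key.
    """
    name = str(source)
    if name in FIXTURES:
        params = _load_fixture(name)
        scenario = scenario or FIXTURES[name]
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(
                f"{name!r} is neither a known fixture {sorted(FIXTURES)} "
                "nor an existing file"
            )
        try:
            params = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {name!r}: {exc}") from exc
        if not isinstance(params, dict):
            raise ConfigError(f"{name!r} must contain a flat key: value mapping")
        scenario = scenario or params.pop("scenario", None)
        if scenario is None:
            raise ConfigError(
                f"scenario not given and {name!r} has no 'scenario' key"
            )
    return ScenarioConfig(
        scenario=scenario,
        source=name,
        params=params,
        overrides=dict(overrides or {}),
        seed=seed,
        out=out,
    )
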