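"""Packaged example configuration: unit costs, plausibility limits, scenario.

The unit-cost table shipped here is a synthetic example in the style of the
Dutch costing manuals; real analyses must supply their own prices and price
indices (the published manuals' values are not reproduced here).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .costing import InterventionCostSpec, UnitCostTable
from .screening import PlausibilityLimits


def _data_path(name: str):
    return resources.files("ceatrial") / "data" / name


def default_unit_costs() -> UnitCostTable:
    with _data_path("unit_costs.yaml").open() as fh:
        return UnitCostTable.from_dict(yaml.safe_load(fh))


def default_limits() -> PlausibilityLimits:
    with _data_path("limits.yaml").open() as fh:
        d = yaml.safe_load(fh)
    return PlausibilityLimits(limits={k: float(v) for k, v in d["limits"].items()},
                              recall_days=int(d.get("recall_days", 120)))


def default_intervention_spec() -> InterventionCostSpec:
    return InterventionCostSpec()


def load_scenario_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
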