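"""Valuation of service-use volumes into Euro costs.

Costs are assembled per participant from category volumes and a unit-cost
table, classified into sectors (health care plus the intersectoral sectors:
education, labor & social security, household & leisure, criminal justice,
and substance use), indexed to a common reference price year, and summed into
perspective totals:

* health-care perspective = health-care service costs + intervention cost
* societal perspective   = health-care perspective + intersectoral costs
                           + substance-use costs

Money is held in exact decimal cents internally; floating point appears only
in aggregate statistics.  The cost of alcohol purchases itself is never a
category: alcohol use is the effect measure, so costing it would double
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

CENT = Decimal("0.01")
EURO = Decimal("1")

HEALTH_CARE = "health_care"
EDUCATION = "education"
LABOR = "labor_social_security"
HOUSEHOLD = "household_leisure"
JUSTICE = "criminal_justice"
SUBSTANCE = "substance_use"

SECTORS = (HEALTH_CARE, EDUCATION, LABOR, HOUSEHOLD, JUSTICE, SUBSTANCE)
#: sectors counted as intersectoral costs and benefits (outside health care,
#: excluding substance use which is kept toggleable as its own block)
ICB_SECTORS = (EDUCATION, LABOR, HOUSEHOLD, JUSTICE)

#: category name fragments that are never allowed: the outcome itself must
#: not be costed (double counting)
_FORBIDDEN_FRAGMENTS = ("alcohol",)


class ConfigurationError(ValueError):
    """Raised for invalid unit-cost tables, unknown categories or years."""


def _as_money(x) -> Decimal:
    """Convert a number to an exact Decimal via its string representation."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


@dataclass(frozen=True)
class UnitCostTable:
    """Unit prices per category with sector labels and price-index factors.

    Parameters
    ----------
    entries : mapping category -> (unit_price in Euro, price_year)
    sector_map : mapping category -> sector name (one of :data:`SECTORS`)
    index_factors : mapping calendar year -> price-index multiplier; the
        reference year must carry factor 1.
    reference_year : year all prices are indexed to.
    """

    entries: Mapping[str, tuple]
    sector_map: Mapping[str, str]
    index_factors: Mapping[int, Decimal]
    reference_year: int = 2014

    def __post_init__(self):
        for cat, (price, year) in self.entries.items():
            price = _as_money(price)
            if price < 0:
                raise ConfigurationError(f"negative unit price for {cat!r}")
            if cat not in self.sector_map:
                raise ConfigurationError(f"category {cat!r} has no sector")
            for frag in _FORBIDDEN_FRAGMENTS:
                if frag in cat.lower():
                    raise ConfigurationError(
                        f"category {cat!r} would cost the outcome itself "
                        "(alcohol purchases are excluded to avoid double counting)"
                    )
        for cat, sector in self.sector_map.items():
            if sector not in SECTORS:
                raise ConfigurationError(f"unknown sector {sector!r} for {cat!r}")
        ref = self.index_factors.get(self.reference_year)
        if ref is None or _as_money(ref) != 1:
            raise ConfigurationError(
                f"index factor for reference year {self.reference_year} must be 1"
            )

    @property
    def categories(self) -> tuple:
        return tuple(self.entries)

    def indexed_price(self, category: str) -> Decimal:
        """Unit price of *category* indexed to the reference year, to the cent."""
        price, year = self.entries[category]
        return index_price(_as_money(price), int(year), self.reference_year,
                           self.index_factors)

    def categories_in_sector(self, sector: str) -> tuple:
        return tuple(c for c in self.entries if self.sector_map[c] == sector)

    @classmethod
    def from_dict(cls, d: dict) -> "UnitCostTable":
        entries = {}
        sector_map = {}
        for cat, spec in d["categories"].items():
            entries[cat] = (_as_money(spec["unit_price"]), int(spec["price_year"]))
            sector_map[cat] = spec["sector"]
        factors = {int(y): _as_money(f) for y, f in d["index_factors"].items()}
        return cls(entries=entries, sector_map=sector_map, index_factors=factors,
                   reference_year=int(d.get("reference_year", 2014)))

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def index_price(price, from_year: int, to_year: int,
                index_factors: Mapping[int, Decimal]) -> Decimal:
    """Index a price between calendar years: price * factor(to)/factor(from).

    Exact decimal arithmetic, rounded half-up to the cent.
    """
    price = _as_money(price)
    if price < 0:
        raise ConfigurationError("price must be nonnegative")
    try:
        f_from = _as_money(index_factors[from_year])
        f_to = _as_money(index_factors[to_year])
    except KeyError as exc:
        raise ConfigurationError(f"no price-index factor for year {exc.args[0]}")
    return (price * f_to / f_from).quantize(CENT, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class InterventionCostSpec:
    """Per-participant running cost of the tailored-feedback intervention.

    The default build-up: tailored-feedback software at 7 Euro per participant
    per week over a mean 4-week intervention (28 Euro), plus participant time
    (1.5 h at school at 8.30 Euro/h and a 12.50 Euro lump for one hour of
    free time), rounded to the nearest Euro (25), totalling 53 Euro.
    """

    feedback_fee_per_week: Decimal = Decimal("7.00")
    feedback_weeks: Decimal = Decimal("4")
    school_hours: Decimal = Decimal("1.5")
    school_hour_rate: Decimal = Decimal("8.30")
    free_time_hours: Decimal = Decimal("1")
    free_time_value: Decimal = Decimal("12.50")
    rounding: str = "nearest_euro"

    def __post_init__(self):
        for name in ("feedback_fee_per_week", "feedback_weeks", "school_hours",
                     "school_hour_rate", "free_time_hours", "free_time_value"):
            val = _as_money(getattr(self, name))
            if val < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
            object.__setattr__(self, name, val)
        if self.rounding not in ("nearest_euro", "none"):
            raise ConfigurationError(f"unknown rounding rule {self.rounding!r}")

    @property
    def feedback_cost(self) -> Decimal:
        return (self.feedback_fee_per_week * self.feedback_weeks).quantize(CENT)

    @property
    def time_cost(self) -> Decimal:
        raw = self.school_hours * self.school_hour_rate + self.free_time_value
        if self.rounding == "nearest_euro":
            return raw.quantize(EURO, rounding=ROUND_HALF_UP).quantize(CENT)
        return raw.quantize(CENT, rounding=ROUND_HALF_UP)

    def total(self) -> Decimal:
        return (self.feedback_cost + self.time_cost).quantize(CENT)

    @classmethod
    def from_dict(cls, d: dict) -> "InterventionCostSpec":
        return cls(**{k: (_as_money(v) if k != "rounding" else v)
                      for k, v in d.items()})


def intervention_cost(spec: InterventionCostSpec) -> Decimal:
    """Total per-participant intervention cost under the spec's rounding rule."""
    return spec.total()


@dataclass
class CostBreakdown:
    """Per-participant costs by category, sector, and analysis perspective."""

    per_category: dict = field(default_factory=dict)
    per_sector: dict = field(default_factory=dict)
    intervention_cost: Decimal = Decimal("0")

    @property
    def health_care_total(self) -> Decimal:
        return self.per_sector.get(HEALTH_CARE, Decimal("0"))

    @property
    def icb_total(self) -> Decimal:
        return sum((self.per_sector.get(s, Decimal("0")) for s in ICB_SECTORS),
                   Decimal("0"))

    @property
    def substance_total(self) -> Decimal:
        return self.per_sector.get(SUBSTANCE, Decimal("0"))

    @property
    def healthcare_perspective_total(self) -> Decimal:
        return self.health_care_total + self.intervention_cost

    @property
    def societal_perspective_total(self) -> Decimal:
        return (self.health_care_total + self.icb_total + self.substance_total
                + self.intervention_cost)


def value_costs(record: Mapping, unit_costs: UnitCostTable,
                intervention_spec: InterventionCostSpec | None = None,
                arm_rule: str = "intervention_only") -> CostBreakdown:
    """Value one participant's volumes into a :class:`CostBreakdown`.

    ``record`` maps category names to nonnegative volumes and must carry an
    ``arm`` key; the intervention cost is attributed according to
    ``arm_rule``: ``intervention_only`` (default), ``all`` or ``none``.
    """
    if arm_rule not in ("intervention_only", "all", "none"):
        raise ConfigurationError(f"unknown arm_rule {arm_rule!r}")
    unknown = [c for c, v in record.items()
               if c not in unit_costs.entries and c != "arm"
               and isinstance(v, (int, float, Decimal)) and float(v) != 0.0]
    if unknown:
        raise ConfigurationError(
            f"volume categories without unit costs: {sorted(unknown)}")
    per_category = {}
    per_sector = {s: Decimal("0") for s in SECTORS}
    for cat in unit_costs.categories:
        vol = record.get(cat, 0) or 0
        cost = (_as_money(vol) * unit_costs.indexed_price(cat)).quantize(
            CENT, rounding=ROUND_HALF_UP)
        per_category[cat] = cost
        per_sector[unit_costs.sector_map[cat]] += cost
    iv = Decimal("0")
    if intervention_spec is not None:
        if arm_rule == "all" or (arm_rule == "intervention_only"
                                 and record.get("arm") == "intervention"):
            iv = intervention_spec.total()
    return CostBreakdown(per_category=per_category, per_sector=per_sector,
                         intervention_cost=iv)


class CostValuer(BaseEstimator):
    """Transformer turning a participant table into a per-participant cost table.

    Parameters
    ----------
    unit_costs : UnitCostTable
    intervention_spec : InterventionCostSpec or None
        When None, intervention cost is 0 for everyone.
    arm_rule : {'intervention_only', 'all', 'none'}
        Who is charged the intervention cost.

    The transformed frame carries one ``cost_<category>`` column per category,
    sector totals, and the two perspective totals, as floats in Euro.
    """

    def __init__(self, unit_costs=None, intervention_spec=None,
                 arm_rule="intervention_only"):
        self.unit_costs = unit_costs
        self.intervention_spec = intervention_spec
        self.arm_rule = arm_rule

    def fit(self, X: pd.DataFrame, y=None):
        if self.unit_costs is None:
            raise ConfigurationError("unit_costs is required")
        if self.arm_rule not in ("intervention_only", "all", "none"):
            raise ConfigurationError(f"unknown arm_rule {self.arm_rule!r}")
        missing = [c for c in self.unit_costs.categories if c not in X.columns]
        if missing:
            raise ConfigurationError(
                f"participant table lacks volume columns: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        uc = self.unit_costs
        out = pd.DataFrame(index=X.index)
        for key in ("participant_id", "cluster_id", "arm"):
            if key in X.columns:
                out[key] = X[key]
        sector_tot = {s: np.zeros(len(X)) for s in SECTORS}
        for cat in uc.categories:
            price = uc.indexed_price(cat)
            vols = X[cat].fillna(0)
            cents = np.array(
                [int((_as_money(v) * price).quantize(CENT, rounding=ROUND_HALF_UP)
                     * 100) for v in vols])
            col = cents / 100.0
            out[f"cost_{cat}"] = col
            sector_tot[uc.sector_map[cat]] += col
        for s in SECTORS:
            out[f"cost_sector_{s}"] = sector_tot[s]
        iv_total = 0.0
        if self.intervention_spec is not None:
            iv_total = float(self.intervention_spec.total())
        if self.arm_rule == "all":
            iv = np.full(len(X), iv_total)
        elif self.arm_rule == "none" or "arm" not in X.columns:
            iv = np.zeros(len(X))
        else:
            iv = np.where(X["arm"].to_numpy() == "intervention", iv_total, 0.0)
        out["cost_intervention"] = iv
        hc = sector_tot[HEALTH_CARE]
        icb = sum(sector_tot[s] for s in ICB_SECTORS)
        sub = sector_tot[SUBSTANCE]
        out["cost_healthcare_perspective"] = np.round(hc + iv, 2)
        out["cost_societal_perspective"] = np.round(hc + icb + sub + iv, 2)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def value_costs_table(X: pd.DataFrame, unit_costs: UnitCostTable,
                      intervention_spec: InterventionCostSpec | None = None,
                      arm_rule: str = "intervention_only") -> pd.DataFrame:
    """Functional wrapper over :class:`CostValuer`."""
    return CostValuer(unit_costs, intervention_spec, arm_rule).fit_transform(X)


def summarize_costs(costs: pd.DataFrame, group: str = "arm",
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-arm cost summary: mean, SD, bootstrap median and variance.

    The bootstrap median of a column is the 50th percentile of ``n_boot``
    means of within-group resamples (with replacement, original group size);
    the bootstrap variance is the variance of those resampled means.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(costs) == 0:
        raise ValueError("empty group")
    value_cols = [c for c in costs.columns if c.startswith("cost_")]
    rows = []
    for gi, (gname, gdf) in enumerate(costs.groupby(group, sort=True)):
        if len(gdf) == 0:
            raise ValueError(f"empty group {gname!r}")
        rng = np.random.default_rng([int(seed), gi])
        n = len(gdf)
        idx = rng.integers(0, n, size=(n_boot, n))
        mat = gdf[value_cols].to_numpy(dtype=float)
        boot_means = mat[idx].mean(axis=1)  # (n_boot, n_cols)
        for j, col in enumerate(value_cols):
            vals = mat[:, j]
            rows.append({
                group: gname,
                "category": col.removeprefix("cost_"),
                "n": n,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                "boot_median": float(np.percentile(boot_means[:, j], 50)),
                "boot_variance": float(boot_means[:, j].var(ddof=1))
                if n_boot > 1 else 0.0,
            })
    return pd.DataFrame(rows)
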