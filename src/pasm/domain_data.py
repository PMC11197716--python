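"""Domain types, bundle I/O and validation.

A *model input bundle* is a directory of plain CSV tables plus a
``settings.json`` that together describe one regional sector-model
instance: crops, districts, per-(district, crop, technology) budgets,
demand calibration points, historical crop mixes and an observed
baseline year.  All loading, cross-table validation and results
serialization lives here; nothing in this module solves anything.

Unit conventions (fixed globally):

* areas in ha, yields in kg/ha, production and sales in t (1 t = 1000 kg)
* prices stored externally in yuan/kg, converted to yuan/t internally
  for surplus arithmetic
* pesticide totals in t, application rates in kg/ha
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

CROP_CATEGORIES = ("grain", "leafy_vegetable", "other_vegetable", "fruit", "oilseed")
TECH_LEVELS = ("base", "mechanized")
INPUT_IDS = ("pesticide", "fertilizer", "labor")

#: categories treated as horticultural (vs field crops) in generators/checks
HORTICULTURAL_CATEGORIES = ("leafy_vegetable", "other_vegetable", "fruit")

BUNDLE_FILES = (
    "crops.csv",
    "districts.csv",
    "budgets.csv",
    "input_prices.csv",
    "demand.csv",
    "historical_mix.csv",
    "observed.csv",
    "settings.json",
)

RESULTS_COLUMNS = (
    "scenario_id",
    "reduction_level",
    "tech",
    "imposition",
    "economy",
    "metric",
    "entity",
    "value",
)


class BundleLoadError(Exception):
    """Raised when a bundle directory is missing files or malformed."""


@dataclass(frozen=True)
class Crop:
    id: str
    name: str
    category: str


@dataclass(frozen=True)
class District:
    id: str
    name: str
    land_ha: float


@dataclass(frozen=True)
class CropBudget:
    """Per-hectare enterprise account for one (district, crop, tech)."""

    district: str
    crop: str
    tech: str
    yield_kg_per_ha: float
    pesticide_kg_per_ha: float
    fertilizer_kg_per_ha: float
    labor_pm_per_ha: float
    machinery_cost_yuan_per_ha: float
    other_cost_yuan_per_ha: float

    @property
    def yield_t_per_ha(self) -> float:
        return self.yield_kg_per_ha / 1000.0

    @property
    def activity_cost_yuan_per_ha(self) -> float:
        """Direct cost per hectare not routed through priced inputs."""
        return self.machinery_cost_yuan_per_ha + self.other_cost_yuan_per_ha


@dataclass(frozen=True)
class InputPrice:
    input_id: str
    price: float  # yuan/kg for chemicals, yuan/person-month for labor


@dataclass
class DemandSpec:
    """Linear inverse-demand calibration point for one commodity.

    ``intercept_a`` / ``slope_b`` are in yuan/t and yuan/t per t and are
    derived from the observed point by
    :func:`pasm.demand_supply.calibrate_linear_inverse_demand`.
    """

    crop: str
    p0_yuan_per_kg: float
    q0_t: float
    elasticity: float
    intercept_a: Optional[float] = None
    slope_b: Optional[float] = None

    @property
    def p0_yuan_per_t(self) -> float:
        return self.p0_yuan_per_kg * 1000.0


@dataclass(frozen=True)
class HistoricalMix:
    district: str
    year: str
    acreage_by_crop: dict  # crop id -> ha


@dataclass
class ObservedBaseline:
    """Base-year observed acreage/production/price, used for validation
    and for baseline pesticide usage."""

    acreage_ha: dict  # crop -> ha
    production_t: dict  # crop -> t
    price_yuan_per_kg: dict  # crop -> yuan/kg
    district_acreage_ha: Optional[dict] = None  # (district, crop) -> ha


@dataclass
class Settings:
    mix_delta: float = 0.15
    crop_mix_enabled: bool = True
    feasibility_tol: float = 1e-7
    optimality_tol: float = 1e-7
    discount_rate: float = 0.05
    machine_lifespan_years: float = 10.0
    rice_crop_id: str = "rice"
    solver: str = "auto"
    baseline_from_solution: bool = False


@dataclass
class ModelInputBundle:
    crops: list
    districts: list
    budgets: list
    input_prices: list
    demand_specs: list
    historical_mixes: list
    observed_baseline: ObservedBaseline
    settings: Settings = field(default_factory=Settings)

    # -- convenience lookups -------------------------------------------------
    def crop_ids(self) -> list:
        return [c.id for c in self.crops]

    def district_ids(self) -> list:
        return [d.id for d in self.districts]

    def crop(self, crop_id: str) -> Crop:
        for c in self.crops:
            if c.id == crop_id:
                return c
        raise KeyError(crop_id)

    def district(self, district_id: str) -> District:
        for d in self.districts:
            if d.id == district_id:
                return d
        raise KeyError(district_id)

    def demand_spec(self, crop_id: str) -> DemandSpec:
        for s in self.demand_specs:
            if s.crop == crop_id:
                return s
        raise KeyError(crop_id)

    def input_price(self, input_id: str) -> float:
        for p in self.input_prices:
            if p.input_id == input_id:
                return p.price
        raise KeyError(input_id)

    def budgets_for(self, tech: Optional[str] = None) -> list:
        if tech is None:
            return list(self.budgets)
        return [b for b in self.budgets if b.tech == tech]

    def budget(self, district: str, crop: str, tech: str) -> CropBudget:
        for b in self.budgets:
            if b.district == district and b.crop == crop and b.tech == tech:
                return b
        raise KeyError((district, crop, tech))


@dataclass(frozen=True)
class Issue:
    """One validation finding: which table, which key, which rule failed."""

    table: str
    key: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.key}]: {self.rule}"


@dataclass
class ResultsTable:
    """Long-format results: one row per (scenario, metric, entity)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in RESULTS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"results frame missing columns: {missing}")
        self.frame = self.frame[list(RESULTS_COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list) -> "ResultsTable":
        return cls(pd.DataFrame.from_records(records, columns=list(RESULTS_COLUMNS)))

    def __len__(self) -> int:
        return len(self.frame)

    def scenario_ids(self) -> list:
        return list(pd.unique(self.frame["scenario_id"]))

    def value(self, scenario_id: str, metric: str, entity: str) -> float:
        f = self.frame
        sel = f[
            (f["scenario_id"] == scenario_id)
            & (f["metric"] == metric)
            & (f["entity"] == entity)
        ]
        if len(sel) != 1:
            raise KeyError((scenario_id, metric, entity))
        return float(sel["value"].iloc[0])


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_csv(directory: str, name: str, required_columns: tuple) -> pd.DataFrame:
    path = os.path.join(directory, name)
    if not os.path.exists(path):
        raise BundleLoadError(f"bundle is missing required file {name!r}")
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    for col in required_columns:
        if col not in df.columns:
            raise BundleLoadError(f"{name}: missing required column {col!r}")
    return df


def load_bundle(directory: str) -> ModelInputBundle:
    """Load a bundle directory into a :class:`ModelInputBundle`.

    Demand coefficients (``intercept_a``, ``slope_b``) are derived from
    the calibration point at load time.
    """
    from . import demand_supply  # local import to avoid a cycle

    crops_df = _read_csv(directory, "crops.csv", ("id", "name", "category"))
    districts_df = _read_csv(directory, "districts.csv", ("id", "name", "land_ha"))
    budgets_df = _read_csv(
        directory,
        "budgets.csv",
        (
            "district",
            "crop",
            "tech",
            "yield_kg_per_ha",
            "pesticide_kg_per_ha",
            "fertilizer_kg_per_ha",
            "labor_pm_per_ha",
            "machinery_cost_yuan_per_ha",
            "other_cost_yuan_per_ha",
        ),
    )
    prices_df = _read_csv(directory, "input_prices.csv", ("input_id", "price"))
    demand_df = _read_csv(directory, "demand.csv", ("crop", "p0_yuan_per_kg", "q0_t", "elasticity"))
    mix_df = _read_csv(directory, "historical_mix.csv", ("district", "year", "crop", "area_ha"))
    observed_df = _read_csv(
        directory, "observed.csv", ("crop", "acreage_ha", "production_t", "price_yuan_per_kg")
    )

    settings_path = os.path.join(directory, "settings.json")
    if not os.path.exists(settings_path):
        raise BundleLoadError("bundle is missing required file 'settings.json'")
    with open(settings_path) as fh:
        raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(Settings)}
    settings = Settings(**{k: v for k, v in raw.items() if k in known})

    crops = [Crop(str(r.id), str(r.name), str(r.category)) for r in crops_df.itertuples()]
    districts = [
        District(str(r.id), str(r.name), float(r.land_ha)) for r in districts_df.itertuples()
    ]
    budgets = [
        CropBudget(
            district=str(r.district),
            crop=str(r.crop),
            tech=str(r.tech),
            yield_kg_per_ha=float(r.yield_kg_per_ha),
            pesticide_kg_per_ha=float(r.pesticide_kg_per_ha),
            fertilizer_kg_per_ha=float(r.fertilizer_kg_per_ha),
            labor_pm_per_ha=float(r.labor_pm_per_ha),
            machinery_cost_yuan_per_ha=float(r.machinery_cost_yuan_per_ha),
            other_cost_yuan_per_ha=float(r.other_cost_yuan_per_ha),
        )
        for r in budgets_df.itertuples()
    ]
    input_prices = [InputPrice(str(r.input_id), float(r.price)) for r in prices_df.itertuples()]
    demand_specs = []
    for r in demand_df.itertuples():
        spec = DemandSpec(
            crop=str(r.crop),
            p0_yuan_per_kg=float(r.p0_yuan_per_kg),
            q0_t=float(r.q0_t),
            elasticity=float(r.elasticity),
        )
        if spec.p0_yuan_per_kg > 0 and spec.q0_t > 0 and spec.elasticity < 0:
            a, b = demand_supply.calibrate_linear_inverse_demand(
                spec.p0_yuan_per_t, spec.q0_t, spec.elasticity
            )
            spec.intercept_a, spec.slope_b = a, b
        demand_specs.append(spec)

    mixes = []
    for (district, year), grp in mix_df.groupby(["district", "year"], sort=True):
        acreage = {str(r.crop): float(r.area_ha) for r in grp.itertuples()}
        mixes.append(HistoricalMix(str(district), str(year), acreage))

    observed = ObservedBaseline(
        acreage_ha={str(r.crop): float(r.acreage_ha) for r in observed_df.itertuples()},
        production_t={str(r.crop): float(r.production_t) for r in observed_df.itertuples()},
        price_yuan_per_kg={
            str(r.crop): float(r.price_yuan_per_kg) for r in observed_df.itertuples()
        },
    )
    district_observed_path = os.path.join(directory, "observed_district.csv")
    if os.path.exists(district_observed_path):
        dd = pd.read_csv(district_observed_path)
        observed.district_acreage_ha = {
            (str(r.district), str(r.crop)): float(r.acreage_ha) for r in dd.itertuples()
        }

    return ModelInputBundle(
        crops=crops,
        districts=districts,
        budgets=budgets,
        input_prices=input_prices,
        demand_specs=demand_specs,
        historical_mixes=mixes,
        observed_baseline=observed,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_bundle(bundle: ModelInputBundle) -> list:
    """Check every type invariant and cross-table reference.

    Returns a list of :class:`Issue`; an empty list means the bundle can
    be assembled into a solvable baseline problem.
    """
    issues = []
    crop_ids = set()
    for c in bundle.crops:
        if c.id in crop_ids:
            issues.append(Issue("crops", c.id, "id unique"))
        crop_ids.add(c.id)
        if c.category not in CROP_CATEGORIES:
            issues.append(Issue("crops", c.id, f"category in {CROP_CATEGORIES}"))

    district_ids = set()
    for d in bundle.districts:
        if d.id in district_ids:
            issues.append(Issue("districts", d.id, "id unique"))
        district_ids.add(d.id)
        if not d.land_ha > 0:
            issues.append(Issue("districts", d.id, "land_ha > 0"))

    seen_budget_keys = set()
    for b in bundle.budgets:
        key = f"{b.district}/{b.crop}/{b.tech}"
        if (b.district, b.crop, b.tech) in seen_budget_keys:
            issues.append(Issue("budgets", key, "(district, crop, tech) unique"))
        seen_budget_keys.add((b.district, b.crop, b.tech))
        if b.district not in district_ids:
            issues.append(Issue("budgets", key, "district exists"))
        if b.crop not in crop_ids:
            issues.append(Issue("budgets", key, "crop exists"))
        if b.tech not in TECH_LEVELS:
            issues.append(Issue("budgets", key, f"tech in {TECH_LEVELS}"))
        if not b.yield_kg_per_ha > 0:
            issues.append(Issue("budgets", key, "yield_kg_per_ha > 0"))
        for fname in (
            "pesticide_kg_per_ha",
            "fertilizer_kg_per_ha",
            "labor_pm_per_ha",
            "machinery_cost_yuan_per_ha",
            "other_cost_yuan_per_ha",
        ):
            if getattr(b, fname) < 0:
                issues.append(Issue("budgets", key, f"{fname} >= 0"))

    price_ids = set()
    for p in bundle.input_prices:
        if p.input_id not in INPUT_IDS:
            issues.append(Issue("input_prices", p.input_id, f"input_id in {INPUT_IDS}"))
        if p.input_id in price_ids:
            issues.append(Issue("input_prices", p.input_id, "input_id unique"))
        price_ids.add(p.input_id)
        if p.price < 0:
            issues.append(Issue("input_prices", p.input_id, "price >= 0"))
    for required in INPUT_IDS:
        if required not in price_ids:
            issues.append(Issue("input_prices", required, "price present for every input"))

    demand_crops = set()
    for s in bundle.demand_specs:
        if s.crop not in crop_ids:
            issues.append(Issue("demand", s.crop, "crop exists"))
        demand_crops.add(s.crop)
        if not s.p0_yuan_per_kg > 0:
            issues.append(Issue("demand", s.crop, "p0 > 0"))
        if not s.q0_t > 0:
            issues.append(Issue("demand", s.crop, "q0 > 0"))
        if not s.elasticity < 0:
            issues.append(Issue("demand", s.crop, "elasticity < 0"))
        if s.slope_b is not None and s.slope_b < 0:
            issues.append(Issue("demand", s.crop, "slope_b >= 0"))
        if (
            s.intercept_a is not None
            and s.p0_yuan_per_kg > 0
            and s.intercept_a < 1000.0 * s.p0_yuan_per_kg - 1e-9
        ):
            issues.append(Issue("demand", s.crop, "intercept_a >= 1000*p0_yuan_per_kg"))
    for cid in crop_ids:
        if cid not in demand_crops:
            issues.append(Issue("demand", cid, "every crop has a demand spec"))

    positive_acreage = set()  # (district, crop) pairs needing a base budget
    for m in bundle.historical_mixes:
        key = f"{m.district}/{m.year}"
        if m.district not in district_ids:
            issues.append(Issue("historical_mix", key, "district exists"))
        if not any(v > 0 for v in m.acreage_by_crop.values()):
            issues.append(Issue("historical_mix", key, "at least one positive acreage"))
        for crop, area in m.acreage_by_crop.items():
            if crop not in crop_ids:
                issues.append(Issue("historical_mix", f"{key}/{crop}", "crop exists"))
            if area < 0:
                issues.append(Issue("historical_mix", f"{key}/{crop}", "area_ha >= 0"))
            if area > 0:
                positive_acreage.add((m.district, crop))

    obs = bundle.observed_baseline
    for crop, v in obs.acreage_ha.items():
        if crop not in crop_ids:
            issues.append(Issue("observed", crop, "crop exists"))
        if not v > 0:
            issues.append(Issue("observed", crop, "acreage_ha > 0"))
    for crop, v in obs.production_t.items():
        if not v > 0:
            issues.append(Issue("observed", crop, "production_t > 0"))
    for crop, v in obs.price_yuan_per_kg.items():
        if not v > 0:
            issues.append(Issue("observed", crop, "price_yuan_per_kg > 0"))
    if obs.district_acreage_ha:
        for (district, crop), v in obs.district_acreage_ha.items():
            if v > 0:
                positive_acreage.add((district, crop))

    base_budget_keys = {(b.district, b.crop) for b in bundle.budgets if b.tech == "base"}
    for district, crop in sorted(positive_acreage):
        if (district, crop) not in base_budget_keys:
            issues.append(
                Issue(
                    "budgets",
                    f"{district}/{crop}/base",
                    "base budget present for every positive acreage",
                )
            )

    if not 0 <= bundle.settings.mix_delta:
        issues.append(Issue("settings", "mix_delta", "mix_delta >= 0"))

    return issues


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------


def write_results(results: ResultsTable, path: str) -> None:
    """Write a results table as CSV (12 significant digits on values)."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    frame = results.frame.copy()
    frame["value"] = [format(float(v), ".12g") for v in frame["value"]]
    frame.to_csv(path, index=False)


def write_bundle(bundle: ModelInputBundle, directory: str) -> None:
    """Write a bundle as a directory of CSV tables plus settings.json."""
    os.makedirs(directory, exist_ok=True)

    def _dump(name: str, frame: pd.DataFrame) -> None:
        out = frame.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = [repr(float(v)) for v in out[col]]  # exact round trip
        out.to_csv(os.path.join(directory, name), index=False)

    _dump(
        "crops.csv",
        pd.DataFrame(
            [(c.id, c.name, c.category) for c in bundle.crops],
            columns=["id", "name", "category"],
        ),
    )
    _dump(
        "districts.csv",
        pd.DataFrame(
            [(d.id, d.name, d.land_ha) for d in bundle.districts],
            columns=["id", "name", "land_ha"],
        ),
    )
    _dump(
        "budgets.csv",
        pd.DataFrame(
            [
                (
                    b.district,
                    b.crop,
                    b.tech,
                    b.yield_kg_per_ha,
                    b.pesticide_kg_per_ha,
                    b.fertilizer_kg_per_ha,
                    b.labor_pm_per_ha,
                    b.machinery_cost_yuan_per_ha,
                    b.other_cost_yuan_per_ha,
                )
                for b in bundle.budgets
            ],
            columns=[
                "district",
                "crop",
                "tech",
                "yield_kg_per_ha",
                "pesticide_kg_per_ha",
                "fertilizer_kg_per_ha",
                "labor_pm_per_ha",
                "machinery_cost_yuan_per_ha",
                "other_cost_yuan_per_ha",
            ],
        ),
    )
    _dump(
        "input_prices.csv",
        pd.DataFrame(
            [(p.input_id, p.price) for p in bundle.input_prices],
            columns=["input_id", "price"],
        ),
    )
    _dump(
        "demand.csv",
        pd.DataFrame(
            [
                (s.crop, s.p0_yuan_per_kg, s.q0_t, s.elasticity)
                for s in bundle.demand_specs
            ],
            columns=["crop", "p0_yuan_per_kg", "q0_t", "elasticity"],
        ),
    )
    mix_rows = []
    for m in bundle.historical_mixes:
        for crop in sorted(m.acreage_by_crop):
            mix_rows.append((m.district, m.year, crop, m.acreage_by_crop[crop]))
    _dump(
        "historical_mix.csv",
        pd.DataFrame(mix_rows, columns=["district", "year", "crop", "area_ha"]),
    )
    obs = bundle.observed_baseline
    _dump(
        "observed.csv",
        pd.DataFrame(
            [
                (c, obs.acreage_ha[c], obs.production_t[c], obs.price_yuan_per_kg[c])
                for c in sorted(obs.acreage_ha)
            ],
            columns=["crop", "acreage_ha", "production_t", "price_yuan_per_kg"],
        ),
    )
    if obs.district_acreage_ha:
        _dump(
            "observed_district.csv",
            pd.DataFrame(
                [
                    (d, c, a)
                    for (d, c), a in sorted(obs.district_acreage_ha.items())
                ],
                columns=["district", "crop", "acreage_ha"],
            ),
        )
    with open(os.path.join(directory, "settings.json"), "w") as fh:
        json.dump(dataclasses.asdict(bundle.settings), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str) -> ResultsTable:
    df = pd.read_csv(path, dtype={c: str for c in RESULTS_COLUMNS if c != "value"})
    df["value"] = df["value"].astype(float)
    df["reduction_level"] = df["reduction_level"].astype(float)
    return ResultsTable(df)
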