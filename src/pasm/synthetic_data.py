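"""Synthetic model-input bundles, survey tables and known-equilibrium
test instances.

Everything downstream of raw data collection is testable offline: the
generator emits complete bundles with the default 9-district x 15-crop
layout (pesticide rates for horticultural crops stochastically dominate
field crops), paired-subsample farm surveys with injected technology
effects, and tiny instances whose welfare optimum is known in closed
form (interior solutions where marginal net revenue per hectare is
equalized across planted crops).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import budget_engine, demand_supply
from .domain_data import (
    Crop,
    CropBudget,
    DemandSpec,
    District,
    HistoricalMix,
    HORTICULTURAL_CATEGORIES,
    InputPrice,
    ModelInputBundle,
    ObservedBaseline,
    Settings,
    validate_bundle,
)


class GenerationError(Exception):
    """Raised when a config cannot yield a valid instance."""


#: default per-category agronomic parameters (means of the generating
#: distributions; yields kg/ha, rates kg/ha, costs yuan/ha, prices yuan/kg)
DEFAULT_CATEGORY_PARAMS = {
    "grain": dict(yield_mean=7200.0, fert_mean=950.0, labor_mean=5.0, price_mean=3.2),
    "leafy_vegetable": dict(yield_mean=32000.0, fert_mean=650.0, labor_mean=11.0, price_mean=2.5),
    "other_vegetable": dict(yield_mean=36000.0, fert_mean=700.0, labor_mean=10.0, price_mean=4.2),
    "fruit": dict(yield_mean=24000.0, fert_mean=800.0, labor_mean=12.0, price_mean=7.5),
    "oilseed": dict(yield_mean=2400.0, fert_mean=550.0, labor_mean=4.0, price_mean=3.0),
}

#: crop-count shares per category for the default 15-crop layout
DEFAULT_CATEGORY_SHARES = {
    "grain": 3 / 15,
    "oilseed": 1 / 15,
    "fruit": 3 / 15,
    "leafy_vegetable": 2 / 15,
    "other_vegetable": 6 / 15,
}


@dataclass
class GeneratorConfig:
    n_districts: int = 9
    n_crops: int = 15
    category_shares: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_SHARES))
    category_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CATEGORY_PARAMS.items()
    })
    # distribution dispersions (log-normal sigma unless noted)
    yield_sigma: float = 0.12
    district_multiplier_sigma: float = 0.08
    cost_sigma: float = 0.15
    price_sigma: float = 0.10
    # pesticide rates: gamma with category means; horticulture mean is
    # grain mean times this ratio
    grain_pesticide_mean: float = 4.0
    horticulture_pesticide_ratio: float = 5.0
    pesticide_gamma_shape: float = 9.0
    # land and cropping
    mean_land_ha: float = 20000.0
    land_sigma: float = 0.35
    cropland_fraction: float = 0.8
    n_mix_years: int = 3
    mix_noise_sigma: float = 0.10
    mix_delta: float = 0.15
    crop_mix_enabled: bool = True
    # demand
    elasticity_range: tuple = (-1.2, -0.2)
    # input prices (yuan/kg, yuan/kg, yuan/person-month)
    pesticide_price: float = 60.0
    fertilizer_price: float = 3.0
    labor_price: float = 1900.0
    # machinery / other costs
    machinery_cost_mean: float = 3000.0
    other_cost_mean: float = 6000.0
    # survey
    n_total: int = 532
    n_mechanized: int = 281
    survey_noise_sigma: float = 0.10
    yield_pct: float = 1.788
    pesticide_pct: float = -4.693
    labor_pct: float = -9.845
    machinery_pct: float = 16.182
    fertilizer_pct: float = -1.352
    wage_pct: float = 3.252
    survey_base_means: dict = field(default_factory=lambda: dict(
        yield_kg_per_ha=7943.18,
        fertilizer_kg_per_ha=1009.09,
        pesticide_kg_per_ha=18.75,
        labor_wage_yuan_per_pm=1863.64,
        labor_pm_per_ha=14.83,
        machinery_purchase_cost_raw_yuan_per_ha=13857.0,
        machinery_rent_yuan_per_ha=2147.73,
    ))
    include_mechanized_budgets: bool = True
    discount_rate: float = 0.05
    machine_lifespan_years: float = 10.0
    # known-equilibrium instance parameters (None -> random interior draw)
    eq_land_ha: float = 100.0
    eq_yields_t_per_ha: Optional[list] = None
    eq_costs_yuan_per_ha: Optional[list] = None
    eq_demand_a: Optional[list] = None
    eq_demand_b: Optional[list] = None
    eq_pesticide_kg_per_ha: Optional[list] = None
    eq_n_crops: int = 2
    seed: int = 0

    @property
    def n_base(self) -> int:
        return self.n_total - self.n_mechanized

    def validate(self) -> None:
        if self.n_districts < 1 or self.n_crops < 1:
            raise GenerationError("need at least one district and one crop")
        if self.n_mechanized < 0 or self.n_mechanized > self.n_total:
            raise GenerationError("n_mechanized must lie in [0, n_total]")
        lo, hi = self.elasticity_range
        if not (lo <= hi < 0):
            raise GenerationError("elasticity range must be negative")
        for s in (
            self.yield_sigma,
            self.cost_sigma,
            self.price_sigma,
            self.mix_noise_sigma,
            self.survey_noise_sigma,
        ):
            if s < 0:
                raise GenerationError("dispersions must be non-negative")
        if not 0 < self.cropland_fraction <= 1:
            raise GenerationError("cropland_fraction must be in (0, 1]")


def _category_counts(config: GeneratorConfig) -> dict:
    """Largest-remainder apportionment of crops to categories; at least
    one grain crop so TechR scenarios are well-defined."""
    shares = config.category_shares
    raw = {cat: config.n_crops * share for cat, share in shares.items()}
    counts = {cat: int(np.floor(v)) for cat, v in raw.items()}
    remaining = config.n_crops - sum(counts.values())
    for cat in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:remaining]:
        counts[cat] += 1
    if counts.get("grain", 0) == 0:
        donor = max(counts, key=counts.get)
        counts[donor] -= 1
        counts["grain"] = counts.get("grain", 0) + 1
    return {cat: cnt for cat, cnt in counts.items() if cnt > 0}


def _make_crops(config: GeneratorConfig) -> list:
    crops = []
    counts = _category_counts(config)
    for cat in sorted(counts):
        for i in range(counts[cat]):
            if cat == "grain" and i == 0:
                crops.append(Crop("rice", "Rice", "grain"))
            else:
                cid = f"{cat}_{i + 1}"
                crops.append(Crop(cid, cid.replace("_", " ").title(), cat))
    return crops


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Log-normal draw with the requested arithmetic mean."""
    if sigma == 0:
        return mean
    return float(rng.lognormal(np.log(mean) - sigma * sigma / 2.0, sigma))


def generate_instance(config: GeneratorConfig, seed: Optional[int] = None) -> ModelInputBundle:
    """Generate a complete, internally consistent model input bundle.

    Demand specs are calibrated to the generated observed baseline, the
    historical mixes fit inside district land endowments, and (by
    default) mechanized budgets are derived from a generated survey via
    the budget engine so the full scenario grid is runnable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    crops = _make_crops(config)
    cat_of = {c.id: c.category for c in crops}

    districts = []
    for i in range(config.n_districts):
        land = _lognormal(rng, config.mean_land_ha, config.land_sigma)
        districts.append(District(f"d{i + 1}", f"District {i + 1}", round(land, 2)))

    district_mult = {
        d.id: _lognormal(rng, 1.0, config.district_multiplier_sigma) for d in districts
    }

    budgets = []
    for d in districts:
        for c in crops:
            params = config.category_params[c.category]
            if c.category in HORTICULTURAL_CATEGORIES:
                pest_mean = config.grain_pesticide_mean * config.horticulture_pesticide_ratio
            else:
                pest_mean = config.grain_pesticide_mean
            shape = config.pesticide_gamma_shape
            pest = float(rng.gamma(shape, pest_mean / shape))
            budgets.append(
                CropBudget(
                    district=d.id,
                    crop=c.id,
                    tech="base",
                    yield_kg_per_ha=round(
                        _lognormal(rng, params["yield_mean"] * district_mult[d.id], config.yield_sigma), 2
                    ),
                    pesticide_kg_per_ha=round(pest, 4),
                    fertilizer_kg_per_ha=round(
                        _lognormal(rng, params["fert_mean"], config.cost_sigma), 2
                    ),
                    labor_pm_per_ha=round(
                        _lognormal(rng, params["labor_mean"], config.cost_sigma), 4
                    ),
                    machinery_cost_yuan_per_ha=round(
                        _lognormal(rng, config.machinery_cost_mean, config.cost_sigma), 2
                    ),
                    other_cost_yuan_per_ha=round(
                        _lognormal(rng, config.other_cost_mean, config.cost_sigma), 2
                    ),
                )
            )
    budget_by_key = {(b.district, b.crop): b for b in budgets}

    # observed base-year mix per district: Dirichlet shares over crops
    district_acreage = {}
    for d in districts:
        shares = rng.dirichlet(np.full(len(crops), 2.0))
        cropland = config.cropland_fraction * d.land_ha
        for c, s in zip(crops, shares):
            district_acreage[(d.id, c.id)] = round(float(s * cropland), 2)

    # historical mixes: noisy copies of the observed mix, rescaled to land
    mixes = []
    for d in districts:
        for h in range(config.n_mix_years):
            acreage = {}
            for c in crops:
                base = district_acreage[(d.id, c.id)]
                acreage[c.id] = base * _lognormal(rng, 1.0, config.mix_noise_sigma)
            total = sum(acreage.values())
            if total > d.land_ha:
                acreage = {k: v * d.land_ha / total for k, v in acreage.items()}
            if not any(v > 0 for v in acreage.values()):
                raise GenerationError(f"degenerate historical mix for {d.id}")
            mixes.append(
                HistoricalMix(d.id, f"y{h + 1}", {k: round(v, 2) for k, v in acreage.items()})
            )

    # observed production from acreage x budget yields; prices by category
    acreage_by_crop = {c.id: 0.0 for c in crops}
    production = {c.id: 0.0 for c in crops}
    for (did, cid), area in district_acreage.items():
        acreage_by_crop[cid] += area
        production[cid] += area * budget_by_key[(did, cid)].yield_kg_per_ha / 1000.0
    prices = {
        c.id: round(
            _lognormal(rng, config.category_params[c.category]["price_mean"], config.price_sigma), 3
        )
        for c in crops
    }
    observed = ObservedBaseline(
        acreage_ha={k: round(v, 2) for k, v in acreage_by_crop.items()},
        production_t={k: round(v, 2) for k, v in production.items()},
        price_yuan_per_kg=prices,
        district_acreage_ha=dict(district_acreage),
    )

    lo, hi = config.elasticity_range
    demand_specs = []
    for c in crops:
        e = round(float(rng.uniform(lo, hi)), 4)
        spec = DemandSpec(
            crop=c.id,
            p0_yuan_per_kg=prices[c.id],
            q0_t=observed.production_t[c.id],
            elasticity=e,
        )
        spec.intercept_a, spec.slope_b = demand_supply.calibrate_linear_inverse_demand(
            spec.p0_yuan_per_t, spec.q0_t, spec.elasticity
        )
        demand_specs.append(spec)

    settings = Settings(
        mix_delta=config.mix_delta,
        crop_mix_enabled=config.crop_mix_enabled,
        discount_rate=config.discount_rate,
        machine_lifespan_years=config.machine_lifespan_years,
        rice_crop_id="rice" if any(c.id == "rice" for c in crops) else crops[0].id,
    )

    if config.include_mechanized_budgets:
        import warnings

        survey = generate_survey(config, int(rng.integers(0, 2**31)))
        summary = budget_engine.summarize_survey(survey)
        with warnings.catch_warnings():
            # at small survey sizes sampling noise can flip effect signs
            warnings.simplefilter("ignore", UserWarning)
            effect = budget_engine.tech_effects(summary)
        budgets = budget_engine.build_tech_budgets(
            budgets, effect, scope="all_crops", rice_crop_id=settings.rice_crop_id
        )

    bundle = ModelInputBundle(
        crops=crops,
        districts=districts,
        budgets=budgets,
        input_prices=[
            InputPrice("pesticide", config.pesticide_price),
            InputPrice("fertilizer", config.fertilizer_price),
            InputPrice("labor", config.labor_price),
        ],
        demand_specs=demand_specs,
        historical_mixes=mixes,
        observed_baseline=observed,
        settings=settings,
    )
    issues = validate_bundle(bundle)
    if issues:
        raise GenerationError(f"generated bundle fails validation: {issues[:3]}")
    return bundle


def generate_survey(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Paired-subsample farm survey with injected technology effects.

    The mechanized arm's means differ from the non-mechanized arm's by
    the configured signed percentages (applied to yield, pesticide,
    labor, both machinery components, fertilizer and wage) plus
    independent multiplicative log-normal noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base_means = config.survey_base_means
    raw_purchase = base_means["machinery_purchase_cost_raw_yuan_per_ha"]
    effects = {
        "yield_kg_per_ha": config.yield_pct,
        "fertilizer_kg_per_ha": config.fertilizer_pct,
        "pesticide_kg_per_ha": config.pesticide_pct,
        "labor_wage_yuan_per_pm": config.wage_pct,
        "labor_pm_per_ha": config.labor_pct,
        "machinery_purchase_cost_raw_yuan_per_ha": config.machinery_pct,
        "machinery_rent_yuan_per_ha": config.machinery_pct,
    }
    records = []
    sigma = config.survey_noise_sigma
    for arm, n in (("base", config.n_base), ("mech", config.n_mechanized)):
        for _ in range(n):
            row = {
                "district": f"d{int(rng.integers(1, config.n_districts + 1))}",
                "mechanized": arm == "mech",
            }
            for var, mean in base_means.items():
                m = mean * (1.0 + effects[var] / 100.0) if arm == "mech" else mean
                row[var] = _lognormal(rng, m, sigma)
            row["machinery_purchase_cost_annualized_yuan_per_ha"] = (
                budget_engine.annualize_equivalent_cost(
                    row.pop("machinery_purchase_cost_raw_yuan_per_ha"),
                    config.machine_lifespan_years,
                    config.discount_rate,
                )
            )
            records.append(row)
    columns = ["district", "mechanized"] + list(budget_engine.SURVEY_VARIABLES)
    return pd.DataFrame.from_records(records)[columns]


# ---------------------------------------------------------------------------
# known-equilibrium instances
# ---------------------------------------------------------------------------


def _interior_solution(land, yields, costs, a, b):
    """Closed-form interior optimum: marginal net revenue per hectare is
    equalized across crops and equals the land shadow price.

    margin_m(q) = c_m * (a_m - b_m * c_m * q_m) - g_m ; solving
    margin_m(q_m) = mu with sum q_m = land gives a linear system.
    """
    yields = np.asarray(yields, dtype=float)
    costs = np.asarray(costs, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0) or np.any(yields <= 0):
        raise GenerationError("interior construction needs positive demand slopes and yields")
    k = b * yields * yields  # d(margin)/dq
    top = yields * a - costs  # margin at q = 0
    # q_m = (top_m - mu) / k_m ; sum q = land
    mu = (np.sum(top / k) - land) / np.sum(1.0 / k)
    q = (top - mu) / k
    if np.any(q <= 0):
        raise GenerationError("configuration yields a corner solution, not interior")
    if mu <= 0:
        raise GenerationError("land constraint not binding; interior construction failed")
    return q, float(mu)


def generate_known_equilibrium_instance(
    config: GeneratorConfig, seed: Optional[int] = None
):
    """Single-district instance with a closed-form interior optimum.

    Returns ``(bundle, expected)`` where ``expected`` is the exact
    welfare-maximizing solution (acreage, sales, prices, land rent,
    welfare components) against which the solver is checked.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.eq_n_crops
    if n < 2:
        raise GenerationError("known-equilibrium instance needs >= 2 crops")
    land = config.eq_land_ha

    explicit = config.eq_yields_t_per_ha is not None
    for _ in range(200):
        yields = (
            np.asarray(config.eq_yields_t_per_ha, dtype=float)
            if explicit
            else rng.uniform(4.0, 12.0, n)
        )
        costs = (
            np.asarray(config.eq_costs_yuan_per_ha, dtype=float)
            if config.eq_costs_yuan_per_ha is not None
            else rng.uniform(300.0, 1500.0, n)
        )
        a = (
            np.asarray(config.eq_demand_a, dtype=float)
            if config.eq_demand_a is not None
            else rng.uniform(1500.0, 3500.0, n)
        )
        b = (
            np.asarray(config.eq_demand_b, dtype=float)
            if config.eq_demand_b is not None
            else rng.uniform(0.5, 3.0, n)
        )
        try:
            q, mu = _interior_solution(land, yields, costs, a, b)
            break
        except GenerationError:
            if explicit:
                raise
    else:
        raise GenerationError("could not draw an interior instance in 200 attempts")

    pest = (
        np.asarray(config.eq_pesticide_kg_per_ha, dtype=float)
        if config.eq_pesticide_kg_per_ha is not None
        else np.zeros(n)
    )

    crop_ids = [chr(ord("A") + i) for i in range(n)]
    crops = [Crop(cid, f"Crop {cid}", "grain" if i == 0 else "other_vegetable")
             for i, cid in enumerate(crop_ids)]
    district = District("d1", "District 1", float(land))
    budgets = [
        CropBudget(
            district="d1",
            crop=cid,
            tech="base",
            yield_kg_per_ha=float(yields[i] * 1000.0),
            pesticide_kg_per_ha=float(pest[i]),
            fertilizer_kg_per_ha=0.0,
            labor_pm_per_ha=0.0,
            machinery_cost_yuan_per_ha=0.0,
            other_cost_yuan_per_ha=float(costs[i]),
        )
        for i, cid in enumerate(crop_ids)
    ]
    # demand spec reproducing (a, b) exactly: q0 = a/(2b), p0 = a/2, e = -1
    demand_specs = []
    for i, cid in enumerate(crop_ids):
        q0 = a[i] / (2.0 * b[i])
        p0_t = a[i] / 2.0
        spec = DemandSpec(
            crop=cid, p0_yuan_per_kg=p0_t / 1000.0, q0_t=float(q0), elasticity=-1.0
        )
        spec.intercept_a, spec.slope_b = demand_supply.calibrate_linear_inverse_demand(
            p0_t, q0, -1.0
        )
        demand_specs.append(spec)

    y = yields * q
    observed = ObservedBaseline(
        acreage_ha={cid: float(q[i]) for i, cid in enumerate(crop_ids)},
        production_t={cid: float(y[i]) for i, cid in enumerate(crop_ids)},
        price_yuan_per_kg={
            cid: (a[i] - b[i] * y[i]) / 1000.0 for i, cid in enumerate(crop_ids)
        },
        district_acreage_ha={("d1", cid): float(q[i]) for i, cid in enumerate(crop_ids)},
    )
    bundle = ModelInputBundle(
        crops=crops,
        districts=[district],
        budgets=budgets,
        input_prices=[
            InputPrice("pesticide", 0.0),
            InputPrice("fertilizer", 0.0),
            InputPrice("labor", 0.0),
        ],
        demand_specs=demand_specs,
        historical_mixes=[],
        observed_baseline=observed,
        settings=Settings(crop_mix_enabled=False, rice_crop_id=crop_ids[0]),
    )

    gross = float(np.sum(a * y - b * y * y / 2.0))
    activity = float(np.sum(costs * q))
    consumer = float(np.sum(b * y * y / 2.0))
    from .sector_model import SolutionBundle  # late import avoids a cycle

    expected = SolutionBundle(
        status="optimal",
        acreage_ha={("d1", cid, "base"): float(q[i]) for i, cid in enumerate(crop_ids)},
        production_t={cid: float(y[i]) for i, cid in enumerate(crop_ids)},
        sales_t={cid: float(y[i]) for i, cid in enumerate(crop_ids)},
        prices_yuan_per_kg={
            cid: float((a[i] - b[i] * y[i]) / 1000.0) for i, cid in enumerate(crop_ids)
        },
        pesticide_use_t={"d1": float(np.sum(pest * q) / 1000.0)},
        welfare={
            "gross_consumer_benefit": gross,
            "input_cost": 0.0,
            "activity_cost": activity,
            "total": gross - activity,
            "consumer_surplus": consumer,
            "producer_surplus": gross - activity - consumer,
        },
        land_rent_yuan_per_ha={"d1": mu},
        objective_value=gross - activity,
    )
    return bundle, expected


def scaled_instance(config: GeneratorConfig, factor: float) -> GeneratorConfig:
    """Config for the same known-equilibrium instance with all monetary
    values scaled by ``factor`` (acreage invariant, duals scale)."""
    if config.eq_costs_yuan_per_ha is None or config.eq_demand_a is None:
        raise GenerationError("scaled_instance needs explicit monetary parameters")
    return replace(
        config,
        eq_costs_yuan_per_ha=[c * factor for c in config.eq_costs_yuan_per_ha],
        eq_demand_a=[a * factor for a in config.eq_demand_a],
        eq_demand_b=[b * factor for b in (config.eq_demand_b or [])] or None,
    )
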