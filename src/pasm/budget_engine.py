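"""Survey-to-budget pipeline.

Turns a farm-survey table (paired mechanized / non-mechanized
subsamples) into technology-specific crop budgets:

1. annualize machinery purchase costs (equivalent annual cost),
2. summarize the two subsamples (arithmetic means per variable),
3. express the mechanized-vs-base differences as signed percentages,
4. apply those percentages to base budgets to create ``mechanized``
   budget rows, either for the designated rice crop only or for all
   crops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .domain_data import CropBudget

#: survey variables summarized per subsample
SURVEY_VARIABLES = (
    "yield_kg_per_ha",
    "fertilizer_kg_per_ha",
    "pesticide_kg_per_ha",
    "labor_wage_yuan_per_pm",
    "labor_pm_per_ha",
    "machinery_purchase_cost_annualized_yuan_per_ha",
    "machinery_rent_yuan_per_ha",
)

TECH_SCOPES = ("rice_only", "all_crops")


def annualize_equivalent_cost(
    purchase_cost: float, lifespan_years: float, discount_rate: float
) -> float:
    """Equivalent annual cost: the constant yearly payment over
    ``lifespan_years`` whose present value at ``discount_rate`` equals
    ``purchase_cost``.

    ``C * r / (1 - (1+r)^-L)`` for ``r > 0``; ``C / L`` at ``r = 0``.
    """
    if purchase_cost < 0:
        raise ValueError("purchase_cost must be non-negative")
    if lifespan_years < 1:
        raise ValueError("lifespan_years must be >= 1")
    if discount_rate < 0:
        raise ValueError("discount_rate must be non-negative")
    if discount_rate == 0:
        return purchase_cost / lifespan_years
    r = discount_rate
    annuity_factor = (1.0 - (1.0 + r) ** (-lifespan_years)) / r
    return purchase_cost / annuity_factor


@dataclass
class PairedBudgetSummary:
    """Per-variable means over the full sample and the two subsamples."""

    mean_all: dict  # variable -> mean over all records
    mean_base: dict  # variable -> mean over non-mechanized records
    mean_mech: dict  # variable -> mean over mechanized records
    n_total: int
    n_base: int
    n_mech: int

    def machinery_cost_total(self, column: str) -> float:
        """Annualized purchase mean + rent mean for one column
        (``all`` | ``base`` | ``mech``)."""
        means = {"all": self.mean_all, "base": self.mean_base, "mech": self.mean_mech}[column]
        return (
            means["machinery_purchase_cost_annualized_yuan_per_ha"]
            + means["machinery_rent_yuan_per_ha"]
        )


@dataclass
class TechEffect:
    """Signed percentage differences, mechanized vs non-mechanized."""

    yield_pct: float
    pesticide_pct: float
    labor_pct: float
    machinery_cost_pct: float


def summarize_survey(survey: pd.DataFrame) -> PairedBudgetSummary:
    """Arithmetic means per variable for the full sample and both
    application-method subsamples."""
    if len(survey) == 0:
        raise ValueError("survey is empty")
    for col in SURVEY_VARIABLES + ("mechanized",):
        if col not in survey.columns:
            raise ValueError(f"survey missing column {col!r}")
    mech_mask = survey["mechanized"].astype(bool)
    base = survey[~mech_mask]
    mech = survey[mech_mask]
    if len(base) == 0:
        raise ValueError("non-mechanized subsample is empty")
    if len(mech) == 0:
        raise ValueError("mechanized subsample is empty")
    return PairedBudgetSummary(
        mean_all={v: float(survey[v].mean()) for v in SURVEY_VARIABLES},
        mean_base={v: float(base[v].mean()) for v in SURVEY_VARIABLES},
        mean_mech={v: float(mech[v].mean()) for v in SURVEY_VARIABLES},
        n_total=len(survey),
        n_base=len(base),
        n_mech=len(mech),
    )


def tech_effects(summary: PairedBudgetSummary) -> TechEffect:
    """Percentage differences of subsample means, base = non-mechanized.

    The machinery effect is computed on the total machinery cost column
    (annualized purchase + rent).
    """

    def pct(mech_mean: float, base_mean: float, name: str) -> float:
        if base_mean == 0:
            raise ValueError(f"zero non-mechanized mean for {name}")
        return (mech_mean - base_mean) / base_mean * 100.0

    effect = TechEffect(
        yield_pct=pct(
            summary.mean_mech["yield_kg_per_ha"], summary.mean_base["yield_kg_per_ha"], "yield"
        ),
        pesticide_pct=pct(
            summary.mean_mech["pesticide_kg_per_ha"],
            summary.mean_base["pesticide_kg_per_ha"],
            "pesticide",
        ),
        labor_pct=pct(
            summary.mean_mech["labor_pm_per_ha"], summary.mean_base["labor_pm_per_ha"], "labor"
        ),
        machinery_cost_pct=pct(
            summary.machinery_cost_total("mech"),
            summary.machinery_cost_total("base"),
            "machinery cost",
        ),
    )
    if effect.yield_pct < 0 or effect.machinery_cost_pct < 0:
        warnings.warn(
            "unexpected sign: mechanization usually raises yield and machinery cost",
            stacklevel=2,
        )
    if effect.pesticide_pct > 0 or effect.labor_pct > 0:
        warnings.warn(
            "unexpected sign: mechanization usually lowers pesticide and labor use",
            stacklevel=2,
        )
    return effect


def build_tech_budgets(
    base_budgets: list,
    effect: TechEffect,
    scope: str,
    rice_crop_id: str = "rice",
) -> list:
    """Return base budgets plus ``mechanized`` variants for in-scope crops.

    Mechanized yield, pesticide, labor and machinery cost are the base
    values scaled by the respective percentage effects; fertilizer and
    other costs are copied.  Base rows are never mutated.
    """
    if scope not in TECH_SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {TECH_SCOPES}")
    bases = [b for b in base_budgets if b.tech == "base"]
    if scope == "rice_only":
        in_scope = [b for b in bases if b.crop == rice_crop_id]
        if not in_scope:
            raise ValueError(f"scope 'rice_only' but no budget for crop {rice_crop_id!r}")
    else:
        in_scope = bases

    out = list(base_budgets)
    for b in in_scope:
        out.append(
            CropBudget(
                district=b.district,
                crop=b.crop,
                tech="mechanized",
                yield_kg_per_ha=b.yield_kg_per_ha * (1.0 + effect.yield_pct / 100.0),
                pesticide_kg_per_ha=b.pesticide_kg_per_ha * (1.0 + effect.pesticide_pct / 100.0),
                fertilizer_kg_per_ha=b.fertilizer_kg_per_ha,
                labor_pm_per_ha=b.labor_pm_per_ha * (1.0 + effect.labor_pct / 100.0),
                machinery_cost_yuan_per_ha=b.machinery_cost_yuan_per_ha
                * (1.0 + effect.machinery_cost_pct / 100.0),
                other_cost_yuan_per_ha=b.other_cost_yuan_per_ha,
            )
        )
    return out
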