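"""Bundled Shanghai reference data.

Small published statistics used as fixed inputs: citywide pesticide-use
and planted-area totals, the citywide rice budget survey summary
(paired application-method subsamples), and the baseline validation
tables (observed vs model-baseline acreage, production and price for
the 15 crops under both market closures).
"""

from __future__ import annotations

import pandas as pd

from .budget_engine import PairedBudgetSummary
from .domain_data import ObservedBaseline

#: citywide pesticide use totals, t
PESTICIDE_USE_T = {"2015": 4415.0, "2019": 2771.0}

#: citywide planted area, ha
PLANTED_AREA_HA = {"2015": 351700.0, "2018": 285300.0}

#: citywide rice budget survey: means per column (full sample,
#: non-mechanized subsample, mechanized subsample)
RICE_SURVEY_COUNTS = {"all": 532, "base": 251, "mech": 281}

RICE_SURVEY_MEANS = {
    "yield_kg_per_ha": {"all": 8064.94, "base": 7943.18, "mech": 8085.23},
    "fertilizer_kg_per_ha": {"all": 997.40, "base": 1009.09, "mech": 995.45},
    "pesticide_kg_per_ha": {"all": 18.00, "base": 18.75, "mech": 17.87},
    "labor_wage_yuan_per_pm": {"all": 1915.58, "base": 1863.64, "mech": 1924.24},
    "labor_pm_per_ha": {"all": 13.58, "base": 14.83, "mech": 13.37},
    "machinery_purchase_cost_annualized_yuan_per_ha": {
        "all": 2200.30,
        "base": 1794.70,
        "mech": 2267.90,
    },
    "machinery_rent_yuan_per_ha": {"all": 2288.96, "base": 2147.73, "mech": 2312.50},
}


def rice_survey_summary() -> PairedBudgetSummary:
    """The published rice budget as a paired-subsample summary."""
    return PairedBudgetSummary(
        mean_all={k: v["all"] for k, v in RICE_SURVEY_MEANS.items()},
        mean_base={k: v["base"] for k, v in RICE_SURVEY_MEANS.items()},
        mean_mech={k: v["mech"] for k, v in RICE_SURVEY_MEANS.items()},
        n_total=RICE_SURVEY_COUNTS["all"],
        n_base=RICE_SURVEY_COUNTS["base"],
        n_mech=RICE_SURVEY_COUNTS["mech"],
    )


def rice_survey_fixture() -> pd.DataFrame:
    """A 532-record survey whose subsample means equal the published
    subsample means exactly (each arm is constant at its mean)."""
    rows = []
    for arm, n in (("base", RICE_SURVEY_COUNTS["base"]), ("mech", RICE_SURVEY_COUNTS["mech"])):
        for i in range(n):
            row = {"district": f"d{i % 9 + 1}", "mechanized": arm == "mech"}
            for var, means in RICE_SURVEY_MEANS.items():
                row[var] = means[arm]
            rows.append(row)
    return pd.DataFrame.from_records(rows)


# columns: crop, observed acreage (ha), model acreage, observed
# production (t), model production, observed price (yuan/kg), model price
_VALIDATION_P_FIXED = [
    ("Rice", 85656, 87414, 841000, 753873, 4.35, 4.350),
    ("Wheat", 38397, 35598, 199200, 164737, 2.76, 2.760),
    ("Barley", 7183, 8009, 45200, 36160, 2.55, 2.717),
    ("Melon", 6937, 7545, 264500, 226542, 5.52, 5.520),
    ("Rapeseed", 3873, 3944, 9600, 8701, 3.04, 3.038),
    ("Strawberry", 1276, 1143, 22100, 19774, 15.00, 14.997),
    ("Fruit", 20067, 21161, 326900, 337969, 9.28, 9.276),
    ("Leafy", 52125, 50911, 1404000, 1339755, 2.50, 2.501),
    ("Pekinensis", 3361, 3118, 163500, 146749, 1.41, 1.410),
    ("Cabbage", 11154, 12998, 550500, 484307, 1.43, 1.430),
    ("Root", 5587, 5265, 190700, 174143, 1.63, 1.630),
    ("Cucurbit", 5977, 5669, 244900, 224788, 4.16, 4.161),
    ("Beans", 10406, 9485, 226700, 210744, 6.12, 6.118),
    ("Solanaceae", 7912, 7260, 300900, 268735, 5.01, 5.010),
    ("Allium", 1964, 2354, 76500, 70363, 2.66, 2.660),
]

_VALIDATION_P_FREE = [
    ("Rice", 85656, 83627, 841000, 719832, 4.35, 4.304),
    ("Wheat", 38397, 35158, 199200, 163344, 2.76, 3.225),
    ("Barley", 7183, 8209, 45200, 37064, 2.55, 2.834),
    ("Melon", 6937, 7264, 264500, 216890, 5.52, 5.444),
    ("Rapeseed", 3873, 4322, 9600, 9381, 3.04, 3.093),
    ("Strawberry", 1276, 1250, 22100, 21437, 15.00, 15.001),
    ("Fruit", 20067, 20198, 326900, 317093, 9.28, 8.977),
    ("Leafy", 52125, 52764, 1404000, 1361880, 2.50, 2.476),
    ("Pekinensis", 3361, 3283, 163500, 158595, 1.41, 1.461),
    ("Cabbage", 11154, 14255, 550500, 533985, 1.43, 1.493),
    ("Root", 5587, 5494, 190700, 184979, 1.63, 1.695),
    ("Cucurbit", 5977, 5959, 244900, 237553, 4.16, 4.192),
    ("Beans", 10406, 9552, 226700, 219899, 6.12, 6.168),
    ("Solanaceae", 7912, 8043, 300900, 291873, 5.01, 5.011),
    ("Allium", 1964, 2498, 76500, 74205, 2.66, 2.590),
]


def _split(table):
    observed = ObservedBaseline(
        acreage_ha={r[0]: float(r[1]) for r in table},
        production_t={r[0]: float(r[3]) for r in table},
        price_yuan_per_kg={r[0]: float(r[5]) for r in table},
    )
    modeled = {
        "acreage_ha": {r[0]: float(r[2]) for r in table},
        "production_t": {r[0]: float(r[4]) for r in table},
        "price_yuan_per_kg": {r[0]: float(r[6]) for r in table},
    }
    return observed, modeled


def validation_data(economy: str):
    """(observed, modeled) columns of the baseline validation table for
    ``P_fixed`` or ``P_free``."""
    if economy == "P_fixed":
        return _split(_VALIDATION_P_FIXED)
    if economy == "P_free":
        return _split(_VALIDATION_P_FREE)
    raise ValueError(f"unknown economy {economy!r}")
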