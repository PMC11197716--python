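"""Policy-grid enumeration, batch runs and baseline comparisons."""

from __future__ import annotations

import logging
import time
from typing import Optional

import numpy as np

from . import sector_model
from .domain_data import ModelInputBundle, ResultsTable
from .sector_model import (
    IMPOSITIONS,
    REDUCTION_LEVELS,
    ScenarioSpec,
    TECH_REGIMES,
)

logger = logging.getLogger(__name__)

#: metrics excluded from percent-change reporting (flags and duals)
NON_LEVEL_METRICS = {
    "status",
    "baseline_pesticide_t",
    "pesticide_cap_t",
    "pesticide_shadow_yuan_per_kg",
    "land_rent_yuan_per_ha",
}


def enumerate_scenarios(
    levels=REDUCTION_LEVELS,
    techs=TECH_REGIMES,
    impositions=IMPOSITIONS,
    economies=("P_fixed", "P_free"),
) -> list:
    """Full cross product of the policy dimensions, with the imposition
    dimension collapsed at zero reduction, deduplicated and ordered."""
    for name, values, allowed in (
        ("levels", levels, REDUCTION_LEVELS),
        ("techs", techs, TECH_REGIMES),
        ("impositions", impositions, IMPOSITIONS),
        ("economies", economies, ("P_fixed", "P_free")),
    ):
        if not values:
            raise ValueError(f"dimension {name!r} is empty")
        for v in values:
            if v not in allowed:
                raise ValueError(f"unknown value {v!r} for dimension {name!r}")
    seen = {}
    for r in levels:
        for tech in techs:
            for imposition in impositions:
                for economy in economies:
                    spec = ScenarioSpec(r, tech, imposition, economy)
                    seen[spec.scenario_id] = spec
    order = {t: i for i, t in enumerate(TECH_REGIMES)}
    imp_order = {t: i for i, t in enumerate(IMPOSITIONS)}
    eco_order = {"P_fixed": 0, "P_free": 1}
    return sorted(
        seen.values(),
        key=lambda s: (s.level_index, order[s.tech], imp_order[s.imposition], eco_order[s.economy]),
    )


def run_grid(bundle: ModelInputBundle, specs: list) -> ResultsTable:
    """Solve every scenario and emit a long-format metrics table.

    Solver failures are recorded as ``status`` rows with value 0, never
    silently dropped.
    """
    baseline = sector_model.baseline_pesticide_usage(bundle)
    records = []

    def emit(spec, metric, entity, value):
        records.append(
            {
                "scenario_id": spec.scenario_id,
                "reduction_level": spec.reduction_level,
                "tech": spec.tech,
                "imposition": spec.imposition,
                "economy": spec.economy,
                "metric": metric,
                "entity": entity,
                "value": float(value),
            }
        )

    for spec in specs:
        t0 = time.monotonic()
        try:
            problem = sector_model.assemble_problem(bundle, spec, baseline=baseline)
            sol = sector_model.solve_problem(problem)
        except Exception as exc:  # recorded, not raised
            logger.warning("scenario %s failed: %s", spec.scenario_id, exc)
            emit(spec, "status", "region", 0.0)
            continue
        logger.info(
            "scenario %s: %s in %.3fs",
            spec.scenario_id,
            sol.status,
            time.monotonic() - t0,
        )
        emit(spec, "status", "region", 1.0 if sol.status == "optimal" else 0.0)
        if sol.status != "optimal":
            continue

        for comp, v in sol.welfare.items():
            emit(spec, f"welfare_{comp}", "region", v)
        for cid in bundle.crop_ids():
            emit(spec, "production_t", cid, sol.production_t.get(cid, 0.0))
            emit(spec, "sales_t", cid, sol.sales_t.get(cid, 0.0))
            emit(spec, "price_yuan_per_kg", cid, sol.prices_yuan_per_kg.get(cid, 0.0))
        district_acreage = sol.district_acreage_ha()
        for d in bundle.districts:
            acreage = district_acreage.get(d.id, 0.0)
            use = sol.pesticide_use_t.get(d.id, 0.0)
            emit(spec, "acreage_ha", d.id, acreage)
            emit(spec, "pesticide_use_t", d.id, use)
            emit(
                spec,
                "pesticide_intensity_kg_per_ha",
                d.id,
                use * 1000.0 / acreage if acreage > 0 else 0.0,
            )
            emit(spec, "land_rent_yuan_per_ha", d.id, sol.land_rent_yuan_per_ha.get(d.id, 0.0))
            emit(spec, "baseline_pesticide_t", d.id, baseline.pesticide_t.get(d.id, 0.0))
        total_acreage = sum(district_acreage.values())
        total_use = sol.region_pesticide_t()
        emit(spec, "acreage_ha", "region", total_acreage)
        emit(spec, "pesticide_use_t", "region", total_use)
        emit(
            spec,
            "pesticide_intensity_kg_per_ha",
            "region",
            total_use * 1000.0 / total_acreage if total_acreage > 0 else 0.0,
        )
        emit(spec, "baseline_pesticide_t", "region", baseline.region_total_t)
        for scope, v in sol.pesticide_shadow_yuan_per_kg.items():
            emit(spec, "pesticide_shadow_yuan_per_kg", scope, v)
    return ResultsTable.from_records(records)


def percent_change_vs_baseline(
    results: ResultsTable, metrics: Optional[set] = None
) -> ResultsTable:
    """Percentage changes of level metrics against the matching zero-
    reduction scenario (same tech, same economy).

    A zero base with a zero value maps to 0; a zero base with a nonzero
    value is flagged undefined (NaN).
    """
    frame = results.frame
    baselines = {}
    for (tech, economy), _grp in frame.groupby(["tech", "economy"]):
        base_id = f"R0_{tech}_region_{economy}"
        base_rows = frame[frame["scenario_id"] == base_id]
        if len(base_rows) == 0:
            raise ValueError(f"missing baseline scenario {base_id}")
        baselines[(tech, economy)] = {
            (r.metric, r.entity): r.value for r in base_rows.itertuples()
        }

    records = []
    for row in frame.itertuples():
        if row.reduction_level == 0:
            continue
        if row.metric in NON_LEVEL_METRICS or row.metric.endswith("_pct_change"):
            continue
        if metrics is not None and row.metric not in metrics:
            continue
        base = baselines[(row.tech, row.economy)].get((row.metric, row.entity))
        if base is None:
            continue
        if base == 0:
            change = 0.0 if row.value == 0 else float("nan")
        else:
            change = (row.value - base) / base * 100.0
        records.append(
            {
                "scenario_id": row.scenario_id,
                "reduction_level": row.reduction_level,
                "tech": row.tech,
                "imposition": row.imposition,
                "economy": row.economy,
                "metric": f"{row.metric}_pct_change",
                "entity": row.entity,
                "value": change,
            }
        )
    return ResultsTable.from_records(records)
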