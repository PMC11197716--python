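"""Summary metrics: reduction percentages, Laspeyres/Paasche/Fisher
indexes, validation-ratio tables, pesticide intensity and district
deviations from prescribed reduction targets.

Full precision is kept internally; rounding (half-up) happens only at
the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .domain_data import ObservedBaseline
from .sector_model import BaselineUsage, SolutionBundle

VALIDATION_METRICS = ("acreage", "production", "price")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (3.5 -> 4, -3.5 -> -4)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def reduction_percent(v_start: float, v_end: float) -> float:
    """Signed percent decrease from ``v_start`` to ``v_end``, reported
    to 2 decimals."""
    if v_start <= 0:
        raise ValueError("v_start must be positive")
    return round_half_up((v_start - v_end) / v_start * 100.0, 2)


@dataclass
class PriceIndexResult:
    laspeyres: float
    paasche: float
    fisher: float
    variant: str  # "price" | "quantity"


def price_index(p0, q0, p1, q1, variant: str = "price") -> PriceIndexResult:
    """Laspeyres, Paasche and Fisher index numbers (base period = 100).

    ``variant="price"``: L = sum(p1*q0)/sum(p0*q0), P = sum(p1*q1)/sum(p0*q1).
    ``variant="quantity"`` swaps the roles of prices and quantities.
    """
    p0 = np.asarray(p0, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    if not (len(p0) == len(q0) == len(p1) == len(q1)):
        raise ValueError("index vectors must be aligned on the same crop set")
    if variant == "quantity":
        p0, q0 = q0, p0
        p1, q1 = q1, p1
    elif variant != "price":
        raise ValueError(f"unknown variant {variant!r}")
    base_expenditure = float(p0 @ q0)
    if base_expenditure <= 0:
        raise ValueError("zero base expenditure")
    denom_paasche = float(p0 @ q1)
    if denom_paasche <= 0:
        raise ValueError("zero current-weighted base expenditure")
    laspeyres = float(p1 @ q0) / base_expenditure * 100.0
    paasche = float(p1 @ q1) / denom_paasche * 100.0
    return PriceIndexResult(
        laspeyres=laspeyres,
        paasche=paasche,
        fisher=math.sqrt(laspeyres * paasche),
        variant=variant,
    )


@dataclass
class ValidationTable:
    """Per-crop modeled/observed ratios with summary means."""

    frame: pd.DataFrame  # crop, metric, observed, modeled, ratio
    arithmetic_means: dict  # metric -> mean of ratios over crops
    weighted_means: dict  # metric -> revenue-weighted mean of ratios

    def rounded_means(self, decimals: int = 3) -> dict:
        return {
            "arithmetic": {
                k: round_half_up(v, decimals) for k, v in self.arithmetic_means.items()
            },
            "weighted": {
                k: round_half_up(v, decimals) for k, v in self.weighted_means.items()
            },
        }


def _modeled_as_dicts(modeled) -> dict:
    if isinstance(modeled, SolutionBundle):
        acreage: dict = {}
        for (_d, crop, _t), q in modeled.acreage_ha.items():
            acreage[crop] = acreage.get(crop, 0.0) + q
        return {
            "acreage": acreage,
            "production": dict(modeled.production_t),
            "price": dict(modeled.prices_yuan_per_kg),
        }
    return {
        "acreage": modeled["acreage_ha"],
        "production": modeled["production_t"],
        "price": modeled["price_yuan_per_kg"],
    }


def validation_table(observed: ObservedBaseline, modeled) -> ValidationTable:
    """Ratios (modeled/observed) per crop for acreage, production and
    price, with arithmetic and revenue-weighted summary means.

    Revenue weights are observed production times observed price.
    ``modeled`` is a baseline :class:`SolutionBundle` or a mapping with
    ``acreage_ha`` / ``production_t`` / ``price_yuan_per_kg`` dicts.
    """
    model = _modeled_as_dicts(modeled)
    observed_by_metric = {
        "acreage": observed.acreage_ha,
        "production": observed.production_t,
        "price": observed.price_yuan_per_kg,
    }
    crops = sorted(observed.acreage_ha)
    rows = []
    for metric in VALIDATION_METRICS:
        for crop in crops:
            if crop not in model[metric]:
                raise ValueError(f"modeled {metric} missing crop {crop!r}")
            obs_v = observed_by_metric[metric][crop]
            mod_v = model[metric][crop]
            rows.append((crop, metric, obs_v, mod_v, mod_v / obs_v))
    frame = pd.DataFrame(rows, columns=["crop", "metric", "observed", "modeled", "ratio"])

    revenue = np.array(
        [observed.production_t[c] * observed.price_yuan_per_kg[c] for c in crops]
    )
    arithmetic = {}
    weighted = {}
    for metric in VALIDATION_METRICS:
        ratios = frame[frame["metric"] == metric].set_index("crop").loc[crops, "ratio"].to_numpy()
        arithmetic[metric] = float(np.mean(ratios))
        weighted[metric] = float(np.sum(ratios * revenue) / np.sum(revenue))
    return ValidationTable(frame=frame, arithmetic_means=arithmetic, weighted_means=weighted)


def pesticide_intensity(pesticide_t: dict, area_ha: dict) -> dict:
    """Intensity (kg/ha) per district plus the region value.

    The region intensity is total use over total area, not the mean of
    district intensities.
    """
    out = {}
    for district, use in pesticide_t.items():
        area = area_ha.get(district, 0.0)
        if area <= 0:
            if use > 0:
                raise ValueError(f"positive use with zero area in {district!r}")
            out[district] = 0.0
        else:
            out[district] = use * 1000.0 / area
    total_area = sum(area_ha.get(d, 0.0) for d in pesticide_t)
    total_use = sum(pesticide_t.values())
    if total_area <= 0:
        if total_use > 0:
            raise ValueError("positive regional use with zero area")
        out["region"] = 0.0
    else:
        out["region"] = total_use * 1000.0 / total_area
    return out


def district_target_deviation(use_t: dict, baseline: BaselineUsage, r: float) -> dict:
    """Signed percent deviation of district use from the prescribed
    district target ``(1 - r) * B_n``.

    Negative values mean deeper-than-prescribed reductions; positive
    values (possible only under region-level imposition) mean the
    district exceeds its notional target.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie in (0, 1)")
    out = {}
    for district, use in use_t.items():
        b = baseline.pesticide_t.get(district, 0.0)
        if b <= 0:
            raise ValueError(f"non-positive baseline usage for district {district!r}")
        target = (1.0 - r) * b
        out[district] = (use - target) / target * 100.0
    return out
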