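"""Linear inverse-demand calibration, evaluation and market closures.

Each commodity's demand side is a straight line ``p = a - b*y`` (yuan/t
against t) calibrated so that it passes through the observed point
``(q0, p0)`` with the stated own-price point elasticity.  Input supply
is perfectly elastic at the bundle's input prices, so the input-side
surplus integral reduces to a linear cost term handled in the sector
model.

Market closures:

* ``P_free`` — closed regional economy; prices move along the
  calibrated lines.
* ``P_fixed`` — price taker; demand perfectly elastic at the observed
  price (``b = 0``, ``a = p0``).
"""

from __future__ import annotations

import copy

from .domain_data import DemandSpec

ECONOMIES = ("P_fixed", "P_free")


def calibrate_linear_inverse_demand(
    p0_yuan_per_t: float, q0_t: float, elasticity: float
) -> tuple:
    """Return ``(intercept_a, slope_b)`` of ``p = a - b*y`` through
    ``(q0, p0)`` with the given (negative) own-price elasticity.

    The point elasticity of the line at the calibration point is
    ``-(1/b) * (p0/q0)``, so ``b = p0 / (|e| * q0)`` and
    ``a = p0 * (1 + 1/|e|)``.
    """
    if p0_yuan_per_t <= 0:
        raise ValueError("p0 must be positive")
    if q0_t <= 0:
        raise ValueError("q0 must be positive")
    if elasticity >= 0:
        raise ValueError("own-price elasticity must be negative")
    abs_e = abs(elasticity)
    slope_b = p0_yuan_per_t / (abs_e * q0_t)
    intercept_a = p0_yuan_per_t * (1.0 + 1.0 / abs_e)
    return intercept_a, slope_b


def point_elasticity(spec: DemandSpec) -> float:
    """Recompute the own-price elasticity implied by (a, b, p0, q0)."""
    if spec.slope_b is None or spec.slope_b == 0:
        return float("-inf")
    return -(1.0 / spec.slope_b) * (spec.p0_yuan_per_t / spec.q0_t)


def price_at_quantity(spec: DemandSpec, y_t: float) -> float:
    """Inverse-demand price (yuan/t) at quantity ``y_t``, floored at 0."""
    if y_t < 0:
        raise ValueError("quantity must be non-negative")
    a = spec.intercept_a if spec.intercept_a is not None else spec.p0_yuan_per_t
    b = spec.slope_b if spec.slope_b is not None else 0.0
    return max(a - b * y_t, 0.0)


def choke_quantity(spec: DemandSpec) -> float:
    """Quantity at which the calibrated price hits zero (inf if b = 0)."""
    b = spec.slope_b if spec.slope_b is not None else 0.0
    if b == 0:
        return float("inf")
    a = spec.intercept_a if spec.intercept_a is not None else spec.p0_yuan_per_t
    return a / b


def gross_consumer_benefit(spec: DemandSpec, y_t: float) -> float:
    """Area under the inverse-demand line from 0 to ``y_t`` (yuan)."""
    if y_t < 0:
        raise ValueError("quantity must be non-negative")
    a = spec.intercept_a if spec.intercept_a is not None else spec.p0_yuan_per_t
    b = spec.slope_b if spec.slope_b is not None else 0.0
    if b > 0 and y_t > a / b * (1 + 1e-12):
        raise ValueError(
            f"quantity {y_t} beyond choke quantity {a / b} for crop {spec.crop}"
        )
    return a * y_t - b * y_t * y_t / 2.0


def apply_closure(specs: list, economy: str) -> list:
    """Apply a market closure to a list of demand specs.

    ``P_free`` returns the specs unchanged; ``P_fixed`` returns copies
    with perfectly elastic demand at the observed price.
    """
    if economy not in ECONOMIES:
        raise ValueError(f"unknown economy {economy!r}; expected one of {ECONOMIES}")
    if economy == "P_free":
        return specs
    fixed = []
    for spec in specs:
        s = copy.copy(spec)
        s.intercept_a = spec.p0_yuan_per_t
        s.slope_b = 0.0
        fixed.append(s)
    return fixed
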