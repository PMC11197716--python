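"""Welfare-maximizing sector model with pesticide caps.

The model allocates acreage ``Q`` across (district, crop, technology)
production processes to maximize the sum of consumer and producer
surpluses:

    max  sum_m [a_m*Y_m - b_m*Y_m^2/2] - sum_i w_i*X_i - sum_j g_j*Q_j

subject to

* commodity balance:   Y_m <= sum_j c_mj * Q_j          (yield, t/ha)
* input linkage:       X_i >= sum_j a_ij * Q_j          (kg or pm /ha)
* land per district:   sum_{j in n} Q_j <= land_n
* crop-mix convexity:  per-district acreage inside a flexible cone of
  historical mix vectors (optional, flexibility multiplier delta)
* pesticide cap(s):    district-level or region-level quantity caps at
  (1 - r) times the base-year usage
* non-negativity of all decision variables.

Price-taker instances (all demand slopes zero) are pure LPs solved with
HiGHS via :func:`scipy.optimize.linprog`; price-endogenous instances are
concave QPs solved with ``trust-constr`` followed by an active-set KKT
polish.  Dual values (land rents, pesticide shadow prices) are recovered
from the KKT stationarity system by non-negative least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from . import demand_supply
from .domain_data import INPUT_IDS, ModelInputBundle

REDUCTION_LEVELS = (0.0, 0.10, 0.15, 0.20, 0.25, 0.30)
TECH_REGIMES = ("TechB", "TechR", "TechA")
IMPOSITIONS = ("district", "region")

_LEVEL_INDEX = {0.0: 0, 0.10: 1, 0.15: 2, 0.20: 3, 0.25: 4, 0.30: 5}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the policy grid.

    At zero reduction the imposition dimension is vacuous and is
    normalized to ``region``.
    """

    reduction_level: float
    tech: str
    imposition: str
    economy: str

    def __post_init__(self):
        if self.reduction_level not in _LEVEL_INDEX:
            raise ValueError(f"unknown reduction level {self.reduction_level!r}")
        if self.tech not in TECH_REGIMES:
            raise ValueError(f"unknown tech {self.tech!r}")
        if self.imposition not in IMPOSITIONS:
            raise ValueError(f"unknown imposition {self.imposition!r}")
        if self.economy not in demand_supply.ECONOMIES:
            raise ValueError(f"unknown economy {self.economy!r}")
        if self.reduction_level == 0.0 and self.imposition != "region":
            object.__setattr__(self, "imposition", "region")

    @property
    def level_index(self) -> int:
        return _LEVEL_INDEX[self.reduction_level]

    @property
    def scenario_id(self) -> str:
        return f"R{self.level_index}_{self.tech}_{self.imposition}_{self.economy}"


@dataclass
class BaselineUsage:
    """Base-year pesticide usage totals (t) per district plus region."""

    pesticide_t: dict  # district id -> t
    region_total_t: float


@dataclass
class SectorProblem:
    """Assembled QP/LP in matrix form plus index metadata."""

    scenario: ScenarioSpec
    process_keys: list  # (district, crop, tech) per Q column
    crop_ids: list
    lambda_keys: list  # (district, year) per lambda column
    c: np.ndarray  # linear objective (maximize)
    quad_diag: np.ndarray  # diagonal of the quadratic term (>= 0)
    A: np.ndarray  # inequality matrix, A z <= b
    b: np.ndarray
    row_meta: list  # (kind, key) per row
    bundle: ModelInputBundle = None
    baseline: Optional[BaselineUsage] = None

    @property
    def n_vars(self) -> int:
        return len(self.c)

    @property
    def n_processes(self) -> int:
        return len(self.process_keys)

    def rows_of_kind(self, kind: str) -> list:
        return [i for i, (k, _) in enumerate(self.row_meta) if k == kind]


@dataclass
class SolutionBundle:
    """Primal/dual optimum of one scenario."""

    status: str
    scenario: Optional[ScenarioSpec] = None
    acreage_ha: dict = field(default_factory=dict)  # (district, crop, tech) -> ha
    production_t: dict = field(default_factory=dict)  # crop -> t
    sales_t: dict = field(default_factory=dict)  # crop -> t
    input_use: dict = field(default_factory=dict)  # input -> quantity
    prices_yuan_per_kg: dict = field(default_factory=dict)  # crop -> yuan/kg
    pesticide_use_t: dict = field(default_factory=dict)  # district -> t
    welfare: dict = field(default_factory=dict)  # component -> yuan
    land_rent_yuan_per_ha: dict = field(default_factory=dict)  # district -> yuan/ha
    pesticide_shadow_yuan_per_kg: dict = field(default_factory=dict)  # scope -> yuan/kg
    mix_duals: dict = field(default_factory=dict)
    objective_value: float = 0.0
    message: str = ""

    def district_acreage_ha(self) -> dict:
        out: dict = {}
        for (district, _crop, _tech), q in self.acreage_ha.items():
            out[district] = out.get(district, 0.0) + q
        return out

    def region_pesticide_t(self) -> float:
        return float(sum(self.pesticide_use_t.values()))


class AssemblyError(Exception):
    """Raised when a scenario cannot be assembled against a bundle."""


# ---------------------------------------------------------------------------
# baseline usage
# ---------------------------------------------------------------------------


def _district_acreage(bundle: ModelInputBundle) -> dict:
    """Observed per-(district, crop) acreage; apportioned from per-crop
    totals by mean historical mix shares when not given directly."""
    obs = bundle.observed_baseline
    if obs.district_acreage_ha:
        return dict(obs.district_acreage_ha)
    # share of each district in each crop's historical acreage
    totals: dict = {}
    for mix in bundle.historical_mixes:
        for crop, area in mix.acreage_by_crop.items():
            totals[(mix.district, crop)] = totals.get((mix.district, crop), 0.0) + area
    crop_totals: dict = {}
    for (_d, crop), area in totals.items():
        crop_totals[crop] = crop_totals.get(crop, 0.0) + area
    out = {}
    for crop, acreage in obs.acreage_ha.items():
        denom = crop_totals.get(crop, 0.0)
        if denom <= 0:
            # no historical footprint: spread uniformly over districts
            for d in bundle.districts:
                out[(d.id, crop)] = acreage / len(bundle.districts)
            continue
        for d in bundle.districts:
            share = totals.get((d.id, crop), 0.0) / denom
            if share > 0:
                out[(d.id, crop)] = acreage * share
    return out


def baseline_pesticide_usage(bundle: ModelInputBundle) -> BaselineUsage:
    """Base-year pesticide usage per district (t): observed acreage times
    base budget application rates."""
    acreage = _district_acreage(bundle)
    rates = {
        (b.district, b.crop): b.pesticide_kg_per_ha
        for b in bundle.budgets
        if b.tech == "base"
    }
    per_district = {d.id: 0.0 for d in bundle.districts}
    for (district, crop), area in acreage.items():
        if area <= 0:
            continue
        if (district, crop) not in rates:
            raise AssemblyError(
                f"no base budget for observed acreage in {district}/{crop}"
            )
        per_district[district] += area * rates[(district, crop)] / 1000.0
    return BaselineUsage(
        pesticide_t=per_district, region_total_t=float(sum(per_district.values()))
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _scenario_budgets(bundle: ModelInputBundle, scenario: ScenarioSpec) -> list:
    base = [b for b in bundle.budgets if b.tech == "base"]
    if scenario.tech == "TechB":
        return base
    mech = [b for b in bundle.budgets if b.tech == "mechanized"]
    if scenario.tech == "TechR":
        rice = bundle.settings.rice_crop_id
        mech = [b for b in mech if b.crop == rice]
        if not mech:
            raise AssemblyError(
                f"TechR requires mechanized budgets for crop {rice!r}"
            )
    elif not mech:
        raise AssemblyError("TechA requires mechanized budgets")
    return base + mech


def assemble_problem(
    bundle: ModelInputBundle,
    scenario: ScenarioSpec,
    baseline: Optional[BaselineUsage] = None,
) -> SectorProblem:
    """Build the constraint matrices for one scenario."""
    budgets = _scenario_budgets(bundle, scenario)
    specs = demand_supply.apply_closure(bundle.demand_specs, scenario.economy)
    for s in specs:
        if s.intercept_a is None or s.slope_b is None:
            raise AssemblyError(f"demand spec for crop {s.crop!r} not calibrated")
    spec_by_crop = {s.crop: s for s in specs}
    if baseline is None:
        baseline = baseline_pesticide_usage(bundle)

    crop_ids = bundle.crop_ids()
    crop_index = {c: i for i, c in enumerate(crop_ids)}
    district_ids = bundle.district_ids()
    process_keys = [(b.district, b.crop, b.tech) for b in budgets]

    mix_enabled = bundle.settings.crop_mix_enabled and len(bundle.historical_mixes) > 0
    lambda_keys = (
        [(m.district, m.year) for m in bundle.historical_mixes] if mix_enabled else []
    )

    n_q = len(process_keys)
    n_y = len(crop_ids)
    n_x = len(INPUT_IDS)
    n_l = len(lambda_keys)
    n = n_q + n_y + n_x + n_l
    off_y, off_x, off_l = n_q, n_q + n_y, n_q + n_y + n_x

    c = np.zeros(n)
    quad_diag = np.zeros(n)
    for m, cid in enumerate(crop_ids):
        spec = spec_by_crop.get(cid)
        if spec is None:
            raise AssemblyError(f"no demand spec for crop {cid!r}")
        c[off_y + m] = spec.intercept_a
        quad_diag[off_y + m] = spec.slope_b
    for i, iid in enumerate(INPUT_IDS):
        c[off_x + i] = -bundle.input_price(iid)
    for j, b in enumerate(budgets):
        c[j] = -b.activity_cost_yuan_per_ha

    rows = []
    rhs = []
    meta = []

    # commodity balance: Y_m - sum_j c_mj Q_j <= 0
    for m, cid in enumerate(crop_ids):
        row = np.zeros(n)
        row[off_y + m] = 1.0
        for j, b in enumerate(budgets):
            if b.crop == cid:
                row[j] = -b.yield_t_per_ha
        rows.append(row)
        rhs.append(0.0)
        meta.append(("balance", cid))

    # input linkage: sum_j a_ij Q_j - X_i <= 0
    rate_attr = {
        "pesticide": "pesticide_kg_per_ha",
        "fertilizer": "fertilizer_kg_per_ha",
        "labor": "labor_pm_per_ha",
    }
    for i, iid in enumerate(INPUT_IDS):
        row = np.zeros(n)
        row[off_x + i] = -1.0
        for j, b in enumerate(budgets):
            row[j] = getattr(b, rate_attr[iid])
        rows.append(row)
        rhs.append(0.0)
        meta.append(("input", iid))

    # land: sum_{j in n} Q_j <= Z_n
    for d in bundle.districts:
        row = np.zeros(n)
        for j, (district, _crop, _tech) in enumerate(process_keys):
            if district == d.id:
                row[j] = 1.0
        rows.append(row)
        rhs.append(d.land_ha)
        meta.append(("land", d.id))

    # crop-mix cone: sum_tech Q_{n,crop,.} - (1+delta) sum_h lam_{n,h} hist <= 0
    if mix_enabled:
        delta = bundle.settings.mix_delta
        for did in district_ids:
            district_crops = sorted(
                {crop for (district, crop, _t) in process_keys if district == did}
            )
            for cid in district_crops:
                row = np.zeros(n)
                for j, (district, crop, _t) in enumerate(process_keys):
                    if district == did and crop == cid:
                        row[j] = 1.0
                for h, (district, year) in enumerate(lambda_keys):
                    if district != did:
                        continue
                    hist = next(
                        m
                        for m in bundle.historical_mixes
                        if m.district == district and m.year == year
                    )
                    row[off_l + h] = -(1.0 + delta) * hist.acreage_by_crop.get(cid, 0.0)
                rows.append(row)
                rhs.append(0.0)
                meta.append(("mix", f"{did}/{cid}"))

    # pesticide cap(s), expressed in kg so the dual is yuan/kg
    r = scenario.reduction_level
    if scenario.imposition == "district" and r > 0:
        for d in bundle.districts:
            row = np.zeros(n)
            for j, b in enumerate(budgets):
                if b.district == d.id:
                    row[j] = b.pesticide_kg_per_ha
            rows.append(row)
            rhs.append((1.0 - r) * baseline.pesticide_t.get(d.id, 0.0) * 1000.0)
            meta.append(("pesticide_cap", d.id))
    else:
        row = np.zeros(n)
        for j, b in enumerate(budgets):
            row[j] = b.pesticide_kg_per_ha
        rows.append(row)
        rhs.append((1.0 - r) * baseline.region_total_t * 1000.0)
        meta.append(("pesticide_cap", "region"))

    return SectorProblem(
        scenario=scenario,
        process_keys=process_keys,
        crop_ids=crop_ids,
        lambda_keys=lambda_keys,
        c=c,
        quad_diag=quad_diag,
        A=np.array(rows),
        b=np.array(rhs),
        row_meta=meta,
        bundle=bundle,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def _solve_lp(problem: SectorProblem):
    res = optimize.linprog(
        -problem.c,
        A_ub=problem.A,
        b_ub=problem.b,
        bounds=(0, None),
        method="highs",
    )
    if res.status != 0:
        return None, None, res.message
    duals = -np.asarray(res.ineqlin.marginals)
    return np.asarray(res.x), duals, res.message


def _mehrotra_qp(
    quad_diag: np.ndarray,
    q: np.ndarray,
    G: np.ndarray,
    h: np.ndarray,
    tol: float = 1e-9,
    maxiter: int = 100,
):
    """Mehrotra predictor-corrector interior-point method for

        min 0.5*x'*diag(d)*x + q'*x   s.t.  G x <= h

    (variable bounds must already be folded into ``G``).  Returns
    ``(x, lam, converged)`` with ``lam`` the multipliers of the rows of
    ``G``.  Dense linear algebra; intended for problems with a few
    hundred variables.
    """
    m, n = G.shape
    # equilibrate rows of G for numerical stability
    row_scale = np.maximum(np.abs(G).max(axis=1), 1e-12)
    Gs = G / row_scale[:, None]
    hs = h / row_scale
    obj_scale = max(1.0, np.abs(q).max())
    d = quad_diag / obj_scale
    qs = q / obj_scale

    x = np.zeros(n)
    s = np.maximum(hs, 1.0)
    lam = np.ones(m)
    reg = 1e-12

    converged = False
    for _ in range(maxiter):
        r_d = d * x + qs + Gs.T @ lam
        r_p = Gs @ x + s - hs
        mu = float(s @ lam) / m

        norm_ref = 1.0 + max(np.abs(hs).max(initial=0.0), np.abs(qs).max(initial=0.0))
        if (
            np.abs(r_p).max() < tol * norm_ref
            and np.abs(r_d).max() < tol * norm_ref
            and mu < tol * norm_ref
        ):
            converged = True
            break

        w = lam / s
        M = (Gs.T * w) @ Gs
        M[np.diag_indices_from(M)] += d + reg * (1.0 + M.diagonal())
        try:
            cho = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            M[np.diag_indices_from(M)] += 1e-8 * (1.0 + M.diagonal())
            cho = np.linalg.cholesky(M)

        def solve_kkt(r_d_, r_p_, r_c_):
            # eliminate ds and dlam; solve for dx
            rhs = -r_d_ - Gs.T @ (w * (r_p_ - r_c_ / lam))
            dx = np.linalg.solve(cho.T, np.linalg.solve(cho, rhs))
            dlam = w * (Gs @ dx + r_p_ - r_c_ / lam)
            ds = -(r_c_ + s * dlam) / lam
            return dx, dlam, ds

        # affine (predictor) direction
        r_c = s * lam
        dx_a, dlam_a, ds_a = solve_kkt(r_d, r_p, r_c)
        alpha_p = _max_step(s, ds_a)
        alpha_d = _max_step(lam, dlam_a)
        mu_aff = float((s + alpha_p * ds_a) @ (lam + alpha_d * dlam_a)) / m
        sigma = (mu_aff / mu) ** 3 if mu > 0 else 0.0

        # corrector
        r_c = s * lam + ds_a * dlam_a - sigma * mu
        dx, dlam, ds = solve_kkt(r_d, r_p, r_c)
        alpha_p = min(1.0, 0.99 * _max_step(s, ds))
        alpha_d = min(1.0, 0.99 * _max_step(lam, dlam))
        x += alpha_p * dx
        s += alpha_p * ds
        lam += alpha_d * dlam

    return x, lam * obj_scale / row_scale, converged


def _max_step(v: np.ndarray, dv: np.ndarray) -> float:
    neg = dv < 0
    if not np.any(neg):
        return 1.0
    return float(min(1.0, np.min(-v[neg] / dv[neg])))


def _polish_qp(problem: SectorProblem, z: np.ndarray, act_tol: float):
    """Re-solve the equality-constrained QP on the active set found by the
    iterative solver; near-machine precision when the guess is right."""
    A, b, c, D = problem.A, problem.b, problem.c, problem.quad_diag
    n = len(c)
    slack = b - A @ z
    row_scale = 1.0 + np.abs(b)
    active_rows = np.where(slack <= act_tol * row_scale)[0]
    var_scale = 1.0 + np.abs(z).max() if len(z) else 1.0
    fixed_vars = np.where(z <= act_tol * var_scale)[0]
    free = np.setdiff1d(np.arange(n), fixed_vars)
    # variables with no objective term and no active-row footprint are
    # indeterminate in the KKT system (e.g. input purchases at zero
    # price); hold them at their current feasible values
    footprint = (
        (np.abs(A[active_rows]) > 0).any(axis=0)
        if len(active_rows)
        else np.zeros(n, dtype=bool)
    )
    inert = (D == 0) & (c == 0) & ~footprint
    free = np.setdiff1d(free, np.where(inert)[0])
    z_new = np.zeros(n)
    z_new[inert] = z[inert]
    if len(free):
        A_act = A[np.ix_(active_rows, free)]
        # KKT: D z - c + A' mu = 0 on free vars; A_act z = b_act
        k = len(free) + len(active_rows)
        K = np.zeros((k, k))
        K[: len(free), : len(free)] = np.diag(D[free])
        K[: len(free), len(free):] = A_act.T
        K[len(free):, : len(free)] = A_act
        rhs = np.concatenate([c[free], b[active_rows]])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        z_new[free] = sol[: len(free)]
    # accept only if primal-feasible and objective not worse
    if z_new.min() < -1e-7 * var_scale:
        return None
    if np.any(problem.A @ z_new - problem.b > 1e-6 * row_scale):
        return None
    def obj(v):
        return float(problem.c @ v - 0.5 * v @ (problem.quad_diag * v))
    if obj(z_new) < obj(z) - 1e-9 * (1 + abs(obj(z))):
        return None
    return z_new


def _duals_from_kkt(problem: SectorProblem, z: np.ndarray, act_tol: float = 1e-6):
    """Recover inequality multipliers by non-negative least squares on the
    KKT stationarity condition at the primal optimum."""
    A, b, c, D = problem.A, problem.b, problem.c, problem.quad_diag
    n = len(c)
    grad = D * z - c  # gradient of the minimized objective
    slack = b - A @ z
    row_scale = 1.0 + np.abs(b)
    active_rows = np.where(slack <= act_tol * row_scale)[0]
    var_scale = 1.0 + (np.abs(z).max() if len(z) else 0.0)
    at_bound = np.where(z <= act_tol * var_scale)[0]
    # stationarity: grad + A_act' mu - e_k nu = 0, mu >= 0, nu >= 0
    cols = []
    for r in active_rows:
        cols.append(A[r])
    for k in at_bound:
        e = np.zeros(n)
        e[k] = -1.0
        cols.append(e)
    duals = np.zeros(len(problem.row_meta))
    if not cols:
        return duals
    M = np.array(cols).T
    scale = max(1.0, np.abs(grad).max())
    try:
        w, _ = optimize.nnls(M / scale, -grad / scale, maxiter=10 * M.shape[1])
    except RuntimeError:
        return None
    w *= 1.0  # multipliers are scale-invariant here (both sides divided)
    for idx, r in enumerate(active_rows):
        duals[r] = w[idx]
    return duals


def solve_problem(problem: SectorProblem) -> SolutionBundle:
    """Solve an assembled problem and extract primal and dual values."""
    is_lp = not np.any(problem.quad_diag > 0)
    if is_lp:
        z, duals, message = _solve_lp(problem)
        if z is None:
            return SolutionBundle(
                status="infeasible", scenario=problem.scenario, message=message
            )
    else:
        n = problem.n_vars
        # fold x >= 0 into the inequality system
        G = np.vstack([problem.A, -np.eye(n)])
        h = np.concatenate([problem.b, np.zeros(n)])
        z, lam, converged = _mehrotra_qp(problem.quad_diag, -problem.c, G, h)
        z = np.clip(z, 0.0, None)
        message = "interior-point converged" if converged else "interior-point max iterations"
        polished = _polish_qp(problem, z, act_tol=1e-6)
        if polished is not None:
            z = polished
        duals = _duals_from_kkt(problem, z)
        if duals is None:
            duals = lam[: len(problem.row_meta)]
    return _extract_solution(problem, z, duals, message)


def _extract_solution(problem, z, duals, message="") -> SolutionBundle:
    bundle = problem.bundle
    scenario = problem.scenario
    n_q = problem.n_processes
    n_y = len(problem.crop_ids)
    off_y, off_x = n_q, n_q + n_y
    specs = demand_supply.apply_closure(bundle.demand_specs, scenario.economy)
    spec_by_crop = {s.crop: s for s in specs}

    q = np.clip(z[:n_q], 0.0, None)
    acreage = {key: float(v) for key, v in zip(problem.process_keys, q)}

    budgets = _scenario_budgets(bundle, scenario)
    production = {cid: 0.0 for cid in problem.crop_ids}
    pesticide_use = {d.id: 0.0 for d in bundle.districts}
    input_use = {iid: 0.0 for iid in INPUT_IDS}
    rate_attr = {
        "pesticide": "pesticide_kg_per_ha",
        "fertilizer": "fertilizer_kg_per_ha",
        "labor": "labor_pm_per_ha",
    }
    for j, b in enumerate(budgets):
        production[b.crop] += q[j] * b.yield_t_per_ha
        pesticide_use[b.district] += q[j] * b.pesticide_kg_per_ha / 1000.0
        for iid in INPUT_IDS:
            input_use[iid] += q[j] * getattr(b, rate_attr[iid])

    sales = {
        cid: float(min(max(z[off_y + m], 0.0), production[cid]))
        for m, cid in enumerate(problem.crop_ids)
    }
    prices = {}
    for cid in problem.crop_ids:
        spec = spec_by_crop[cid]
        prices[cid] = demand_supply.price_at_quantity(spec, sales[cid]) / 1000.0

    gross = sum(
        demand_supply.gross_consumer_benefit(spec_by_crop[cid], sales[cid])
        for cid in problem.crop_ids
    )
    input_cost = sum(bundle.input_price(iid) * input_use[iid] for iid in INPUT_IDS)
    activity_cost = sum(q[j] * b.activity_cost_yuan_per_ha for j, b in enumerate(budgets))
    total = gross - input_cost - activity_cost
    if scenario.economy == "P_free":
        consumer = sum(
            0.5 * (spec_by_crop[cid].slope_b or 0.0) * sales[cid] ** 2
            for cid in problem.crop_ids
        )
    else:
        consumer = 0.0
    welfare = {
        "gross_consumer_benefit": float(gross),
        "input_cost": float(input_cost),
        "activity_cost": float(activity_cost),
        "total": float(total),
        "consumer_surplus": float(consumer),
        "producer_surplus": float(total - consumer),
    }

    land_rent = {}
    pest_shadow = {}
    mix_duals = {}
    for i, (kind, key) in enumerate(problem.row_meta):
        if kind == "land":
            land_rent[key] = float(max(duals[i], 0.0))
        elif kind == "pesticide_cap":
            pest_shadow[key] = float(max(duals[i], 0.0))
        elif kind == "mix":
            mix_duals[key] = float(max(duals[i], 0.0))

    return SolutionBundle(
        status="optimal",
        scenario=scenario,
        acreage_ha=acreage,
        production_t={k: float(v) for k, v in production.items()},
        sales_t=sales,
        input_use={k: float(v) for k, v in input_use.items()},
        prices_yuan_per_kg=prices,
        pesticide_use_t={k: float(v) for k, v in pesticide_use.items()},
        welfare=welfare,
        land_rent_yuan_per_ha=land_rent,
        pesticide_shadow_yuan_per_kg=pest_shadow,
        mix_duals=mix_duals,
        objective_value=float(total),
        message=str(message),
    )


def solve(bundle: ModelInputBundle, scenario: ScenarioSpec) -> SolutionBundle:
    """Assemble and solve one scenario against a bundle."""
    return solve_problem(assemble_problem(bundle, scenario))


def welfare(solution: SolutionBundle) -> dict:
    """Welfare components of an optimal solution."""
    if solution.status != "optimal":
        raise ValueError(f"solution status is {solution.status!r}")
    return dict(solution.welfare)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_solve(
    bundle: ModelInputBundle,
    scenario: ScenarioSpec,
    grid_step_ha: float,
    baseline: Optional[BaselineUsage] = None,
) -> SolutionBundle:
    """Exhaustive grid search over the acreage simplex.

    Independent oracle for :func:`solve_problem` on tiny instances
    (at most 3 acreage variables, crop-mix constraint disabled).
    Sales are set to the surplus-maximizing level given production.
    """
    budgets = _scenario_budgets(bundle, scenario)
    if len(budgets) > 3:
        raise ValueError("brute force limited to <= 3 acreage variables")
    if bundle.settings.crop_mix_enabled and bundle.historical_mixes:
        raise ValueError("brute force requires the crop-mix constraint disabled")
    if baseline is None:
        baseline = baseline_pesticide_usage(bundle)
    specs = demand_supply.apply_closure(bundle.demand_specs, scenario.economy)
    spec_by_crop = {s.crop: s for s in specs}
    land = {d.id: d.land_ha for d in bundle.districts}
    r = scenario.reduction_level

    axes = []
    for b in budgets:
        n_steps = int(np.floor(land[b.district] / grid_step_ha + 1e-9))
        axes.append([i * grid_step_ha for i in range(n_steps + 1)])

    best_q = None
    best_w = -np.inf
    for combo in itertools.product(*axes):
        per_district: dict = {}
        for b, qv in zip(budgets, combo):
            per_district[b.district] = per_district.get(b.district, 0.0) + qv
        if any(v > land[d] + 1e-9 for d, v in per_district.items()):
            continue
        if r > 0 or True:  # caps always present (slack at r = 0)
            if scenario.imposition == "district" and r > 0:
                ok = True
                use: dict = {}
                for b, qv in zip(budgets, combo):
                    use[b.district] = use.get(b.district, 0.0) + qv * b.pesticide_kg_per_ha
                for d, u in use.items():
                    if u > (1 - r) * baseline.pesticide_t.get(d, 0.0) * 1000.0 + 1e-9:
                        ok = False
                        break
                if not ok:
                    continue
            else:
                total_use = sum(qv * b.pesticide_kg_per_ha for b, qv in zip(budgets, combo))
                if total_use > (1 - r) * baseline.region_total_t * 1000.0 + 1e-9:
                    continue
        w = _welfare_at(bundle, budgets, spec_by_crop, combo)
        if w > best_w:
            best_w = w
            best_q = combo

    if best_q is None:
        return SolutionBundle(status="infeasible", scenario=scenario)
    sol = SolutionBundle(status="optimal", scenario=scenario)
    sol.acreage_ha = {
        (b.district, b.crop, b.tech): float(qv) for b, qv in zip(budgets, best_q)
    }
    production = {cid: 0.0 for cid in bundle.crop_ids()}
    for b, qv in zip(budgets, best_q):
        production[b.crop] += qv * b.yield_t_per_ha
    sol.production_t = production
    sol.sales_t = {
        cid: min(production[cid], demand_supply.choke_quantity(spec_by_crop[cid]))
        for cid in production
    }
    sol.pesticide_use_t = {d.id: 0.0 for d in bundle.districts}
    for b, qv in zip(budgets, best_q):
        sol.pesticide_use_t[b.district] += qv * b.pesticide_kg_per_ha / 1000.0
    sol.welfare = {"total": float(best_w)}
    sol.objective_value = float(best_w)
    return sol


def _welfare_at(bundle, budgets, spec_by_crop, q) -> float:
    production: dict = {}
    for b, qv in zip(budgets, q):
        production[b.crop] = production.get(b.crop, 0.0) + qv * b.yield_t_per_ha
    gross = 0.0
    for cid, prod in production.items():
        spec = spec_by_crop[cid]
        y = min(prod, demand_supply.choke_quantity(spec))
        gross += demand_supply.gross_consumer_benefit(spec, y)
    input_cost = 0.0
    for b, qv in zip(budgets, q):
        input_cost += qv * (
            b.pesticide_kg_per_ha * bundle.input_price("pesticide")
            + b.fertilizer_kg_per_ha * bundle.input_price("fertilizer")
            + b.labor_pm_per_ha * bundle.input_price("labor")
        )
    activity_cost = sum(qv * b.activity_cost_yuan_per_ha for b, qv in zip(budgets, q))
    return gross - input_cost - activity_cost
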