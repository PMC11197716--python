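import numpy as np
import pytest

from pasm import sector_model, synthetic_data
from pasm.domain_data import (
    Crop,
    CropBudget,
    DemandSpec,
    District,
    InputPrice,
    ModelInputBundle,
    ObservedBaseline,
    Settings,
)
from pasm.sector_model import (
    AssemblyError,
    ScenarioSpec,
    assemble_problem,
    baseline_pesticide_usage,
    brute_force_solve,
    solve,
    solve_problem,
)
from pasm.synthetic_data import GeneratorConfig


def two_crop_usage_bundle():
    """One district, two crops, known acreage and pesticide rates."""
    crops = [Crop("a", "A", "grain"), Crop("b", "B", "leafy_vegetable")]
    district = District("d1", "D1", 200.0)
    budgets = [
        CropBudget("d1", "a", "base", 5000.0, 10.0, 0.0, 0.0, 0.0, 100.0),
        CropBudget("d1", "b", "base", 20000.0, 2.0, 0.0, 0.0, 0.0, 100.0),
    ]
    specs = []
    for cid, p0, q0 in (("a", 3.0, 500.0), ("b", 2.5, 1000.0)):
        s = DemandSpec(cid, p0, q0, -0.5)
        from pasm.demand_supply import calibrate_linear_inverse_demand

        s.intercept_a, s.slope_b = calibrate_linear_inverse_demand(p0 * 1000, q0, -0.5)
        specs.append(s)
    observed = ObservedBaseline(
        acreage_ha={"a": 100.0, "b": 50.0},
        production_t={"a": 500.0, "b": 1000.0},
        price_yuan_per_kg={"a": 3.0, "b": 2.5},
        district_acreage_ha={("d1", "a"): 100.0, ("d1", "b"): 50.0},
    )
    return ModelInputBundle(
        crops=crops,
        districts=[district],
        budgets=budgets,
        input_prices=[InputPrice("pesticide", 0.0), InputPrice("fertilizer", 0.0),
                      InputPrice("labor", 0.0)],
        demand_specs=specs,
        historical_mixes=[],
        observed_baseline=observed,
        settings=Settings(crop_mix_enabled=False),
    )


class TestBaselineUsage:
    def test_hand_arithmetic(self):
        usage = baseline_pesticide_usage(two_crop_usage_bundle())
        # 100 ha x 10 kg/ha + 50 ha x 2 kg/ha = 1100 kg = 1.1 t
        assert usage.pesticide_t["d1"] == pytest.approx(1.1, rel=1e-12)
        assert usage.region_total_t == pytest.approx(1.1, rel=1e-12)

    def test_zero_acreage(self):
        bundle = two_crop_usage_bundle()
        bundle.observed_baseline.district_acreage_ha = {("d1", "a"): 0.0, ("d1", "b"): 0.0}
        usage = baseline_pesticide_usage(bundle)
        assert usage.region_total_t == 0.0

    def test_region_total_is_sum(self, default_bundle):
        usage = baseline_pesticide_usage(default_bundle)
        assert usage.region_total_t == pytest.approx(
            sum(usage.pesticide_t.values()), rel=1e-9
        )
        assert len(usage.pesticide_t) == 9

    def test_missing_budget_rejected(self):
        bundle = two_crop_usage_bundle()
        bundle.budgets = bundle.budgets[:1]
        with pytest.raises(AssemblyError):
            baseline_pesticide_usage(bundle)


class TestAssembleProblem:
    def test_oracle_shape_and_slack_cap(self, oracle_instance):
        bundle, _ = oracle_instance
        problem = assemble_problem(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        assert problem.n_processes == 2
        assert len(problem.crop_ids) == 2
        assert len(problem.rows_of_kind("pesticide_cap")) == 1
        sol = solve_problem(problem)
        assert sol.status == "optimal"
        # zero-reduction cap never binds: shadow price is zero
        assert sol.pesticide_shadow_yuan_per_kg["region"] == pytest.approx(0.0, abs=1e-6)

    def test_district_imposition_cap_rows(self, default_bundle):
        problem = assemble_problem(
            default_bundle, ScenarioSpec(0.20, "TechB", "district", "P_free")
        )
        assert len(problem.rows_of_kind("pesticide_cap")) == 9

    def test_region_imposition_single_cap_row(self, default_bundle):
        problem = assemble_problem(
            default_bundle, ScenarioSpec(0.20, "TechB", "region", "P_free")
        )
        assert len(problem.rows_of_kind("pesticide_cap")) == 1

    def test_tech_restriction(self, default_bundle):
        base_n = len([b for b in default_bundle.budgets if b.tech == "base"])
        p_b = assemble_problem(default_bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        p_r = assemble_problem(default_bundle, ScenarioSpec(0.0, "TechR", "region", "P_free"))
        p_a = assemble_problem(default_bundle, ScenarioSpec(0.0, "TechA", "region", "P_free"))
        assert p_b.n_processes == base_n
        assert p_r.n_processes == base_n + 9  # mechanized rice in each district
        assert p_a.n_processes == 2 * base_n

    def test_techr_without_rice_rejected(self):
        bundle = two_crop_usage_bundle()
        with pytest.raises(AssemblyError):
            assemble_problem(bundle, ScenarioSpec(0.0, "TechR", "region", "P_free"))


class TestSolveProblem:
    def test_known_equilibrium(self, oracle_instance):
        bundle, expected = oracle_instance
        sol = solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        assert sol.acreage_ha[("d1", "A", "base")] == pytest.approx(63.3333, abs=1e-3)
        assert sol.acreage_ha[("d1", "B", "base")] == pytest.approx(36.6667, abs=1e-3)
        assert sol.land_rent_yuan_per_ha["d1"] == pytest.approx(12666.67, abs=0.01)
        assert sol.welfare["total"] == pytest.approx(1_500_833.33, abs=0.01)

    def test_pesticide_cap_shifts_mix(self, capped_oracle_instance):
        bundle, expected = capped_oracle_instance
        r0 = solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        r3 = solve(bundle, ScenarioSpec(0.20, "TechB", "region", "P_free"))
        # baseline usage 706.67 kg; at r=0.2 the cap binds and acreage
        # shifts toward the low-pesticide crop
        assert baseline_pesticide_usage(bundle).region_total_t * 1000 == pytest.approx(
            706.67, abs=0.01
        )
        assert r3.acreage_ha[("d1", "A", "base")] < r0.acreage_ha[("d1", "A", "base")]
        assert r3.acreage_ha[("d1", "B", "base")] > r0.acreage_ha[("d1", "B", "base")]
        assert r3.region_pesticide_t() * 1000 == pytest.approx(
            0.8 * 706.6666667, rel=1e-6
        )
        assert r3.pesticide_shadow_yuan_per_kg["region"] > 0
        assert r3.welfare["total"] < r0.welfare["total"]

    def test_welfare_components(self, oracle_instance):
        bundle, expected = oracle_instance
        sol = solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        assert sol.welfare["consumer_surplus"] == pytest.approx(234_166.67, abs=0.01)
        assert sol.welfare["consumer_surplus"] == pytest.approx(
            200_555.56 + 33_611.11, abs=0.02
        )
        assert sol.welfare["total"] == pytest.approx(sol.objective_value, rel=1e-9)
        assert sector_model.welfare(sol) == sol.welfare

    def test_zero_production_welfare(self):
        from dataclasses import replace

        bundle = two_crop_usage_bundle()
        # production never profitable -> optimum is zero everywhere, yet
        # the problem stays feasible (caps are upper bounds)
        bundle.budgets = [
            replace(b, other_cost_yuan_per_ha=1e9) for b in bundle.budgets
        ]
        sol = solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        assert sol.status == "optimal"
        assert sol.welfare["total"] == pytest.approx(0.0, abs=1e-3)
        assert sum(sol.production_t.values()) == pytest.approx(0.0, abs=1e-6)

    def test_commodity_balance_and_caps_residuals(self, default_bundle):
        for spec in (
            ScenarioSpec(0.25, "TechB", "district", "P_free"),
            ScenarioSpec(0.25, "TechA", "region", "P_free"),
        ):
            problem = assemble_problem(default_bundle, spec)
            sol = solve_problem(problem)
            assert sol.status == "optimal"
            for cid in problem.crop_ids:
                assert sol.sales_t[cid] <= sol.production_t[cid] * (1 + 1e-6) + 1e-6
            usage = baseline_pesticide_usage(default_bundle)
            if spec.imposition == "region":
                cap = (1 - spec.reduction_level) * usage.region_total_t
                assert sol.region_pesticide_t() <= cap * (1 + 1e-6)
            else:
                for d, b_n in usage.pesticide_t.items():
                    cap = (1 - spec.reduction_level) * b_n
                    assert sol.pesticide_use_t[d] <= cap * (1 + 1e-6) + 1e-9


class TestBruteForceOracle:
    def test_uncapped_agreement(self, oracle_instance):
        bundle, expected = oracle_instance
        spec = ScenarioSpec(0.0, "TechB", "region", "P_free")
        bf = brute_force_solve(bundle, spec, grid_step_ha=0.5)
        assert bf.acreage_ha[("d1", "A", "base")] == pytest.approx(63.3333, abs=0.5)
        sol = solve(bundle, spec)
        assert bf.objective_value <= sol.welfare["total"] * (1 + 1e-9)
        assert sol.welfare["total"] == pytest.approx(bf.objective_value, rel=1e-3)

    def test_capped_agreement(self, capped_oracle_instance):
        bundle, _ = capped_oracle_instance
        spec = ScenarioSpec(0.20, "TechB", "region", "P_free")
        bf = brute_force_solve(bundle, spec, grid_step_ha=0.5)
        sol = solve(bundle, spec)
        for key in bf.acreage_ha:
            assert bf.acreage_ha[key] == pytest.approx(sol.acreage_ha[key], abs=0.5)
        assert sol.welfare["total"] == pytest.approx(bf.objective_value, rel=1e-3)
        usage = baseline_pesticide_usage(bundle)
        assert bf.region_pesticide_t() <= 0.8 * usage.region_total_t * (1 + 1e-9)

    def test_refinement_monotonicity(self, capped_oracle_instance):
        bundle, _ = capped_oracle_instance
        spec = ScenarioSpec(0.20, "TechB", "region", "P_free")
        coarse = brute_force_solve(bundle, spec, grid_step_ha=1.0)
        fine = brute_force_solve(bundle, spec, grid_step_ha=0.5)
        assert fine.objective_value >= coarse.objective_value - 1e-9

    def test_refuses_large_instances(self, default_bundle):
        with pytest.raises(ValueError):
            brute_force_solve(
                default_bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"), 1.0
            )


class TestOrderingInvariants:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_welfare_monotone_in_stringency(self, seed):
        config = GeneratorConfig(n_districts=2, n_crops=3, mean_land_ha=400.0,
                                 n_total=30, n_mechanized=16, survey_noise_sigma=0.02)
        bundle = synthetic_data.generate_instance(config, seed=seed)
        last = np.inf
        for r in sector_model.REDUCTION_LEVELS:
            sol = solve(bundle, ScenarioSpec(r, "TechB", "region", "P_free"))
            assert sol.status == "optimal"
            total = sol.welfare["total"]
            assert total <= last * (1 + 1e-6) + 1e-6
            last = total

    @pytest.mark.parametrize("seed", [3, 11])
    def test_region_welfare_at_least_district(self, seed):
        config = GeneratorConfig(n_districts=2, n_crops=3, mean_land_ha=400.0,
                                 n_total=30, n_mechanized=16, survey_noise_sigma=0.02)
        bundle = synthetic_data.generate_instance(config, seed=seed)
        for r in (0.15, 0.30):
            region = solve(bundle, ScenarioSpec(r, "TechB", "region", "P_free"))
            district = solve(bundle, ScenarioSpec(r, "TechB", "district", "P_free"))
            assert region.welfare["total"] >= district.welfare["total"] * (1 - 1e-6) - 1e-6

    def test_tech_options_weakly_increase_welfare(self, small_bundle):
        for r in (0.0, 0.20):
            w = {}
            for tech in sector_model.TECH_REGIMES:
                sol = solve(small_bundle, ScenarioSpec(r, tech, "region", "P_free"))
                assert sol.status == "optimal"
                w[tech] = sol.welfare["total"]
            assert w["TechR"] >= w["TechB"] * (1 - 1e-6) - 1e-6
            assert w["TechA"] >= w["TechB"] * (1 - 1e-6) - 1e-6

    def test_complementary_slackness(self, small_bundle):
        usage = baseline_pesticide_usage(small_bundle)
        for spec in (
            ScenarioSpec(0.20, "TechB", "region", "P_free"),
            ScenarioSpec(0.30, "TechB", "district", "P_free"),
        ):
            sol = solve(small_bundle, spec)
            if spec.imposition == "region":
                slack = (1 - spec.reduction_level) * usage.region_total_t - sol.region_pesticide_t()
                shadow = sol.pesticide_shadow_yuan_per_kg["region"]
                scale = max(1.0, usage.region_total_t)
                assert shadow * max(slack, 0.0) / scale <= 1e-4
            else:
                for d, b_n in usage.pesticide_t.items():
                    slack = (1 - spec.reduction_level) * b_n - sol.pesticide_use_t[d]
                    shadow = sol.pesticide_shadow_yuan_per_kg.get(d, 0.0)
                    assert shadow * max(slack, 0.0) / max(1.0, b_n) <= 1e-4
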