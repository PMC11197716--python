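import filecmp
from dataclasses import replace

import numpy as np
import pytest

from pasm import budget_engine, domain_data, sector_model, synthetic_data
from pasm.domain_data import HORTICULTURAL_CATEGORIES, write_bundle
from pasm.sector_model import ScenarioSpec
from pasm.synthetic_data import GenerationError, GeneratorConfig


class TestGenerateInstance:
    def test_determinism_byte_identical(self, tmp_path, small_config):
        dirs = []
        for name in ("a", "b"):
            bundle = synthetic_data.generate_instance(small_config, seed=42)
            out = tmp_path / name
            write_bundle(bundle, str(out))
            dirs.append(out)
        for fname in domain_data.BUNDLE_FILES:
            assert filecmp.cmp(dirs[0] / fname, dirs[1] / fname, shallow=False), fname

    def test_default_matches_shanghai_layout(self, default_bundle):
        assert len(default_bundle.districts) == 9
        assert len(default_bundle.crops) == 15
        assert default_bundle.settings.rice_crop_id == "rice"

    def test_bundle_passes_validation(self, default_bundle):
        assert domain_data.validate_bundle(default_bundle) == []

    def test_horticulture_grain_pesticide_ratio(self):
        """Mean horticultural rate / mean grain rate near the configured 5."""
        config = GeneratorConfig(horticulture_pesticide_ratio=5.0)
        grain_rates, hort_rates = [], []
        for seed in range(10):  # 10 x 135 budget rows pooled
            bundle = synthetic_data.generate_instance(config, seed=seed)
            cat = {c.id: c.category for c in bundle.crops}
            for b in bundle.budgets:
                if b.tech != "base":
                    continue
                if cat[b.crop] in HORTICULTURAL_CATEGORIES:
                    hort_rates.append(b.pesticide_kg_per_ha)
                elif cat[b.crop] == "grain":
                    grain_rates.append(b.pesticide_kg_per_ha)
        assert len(grain_rates) + len(hort_rates) > 1000
        ratio = np.mean(hort_rates) / np.mean(grain_rates)
        assert 4.0 <= ratio <= 6.0

    def test_mix_years_fit_land(self, default_bundle):
        land = {d.id: d.land_ha for d in default_bundle.districts}
        for mix in default_bundle.historical_mixes:
            assert sum(mix.acreage_by_crop.values()) <= land[mix.district] * (1 + 1e-9)

    def test_infeasible_config_rejected(self):
        with pytest.raises(GenerationError):
            GeneratorConfig(n_total=10, n_mechanized=11).validate()
        with pytest.raises(GenerationError):
            GeneratorConfig(elasticity_range=(-0.5, 0.5)).validate()


class TestKnownEquilibrium:
    def test_hand_derived_oracle_values(self, oracle_instance):
        _bundle, expected = oracle_instance
        assert expected.acreage_ha[("d1", "A", "base")] == pytest.approx(63.3333, abs=1e-4)
        assert expected.acreage_ha[("d1", "B", "base")] == pytest.approx(36.6667, abs=1e-4)
        assert expected.land_rent_yuan_per_ha["d1"] == pytest.approx(12666.67, abs=0.01)
        assert expected.welfare["total"] == pytest.approx(1_500_833.33, abs=0.01)

    def test_solver_recovers_equilibrium(self, oracle_instance):
        bundle, expected = oracle_instance
        sol = sector_model.solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        assert sol.status == "optimal"
        for key, want in expected.acreage_ha.items():
            assert sol.acreage_ha[key] == pytest.approx(want, rel=1e-4)
        assert sol.welfare["total"] == pytest.approx(expected.welfare["total"], rel=1e-6)
        assert sol.land_rent_yuan_per_ha["d1"] == pytest.approx(
            expected.land_rent_yuan_per_ha["d1"], rel=1e-4
        )

    def test_fixed_prices_give_corner_solution(self, oracle_config):
        """With flat demand at the calibration intercepts, the whole
        district goes to the crop with the larger fixed-price margin."""
        bundle, _ = synthetic_data.generate_known_equilibrium_instance(oracle_config, seed=1)
        sol = sector_model.solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_fixed"))
        # margins at fixed p0 = a/2: A: 10*1000-1000=9000, B: 5*1500-500=7000
        assert sol.acreage_ha[("d1", "A", "base")] == pytest.approx(100.0, abs=1e-6)
        assert sol.acreage_ha[("d1", "B", "base")] == pytest.approx(0.0, abs=1e-6)
        assert sol.welfare["consumer_surplus"] == 0.0

    def test_monetary_scaling_homogeneity(self, oracle_config):
        scaled = synthetic_data.scaled_instance(oracle_config, 10.0)
        _, base_exp = synthetic_data.generate_known_equilibrium_instance(oracle_config, 1)
        bundle, expected = synthetic_data.generate_known_equilibrium_instance(scaled, 1)
        for key, want in base_exp.acreage_ha.items():
            assert expected.acreage_ha[key] == pytest.approx(want, rel=1e-12)
        assert expected.land_rent_yuan_per_ha["d1"] == pytest.approx(
            10.0 * base_exp.land_rent_yuan_per_ha["d1"], rel=1e-12
        )
        sol = sector_model.solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        for key, want in expected.acreage_ha.items():
            assert sol.acreage_ha[key] == pytest.approx(want, rel=1e-4)

    def test_corner_configuration_rejected(self):
        # crop B cannot compete at any interior allocation
        config = GeneratorConfig(
            eq_yields_t_per_ha=[10.0, 1.0],
            eq_costs_yuan_per_ha=[100.0, 5000.0],
            eq_demand_a=[2000.0, 500.0],
            eq_demand_b=[0.1, 0.1],
        )
        with pytest.raises(GenerationError):
            synthetic_data.generate_known_equilibrium_instance(config, seed=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_recovered(self, seed):
        config = GeneratorConfig(eq_n_crops=3)
        bundle, expected = synthetic_data.generate_known_equilibrium_instance(config, seed)
        sol = sector_model.solve(bundle, ScenarioSpec(0.0, "TechB", "region", "P_free"))
        for key, want in expected.acreage_ha.items():
            assert sol.acreage_ha[key] == pytest.approx(want, rel=1e-4)
        assert sol.welfare["total"] == pytest.approx(expected.welfare["total"], rel=1e-6)


class TestGenerateSurvey:
    def test_default_subsample_split(self):
        survey = synthetic_data.generate_survey(GeneratorConfig(), seed=3)
        assert len(survey) == 532
        assert int((~survey["mechanized"]).sum()) == 251
        assert int(survey["mechanized"].sum()) == 281

    def test_determinism(self):
        a = synthetic_data.generate_survey(GeneratorConfig(), seed=5)
        b = synthetic_data.generate_survey(GeneratorConfig(), seed=5)
        assert a.equals(b)

    def test_effect_recovery_large_n(self):
        config = GeneratorConfig(n_total=200_000, n_mechanized=100_000)
        survey = synthetic_data.generate_survey(config, seed=11)
        effect = budget_engine.tech_effects(budget_engine.summarize_survey(survey))
        assert effect.yield_pct == pytest.approx(config.yield_pct, abs=0.1)
        assert effect.pesticide_pct == pytest.approx(config.pesticide_pct, abs=0.1)
        assert effect.labor_pct == pytest.approx(config.labor_pct, abs=0.1)
        assert effect.machinery_cost_pct == pytest.approx(config.machinery_pct, abs=0.15)

    def test_zero_effects_within_noise(self):
        config = GeneratorConfig(
            n_total=100_000, n_mechanized=50_000,
            yield_pct=0.0, pesticide_pct=0.0, labor_pct=0.0, machinery_pct=0.0,
            fertilizer_pct=0.0, wage_pct=0.0,
        )
        survey = synthetic_data.generate_survey(config, seed=13)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sign warnings expected at zero effect
            effect = budget_engine.tech_effects(budget_engine.summarize_survey(survey))
        for value in (
            effect.yield_pct, effect.pesticide_pct, effect.labor_pct,
            effect.machinery_cost_pct,
        ):
            assert abs(value) < 0.25

    def test_oversized_mechanized_arm_rejected(self):
        with pytest.raises(GenerationError):
            synthetic_data.generate_survey(
                GeneratorConfig(n_total=100, n_mechanized=101), seed=1
            )
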