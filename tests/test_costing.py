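"""Dosing, dispensing, per-cycle costs, and accrued cost categories."""

import numpy as np
import pytest

from psmcea.costing import (
    AEProfile,
    ConfigurationError,
    GlobalAssumptions,
    PackSpec,
    UnitCosts,
    admin_cost_per_cycle,
    ae_expected_cost,
    dose_mg,
    drug_cost_per_cycle,
    lab_panel_cost,
    packs_needed,
    pd_management_cost,
    terminal_cost,
    total_costs,
)
from psmcea.icer import evaluate_arm
from psmcea.psm import CycleGrid, OccupancyTrace

ASSUMPTIONS = GlobalAssumptions()


def flat_trace(pf=1.0, pd=0.0, n=10):
    dead = 1.0 - pf - pd
    return OccupancyTrace(
        grid=CycleGrid(cycle_length_days=21, horizon_years=n * 0.7 / 12),
        pf=np.full(n, pf),
        pd=np.full(n, pd),
        dead=np.full(n, dead),
    )


class TestDosing:
    def test_reference_body_surface_area_doses(self):
        assert dose_mg(30, ASSUMPTIONS) == pytest.approx(51.9)
        assert dose_mg(1000, ASSUMPTIONS) == pytest.approx(1730.0)
        assert dose_mg(0, ASSUMPTIONS) == 0.0

    def test_exact_multiple_is_mode_independent(self):
        for mode in ("nearest", "up"):
            spec = PackSpec("d", 500, 1.0, rounding_mode=mode)
            assert packs_needed(1500, spec) == 3

    def test_nearest_vs_up_rounding(self):
        assert packs_needed(51.9, PackSpec("u", 50, 1.0)) == 1
        assert packs_needed(1730, PackSpec("c", 500, 1.0, rounding_mode="nearest")) == 3
        assert packs_needed(1730, PackSpec("c", 500, 1.0, rounding_mode="up")) == 4


class TestPerCycleCosts:
    def test_utidelone_cycle_cost(self, config):
        # 51.9 mg/day -> one 50 mg vial/day for five days
        regimen = config.regimen(config.treated)
        specs = config.pack_specs()
        uti = [d for d in regimen.drugs if d.drug == "utidelone"]
        from psmcea.costing import Regimen

        assert drug_cost_per_cycle(Regimen(tuple(uti)), specs, ASSUMPTIONS) == pytest.approx(
            5 * 408.94
        )

    def test_combination_cycle_cost_includes_capecitabine_packs(self, config):
        # 3 tablets x 2/day x 14 days = 84 tablets = 7 packs of 12
        cost = drug_cost_per_cycle(
            config.regimen(config.treated), config.pack_specs(), ASSUMPTIONS
        )
        assert cost == pytest.approx(5 * 408.94 + 7 * 36.51)

    def test_monotherapy_cycle_cost(self, config):
        # 4 tablets x 2/day x 14 days = 112 tablets -> 10 packs rounded up
        cost = drug_cost_per_cycle(
            config.regimen(config.comparator), config.pack_specs(), ASSUMPTIONS
        )
        assert cost == pytest.approx(10 * 36.51)

    def test_zero_priced_packs(self):
        from psmcea.costing import DrugSchedule, Regimen

        reg = Regimen((DrugSchedule("x", 100, 1, 5),))
        specs = {"x": PackSpec("x", 50, 0.0)}
        assert drug_cost_per_cycle(reg, specs, ASSUMPTIONS) == 0.0

    def test_missing_pack_spec_is_configuration_error(self):
        from psmcea.costing import DrugSchedule, Regimen

        with pytest.raises(ConfigurationError):
            drug_cost_per_cycle(Regimen((DrugSchedule("x", 1, 1, 1),)), {}, ASSUMPTIONS)

    def test_administration_cost(self):
        uc = UnitCosts()
        assert admin_cost_per_cycle(0, uc) == 0.0
        assert admin_cost_per_cycle(5, uc) == pytest.approx(
            5 * (17.27 + 1.64 + 3.38 + 4.69 + 0.99)
        )

    def test_lab_panel_sum(self):
        assert lab_panel_cost(UnitCosts()) == pytest.approx(36.19)


class TestCategoryAccruals:
    def test_mechanistic_ae_cost_is_incidence_weighted(self, config):
        profile = config.ae_profile(config.treated)
        uc = UnitCosts()
        expected = sum(p * uc.ae_costs[n] for n, p in profile.incidence.items())
        assert ae_expected_cost(profile, uc) == pytest.approx(expected)
        assert ae_expected_cost(AEProfile({"anemia": 0.0}), uc) == 0.0

    def test_terminal_cost_bounds_and_degenerate_cases(self):
        uc = UnitCosts()
        alive = flat_trace(pf=0.4, pd=0.6)
        assert terminal_cost(alive, uc, 0.05) == 0.0
        # instant extinction: the whole unit cost, undiscounted
        n = 10
        dead_now = OccupancyTrace(
            grid=alive.grid, pf=np.zeros(n), pd=np.zeros(n), dead=np.ones(n)
        )
        assert terminal_cost(dead_now, uc, 0.05) == pytest.approx(uc.end_of_life)

    def test_terminal_cost_never_exceeds_unit_cost(self, traces, config):
        uc = UnitCosts()
        for tr in traces.values():
            assert terminal_cost(tr, uc, 0.05) <= uc.end_of_life

    def test_pd_management_rate_and_override(self):
        uc_rate = UnitCosts(pd_management_per_cycle=10.0)
        tr = flat_trace(pf=0.5, pd=0.25, n=8)
        assert pd_management_cost(tr, uc_rate, 0.0) == pytest.approx(10.0 * 0.25 * 8)
        assert pd_management_cost(tr, uc_rate, 0.0, override=496.50) == 496.50
        none_pd = flat_trace(pf=1.0, pd=0.0, n=8)
        assert pd_management_cost(none_pd, uc_rate, 0.05) == 0.0
        with pytest.raises(ConfigurationError):
            pd_management_cost(tr, UnitCosts(), 0.05)

    def test_category_sum_equals_total_to_the_cent(self, base_case):
        _, outcomes = base_case
        for oc in outcomes.values():
            parts = sum(getattr(oc.costs, c) for c in oc.costs.CATEGORIES)
            assert oc.costs.total == pytest.approx(parts, abs=0.01)

    def test_costs_are_homogeneous_in_unit_costs(self, config):
        names = [
            n for n, p in config.params.items()
            if p.category in ("cost", "override")
        ]
        doubled = config.with_values({n: 2 * config[n] for n in names})
        for label in config.arm_labels:
            base = evaluate_arm(config, label).costs
            twice = evaluate_arm(doubled, label).costs
            for cat in base.CATEGORIES:
                assert getattr(twice, cat) == pytest.approx(2 * getattr(base, cat), abs=1e-9)
            assert twice.total == pytest.approx(2 * base.total)

    def test_zero_unit_costs_give_zero_total(self, config):
        names = [
            n for n, p in config.params.items()
            if p.category in ("cost", "override")
        ]
        zeroed = config.with_values({n: 0.0 for n in names})
        for label in config.arm_labels:
            assert evaluate_arm(zeroed, label).costs.total == 0.0

    def test_undiscounted_acquisition_is_cycle_cost_times_pf_time(self, config):
        cfg = config.with_values({"discount.annual": 0.0})
        from psmcea.psm import build_trace

        label = cfg.comparator
        tr = build_trace(cfg.arm_model(label), cfg.grid)
        oc = evaluate_arm(cfg, label, tr)
        per_cycle = drug_cost_per_cycle(cfg.regimen(label), cfg.pack_specs(), cfg.assumptions)
        expected = per_cycle * float(np.sum(tr.pf * tr.grid.cycle_fractions))
        assert oc.costs.acquisition == pytest.approx(expected, rel=1e-12)


class TestAgainstReportedCategories:
    """Category totals published for the base case, at coarse tolerances."""

    def test_monotherapy_acquisition_within_10pct(self, base_case):
        _, outcomes = base_case
        assert outcomes["capecitabine"].costs.acquisition == pytest.approx(
            3_327.61, rel=0.10
        )

    def test_monotherapy_monitoring_within_10pct(self, base_case):
        _, outcomes = base_case
        assert outcomes["capecitabine"].costs.monitoring == pytest.approx(
            1_603.13, rel=0.10
        )

    def test_combination_terminal_within_5pct(self, base_case):
        _, outcomes = base_case
        assert outcomes["utidelone_capecitabine"].costs.terminal == pytest.approx(
            987.90, rel=0.05
        )

    def test_override_mode_reports_published_ae_and_pd_totals(self, base_case):
        _, outcomes = base_case
        comb = outcomes["utidelone_capecitabine"].costs
        assert comb.ae == 855.63
        assert comb.pd_management == 496.50
        # the mechanistic AE value is reported alongside and differs
        assert comb.mechanistic_ae == pytest.approx(232.49, abs=0.5)
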