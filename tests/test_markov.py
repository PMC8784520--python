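"""Cohort engine: occupancy partition, time-to-death utilities, accrual, ICER."""

import numpy as np
import pytest

from pembrocea import CostEffectivenessModel
from pembrocea.markov import (
    AccrualInputs,
    StrategyResult,
    TimeToDeathUtilities,
    accrue,
    build_trace,
    icer,
    time_to_death_utility,
)
from pembrocea.survival import LogLogisticParams, SurvivalCurve, loglogistic_curve

NONSQ_OS = loglogistic_curve(LogLogisticParams(0.03084, 0.92588))
NONSQ_PFS = loglogistic_curve(LogLogisticParams(0.01422, 1.80138))
U_NONSQ = TimeToDeathUtilities(u_le1=0.563, u_1_6=0.709, u_6_12=0.765, u_ge12=0.834)


def flat_curve(value=1.0):
    return SurvivalCurve(lambda t: np.full_like(t, value), "parametric")


def zero_inputs(horizon=240, **kw):
    defaults = dict(
        drug_admin_cost=np.zeros(horizon), visit_cost=0.0, imaging_cost=0.0,
        imaging_interval=3, bsc_cost=0.0, subsequent_cost=0.0, subsequent_uptake=0.5,
        death_cost=0.0, ae_cost=0.0, ae_qaly_decrement=0.0,
    )
    defaults.update(kw)
    return AccrualInputs(**defaults)


class TestBuildTrace:
    def test_immortal_untreated_cohort_frozen_in_pfs_on_treatment(self):
        trace = build_trace(flat_curve(), flat_curve(), {"pembrolizumab": 0.0}, 24)
        assert np.all(trace.pfs_on == 1.0)
        assert np.all(trace.pd == 0.0) and np.all(trace.dead == 0.0)

    def test_on_treatment_fraction_decays_by_discontinuation(self):
        p = 0.005559  # monotherapy per-cycle discontinuation
        trace = build_trace(NONSQ_OS, NONSQ_PFS, {"pembrolizumab": p}, 240)
        s_pfs_12 = min(NONSQ_PFS(12.0), NONSQ_OS(12.0))
        assert trace.pfs_on[12] == pytest.approx(s_pfs_12 * (1 - p) ** 12, rel=1e-12)
        assert trace.on_drug["pembrolizumab"][12] == pytest.approx(
            s_pfs_12 * (1 - p) ** 12, rel=1e-12
        )

    def test_occupancy_conserved_and_death_monotone(self):
        trace = build_trace(
            NONSQ_OS, NONSQ_PFS, {"a": 0.01, "b": 0.012}, 240
        )
        trace.check()
        total = trace.pfs_on + trace.pfs_off + trace.pd + trace.dead
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(trace.on_drug["a"] <= trace.pfs + 1e-12)

    def test_crossing_curves_clip_pd_to_zero(self, caplog):
        os_low = SurvivalCurve(lambda t: np.exp(-0.05 * t), "parametric")
        pfs_high = SurvivalCurve(lambda t: np.exp(-0.02 * t), "parametric")
        with caplog.at_level("WARNING"):
            trace = build_trace(os_low, pfs_high, {}, 60)
        assert np.all(trace.pd == 0.0)
        assert any("clipping" in r.message for r in caplog.records)

    def test_invalid_discontinuation_probability(self):
        with pytest.raises(ValueError):
            build_trace(NONSQ_OS, NONSQ_PFS, {"x": 1.5}, 12)


class TestTimeToDeathUtility:
    def test_immortal_patient_gets_the_far_from_death_utility(self):
        assert time_to_death_utility(flat_curve(), 10.0, U_NONSQ) == pytest.approx(0.834)

    def test_certain_death_within_a_month(self):
        cliff = SurvivalCurve(lambda t: np.where(t <= 10.0, 1.0, 0.0), "parametric")
        assert time_to_death_utility(cliff, 10.0, U_NONSQ) == pytest.approx(0.563)

    def test_mixed_prognosis_lies_between_extremes(self):
        u = time_to_death_utility(NONSQ_OS, 0.0, U_NONSQ)
        assert 0.563 < u < 0.834

    def test_no_survivors_raises(self):
        dead = SurvivalCurve(lambda t: np.where(t < 5, 1.0, 0.0), "parametric")
        with pytest.raises(ZeroDivisionError):
            time_to_death_utility(dead, 20.0, U_NONSQ)


class TestAccrue:
    def test_immortal_cohort_undiscounted_qalys(self):
        trace = build_trace(flat_curve(), flat_curve(), {}, 240)
        res = accrue(trace, zero_inputs(), U_NONSQ, flat_curve(), discount_rate=0.0)
        assert res.qalys == pytest.approx(0.834 * 20.0, rel=1e-12)
        assert res.life_years == pytest.approx(20.0, rel=1e-12)

    def test_all_utilities_one_makes_qalys_equal_life_years(self):
        ones = TimeToDeathUtilities(1.0, 1.0, 1.0, 1.0)
        trace = build_trace(NONSQ_OS, NONSQ_PFS, {"d": 0.01}, 240)
        res = accrue(trace, zero_inputs(), ones, NONSQ_OS, discount_rate=0.03)
        assert res.qalys == pytest.approx(res.life_years, rel=1e-12)

    def test_discounting_a_single_cost_at_one_year(self):
        # the whole cohort's death registers at the cycle starting t=12 mo
        cliff = SurvivalCurve(lambda t: np.where(t < 12.0, 1.0, 0.0), "parametric")
        trace = build_trace(cliff, cliff, {}, 240)
        res = accrue(trace, zero_inputs(death_cost=1.0), U_NONSQ, cliff, discount_rate=0.03)
        assert res.cost == pytest.approx(1.0 / 1.03, rel=1e-9)

    def test_terminal_cost_conservation(self):
        # certain death well before the horizon: total undiscounted
        # terminal-care spend equals one package per patient
        trace = build_trace(NONSQ_OS, NONSQ_PFS, {}, 240)
        dead_by_end = trace.dead[-1]
        res = accrue(
            trace, zero_inputs(death_cost=9433.0), U_NONSQ, NONSQ_OS, discount_rate=0.0
        )
        assert res.cost_undiscounted == pytest.approx(9433.0 * dead_by_end, rel=1e-9)

    def test_discounted_never_exceeds_undiscounted(self):
        trace = build_trace(NONSQ_OS, NONSQ_PFS, {"d": 0.01}, 240)
        inputs = zero_inputs(visit_cost=183.19, imaging_cost=117.59, death_cost=9433.0)
        res = accrue(trace, inputs, U_NONSQ, NONSQ_OS, discount_rate=0.03)
        assert res.cost <= res.cost_undiscounted
        assert res.qalys <= res.qalys_undiscounted
        assert res.qalys <= res.life_years


class TestIcer:
    def make(self, cost, qalys):
        return StrategyResult(
            cost=cost, qalys=qalys, life_years=max(qalys, 0.0), qalys_pfs=0.0,
            qalys_pd=0.0, cost_undiscounted=cost, qalys_undiscounted=qalys,
            life_years_undiscounted=max(qalys, 0.0),
        )

    def test_simple_ratio(self):
        out = icer(self.make(100.0, 2.0), self.make(0.0, 0.0))
        assert out.icer == pytest.approx(50.0)

    def test_published_rounded_increments(self):
        out = icer(self.make(182182.0, 1.08), self.make(0.0, 0.0))
        assert out.icer == pytest.approx(182182.0 / 1.08, rel=1e-12)
        assert round(out.icer) == 168687

    def test_dominated_and_dominant_flags(self):
        assert icer(self.make(10.0, -0.5), self.make(0.0, 0.0)).flag == "dominated"
        assert icer(self.make(0.0, 0.5), self.make(10.0, 0.0)).flag == "dominant"

    def test_equal_effect_flag(self):
        out = icer(self.make(10.0, 1.0), self.make(0.0, 1.0))
        assert out.flag == "equal_effect" and out.icer is None


class TestModelLevelIdentities:
    def test_cost_linearity_doubling_every_cost_parameter(self, nonsq_params):
        model = CostEffectivenessModel(nonsq_params, mode="scenario1")
        base = model.run()
        doubled = {
            name: 2.0 * p.value
            for name, p in nonsq_params.parameters.items()
            if p.kind == "cost"
        }
        res = model.run(doubled)
        for arm_base, arm_2x in (
            (base.combination, res.combination),
            (base.monotherapy, res.monotherapy),
        ):
            assert arm_2x.cost == pytest.approx(2.0 * arm_base.cost, rel=1e-9)
            assert arm_2x.qalys == pytest.approx(arm_base.qalys, rel=1e-12)

    def test_zero_discount_exceeds_discounted(self, nonsq_params):
        model = CostEffectivenessModel(nonsq_params, mode="scenario1")
        disc = model.run()
        undisc = model.run({"discount_rate": 0.0})
        for a, b in ((undisc.combination, disc.combination), (undisc.monotherapy, disc.monotherapy)):
            assert a.cost > b.cost and a.qalys > b.qalys

    def test_arm_symmetry_identical_inputs(self, nonsq_params):
        # neutral hazard ratios + shared arm-specific inputs + a single
        # identical regimen per arm -> increments vanish exactly
        from pembrocea.parameters import ParameterSet

        ps = ParameterSet(
            nonsq_params.histology,
            dict(nonsq_params.parameters),
            {
                "pembro": nonsq_params.regimens["pembro"],
                "pembro_chemo": nonsq_params.regimens["pembro"],
            },
        )
        model = CostEffectivenessModel(ps, mode="scenario1")
        same = {
            "hr_os": 1.0,
            "hr_pfs": 1.0,
            "disc_pembro_combo": ps.value("disc_pembro_mono"),
            "ae_cost_pembro_chemo": ps.value("ae_cost_pembro"),
            "disutility_pembro_chemo": ps.value("disutility_pembro"),
            "subsequent_cost_pembro_chemo": ps.value("subsequent_cost_pembro"),
        }
        comp = model.run(same)
        assert comp.incremental.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert comp.incremental.delta_qalys == pytest.approx(0.0, abs=1e-12)
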