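"""QALY/cost accrual, cohort summaries and incremental net monetary
benefit."""
import numpy as np
import pandas as pd
import pytest

from sca1cea.config import EconParams
from sca1cea.econ import accrue, accrue_cohort, incremental, summarize
from sca1cea.engine import USUAL_CARE, PatientTrace, Strategy, run_cohort

UTILITIES = {"pre_ataxic": 0.94, "slight": 0.74, "moderate": 0.65,
             "severe": 0.38, "end_stage": 0.16}
COSTS = {"pre_ataxic": 110.50, "slight": 2041.78, "moderate": 9686.13,
         "severe": 39301.28, "end_stage": 66283.56}


def make_trace(states, on=None, patient_id=0):
    states = np.asarray(states, dtype=np.int8)
    return PatientTrace(
        patient_id=patient_id,
        rate=1.83,
        sara=np.zeros(len(states)),
        state=states,
        on_treatment=np.zeros(len(states), bool) if on is None else np.asarray(on, bool),
    )


def econ(qaly_rate=0.015, cost_rate=0.04):
    return EconParams(utility=UTILITIES, annual_cost=COSTS,
                      discount_rate_qaly=qaly_rate, discount_rate_cost=cost_rate)


class TestAccrue:
    def test_one_cycle_slight_undiscounted(self):
        out = accrue(make_trace([1]), econ(0.0, 0.0))
        assert out.qalys == pytest.approx(0.74)
        assert out.costs == pytest.approx(2041.78)
        assert out.survival_years == 1.0

    def test_two_cycles_pre_ataxic_discounted(self):
        out = accrue(make_trace([0, 0]), econ())
        assert out.qalys == pytest.approx(0.94 + 0.94 / 1.015)
        assert out.costs == pytest.approx(110.50 + 110.50 / 1.04)

    def test_zero_length_trace_accrues_nothing(self):
        out = accrue(make_trace([]), econ())
        assert out.qalys == 0.0 and out.costs == 0.0 and out.survival_years == 0.0

    def test_time_in_state_conserves_survival(self, small_cfg):
        traces = run_cohort(small_cfg.settings, USUAL_CARE,
                            small_cfg.progression, small_cfg.mortality)
        for trace in traces[:50]:
            out = accrue(trace, small_cfg.econ)
            assert sum(out.years_in_state.values()) == out.survival_years
            assert 0 <= out.qalys <= out.survival_years

    def test_treatment_years_counts_on_cycles(self):
        out = accrue(make_trace([0, 1, 1], on=[True, True, False]), econ())
        assert out.treatment_years == 2.0

    def test_cohort_frame_matches_per_trace_accrual(self, small_cfg):
        traces = run_cohort(small_cfg.settings.replace(n_patients=40), USUAL_CARE,
                            small_cfg.progression, small_cfg.mortality)
        frame = accrue_cohort(traces, small_cfg.econ)
        for trace in traces:
            out = accrue(trace, small_cfg.econ)
            row = frame.loc[trace.patient_id]
            assert row["qalys"] == pytest.approx(out.qalys)
            assert row["costs"] == pytest.approx(out.costs)
            assert row["years_moderate"] == out.years_in_state["moderate"]

    def test_zero_discounting_weakly_increases_both(self, small_cfg):
        traces = run_cohort(small_cfg.settings.replace(n_patients=60), USUAL_CARE,
                            small_cfg.progression, small_cfg.mortality)
        disc = accrue_cohort(traces, econ())
        flat = accrue_cohort(traces, econ(0.0, 0.0))
        assert (flat["qalys"] >= disc["qalys"] - 1e-12).all()
        assert (flat["costs"] >= disc["costs"] - 1e-12).all()


class TestSummarize:
    def test_identical_outcomes_zero_width_ci(self):
        frame = accrue_cohort([make_trace([1], patient_id=i) for i in range(5)], econ())
        result = summarize(frame, "x")
        mean, lo, hi = result.stats["qalys"]
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_two_point_mean(self):
        frame = pd.DataFrame(
            {"qalys": [0.0, 2.0], "costs": [0.0, 0.0], "survival_years": [1, 1],
             "treatment_years": [0, 0],
             **{f"years_{n}": [0.0, 0.0] for n in UTILITIES}},
            index=pd.Index([0, 1], name="patient_id"))
        result = summarize(frame, "x")
        assert result.mean("qalys") == 1.0
        lo, hi = result.ci("qalys")
        assert lo < 1.0 < hi

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(), "x")


class TestIncremental:
    # Table-style printed inputs: (strategy, effectiveness, delta costs,
    # delta QALYs, published iNMB).  Printed inputs are rounded, so the
    # identity reproduces the published iNMB only within rounding slack.
    PRINTED_ROWS = [
        ("full_treatment", 0.25, 5079, 2.44, 190_165),
        ("start_at_slight", 0.25, 6217, 2.31, 178_648),
        ("start_at_moderate", 0.25, 11_872, 1.12, 77_734),
        ("stop_after_moderate", 0.25, -3604, 2.21, 180_754),
        ("stop_after_severe", 0.25, 3686, 2.42, 189_598),
        ("full_treatment", 0.50, 324, 6.68, 534_274),
        ("start_at_slight", 0.50, 3385, 6.27, 498_372),
        ("start_at_moderate", 0.50, 27_241, 3.11, 221_557),
        ("stop_after_moderate", 0.50, -14_048, 6.15, 505_732),
        ("stop_after_severe", 0.50, -755, 6.65, 533_115),
    ]

    @pytest.mark.parametrize("name,eff,dc,dq,published", PRINTED_ROWS)
    def test_identity_reproduces_published_inmb_within_rounding(self, name, eff, dc, dq, published):
        assert abs(80_000 * dq - dc - published) < 600

    def test_identity_holds_to_machine_precision(self, small_cfg):
        usual_tr = run_cohort(small_cfg.settings, USUAL_CARE,
                              small_cfg.progression, small_cfg.mortality)
        arm_strategy = Strategy("full", 0.0, None, 0.5)
        arm_tr = run_cohort(small_cfg.settings, arm_strategy,
                            small_cfg.progression, small_cfg.mortality)
        usual = summarize(accrue_cohort(usual_tr, small_cfg.econ), USUAL_CARE, seed=11)
        arm = summarize(accrue_cohort(arm_tr, small_cfg.econ), arm_strategy, seed=11)
        inc = incremental(arm, usual, small_cfg.econ)
        identity = small_cfg.econ.wtp_threshold * inc.delta_qalys - inc.delta_costs
        assert inc.inmb == pytest.approx(identity, rel=1e-12, abs=1e-6)
        assert inc.yearly_inmb == pytest.approx(inc.inmb / arm.mean("treatment_years"))
        assert inc.inmb_ci[0] <= inc.inmb <= inc.inmb_ci[1]

    def test_null_contrast_is_zero(self, small_cfg):
        usual_tr = run_cohort(small_cfg.settings, USUAL_CARE,
                              small_cfg.progression, small_cfg.mortality)
        usual = summarize(accrue_cohort(usual_tr, small_cfg.econ), USUAL_CARE, seed=11)
        inc = incremental(usual, usual, small_cfg.econ)
        assert inc.inmb == 0.0 and inc.delta_qalys == 0.0

    def test_mismatched_cohorts_rejected(self, small_cfg):
        frame = accrue_cohort(
            run_cohort(small_cfg.settings.replace(n_patients=10), USUAL_CARE,
                       small_cfg.progression, small_cfg.mortality), small_cfg.econ)
        small = summarize(frame, "a", seed=11)
        smaller = summarize(frame.iloc[:5], "b", seed=11)
        with pytest.raises(ValueError, match="cohort sizes"):
            incremental(small, smaller, small_cfg.econ)
        other_seed = summarize(frame, "c", seed=12)
        with pytest.raises(ValueError, match="seeds"):
            incremental(small, other_seed, small_cfg.econ)
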