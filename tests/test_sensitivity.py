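"""One-way DSA tornado and discount-rate scenarios."""
import numpy as np
import pytest

from sca1cea.config import ConfigError
from sca1cea.econ import accrue_cohort
from sca1cea.engine import USUAL_CARE, Strategy, run_cohort
from sca1cea.sensitivity import (
    DsaSpec,
    default_dsa_specs,
    discount_scenarios,
    one_way_dsa,
    paired_incremental,
)

FULL_50 = Strategy("full_treatment", 0.0, None, 0.5)


@pytest.fixture(scope="module")
def tiny_cfg(cfg):
    return cfg.replace(settings=cfg.settings.replace(n_patients=200, seed=17))


class TestDsaSpec:
    def test_default_parameter_set(self, cfg):
        specs = default_dsa_specs(cfg)
        names = [s.name for s in specs]
        assert names[0] == "progression_rate"
        assert sum(n.startswith("utility_") for n in names) == 4  # no pre-ataxic CI
        assert sum(n.startswith("cost_") for n in names) == 5
        for spec in specs:
            assert spec.low <= spec.high

    def test_joint_cost_mode(self, cfg):
        specs = default_dsa_specs(cfg, joint_costs=True)
        assert any(s.kind == "cost_all" for s in specs)
        assert sum(s.kind == "cost" for s in specs) == 0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            DsaSpec("x", "nope", 0, 1)
        with pytest.raises(ValueError):
            DsaSpec("x", "utility", 1, 0, state="slight")
        with pytest.raises(ValueError):
            DsaSpec("x", "utility", 0.2, 0.4, state="slight", base=0.9)


class TestOneWayDsa:
    def test_base_value_reruns_bit_identical(self, tiny_cfg):
        a = paired_incremental(tiny_cfg, FULL_50)
        b = paired_incremental(tiny_cfg, FULL_50)
        assert a.inmb == b.inmb
        assert a.delta_qalys == b.delta_qalys

    def test_degenerate_spec_swing_zero(self, tiny_cfg):
        base_u = float(tiny_cfg.econ.utility["slight"])
        spec = DsaSpec("utility_slight", "utility", base_u, base_u, state="slight")
        (row,) = one_way_dsa([spec], FULL_50, tiny_cfg)
        assert row.swing == 0.0
        assert row.inmb_at_low == paired_incremental(tiny_cfg, FULL_50).inmb

    def test_slower_progression_raises_inmb(self, tiny_cfg):
        spec = DsaSpec("progression_rate", "progression_mean",
                       tiny_cfg.progression.ci_low, tiny_cfg.progression.ci_high,
                       base=tiny_cfg.progression.mean_rate)
        (row,) = one_way_dsa([spec], FULL_50, tiny_cfg)
        base = paired_incremental(tiny_cfg, FULL_50).inmb
        assert row.inmb_at_low > base > row.inmb_at_high

    def test_rows_sorted_by_descending_swing(self, tiny_cfg):
        rows = one_way_dsa(default_dsa_specs(tiny_cfg)[:4], FULL_50, tiny_cfg)
        swings = [r.swing for r in rows]
        assert swings == sorted(swings, reverse=True)

    def test_cost_swing_matches_trace_level_oracle(self, tiny_cfg):
        """Varying the end-stage cost +/-20% changes the iNMB by exactly
        the paired difference in discounted end-stage exposure, recomputed
        from the stored traces by brute force."""
        base_cost = float(tiny_cfg.econ.annual_cost["end_stage"])
        spec = DsaSpec("cost_end_stage", "cost",
                       0.8 * base_cost, 1.2 * base_cost, state="end_stage", base=base_cost)
        (row,) = one_way_dsa([spec], FULL_50, tiny_cfg)

        def discounted_end_stage_exposure(traces):
            rate = tiny_cfg.econ.discount_rate_cost
            total = 0.0
            for tr in traces:
                factors = (1 + rate) ** -np.arange(tr.n_cycles, dtype=float)
                total += float(factors[tr.state == 4].sum())
            return total / len(traces)

        usual_tr = run_cohort(tiny_cfg.settings, USUAL_CARE,
                              tiny_cfg.progression, tiny_cfg.mortality)
        arm_tr = run_cohort(tiny_cfg.settings, FULL_50,
                            tiny_cfg.progression, tiny_cfg.mortality)
        delta_exposure = (discounted_end_stage_exposure(arm_tr)
                          - discounted_end_stage_exposure(usual_tr))
        expected = -(1.2 - 0.8) * base_cost * delta_exposure
        assert row.inmb_at_high - row.inmb_at_low == pytest.approx(expected, rel=1e-9)


class TestDiscountScenarios:
    def test_qaly_discount_monotone_decreasing(self, tiny_cfg):
        table = discount_scenarios([(0.0, 0.04), (0.015, 0.04), (0.05, 0.04)],
                                   FULL_50, tiny_cfg)
        inmb = table["inmb"].to_numpy()
        assert inmb[0] > inmb[1] > inmb[2]

    def test_cost_discount_monotone_increasing(self, tiny_cfg):
        table = discount_scenarios([(0.015, 0.0), (0.015, 0.04), (0.015, 0.05)],
                                   FULL_50, tiny_cfg)
        inmb = table["inmb"].to_numpy()
        assert inmb[0] < inmb[1] < inmb[2]

    def test_null_effect_inmb_zero_at_any_rates(self, tiny_cfg):
        null = Strategy("full_treatment", 0.0, None, 0.0)
        table = discount_scenarios([(0.0, 0.0), (0.05, 0.05)], null, tiny_cfg)
        assert (table["inmb"] == 0.0).all()

    def test_negative_rates_rejected(self, tiny_cfg):
        with pytest.raises(ConfigError):
            discount_scenarios([(-0.01, 0.04)], FULL_50, tiny_cfg)
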