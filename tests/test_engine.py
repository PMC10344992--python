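"""Microsimulation engine: cycle mechanics, strategies, common random
numbers."""
import numpy as np
import pytest

from sca1cea.config import DEFAULT_STATES, MortalityParams, SimulationSettings
from sca1cea.engine import (
    USUAL_CARE,
    Strategy,
    paper_strategies,
    run_cohort,
    simulate_patient,
    traces_to_frame,
)

from conftest import plateau_mortality


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestStrategy:
    def test_five_paper_strategies_expressible(self):
        by_name = {s.name: s for s in paper_strategies(0.5)}
        assert by_name["full_treatment"].start_sara == 0
        assert by_name["full_treatment"].stop_sara is None
        assert by_name["start_at_slight"].start_sara == 2
        assert by_name["start_at_moderate"].start_sara == 14
        assert by_name["stop_after_moderate"].stop_sara == 26
        assert by_name["stop_after_severe"].stop_sara == 34
        assert all(s.effectiveness == 0.5 for s in by_name.values())

    def test_invalid_effectiveness_rejected(self):
        with pytest.raises(ValueError):
            Strategy("x", 0.0, None, 1.5)

    def test_stop_must_exceed_start(self):
        with pytest.raises(ValueError):
            Strategy("x", 14.0, 10.0, 0.2)


class TestSimulatePatient:
    def test_deterministic_ceiling_death_after_22_cycles(self, no_mortality):
        """With mortality off, a 1.83/year progressor lives ceil(40/1.83)
        = 22 cycles and dies in the cycle during which SARA reaches 40."""
        trace = simulate_patient(0, 1.83, USUAL_CARE, no_mortality, DEFAULT_STATES, _rng())
        assert trace.n_cycles == 22
        assert trace.sara[-1] == pytest.approx(1.83 * 21)
        assert trace.sara[-1] < 40 <= trace.sara[-1] + 1.83
        assert trace.died_this_cycle[-1]
        assert trace.died_this_cycle[:-1].sum() == 0

    def test_sara_non_decreasing_and_states_never_regress(self, cfg):
        trace = simulate_patient(0, 1.2, USUAL_CARE, cfg.mortality, DEFAULT_STATES, _rng(3))
        assert np.all(np.diff(trace.sara) >= 0)
        assert np.all(np.diff(trace.state) >= 0)

    def test_stop_after_moderate_switches_off_permanently(self, no_mortality):
        strategy = Strategy("stop_after_moderate", 0.0, 26.0, 0.0)
        trace = simulate_patient(0, 1.83, strategy, no_mortality, DEFAULT_STATES, _rng())
        on = trace.on_treatment
        assert on[trace.sara <= 26].all()
        assert not on[trace.sara > 26].any()
        # no restart once off
        first_off = int(np.argmin(on))
        assert not on[first_off:].any()

    def test_start_at_slight_waits_for_sara_above_2(self, no_mortality):
        strategy = Strategy("start_at_slight", 2.0, None, 0.0)
        trace = simulate_patient(0, 1.83, strategy, no_mortality, DEFAULT_STATES, _rng())
        assert (trace.on_treatment == (trace.sara > 2)).all()

    def test_effectiveness_halves_progression_while_on(self, no_mortality):
        strategy = Strategy("full", 0.0, None, 0.5)
        trace = simulate_patient(0, 2.0, strategy, no_mortality, DEFAULT_STATES, _rng())
        assert np.allclose(np.diff(trace.sara), 1.0)


class TestRunCohort:
    def test_same_seed_bit_identical(self, small_cfg):
        kwargs = dict(
            settings=small_cfg.settings,
            strategy=USUAL_CARE,
            progression=small_cfg.progression,
            mortality=small_cfg.mortality,
        )
        a, b = run_cohort(**kwargs), run_cohort(**kwargs)
        for ta, tb in zip(a, b):
            assert ta.rate == tb.rate
            assert np.array_equal(ta.sara, tb.sara)
            assert np.array_equal(ta.on_treatment, tb.on_treatment)

    def test_null_effect_matches_usual_care_trajectories(self, small_cfg):
        """Any strategy at effectiveness 0 under CRN reproduces the
        usual-care health trajectory exactly; only the treatment flag
        (drug administration bookkeeping) differs."""
        usual = run_cohort(small_cfg.settings, USUAL_CARE, small_cfg.progression, small_cfg.mortality)
        for base in paper_strategies(0.0):
            arm = run_cohort(small_cfg.settings, base, small_cfg.progression, small_cfg.mortality)
            for tu, ta in zip(usual, arm):
                assert np.array_equal(tu.sara, ta.sara)
                assert np.array_equal(tu.state, ta.state)
                assert tu.n_cycles == ta.n_cycles

    def test_common_random_numbers_share_rate_draws(self, small_cfg):
        full = Strategy("full", 0.0, None, 0.5)
        usual = run_cohort(small_cfg.settings, USUAL_CARE, small_cfg.progression, small_cfg.mortality)
        arm = run_cohort(small_cfg.settings, full, small_cfg.progression, small_cfg.mortality)
        assert [t.rate for t in usual] == [t.rate for t in arm]

    def test_higher_effectiveness_never_shortens_any_life(self, small_cfg):
        base = Strategy("full", 0.0, None, 0.0)
        lives = {}
        for eff in (0.25, 0.5):
            traces = run_cohort(
                small_cfg.settings, base.with_effectiveness(eff),
                small_cfg.progression, small_cfg.mortality)
            lives[eff] = np.array([t.n_cycles for t in traces])
        assert (lives[0.5] >= lives[0.25]).all()

    def test_unit_mortality_gives_exactly_one_cycle(self, small_cfg):
        mort = plateau_mortality(0.0, background=1.0)
        traces = run_cohort(small_cfg.settings, USUAL_CARE, small_cfg.progression, mort)
        assert all(t.n_cycles == 1 for t in traces)

    def test_full_effectiveness_freezes_sara_at_zero(self, small_cfg):
        strategy = Strategy("full", 0.0, None, 1.0)
        mort = plateau_mortality(1.0, background=0.05)
        settings = SimulationSettings(n_patients=50, seed=5)
        traces = run_cohort(settings, strategy, small_cfg.progression, mort)
        for t in traces:
            assert np.all(t.sara == 0.0)
            assert np.all(t.state == 0)
            assert t.on_treatment.all()


class TestTraceFrame:
    def test_long_format_dump(self, small_cfg):
        traces = run_cohort(
            small_cfg.settings.replace(n_patients=5), USUAL_CARE,
            small_cfg.progression, small_cfg.mortality)
        frame = traces_to_frame(traces)
        assert set(frame.columns) == {
            "patient_id", "cycle", "sara", "state", "on_treatment", "alive_at_cycle_end"}
        assert len(frame) == sum(t.n_cycles for t in traces)
        # exactly one terminal record per patient
        assert (~frame["alive_at_cycle_end"]).sum() == 5
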