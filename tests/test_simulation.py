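"""Cohort and microsimulation engines: discounting, accrual arithmetic,
conservation, determinism and cross-engine agreement."""

import dataclasses

import numpy as np
import pytest

from bphce.parameters import set_field
from bphce.simulation import (
    accumulate_outcomes,
    discount_factor,
    event_log_from_history,
    run_cohort,
    run_microsimulation,
)
from bphce.states import Arm, StateId
from bphce.synthetic import ToyModelSpec, closed_form_occupancy, make_toy_model

from conftest import with_horizon


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(1, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(7, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestCohortEngine:
    def test_absorbing_full_health_gives_horizon_qalys(self):
        toy = make_toy_model(ToyModelSpec(n_states=2, p_stay=1.0, utility=1.0,
                                          horizon_years=4, discount_rate=0.0))
        res, _ = run_cohort(toy, Arm.MONOTHERAPY)
        assert res.total_qaly == pytest.approx(4.0)
        assert res.total_cost == 0.0

    @pytest.mark.parametrize("p_stay, rate, horizon", [
        (0.5, 0.0, 3), (0.9, 0.03, 2), (0.7, 0.05, 10), (1.0, 0.0, 4)])
    def test_matches_geometric_series_oracle(self, p_stay, rate, horizon):
        util, cost = 0.8, 137.0
        toy = make_toy_model(ToyModelSpec(n_states=2, p_stay=p_stay, utility=util,
                                          annual_cost=cost, horizon_years=horizon,
                                          discount_rate=rate))
        res, _ = run_cohort(toy, Arm.MONOTHERAPY)
        expect = closed_form_occupancy(p_stay, rate, horizon)
        assert res.total_qaly == pytest.approx(expect * util, abs=1e-9)
        assert res.total_cost == pytest.approx(expect * cost, abs=1e-9)

    def test_occupancy_conserved_and_death_monotone(self, base_params):
        for arm in Arm:
            _, trace = run_cohort(with_horizon(base_params, 35), arm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.occupancy[:, StateId.DEATH]) >= -1e-12)
            assert (trace.occupancy >= 0).all()

    def test_cost_categories_sum_to_total(self, base_params):
        res, _ = run_cohort(base_params, Arm.COMBINATION)
        assert sum(res.cost_breakdown.values()) == pytest.approx(res.total_cost, abs=1e-9)

    def test_discounting_reduces_both_totals(self, base_params):
        undisc = set_field(base_params, "settings.discount_rate", 0.0)
        r0, _ = run_cohort(undisc, Arm.MONOTHERAPY)
        r3, _ = run_cohort(base_params, Arm.MONOTHERAPY)
        assert r0.total_cost >= r3.total_cost
        assert r0.total_qaly >= r3.total_qaly

    def test_qaly_bounded_by_horizon(self, base_params):
        res, _ = run_cohort(base_params, Arm.COMBINATION)
        assert 0.0 < res.total_qaly <= base_params.settings.horizon_years


class TestMonotonicity:
    def test_higher_utility_weakly_raises_qalys(self, base_params):
        lo, _ = run_cohort(base_params, Arm.MONOTHERAPY)
        hi, _ = run_cohort(set_field(base_params, "utilities.u_bph", 0.92),
                           Arm.MONOTHERAPY)
        assert hi.total_qaly >= lo.total_qaly

    def test_higher_cost_weakly_raises_total_cost(self, base_params):
        lo, _ = run_cohort(base_params, Arm.MONOTHERAPY)
        hi, _ = run_cohort(set_field(base_params, "costs.turp_procedure", 8119.0),
                           Arm.MONOTHERAPY)
        assert hi.total_cost >= lo.total_cost

    def test_stronger_surgery_protection_lowers_turp_count(self, base_params):
        weak, _ = run_cohort(set_field(base_params, "efficacy.rrr_turp", 0.577),
                             Arm.COMBINATION)
        strong, _ = run_cohort(set_field(base_params, "efficacy.rrr_turp", 0.795),
                               Arm.COMBINATION)
        assert strong.episodes["turp_procedures"] <= weak.episodes["turp_procedures"]


class TestMicrosimulation:
    def test_seed_reproducibility(self, base_params):
        r1, h1 = run_microsimulation(base_params, Arm.COMBINATION, 500, seed=11)
        r2, h2 = run_microsimulation(base_params, Arm.COMBINATION, 500, seed=11)
        assert r1.total_cost == r2.total_cost
        assert r1.total_qaly == r2.total_qaly
        assert np.array_equal(h1, h2)

    def test_seed_required(self, base_params):
        with pytest.raises(ValueError, match="seed"):
            run_microsimulation(base_params, Arm.COMBINATION, 10)

    def test_agrees_with_cohort_within_monte_carlo_error(self, base_params):
        n = 200_000
        cohort, _ = run_cohort(base_params, Arm.MONOTHERAPY)
        micro, hist = run_microsimulation(base_params, Arm.MONOTHERAPY, n, seed=5)
        # per-patient discounted QALYs for an honest standard error
        u = np.zeros(len(StateId))
        u[StateId.BPH] = base_params.utilities.u_bph
        u[StateId.AUR] = base_params.utilities.u_aur
        u[StateId.TURP] = u[StateId.REPEAT_TURP] = base_params.utilities.u_turp
        u[StateId.MEDICAL_INTERVENTION] = base_params.utilities.u_medical
        u[StateId.RECOVERY] = base_params.utilities.u_recovery
        T = base_params.settings.horizon_years
        disc = (1 + base_params.settings.discount_rate) ** (-np.arange(T))
        per_patient = (u[hist[:, :-1]] * disc).sum(axis=1)
        se = per_patient.std(ddof=1) / np.sqrt(n)
        assert micro.total_qaly == pytest.approx(per_patient.mean())
        assert abs(micro.total_qaly - cohort.total_qaly) <= 3 * se
        assert abs(micro.total_cost - cohort.total_cost) / cohort.total_cost < 0.02

    def test_alive_plus_dead_conservation(self, base_params):
        _, hist = run_microsimulation(base_params, Arm.MONOTHERAPY, 1000, seed=3)
        n_states_per_cycle = (hist >= 0).sum(axis=0)
        assert (n_states_per_cycle == 1000).all()


class TestAccumulation:
    def test_constant_bph_occupancy_drug_cost(self, base_params):
        p = set_field(base_params, "settings.discount_rate", 0.0)
        hist = np.full((1, 5), int(StateId.BPH))
        res = accumulate_outcomes(hist, p, Arm.MONOTHERAPY)
        assert res.cost_breakdown["drug"] == pytest.approx(4 * 55.79)
        assert res.cost_breakdown["bph"] == pytest.approx(4 * 471.0)
        assert res.total_qaly == pytest.approx(4 * 0.876)

    def test_immediate_death_accrues_nothing(self, base_params):
        hist = np.full((3, 5), int(StateId.DEATH))
        res = accumulate_outcomes(hist, base_params, Arm.COMBINATION)
        assert res.total_cost == 0.0
        assert res.total_qaly == 0.0
        assert res.episodes["deaths"] == 1.0

    def test_idempotent_on_stored_log(self, base_params):
        res, hist = run_microsimulation(base_params, Arm.COMBINATION, 400, seed=9)
        again = accumulate_outcomes(hist, base_params, Arm.COMBINATION)
        assert again.total_cost == res.total_cost
        assert again.total_qaly == res.total_qaly
        assert again.episodes == res.episodes

    def test_horizon_mismatch_rejected(self, base_params):
        hist = np.full((2, 7), int(StateId.BPH))
        with pytest.raises(ValueError, match="cycles"):
            accumulate_outcomes(hist, base_params, Arm.MONOTHERAPY)

    def test_out_of_range_state_rejected(self, base_params):
        hist = np.full((2, 5), 9)
        with pytest.raises(ValueError, match="state"):
            accumulate_outcomes(hist, base_params, Arm.MONOTHERAPY)

    def test_event_log_lists_state_entries(self, base_params):
        _, hist = run_microsimulation(base_params, Arm.MONOTHERAPY, 50, seed=21)
        logs = event_log_from_history(hist)
        assert len(logs) == 50
        for entries in logs:
            assert entries[0] == (0, StateId.BPH)
            cycles = [c for c, _ in entries]
            assert cycles == sorted(cycles)
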