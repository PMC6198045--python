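"""One-way and probabilistic sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

from bphce.economics import net_monetary_benefit
from bphce.parameters import ParameterDistribution, ParameterRange, set_field
from bphce.sensitivity import (
    PSAScatter,
    compute_ceac,
    quadrant_shares,
    run_owsa,
    run_psa,
    sample_psa_parameters,
)

N_PSA = 400  # small but seed-stable Monte Carlo size for suite runtime


@pytest.fixture(scope="module")
def scatter4(base_params):
    return run_psa(base_params, n=N_PSA, horizon=4, seed=123)


class TestOwsa:
    def test_degenerate_range_has_zero_spread(self, base_params):
        base_val = base_params.efficacy.rrr_aur
        table = run_owsa(base_params,
                         ranges=[ParameterRange("efficacy.rrr_aur", base_val, base_val)],
                         horizon=4)
        entry = table.entries[0]
        assert entry.spread == 0.0
        assert entry.icer_at_low == pytest.approx(table.base_icer)

    def test_sorted_by_spread_descending(self, base_params):
        table = run_owsa(base_params, horizon=4)
        spreads = [e.spread for e in table.entries if np.isfinite(e.spread)]
        assert spreads == sorted(spreads, reverse=True)
        assert len(table.entries) == len(base_params.owsa_ranges)

    def test_informational_stay_probabilities_do_not_move_icer(self, base_params):
        """Printed stay values are inert under the residual-mass rule."""
        table = run_owsa(base_params,
                         ranges=[ParameterRange("transitions.p_bph_stay", 0.248, 0.45)],
                         horizon=4)
        assert table.entries[0].spread == pytest.approx(0.0)

    def test_range_excluding_base_rejected(self, base_params):
        with pytest.raises(ValueError, match="outside"):
            run_owsa(base_params,
                     ranges=[ParameterRange("efficacy.rrr_aur", 0.9, 0.95)],
                     horizon=4)

    def test_deterministic(self, base_params):
        t1 = run_owsa(base_params, horizon=4)
        t2 = run_owsa(base_params, horizon=4)
        assert t1 == t2


class TestPsaSampling:
    def test_beta_sample_mean_matches_published_efficacy(self, base_params):
        dist = ParameterDistribution("efficacy.rrr_aur", "beta", 1.77, 0.85)
        draws, _ = sample_psa_parameters([dist], 10_000, seed=1, base=base_params)
        vals = np.array([d.efficacy.rrr_aur for d in draws])
        mean = 1.77 / (1.77 + 0.85)
        se = np.sqrt(mean * (1 - mean) / (1.77 + 0.85 + 1) / len(vals))
        assert abs(vals.mean() - mean) <= 3 * se

    def test_gamma_mean_override_recovers_published_mean(self, base_params):
        dist = ParameterDistribution("costs.turp_procedure", "gamma", 12.59, 0.002,
                                     mean_override=6334.0)
        draws, _ = sample_psa_parameters([dist], 10_000, seed=2, base=base_params)
        vals = np.array([d.costs.turp_procedure for d in draws])
        se = 6334.0 / np.sqrt(12.59 * len(vals))
        assert abs(vals.mean() - 6334.0) <= 3 * se

    def test_unsampled_fields_stay_at_base(self, base_params):
        draws, _ = sample_psa_parameters(base_params.psa_distributions, 5,
                                         seed=3, base=base_params)
        for d in draws:
            assert d.utilities == base_params.utilities
            assert d.costs.annual_drug_combination == 464.97
            assert d.transitions.p_aur_to_turp == 0.8

    def test_empty_request_gives_empty_list(self, base_params):
        draws, resampled = sample_psa_parameters(base_params.psa_distributions, 0,
                                                 seed=4, base=base_params)
        assert draws == [] and resampled == 0

    def test_family_target_mismatch_rejected(self, base_params):
        bad = ParameterDistribution("costs.turp_procedure", "beta", 2.0, 2.0)
        with pytest.raises(ValueError, match="beta"):
            sample_psa_parameters([bad], 1, seed=0, base=base_params)

    def test_reproducible_under_seed(self, base_params):
        a, _ = sample_psa_parameters(base_params.psa_distributions, 10, seed=5,
                                     base=base_params)
        b, _ = sample_psa_parameters(base_params.psa_distributions, 10, seed=5,
                                     base=base_params)
        assert a == b


class TestRunPsa:
    def test_bit_reproducible_under_seed(self, base_params, scatter4):
        again = run_psa(base_params, n=N_PSA, horizon=4, seed=123)
        assert np.array_equal(again.delta_cost, scatter4.delta_cost)
        assert np.array_equal(again.delta_qaly, scatter4.delta_qaly)

    def test_no_effect_null_collapses_qaly_gain(self, base_params):
        """With both relative risk reductions forced to zero the arms
        share one disease course: the QALY gain vanishes and the cost
        difference is pure drug acquisition."""
        null = set_field(set_field(base_params, "efficacy.rrr_aur", 0.0),
                         "efficacy.rrr_turp", 0.0)
        dists = tuple(d for d in null.psa_distributions
                      if not d.target.startswith("efficacy."))
        null = dataclasses.replace(null, psa_distributions=dists)
        sc = run_psa(null, n=50, horizon=4, seed=7)
        assert np.allclose(sc.delta_qaly, 0.0, atol=1e-12)
        assert (sc.delta_cost > 0.0).all()

    def test_quadrant_shares_sum_to_one(self, scatter4):
        assert sum(quadrant_shares(scatter4).values()) == pytest.approx(1.0)


class TestCeac:
    def test_at_zero_wtp_probability_is_cost_saving_share(self, scatter4):
        curve = compute_ceac(scatter4, [0.0])
        assert curve.probability[0] == pytest.approx(
            float((scatter4.delta_cost < 0).mean()))

    def test_probabilities_bounded(self, scatter4, base_params):
        curve = compute_ceac(scatter4, base_params.settings.wtp_grid)
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()

    def test_two_path_equivalence_with_nmb(self, scatter4):
        """CEAC from the scatter equals the draw-by-draw NMB computation."""
        grid = [0.0, 10_000.0, 45_887.0, 137_661.0]
        curve = compute_ceac(scatter4, grid)
        for w, p in zip(curve.wtp, curve.probability):
            manual = np.mean([
                net_monetary_benefit(c, q, w) > 0
                for c, q in zip(scatter4.delta_cost, scatter4.delta_qaly)])
            assert p == pytest.approx(manual)

    def test_empty_scatter_rejected(self):
        empty = PSAScatter(delta_cost=np.array([]), delta_qaly=np.array([]),
                           seed=0, horizon_years=4)
        with pytest.raises(ValueError, match="empty"):
            compute_ceac(empty, [0.0])
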