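"""One-way/tornado analysis, distribution fitting, PSA, CEAC, CE plane."""

import numpy as np
import pandas as pd
import pytest

from markovcea import (SAParam, ce_plane, ceac, default_sa_params, fit_beta,
                       fit_gamma, one_way, psa_params, run_psa, tornado)
from markovcea.errors import InfeasibleScenarioError, InvalidSpreadError
from markovcea.sensitivity import _Sampler


class TestFitBeta:
    def test_symmetric_closed_form(self):
        a, b = fit_beta(0.5, 0.4, 0.6)
        assert a == pytest.approx(47.52, abs=0.01)
        assert b == pytest.approx(a)

    def test_published_range_recovers_mean(self):
        a, b = fit_beta(0.243, 0.1944, 0.2916)
        rng = np.random.default_rng(42)
        draws = rng.beta(a, b, 100_000)
        assert abs(draws.mean() - 0.243) < 0.005

    def test_excessive_spread_rejected(self):
        with pytest.raises(InvalidSpreadError):
            fit_beta(0.5, 0.0, 1.0 + 0.97)  # lo/hi invalid
        with pytest.raises(InvalidSpreadError):
            fit_beta(0.02, 0.0, 0.9)        # variance beyond mean(1-mean)


class TestFitGamma:
    def test_closed_form(self):
        shape, scale = fit_gamma(100.0, 80.0, 120.0)
        assert shape == pytest.approx(96.04, abs=0.01)
        assert scale == pytest.approx(1.0412, abs=0.001)

    def test_sampled_mean_recovered(self):
        shape, scale = fit_gamma(100.0, 80.0, 120.0)
        rng = np.random.default_rng(7)
        draws = rng.gamma(shape, scale, 100_000)
        assert abs(draws.mean() - 100.0) / 100.0 < 0.01

    def test_degenerate_interval_becomes_point_mass(self):
        param = SAParam("cost", estimate=500.0, lo=500.0, hi=500.0,
                        family="gamma")
        sampler = _Sampler(param)
        assert sampler.kind == "point"
        assert np.all(sampler.sample(np.random.default_rng(0), 10) == 500.0)


class TestOneWay:
    def test_degenerate_range_zero_swing(self, printed_model):
        param = SAParam("ACTH_sr", 0.243, 0.243, 0.243, "beta")
        res = one_way(printed_model, param)
        assert res.swing == 0.0

    def test_matches_hand_edited_reruns(self, printed_model):
        """One-way bounds reproduce explicit evaluate() calls."""
        param = SAParam("ACTH_sr", 0.243, 0.1944, 0.2916, "beta")
        res = one_way(printed_model, param, wtp=20_000.0)
        for bound, got in ((param.lo, res.output_lo), (param.hi, res.output_hi)):
            a, b, _ = printed_model.evaluate({"ACTH_sr": bound})
            expected = (20_000.0 * a.effect - a.cost) - (20_000.0 * b.effect
                                                         - b.cost)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_infeasible_rebalance_raises(self, printed_model):
        # stable->relapse at 0.9 pushes the TCH stable row past 1
        param = SAParam("TCH_sp", 0.48, 0.384, 0.9, "beta")
        with pytest.raises(InfeasibleScenarioError):
            one_way(printed_model, param)

    def test_untouched_utility_zero_swing(self, printed_model):
        """Death utility is pinned at 0; a param spanning an unoccupied
        quantity produces no swing. Here: intervention cost at its base on
        both bounds."""
        param = SAParam("ACTH_intervention_cost", 3112.0, 3112.0, 3112.0,
                        "gamma")
        assert one_way(printed_model, param).swing == 0.0


class TestTornado:
    def test_single_param(self, printed_model):
        params = [SAParam("ACTH_sr", 0.243, 0.1944, 0.2916, "beta")]
        df = tornado(printed_model, params)
        assert len(df) == 1 and df.loc[0, "parameter"] == "ACTH_sr"

    def test_zero_swing_param_ranks_last(self, printed_model):
        params = [
            SAParam("ACTH_sr", 0.243, 0.1944, 0.2916, "beta"),
            SAParam("TCH_pd", 0.021, 0.021, 0.021, "beta"),
        ]
        df = tornado(printed_model, params)
        assert df.iloc[-1]["parameter"] == "TCH_pd"
        assert df.iloc[-1]["swing"] == 0.0

    def test_ordering_invariant_to_input_order(self, printed_model):
        params = default_sa_params(printed_model)
        fwd = tornado(printed_model, params)
        rev = tornado(printed_model, list(reversed(params)))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_remission_transitions_drive_the_model(self, printed_model):
        """Ranking the transition probabilities (the published tornado's
        scope), the widest bars include TCH remission-related transitions."""
        df = tornado(printed_model,
                     default_sa_params(printed_model,
                                       include=("probabilities",)))
        top5 = set(df.head(5)["parameter"])
        assert top5 & {"TCH_rr", "TCH_rp", "TCH_sr"}

    def test_cumulative_share_truncation(self, printed_model):
        params = default_sa_params(printed_model)
        full = tornado(printed_model, params)
        trunc = tornado(printed_model, params, cumulative_share=0.99)
        assert len(trunc) <= len(full)
        assert trunc["swing"].sum() >= 0.99 * full["swing"].sum() - 1e-9


class TestPSA:
    def test_point_masses_reproduce_base_case(self, printed_model):
        params = [SAParam(n, v, v, v, "beta" if v <= 1 else "gamma")
                  for n, v in printed_model.parameters().items()]
        res = run_psa(printed_model, params, n_sims=1, seed=0)
        a, b, inc = printed_model.evaluate()
        row = res.draws.iloc[0]
        assert row["delta_cost"] == pytest.approx(inc.delta_cost, rel=1e-12)
        assert row["delta_effect"] == pytest.approx(inc.delta_effect, rel=1e-12)

    def test_seed_determinism_bytes(self, printed_model):
        kw = dict(params=psa_params(printed_model), n_sims=25, seed=123)
        one = run_psa(printed_model, **kw).draws.to_csv(index=False)
        two = run_psa(printed_model, **kw).draws.to_csv(index=False)
        assert one == two

    def test_mean_near_base_case(self, printed_model):
        res = run_psa(printed_model, n_sims=400, seed=11)
        _, _, inc = printed_model.evaluate()
        dc = res.draws["delta_cost"]
        de = res.draws["delta_effect"]
        assert abs(dc.mean() - inc.delta_cost) < 4 * dc.std() / np.sqrt(len(dc))
        assert abs(de.mean() - inc.delta_effect) < 4 * de.std() / np.sqrt(len(de))

    def test_interval_widens_with_parameter_spread(self, printed_model):
        lo = run_psa(printed_model, psa_params(printed_model, fraction=0.1),
                     n_sims=300, seed=5)
        hi = run_psa(printed_model, psa_params(printed_model, fraction=0.3),
                     n_sims=300, seed=5)
        w = lambda r: np.subtract(*reversed(r.interval("delta_cost")))
        assert w(hi) > w(lo)


class TestCEAC:
    def test_probabilities_sum_to_one(self, printed_model):
        res = run_psa(printed_model, n_sims=200, seed=3)
        curves = ceac(res, [0.0, 20_000.0, 34_240.0, 100_000.0])
        sums = curves.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)
        assert ((curves["probability"] >= 0) & (curves["probability"] <= 1)).all()

    def test_matches_nmb_maximisation_draw_by_draw(self, printed_model):
        res = run_psa(printed_model, n_sims=100, seed=9)
        wtp = 20_000.0
        curves = ceac(res, [wtp])
        nmb_a = wtp * res.draws["effect_ACTH"] - res.draws["cost_ACTH"]
        nmb_b = wtp * res.draws["effect_TCH"] - res.draws["cost_TCH"]
        expected_a = float((nmb_a >= nmb_b).mean())
        got = curves.set_index("strategy")["probability"]
        assert got["ACTH"] == pytest.approx(expected_a)
        assert got["TCH"] == pytest.approx(1.0 - expected_a)

    def test_limits_reduce_to_cost_and_effect_rules(self, printed_model):
        res = run_psa(printed_model, n_sims=150, seed=21)
        curves = ceac(res, [0.0, 1e9])
        cheaper_a = (res.draws["cost_ACTH"] <= res.draws["cost_TCH"]).mean()
        at0 = curves[(curves["wtp"] == 0.0)
                     & (curves["strategy"] == "ACTH")]["probability"].iloc[0]
        assert at0 == pytest.approx(cheaper_a)
        more_eff_a = (res.draws["effect_ACTH"] >= res.draws["effect_TCH"]).mean()
        atinf = curves[(curves["wtp"] == 1e9)
                       & (curves["strategy"] == "ACTH")]["probability"].iloc[0]
        assert atinf == pytest.approx(more_eff_a)


class TestCEPlane:
    def test_quadrants_partition_draws(self, printed_model):
        res = run_psa(printed_model, n_sims=120, seed=4)
        plane = ce_plane(res, wtp=20_000.0)
        assert len(plane) == 120
        assert plane["quadrant"].isin(["I", "II", "III", "IV"]).all()

    def test_cheaper_more_effective_is_quadrant_iv(self, printed_model):
        res = run_psa(printed_model, n_sims=5, seed=1)
        res.draws.loc[:, "delta_effect"] = 1.0
        res.draws.loc[:, "delta_cost"] = -5.0
        plane = ce_plane(res, wtp=20_000.0)
        assert (plane["quadrant"] == "IV").all()
        assert plane["cost_effective_a"].all()

    def test_point_on_ray_counts_cost_effective(self, printed_model):
        res = run_psa(printed_model, n_sims=1, seed=1)
        res.draws.loc[:, "delta_effect"] = 0.5
        res.draws.loc[:, "delta_cost"] = 10_000.0   # exactly wtp * delta_e
        plane = ce_plane(res, wtp=20_000.0)
        assert plane["cost_effective_a"].all()
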