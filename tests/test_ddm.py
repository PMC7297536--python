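"""Diffusion simulator, bound trajectories, quantile/G-square machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupilbias import ddm


class TestBoundTrajectory:
    def test_origin(self):
        up, lo = ddm.bound_trajectory(ddm.BoundSpec(a=1.3, tau_urgency=2.0), 0.0)
        assert up == pytest.approx(1.3) and lo == pytest.approx(0.0)

    def test_bounds_meet_at_tau_and_stay(self):
        b = ddm.BoundSpec(a=2.0, tau_urgency=1.0)
        for t in (1.0, 1.5, 5.0):
            up, lo = ddm.bound_trajectory(b, t)
            assert up == pytest.approx(1.0) and lo == pytest.approx(1.0)

    def test_hyperbolic_value(self):
        # a=2, tau=1, t=0.5: collapse = 2*0.5/1.5 = 2/3
        up, lo = ddm.bound_trajectory(ddm.BoundSpec(a=2.0, tau_urgency=1.0), 0.5)
        assert up == pytest.approx(4.0 / 3.0)
        assert lo == pytest.approx(2.0 / 3.0)

    def test_constant_when_tau_absent(self):
        up, lo = ddm.bound_trajectory(ddm.BoundSpec(a=1.0), np.array([0.0, 3.0]))
        assert np.allclose(up, 1.0) and np.allclose(lo, 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ddm.bound_trajectory(ddm.BoundSpec(a=1.0), -0.1)


class TestSimulator:
    def test_symmetric_choice_probability(self):
        p = ddm.DDMParams(v=0.0, a=1.0, z_rel=0.5, t0=0.2)
        ch, _ = ddm.simulate_ddm(p, drifts=np.zeros(20000), seed=1)
        assert (ch == 1).mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20000))

    def test_urgency_bounds_terminate_all_paths(self):
        p = ddm.DDMParams(v=0.0, a=1.0, t0=0.2, tau_urgency=1.5)
        ch, rt = ddm.simulate_ddm(p, drifts=np.zeros(5000), seed=2)
        assert np.all(ch >= 0)
        assert np.nanmax(rt) <= 1.5 + 0.2 + 1e-9

    def test_dt_halving_stable_choice_probability(self):
        p = ddm.DDMParams(v=0.5, v_bias=0.5, a=1.0, t0=0.3)
        probs = []
        for dt in (0.002, 0.001):
            ch, _ = ddm.simulate_ddm(p, drifts=np.full(100_000, 1.0), seed=11, dt=dt)
            probs.append((ch == 1).mean())
        assert abs(probs[0] - probs[1]) < 0.005

    def test_drift_bias_shifts_choices_toward_yes(self):
        base = dict(a=1.0, t0=0.3)
        ch0, _ = ddm.simulate_ddm(ddm.DDMParams(v_bias=0.0, **base), drifts=np.zeros(8000), seed=3)
        chb, _ = ddm.simulate_ddm(ddm.DDMParams(v_bias=0.0, **base), drifts=np.full(8000, 0.5), seed=3)
        assert (chb == 1).mean() > (ch0 == 1).mean() + 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            ddm.DDMParams(a=-1).validate()
        with pytest.raises(ValueError):
            ddm.DDMParams(z_rel=1.2).validate()
        with pytest.raises(ValueError):
            ddm.DDMParams(tau_urgency=-0.5).validate()


class TestQuantilesAndGsquare:
    def test_quantiles_of_uniform_ranks(self):
        edges = ddm.rt_quantiles(np.arange(1.0, 11.0))
        assert edges[2] == pytest.approx(5.5)
        assert np.all(np.diff(edges) >= 0)

    def test_quantiles_all_equal_degenerate(self):
        edges = ddm.rt_quantiles(np.full(20, 0.7))
        assert np.allclose(edges, 0.7)

    def test_quantiles_match_exponential_inverse_cdf(self, rng):
        x = rng.exponential(scale=2.0, size=200_000)
        edges = ddm.rt_quantiles(x)
        expected = -2.0 * np.log1p(-np.array([0.1, 0.3, 0.5, 0.7, 0.9]))
        assert np.allclose(edges, expected, rtol=0.03)

    def test_too_few_rts_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            edges = ddm.rt_quantiles(np.array([0.4, 0.5]))
        assert edges.size == 1

    def test_gsquare_zero_when_observed_matches_expected(self):
        assert ddm.gsquare_statistic([10, 30, 60], [0.1, 0.3, 0.6]) == pytest.approx(0.0)

    def test_gsquare_hand_value(self):
        # 2 * 10 * ln 2
        assert ddm.gsquare_statistic([10, 0], [0.5, 0.5]) == pytest.approx(
            13.8629, abs=1e-4
        )

    @given(k=st.integers(min_value=2, max_value=6))
    @settings(max_examples=10, deadline=None)
    def test_gsquare_scales_linearly_with_counts(self, k):
        o = np.array([7, 3, 10])
        p = np.array([0.2, 0.3, 0.5])
        g1 = ddm.gsquare_statistic(o, p)
        gk = ddm.gsquare_statistic(k * o, p)
        assert gk == pytest.approx(k * g1, rel=1e-9)

    def test_gsquare_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ddm.gsquare_statistic([-1, 2], [0.5, 0.5])


class TestCRF:
    def test_all_yes(self):
        crf = ddm.conditional_response_function(np.ones(100), np.linspace(0.3, 1, 100))
        assert np.allclose(crf, 1.0)

    def test_symmetric_simulation_flat_half(self):
        p = ddm.DDMParams(v=0.0, a=1.0, t0=0.3)
        ch, rt = ddm.simulate_ddm(p, drifts=np.zeros(20000), seed=6)
        crf = ddm.conditional_response_function(ch, rt)
        assert np.allclose(crf, 0.5, atol=0.03)

    def test_startpoint_vs_driftbias_signatures(self):
        # a starting-point shift loads the fastest quantile bin; a drift
        # bias shifts the whole conditional response function
        n = 40000
        p_z = ddm.DDMParams(v=0.0, a=1.0, z_rel=0.65, t0=0.3)
        p_v = ddm.DDMParams(v=0.0, v_bias=0.7, a=1.0, z_rel=0.5, t0=0.3)
        ch_z, rt_z = ddm.simulate_ddm(p_z, drifts=np.zeros(n), seed=7)
        ch_v, rt_v = ddm.simulate_ddm(p_v, drifts=np.full(n, 0.7), seed=8)
        crf_z = ddm.conditional_response_function(ch_z, rt_z)
        crf_v = ddm.conditional_response_function(ch_v, rt_v)
        # starting point: effect concentrated early, decaying across bins
        assert crf_z[0] - crf_z[-1] > 0.15
        # drift bias: shifted at every bin, including the slowest
        assert np.all(crf_v > 0.55)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            ddm.conditional_response_function([1, 0], [0.3, 0.4])


class TestFitting:
    def test_objective_locally_optimal_at_generating_parameters(self, simple_trial_frame):
        spec = ddm.ModelSpec(
            free=("v", "a", "t0"), by_condition=(), fixed={"z_rel": 0.5, "sv": 0.0}
        )
        cells, levels = ddm._build_cells(simple_trial_frame, "yesno")
        args = (cells, spec, levels, ddm.DDMParams(), False, 5000, 1)
        truth = np.array([1.0, 1.0, 0.3])
        g0 = ddm._objective(truth, *args)
        for delta in ([0.3, 0, 0], [0, 0.3, 0], [0, 0, 0.08], [-0.3, 0, 0]):
            assert ddm._objective(truth + np.array(delta), *args) > g0

    def test_bic_compare_orders_and_ties(self):
        def mk(gsq, k, n=1000):
            return ddm.FitResult(
                params=ddm.DDMParams(), per_condition={}, gsq=gsq, n_trials=n,
                k_params=k, bic=gsq + k * np.log(n), converged=True,
                observed_bins={}, expected_bins={},
            )

        ranking = ddm.bic_compare({"small": mk(100, 3), "big": mk(100, 5)})
        assert ranking[0]["model"] == "small"
        assert not ranking[0]["tie"] and ranking[0]["delta"] == 0.0

    def test_bic_compare_rejects_mismatched_n(self):
        def mk(n):
            return ddm.FitResult(
                params=ddm.DDMParams(), per_condition={}, gsq=1.0, n_trials=n,
                k_params=1, bic=1.0, converged=True, observed_bins={}, expected_bins={},
            )

        with pytest.raises(ValueError):
            ddm.bic_compare({"a": mk(100), "b": mk(200)})

    def test_gonogo_cells_have_single_nogo_bin(self):
        rng = np.random.default_rng(0)
        n = 300
        df = pd.DataFrame(
            {
                "signal": np.tile([0, 1], n // 2),
                "choice": rng.integers(0, 2, n),
                "rt": rng.uniform(0.4, 1.0, n),
            }
        )
        df.loc[df["choice"] == 0, "rt"] = np.nan
        cells, _ = ddm._build_cells(df, "gonogo")
        for c in cells:
            assert c["counts"].size == 7  # 6 yes-RT bins + 1 no-go bin
            assert c["counts"].sum() == c["n"]

    def test_predict_behavior_metrics_sign_relations(self):
        # drift bias toward yes -> liberal criterion (c < 0)
        out = ddm.predict_behavior_metrics(
            ddm.DDMParams(v=1.0, v_bias=0.8, a=1.0, t0=0.3),
            n_trials=20000, seed=1,
        )
        assert out[0]["criterion"] < -0.1
        out0 = ddm.predict_behavior_metrics(
            ddm.DDMParams(v=1.0, v_bias=0.0, a=1.0, t0=0.3), n_trials=20000, seed=2
        )
        assert abs(out0[0]["criterion"]) < 0.05

    def test_dprime_increases_with_drift(self):
        ds = []
        for v in (0.5, 1.0, 2.0):
            out = ddm.predict_behavior_metrics(
                ddm.DDMParams(v=v, a=1.0, t0=0.3), n_trials=20000, seed=3
            )
            ds.append(out[0]["d_prime"])
        assert ds[0] < ds[1] < ds[2]
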