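import warnings

import numpy as np
import pytest

from larvataxis import (
    ModelParams,
    calibrate_tilted,
    field_from_coefficients,
    fit_beta_tilted,
    fit_temperature,
    greedy_limit_ni,
    joint_refine,
    select_angular_model,
    simulate_ensemble,
)
from larvataxis.errors import NonConvergenceWarning, UnreachableTargetError

# ensemble sizes for the quick calibration exercises in this module;
# accuracy-critical recovery checks run at larger sizes in the
# acceptance-oriented tests
QUICK = dict(n_larvae=15, n_replicates=8, step_cap=2000)


class TestGreedyLimit:
    def test_pure_gradient_limit_is_two_over_pi(self):
        # accepting exactly the darker half-plane of isotropic proposals
        # yields |ni| = 2/pi along the gradient axis
        field = field_from_coefficients(1000, -70, 0)
        params = ModelParams(T=1.0, beta=0.0)
        g = greedy_limit_ni(field, params, axis="x", n_samples=400_000)
        assert g == pytest.approx(2 / np.pi, rel=0.02)

    def test_sign_follows_gradient(self):
        field = field_from_coefficients(1000, 70, 0)
        g = greedy_limit_ni(field, ModelParams(T=1.0), axis="x")
        assert g < 0  # brighter toward +x drives larvae to -x


class TestFitTemperature:
    def test_zero_target_unreachable(self, tilted_field):
        with pytest.raises(UnreachableTargetError):
            fit_temperature(tilted_field, ModelParams(T=5.0), 0.0, axis="y")

    def test_beyond_greedy_limit_unreachable(self, tilted_field):
        with pytest.raises(UnreachableTargetError):
            fit_temperature(
                tilted_field, ModelParams(T=5.0, beta=0.0, seed=1), -0.9, axis="y",
                **QUICK,
            )

    def test_wrong_sign_unreachable(self, tilted_field):
        with pytest.raises(UnreachableTargetError):
            fit_temperature(
                tilted_field, ModelParams(T=5.0, beta=0.0, seed=1), +0.07, axis="y",
                **QUICK,
            )

    def test_converges_to_reachable_target(self, tilted_field):
        res = fit_temperature(
            tilted_field, ModelParams(T=5.0, beta=0.0, seed=2), -0.07, axis="y",
            tol=0.01, **QUICK,
        )
        assert res.converged
        assert abs(res.achieved["y"] + 0.07) <= 0.01
        assert res.params["T"] > 0
        assert len(res.trace) >= 2

    def test_temperature_recovery(self, tilted_field):
        t_true = 6.0
        gen = simulate_ensemble(
            tilted_field,
            ModelParams(T=t_true, beta=0.0, seed=3, max_accepted_steps=2000),
            n_larvae=15, n_replicates=8,
        )
        res = fit_temperature(
            tilted_field, ModelParams(T=2.0, beta=0.0, seed=4), gen.ni_y, axis="y",
            tol=0.005, **QUICK,
        )
        assert abs(res.params["T"] - t_true) / t_true < 0.20


class TestFitBetaTilted:
    def test_zero_directionality_target_gives_zero_beta(self, tilted_field):
        # target ni_x equal to the gradient-only value: no beta needed
        probe = fit_temperature(
            tilted_field, ModelParams(T=5.0, beta=0.0, seed=5), -0.07, axis="y",
            **QUICK,
        )
        base = simulate_ensemble(
            tilted_field,
            ModelParams(T=probe.params["T"], beta=0.0, seed=5, max_accepted_steps=2000),
            n_larvae=15, n_replicates=8,
        )
        res = fit_beta_tilted(
            tilted_field, ModelParams(T=5.0, seed=5), base.ni_x, -0.07, **QUICK
        )
        assert res.params["beta"] == 0.0
        assert res.converged

    def test_two_step_converges(self, tilted_field):
        res = fit_beta_tilted(
            tilted_field, ModelParams(T=5.0, seed=6), -0.25, -0.07, **QUICK
        )
        assert res.converged
        assert abs(res.achieved["x"] + 0.25) <= 0.01
        assert res.params["beta"] > 0

    def test_stage_identified_on_failure(self, tilted_field):
        with pytest.raises(UnreachableTargetError, match="stage 1"):
            fit_beta_tilted(
                tilted_field, ModelParams(T=5.0, seed=7), -0.25, -0.9, **QUICK
            )


class TestJointRefine:
    def test_fixed_point_returns_unchanged(self, tilted_field):
        # calibrate once, then refine from the calibrated point: one sweep
        cal = calibrate_tilted(
            tilted_field, ModelParams(T=5.0, seed=8), -0.25, -0.07, tol=0.01, **QUICK
        )
        res = joint_refine(
            tilted_field, ModelParams(T=5.0, seed=8),
            cal.params["beta"], cal.params["T"], (-0.25, -0.07), tol=0.015, **QUICK,
        )
        assert res.converged
        assert len([e for e in res.trace if "ni_x" in e]) == 1
        assert res.params["beta"] == cal.params["beta"]
        assert res.params["T"] == cal.params["T"]

    def test_perturbed_start_converges_back(self, tilted_field):
        cal = calibrate_tilted(
            tilted_field, ModelParams(T=5.0, seed=9), -0.25, -0.07, tol=0.01, **QUICK
        )
        res = joint_refine(
            tilted_field, ModelParams(T=5.0, seed=9),
            1.5 * cal.params["beta"], 0.7 * cal.params["T"], (-0.25, -0.07),
            tol=0.01, **QUICK,
        )
        assert res.converged
        assert abs(res.achieved["x"] + 0.25) <= 0.01
        assert abs(res.achieved["y"] + 0.07) <= 0.01

    def test_contradictory_targets_raise(self, tilted_field):
        # |ni_y| can never exceed the pure-gradient greedy bound
        # (2/pi scaled by the gradient direction, ~0.62 here)
        with pytest.raises(UnreachableTargetError):
            joint_refine(
                tilted_field, ModelParams(T=5.0, seed=10), 0.005, 5.0,
                (-0.25, -0.9), **QUICK,
            )

    def test_non_convergence_warns(self, tilted_field):
        with pytest.warns(NonConvergenceWarning):
            joint_refine(
                tilted_field, ModelParams(T=5.0, seed=11), 0.005, 5.0,
                (-0.25, -0.07), tol=1e-6, max_sweeps=3, **QUICK,
            )


class TestBetaRecovery:
    def test_median_recovery_over_ten_repetitions(self, tilted_field):
        betas = []
        for rep in range(10):
            gen = simulate_ensemble(
                tilted_field,
                ModelParams(T=8.75, beta=0.014, seed=7000 + 2 * rep,
                            max_accepted_steps=3000),
                n_larvae=20, n_replicates=15,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = calibrate_tilted(
                    tilted_field, ModelParams(T=5.0, seed=7001 + 2 * rep),
                    gen.ni_x, gen.ni_y, tol=0.005,
                    n_larvae=20, n_replicates=15, step_cap=3000,
                )
            betas.append(res.params["beta"])
        median = float(np.median(betas))
        assert abs(median - 0.014) / 0.014 < 0.15


class TestSelectAngularModel:
    def test_single_candidate_returned(self, pos_field):
        params = ModelParams(T=10.95, beta=0.014, seed=12)
        ens = simulate_ensemble(
            pos_field, ModelParams(T=10.95, beta=0.014, seed=13, max_accepted_steps=1500),
            n_larvae=10, n_replicates=5,
        )
        ref = ens.pooled_angular_distribution()
        scores = select_angular_model(
            ref, pos_field, params, [("power", 4)],
            n_larvae=10, n_replicates=5, step_cap=1500,
        )
        assert len(scores) == 1
        assert (scores[0].family, scores[0].n) == ("power", 4)
        assert scores[0].rms >= 0

    def test_cosine_family_self_recovery(self, pos_field):
        gen_params = ModelParams(
            T=10.95, beta=0.014, n=2, angular_family="cosine", seed=14,
            max_accepted_steps=2000,
        )
        ens = simulate_ensemble(pos_field, gen_params, n_larvae=15, n_replicates=8)
        ref = ens.pooled_angular_distribution()
        candidates = [("power", n) for n in (2, 4)] + [("cosine", n) for n in (1, 2, 4)]
        scores = select_angular_model(
            ref, pos_field, ModelParams(T=10.95, beta=0.014, seed=15), candidates,
            n_larvae=15, n_replicates=8, step_cap=2000,
        )
        assert scores[0].family == "cosine"
        assert scores[0].n == 2
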