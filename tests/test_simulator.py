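import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvataxis import (
    ModelParams,
    acceptance_probability,
    angular_weight,
    effective_beta,
    field_from_coefficients,
    navigation_index,
    propose_step,
    simulate_ensemble,
    simulate_larva,
    step_angle,
    step_weight,
)
from larvataxis.errors import CapExceededWarning, DomainError, ZeroStepError


class TestAngularWeight:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0, 1.0), (180, 0.0), (90, 1 - 0.5**4)],
    )
    def test_power_family_values(self, alpha, expected):
        assert angular_weight(alpha, 4, "power") == pytest.approx(expected)

    @pytest.mark.parametrize("family", ["power", "cosine"])
    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    def test_boundaries_and_monotonicity(self, family, n):
        a = np.linspace(0, 180, 721)
        f = angular_weight(a, n, family)
        assert f[0] == pytest.approx(1.0)
        assert f[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(f) <= 1e-12)
        assert np.all((f >= 0) & (f <= 1))

    def test_domain_error(self):
        with pytest.raises(DomainError):
            angular_weight(181.0, 4, "power")
        with pytest.raises(DomainError):
            angular_weight(-0.1, 4, "power")


class TestStepAngle:
    @pytest.mark.parametrize(
        "step,expected",
        [((1, 0), 0.0), ((-1, 0), 180.0), ((0, 1), 90.0), ((0, -1), 90.0)],
    )
    def test_folding(self, step, expected):
        assert step_angle((0, 0), step) == pytest.approx(expected)

    def test_zero_step(self):
        with pytest.raises(ZeroStepError):
            step_angle((1.0, 2.0), (1.0, 2.0))


class TestStepWeight:
    def test_constant_field_beta_zero(self, uniform_field):
        p = ModelParams(T=10, beta=0.0)
        assert step_weight(uniform_field, p, (0, 0), (3.7, -1.2)) == 0.0

    def test_away_step_has_intensity_term_only(self):
        f = field_from_coefficients(20, 0.5, 0)
        p = ModelParams(T=10, beta=0.7)
        w = step_weight(f, p, (0, 0), (-1, 0))
        # f(180)=0 so only dI = 0.5 W/m^2/cm * (-0.01 cm) survives
        assert w == pytest.approx(-0.005)

    def test_sigma_unit_conversion(self):
        f = field_from_coefficients(20, 0.5, 0)
        p = ModelParams(T=10, beta=0.0)
        # one sigma = 0.01 cm, so dI = 0.5 * 0.01
        assert step_weight(f, p, (0, 0), (1, 0)) == pytest.approx(0.005)

    def test_delta_sign_switch_flips_intensity_term(self):
        f = field_from_coefficients(20, 0.5, 0)
        w_fwd = step_weight(f, ModelParams(T=10), (0, 0), (1, 0))
        w_rev = step_weight(f, ModelParams(T=10, delta_sign=-1), (0, 0), (1, 0))
        assert w_rev == pytest.approx(-w_fwd)


class TestProposals:
    def test_moments_and_independence(self, rng):
        d = propose_step(rng, 1.0, size=100_000)
        n = len(d)
        assert abs(d[:, 0].mean()) < 3 / np.sqrt(n)
        assert abs(d[:, 1].mean()) < 3 / np.sqrt(n)
        assert d[:, 0].var() == pytest.approx(1.0, rel=0.05)
        assert d[:, 1].var() == pytest.approx(1.0, rel=0.05)
        assert abs(np.corrcoef(d[:, 0], d[:, 1])[0, 1]) < 0.01


class TestAcceptanceProbability:
    @pytest.mark.parametrize("w,t,expected", [(-5, 10, 1.0), (0, 10, 1.0), (10, 10, np.exp(-1))])
    def test_values(self, w, t, expected):
        assert acceptance_probability(w, t) == pytest.approx(expected, abs=1e-5)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)

    def test_empirical_frequency_matches_theory(self, rng):
        w, t, n = 3.0, 10.0, 100_000
        p = acceptance_probability(w, t)
        freq = (rng.random(n) < p).mean()
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestEffectiveBeta:
    def test_zenithal_source_kills_directionality(self):
        assert effective_beta(0.5, 90.0) == pytest.approx(0.0, abs=1e-16)

    def test_in_plane_source_keeps_full_weight(self):
        assert effective_beta(0.5, 0.0) == 0.5

    def test_published_projection(self):
        assert effective_beta(0.0183, 40.0) == pytest.approx(0.01402, abs=2e-5)


class TestSimulateLarva:
    def test_unbiased_chain_accepts_everything(self, uniform_field):
        p = ModelParams(T=10, beta=0.0, seed=5, max_accepted_steps=3000)
        t = simulate_larva(uniform_field, p)
        assert t.acceptance_rate == 1.0
        assert t.termination == "step_cap"
        assert tuple(t.positions[0]) == (0.0, 0.0)

    def test_boundary_termination(self, pos_field):
        p = ModelParams(T=10.95, beta=0.014, seed=6, boundary_radius_sigma=200.0)
        t = simulate_larva(pos_field, p)
        assert t.termination == "boundary"
        r = np.hypot(*t.positions[-1])
        r_prev = np.hypot(*t.positions[-2])
        assert r >= 200.0 > r_prev

    def test_near_greedy_limit_heads_away_from_source(self, uniform_field):
        # T = 0.01 * beta * <I>: essentially only ~180-degree steps accepted
        beta = 0.014
        p = ModelParams(
            T=0.01 * beta * 1000.0, beta=beta, seed=7,
            boundary_radius_sigma=60.0, max_accepted_steps=2000,
        )
        t = simulate_larva(uniform_field, p)
        assert navigation_index(t, "x") <= -0.9
        assert np.all(t.headings_deg > 150.0)

    def test_proposal_cap_warns_and_flags(self, uniform_field):
        beta = 0.014
        p = ModelParams(
            T=0.001 * beta * 1000.0, beta=beta, seed=8,
            max_proposals=2000, max_accepted_steps=2000,
        )
        with pytest.warns(CapExceededWarning):
            t = simulate_larva(uniform_field, p)
        assert t.termination == "proposal_cap"

    def test_rejections_add_no_displacement(self, pos_field):
        p = ModelParams(T=5.0, beta=0.014, seed=9, max_accepted_steps=500)
        t = simulate_larva(pos_field, p)
        assert t.n_proposals > t.n_accepted  # some rejections occurred
        assert np.all(t.step_lengths > 0)  # consecutive positions differ
        assert t.path_length == pytest.approx(t.step_lengths.sum())


class TestSimulateEnsemble:
    def test_determinism_bit_identical(self, tilted_field):
        p = ModelParams(T=8.75, beta=0.014, seed=42, max_accepted_steps=400)
        a = simulate_ensemble(tilted_field, p, n_larvae=4, n_replicates=2)
        b = simulate_ensemble(tilted_field, p, n_larvae=4, n_replicates=2)
        assert a.ni_x == b.ni_x and a.ni_y == b.ni_y
        for ra, rb in zip(a.trajectories, b.trajectories):
            for ta, tb in zip(ra, rb):
                np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_x_gradient_only_keeps_y_symmetric(self):
        field = field_from_coefficients(1000, 84, 0)
        p = ModelParams(T=10.0, beta=0.0, seed=43, max_accepted_steps=2000)
        ens = simulate_ensemble(field, p, n_larvae=15, n_replicates=10)
        assert abs(ens.ni_y) <= 0.01
        assert ens.ni_x < -0.02  # gradient drive is present

    def test_unbiased_chain_is_isotropic(self, uniform_field):
        p = ModelParams(T=10.0, beta=0.0, seed=44, max_accepted_steps=2000)
        ens = simulate_ensemble(uniform_field, p, n_larvae=10, n_replicates=5)
        dist = ens.pooled_angular_distribution()
        n = dist.n_steps
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        np.testing.assert_allclose(dist.probabilities, 1 / 6, atol=3 * se)

    def test_msd_grows_linearly_for_unbiased_chain(self, uniform_field):
        p = ModelParams(T=10.0, beta=0.0, seed=45, max_accepted_steps=1000)
        ens = simulate_ensemble(uniform_field, p, n_larvae=100, n_replicates=1)
        pos = np.stack([t.positions for t in ens.all_trajectories])
        msd = (pos**2).sum(axis=2).mean(axis=0)
        steps = np.arange(len(msd))
        r = np.corrcoef(steps, msd)[0, 1]
        assert r**2 > 0.99

    def test_theta90_with_beta_prime_equals_beta_zero(self):
        f90 = field_from_coefficients(1000, -70, 0, theta_deg=90.0)
        common = dict(seed=46, max_accepted_steps=2000)
        with_prime = ModelParams(T=9.5, beta_prime=0.1, **common)
        without = ModelParams(T=9.5, beta=0.0, **common)
        a = simulate_ensemble(f90, with_prime, n_larvae=10, n_replicates=8)
        b = simulate_ensemble(f90, without, n_larvae=10, n_replicates=8)
        # beta' projects to 0 at theta=90, so the chains are identical
        np.testing.assert_allclose(a.replicate_ni_x, b.replicate_ni_x)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(w=st.floats(0.01, 50.0), t=st.floats(0.1, 50.0))
def test_acceptance_probability_in_unit_interval(w, t):
    p = acceptance_probability(w, t)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(np.exp(-w / t))
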