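import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxstool import bayes
from saxstool.fixtures import NoiseSpec, default_q_grid, simulate_profile
from saxstool.forward import ComputedProfile
from saxstool.profiles import SAXSProfile


def _profile(I, s=None, q=None):
    I = np.asarray(I, dtype=float)
    s = np.ones_like(I) if s is None else np.asarray(s, dtype=float)
    q = np.linspace(0.01, 0.3, I.size) if q is None else q
    return SAXSProfile(q=q, intensity=I, error=s)


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        exp = _profile([2.0, 4.0, 6.0])
        assert bayes.chi_square(exp, np.array([1.0, 2.0, 3.0]), gamma=2.0) == 0.0

    def test_hand_evaluated_two_point_example(self):
        exp = _profile([1.0, 2.0])
        assert bayes.chi_square(exp, np.array([1.0, 1.0]), gamma=1.0) == pytest.approx(0.5)

    def test_quadratic_error_scaling(self, rng):
        I = rng.normal(10, 1, 40)
        m = rng.normal(10, 1, 40)
        base = bayes.chi_square(_profile(I), m, 1.0)
        doubled = bayes.chi_square(_profile(I, s=np.full(40, 2.0)), m, 1.0)
        assert doubled == pytest.approx(base / 4.0)

    def test_length_mismatch(self):
        with pytest.raises(bayes.ScoreError):
            bayes.chi_square(_profile([1.0, 2.0]), np.array([1.0]))


class TestMapGamma:
    def test_exact_proportionality(self, rng):
        m = np.abs(rng.normal(5, 1, 30)) + 1
        assert bayes.map_gamma(_profile(2.0 * m), m) == pytest.approx(2.0)
        assert bayes.map_gamma(_profile(m), m) == pytest.approx(1.0)

    def test_matches_dense_scan_oracle(self, rng):
        m = np.abs(rng.normal(5, 2, 50)) + 1
        I = 1.7 * m + rng.normal(0, 0.5, 50)
        s = np.abs(rng.normal(0.5, 0.1, 50)) + 0.2
        exp = _profile(I, s=s)
        ghat = bayes.map_gamma(exp, m)
        scan = np.linspace(ghat - 0.01, ghat + 0.01, 20001)
        chis = [(bayes.chi_square(exp, m, g), g) for g in scan]
        g_scan = min(chis)[1]
        assert ghat == pytest.approx(g_scan, abs=1e-6)
        assert bayes.chi_square(exp, m, ghat) <= min(chis)[0] + 1e-12

    def test_degenerate_all_zero_calc(self):
        with pytest.raises(bayes.ScoreError, match="degenerate"):
            bayes.map_gamma(_profile([1.0, 2.0]), np.zeros(2))

    def test_negative_gamma_warns(self):
        with pytest.warns(UserWarning, match="gamma"):
            bayes.map_gamma(_profile([-5.0, -6.0]), np.array([1.0, 1.0]))


class TestMapSigma:
    @pytest.mark.parametrize("chi2,expected", [(4.0, 2.0), (1.0, 1.0)])
    def test_closed_form(self, chi2, expected):
        assert bayes.map_sigma(chi2) == expected

    def test_matches_numeric_minimizer(self):
        # 1-D minimization of (M/2s^2)*chi2 + M*log(s) at fixed chi2 = 2.7
        from scipy.optimize import minimize_scalar

        chi2, M = 2.7, 100
        res = minimize_scalar(
            lambda s: M / (2 * s ** 2) * chi2 + M * np.log(s), bounds=(0.1, 10), method="bounded",
            options={"xatol": 1e-12},
        )
        assert bayes.map_sigma(chi2) == pytest.approx(res.x, abs=1e-8)

    def test_exact_fit_floors_at_sigma_min(self):
        with pytest.warns(UserWarning, match="floor"):
            assert bayes.map_sigma(0.0) == bayes.SIGMA_MIN


class TestNegLogLikelihood:
    def test_plug_in_value(self):
        exp = _profile([1.0, 2.0, 3.0, 4.0])
        calc = np.array([1.0, 2.0, 3.0, 4.0]) + np.array([1.0, -1.0, 1.0, -1.0])  # chi2 = 1
        nll = bayes.neg_log_likelihood(exp, calc, bayes.NuisanceParams(gamma=1.0, sigma=1.0))
        assert nll == pytest.approx(exp.M / 2.0)

    def test_value_at_map_sigma_is_half_m_times_one_plus_log_chi2(self, rng):
        m = np.abs(rng.normal(5, 1, 60)) + 1
        exp = _profile(1.3 * m + rng.normal(0, 1, 60))
        gamma = bayes.map_gamma(exp, m)
        chi2 = bayes.chi_square(exp, m, gamma)
        sigma = bayes.map_sigma(chi2)
        nll = bayes.neg_log_likelihood(exp, m, bayes.NuisanceParams(gamma=gamma, sigma=sigma))
        assert nll == pytest.approx(exp.M / 2.0 * (1.0 + np.log(chi2)))

    def test_increasing_sigma_beyond_optimum_increases_score(self, rng):
        m = np.abs(rng.normal(5, 1, 30)) + 1
        exp = _profile(m + rng.normal(0, 1, 30))
        gamma = bayes.map_gamma(exp, m)
        sigma0 = bayes.map_sigma(bayes.chi_square(exp, m, gamma))
        vals = [
            bayes.neg_log_likelihood(exp, m, bayes.NuisanceParams(gamma=gamma, sigma=s))
            for s in sigma0 * np.array([1.0, 1.5, 2.5, 5.0])
        ]
        assert np.all(np.diff(vals) > 0)


class TestMarginalScore:
    def test_chi2_one_scores_zero(self):
        exp = _profile([1.0, 2.0, 3.0, 4.0])
        calc = np.array([2.0, 1.0, 4.0, 3.0])  # residuals +-1, chi2 = 1
        assert bayes.marginal_score(exp, calc, gamma=1.0) == pytest.approx(0.0)

    def test_monotone_in_chi2(self, rng):
        m = np.abs(rng.normal(5, 1, 40)) + 1
        exp = _profile(m + rng.normal(0, 1, 40))
        good = bayes.marginal_score(exp, m, gamma=1.0)
        worse = bayes.marginal_score(exp, 0.5 * m, gamma=1.0)
        assert worse > good

    def test_equals_nll_at_map_up_to_constant(self, rng):
        m = np.abs(rng.normal(5, 1, 40)) + 1
        exp = _profile(1.1 * m + rng.normal(0, 1, 40))
        gamma = bayes.map_gamma(exp, m)
        chi2 = bayes.chi_square(exp, m, gamma)
        sigma = bayes.map_sigma(chi2)
        nll = bayes.neg_log_likelihood(exp, m, bayes.NuisanceParams(gamma=gamma, sigma=sigma))
        assert bayes.marginal_score(exp, m, gamma) == pytest.approx(nll - exp.M / 2.0)


class TestRestraintWeight:
    def test_plug_in(self):
        nuis = bayes.NuisanceParams(sigma=1.0)
        assert bayes.restraint_weight(nuis, M=100) == 50.0

    def test_halving_chi2_doubles_weight_at_map(self):
        w1 = 100 / (2 * bayes.map_sigma(2.0) ** 2)
        w2 = 100 / (2 * bayes.map_sigma(1.0) ** 2)
        assert w2 == pytest.approx(2 * w1)

    def test_weight_trace_antitone_with_chi2_trace(self):
        # at MAP sigma the weight is M/2chi2: decreasing chi2 => increasing weight
        chis = np.array([8.0, 5.0, 5.0, 3.0, 2.5, 1.2])
        weights = 100 / (2 * np.array([bayes.map_sigma(c) ** 2 for c in chis]))
        assert np.all(np.diff(weights) >= 0)


class TestNuisanceValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(gamma=-1.0), dict(sigma=0.0), dict(c1=0.9), dict(c1=1.2), dict(c2=-3.0), dict(c2=5.0)]
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(bayes.ScoreError):
            bayes.NuisanceParams(**kwargs)


class TestOptimizeC1C2:
    def test_recovers_generating_values_with_tiny_noise(self, atom_cluster):
        q = default_q_grid(100)
        exp = simulate_profile(
            atom_cluster, q, 1.0, c1=1.02, c2=1.5, noise=NoiseSpec(relative=1e-6, floor_frac=1e-8, seed=2)
        )
        nuis = bayes.optimize_c1_c2(exp, atom_cluster)
        # final grid spacings: 0.001 in c1, 0.06 in c2
        assert nuis.c1 == pytest.approx(1.02, abs=1e-3 + 1e-9)
        assert nuis.c2 == pytest.approx(1.5, abs=0.06 + 1e-9)

    def test_flat_model_ties_break_row_major(self, dock_target):
        flat = ComputedProfile(q=dock_target.q, intensity=dock_target.intensity.copy())

        def constant_forward(molecule, q, c1, c2, **kw):
            return flat

        nuis = bayes.optimize_c1_c2(dock_target, None, forward_model=constant_forward)
        # every cell ties; the first cell in c1-major order wins
        assert nuis.c1 == pytest.approx(0.95)
        assert nuis.c2 == pytest.approx(-2.0)

    def test_boundary_best_keeps_refinement_inside_bounds(self, dock_target):
        # a shape distortion vanishing at c1 = 1.05 puts the optimum on the boundary
        bump = np.sin(50 * dock_target.q) * dock_target.intensity.mean()

        def forward(molecule, q, c1, c2, **kw):
            return ComputedProfile(q=q, intensity=dock_target.intensity + (1.05 - c1) * bump)

        nuis = bayes.optimize_c1_c2(dock_target, None, forward_model=forward)
        assert bayes.C1_BOUNDS[0] <= nuis.c1 <= bayes.C1_BOUNDS[1]
        assert nuis.c1 == pytest.approx(1.05)


class TestJointMapProperty:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_gamma_sigma_jointly_minimize_nll(self, seed):
        rng = np.random.default_rng(seed)
        m = np.abs(rng.normal(5, 2, 40)) + 1
        exp = _profile(1.5 * m + rng.normal(0, 1, 40))
        gamma = bayes.map_gamma(exp, m)
        chi2 = bayes.chi_square(exp, m, gamma)
        sigma = bayes.map_sigma(chi2)
        best = bayes.neg_log_likelihood(exp, m, bayes.NuisanceParams(gamma=gamma, sigma=sigma))
        for dg in (-0.05, 0.05):
            for ds in (0.9, 1.1):
                other = bayes.neg_log_likelihood(
                    exp, m, bayes.NuisanceParams(gamma=max(gamma + dg, 1e-9), sigma=sigma * ds)
                )
                assert other >= best - 1e-9
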