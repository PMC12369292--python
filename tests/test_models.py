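import math

import numpy as np
import pytest
from scipy.stats import binom

from ccbmd import (
    ContinuousInput,
    DatasetError,
    DichotomousInput,
    eval_model,
    log_binom_coeff,
    loglik_continuous,
    loglik_dichotomous,
)


class TestEvalModel:
    def test_quantal_linear_flat_curve(self):
        f = eval_model("quantal_linear", np.array([0.1, 0.0]), [0.0, 10.0, 1e6])
        assert f == pytest.approx([0.1, 0.1, 0.1])

    def test_quantal_linear_closed_form(self):
        f = eval_model("quantal_linear", np.array([0.1, 0.001]), [1000.0])
        assert f[0] == pytest.approx(0.1 + 0.9 * (1 - math.exp(-1)), abs=1e-10)
        assert f[0] == pytest.approx(0.6689, abs=1e-4)

    def test_hill_half_max_identity(self):
        # at d = k the Hill term contributes v/2 regardless of the power
        for p in (1.0, 2.5, 7.0):
            f = eval_model("hill", np.array([0.3, 1.0, 50.0, p]), [50.0])
            assert f[0] == pytest.approx(0.3 + 0.5)

    def test_dichotomous_hill_limits(self):
        theta = np.array([0.1, 0.5, -3.0, 1.0])
        f_small = eval_model("dichotomous_hill", theta, [1e-9])
        f_large = eval_model("dichotomous_hill", theta, [1e9])
        assert f_small[0] == pytest.approx(0.1, abs=1e-6)
        # saturates at g + v(1-g)
        assert f_large[0] == pytest.approx(0.1 + 0.5 * 0.9, abs=1e-6)

    def test_dichotomous_hill_rejects_zero_dose(self):
        with pytest.raises(DatasetError):
            eval_model("dichotomous_hill", np.array([0.1, 0.5, 0.0, 1.0]), [0.0])

    @pytest.mark.parametrize(
        "name, theta",
        [
            ("quantal_linear", np.array([0.05, 0.002])),
            ("dichotomous_hill", np.array([0.05, 0.8, -2.0, 1.5])),
        ],
    )
    def test_dichotomous_models_nondecreasing(self, name, theta):
        d = np.linspace(0.01, 2000, 500)
        f = eval_model(name, theta, d)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((f > 0) & (f < 1))

    def test_vectorized_over_parameter_stack(self):
        thetas = np.array([[0.1, 0.001], [0.2, 0.01]])
        f = eval_model("quantal_linear", thetas, [10.0, 100.0])
        assert f.shape == (2, 2)
        single = eval_model("quantal_linear", thetas[1], [10.0, 100.0])
        assert f[1] == pytest.approx(single)


class TestLoglikDichotomous:
    def test_single_group_closed_form(self):
        data = DichotomousInput(doses=[1.0], n=[2.0], y=[1.0])
        # f = 0.5 at any dose with g=0.5, beta=0
        ll = loglik_dichotomous("quantal_linear", np.array([0.5, 0.0]), data)
        assert ll == pytest.approx(math.log(2) - 2 * math.log(2), abs=1e-12)

    def test_matches_binomial_pmf_oracle(self):
        """Integer inputs reproduce the scipy binomial log-pmf sum to 1e-10."""
        rng = np.random.default_rng(0)
        doses = np.array([0.0, 10.0, 50.0, 200.0])
        theta = np.array([0.08, 0.003])
        f = eval_model("quantal_linear", theta, doses)
        n = np.array([40.0, 55.0, 60.0, 45.0])
        y = rng.binomial(n.astype(int), f).astype(float)
        data = DichotomousInput(doses=doses, n=n, y=y)
        oracle = sum(
            binom.logpmf(int(yi), int(ni), fi) for yi, ni, fi in zip(y, n, f)
        )
        assert loglik_dichotomous("quantal_linear", theta, data) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_gamma_extension_continuous_in_y(self):
        """Real-valued counts interpolate smoothly between integer neighbors."""
        theta = np.array([0.1, 0.01])
        lls = []
        for y in (1.0, 1.25, 1.5, 1.75, 2.0):
            data = DichotomousInput(doses=[20.0], n=[3.2], y=[y])
            lls.append(loglik_dichotomous("quantal_linear", theta, data))
        assert all(np.isfinite(lls))
        ll_int = [lls[0], lls[-1]]
        assert min(ll_int) - 1.0 < lls[2] < max(ll_int) + 1.0
        # fine-grained continuity
        eps_diff = abs(
            loglik_dichotomous(
                "quantal_linear", theta, DichotomousInput([20.0], [3.2], [1.5 + 1e-7])
            )
            - lls[2]
        )
        assert eps_diff < 1e-5

    def test_zero_responders_at_zero_probability_limit(self):
        data = DichotomousInput(doses=[0.0, 1.0], n=[10.0, 12.0], y=[0.0, 0.0])
        ll = loglik_dichotomous("quantal_linear", np.array([1e-12, 1e-12]), data)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_probability_one_against_nonresponders_is_minus_inf(self):
        data = DichotomousInput(doses=[1.0], n=[10.0], y=[5.0])
        ll = loglik_dichotomous("quantal_linear", np.array([1.0 - 1e-18, 5.0]), data)
        assert ll == -np.inf


class TestLoglikContinuous:
    def test_residual_free_single_group(self):
        data = ContinuousInput(doses=[10.0], n=[1.0], mean_log=[0.3], sd_log=[0.0])
        # linear model passing exactly through the mean
        ll = loglik_continuous("linear", np.array([0.3, 0.0]), 0.5, data)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * 0.25), abs=1e-12)

    def test_matches_independent_summation(self):
        """Two-group toy agrees with a directly coded normal-density sum."""
        data = ContinuousInput(
            doses=[0.0, 1.0], n=[10.0, 10.0], mean_log=[0.0, 0.5], sd_log=[0.0, 0.2]
        )
        theta = np.array([0.0, 0.5])  # linear: passes through both means
        gamma = 0.3
        ll = loglik_continuous("linear", theta, gamma, data)
        assert ll == pytest.approx(3.700685422425264, abs=1e-10)

    def test_translation_invariance(self):
        data = ContinuousInput(
            doses=[0.0, 5.0, 20.0],
            n=[30.0, 25.0, 40.0],
            mean_log=[0.0, 0.4, 1.1],
            sd_log=[0.0, 0.3, 0.25],
        )
        base = loglik_continuous("linear", np.array([0.1, 0.05]), 0.4, data)
        shifted_data = ContinuousInput(
            doses=data.doses, n=data.n, mean_log=data.mean_log + 2.5, sd_log=data.sd_log
        )
        shifted = loglik_continuous("linear", np.array([2.6, 0.05]), 0.4, shifted_data)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_nonpositive_gamma_rejected(self):
        data = ContinuousInput(doses=[1.0], n=[5.0], mean_log=[0.1], sd_log=[0.0])
        with pytest.raises(DatasetError):
            loglik_continuous("linear", np.array([0.0, 0.1]), 0.0, data)


@pytest.mark.parametrize(
    "track, name, theta_true",
    [
        ("dichotomous", "quantal_linear", np.array([0.1, 0.02])),
        ("continuous", "linear", np.array([0.05, 0.03])),
    ],
)
def test_likelihood_maximized_at_generating_parameters(track, name, theta_true):
    """On noise-free toys, a fine grid around the generating parameters is
    maximized at (or adjacent to) the truth."""
    doses = np.array([0.0, 20.0, 60.0, 150.0])
    if track == "dichotomous":
        f = eval_model(name, theta_true, doses)
        data = DichotomousInput(doses=doses, n=np.full(4, 1000.0), y=1000.0 * f)
        g_grid = np.linspace(0.05, 0.15, 21)
        b_grid = np.linspace(0.01, 0.03, 21)
        thetas = np.array([[g, b] for g in g_grid for b in b_grid])
        lls = loglik_dichotomous(name, thetas, data)
    else:
        m = eval_model(name, theta_true, doses)
        data = ContinuousInput(
            doses=doses, n=np.full(4, 50.0), mean_log=m, sd_log=np.zeros(4)
        )
        a_grid = np.linspace(0.0, 0.1, 21)
        b_grid = np.linspace(0.02, 0.04, 21)
        thetas = np.array([[a, b] for a in a_grid for b in b_grid])
        lls = loglik_continuous(name, thetas, np.full(len(thetas), 0.2), data)
    best = thetas[int(np.argmax(lls))]
    assert best == pytest.approx(theta_true, rel=1e-6)


def test_log_binom_coeff_matches_integers():
    from math import comb, log

    for n, y in [(5, 2), (10, 0), (12, 12), (30, 17)]:
        assert log_binom_coeff(n, y) == pytest.approx(log(comb(n, y)), abs=1e-10)
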