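import numpy as np
import pytest
from scipy import stats

from skewsphere.densities import SFvMLParams, sfvml_logpdf
from skewsphere.geometry import to_cartesian
from skewsphere.priors import (
    FlatPrior,
    FvMLGammaPrior,
    NAGPrior,
    NormalPrior,
    ParamState,
    ScenarioSpec,
    SkewNormalPrior,
    log_full_conditional,
    log_likelihood,
    log_posterior,
    log_prior,
    sample_prior,
    sample_prior_arrays,
)
from skewsphere.samplers import DirectionSample, RandomStream

from conftest import scenario_spec


# --- specification / validation ---------------------------------------------

def test_scenario_prior_family_consistency():
    with pytest.raises(ValueError):
        ScenarioSpec(scenario=1,
                     mu_tau_prior=FvMLGammaPrior(mu0=[1.0], tau0=1, alpha=1, beta=1),
                     gamma_prior=NormalPrior(xi=[0.0], sigma=[1.0]))
    with pytest.raises(ValueError):
        ScenarioSpec(scenario=2,
                     mu_tau_prior=NAGPrior(mu0=[1.0], zeta=2, eta=1),
                     gamma_prior=NormalPrior(xi=[0.0], sigma=[1.0]))


def test_nag_requires_eta_below_zeta():
    with pytest.raises(ValueError):
        NAGPrior(mu0=[1.0], zeta=1.0, eta=2.0)
    with pytest.raises(ValueError):
        NAGPrior(mu0=[1.0], zeta=1.0, eta=0.0)


# --- log prior special cases ------------------------------------------------

def test_gamma_prior_shape_one_is_linear_in_tau():
    prior = FvMLGammaPrior(mu0=[1.0], tau0=2.0, alpha=1.0, beta=3.0)
    taus = np.array([0.5, 1.0, 2.0])
    mu = to_cartesian([1.0])
    from skewsphere.priors import log_prior_mu_tau

    vals = np.array([log_prior_mu_tau(mu, t, prior, 2) for t in taus])
    # alpha = 1: log prior is tau0 * mu@mu0 - beta * tau, linear with slope -beta
    slopes = np.diff(vals) / np.diff(taus)
    assert np.allclose(slopes, -3.0, atol=1e-12)
    assert vals[0] == pytest.approx(2.0 - 3.0 * 0.5)


def test_skew_normal_lambda_zero_is_normal_plus_constant():
    g = np.linspace(-3, 3, 21)[:, None]
    from skewsphere.priors import log_prior_gamma

    sn = SkewNormalPrior(xi=[0.5], sigma=[0.8], lam=[0.0])
    nm = NormalPrior(xi=[0.5], sigma=[0.8])
    diff = log_prior_gamma(g, sn) - log_prior_gamma(g, nm)
    assert np.allclose(diff, np.log(0.5), atol=1e-12)


def test_nag_prior_maximized_at_mu0():
    prior = NAGPrior(mu0=[1.0], zeta=10.0, eta=0.5)
    from skewsphere.priors import log_prior_mu_tau

    at_mu0 = log_prior_mu_tau(to_cartesian([1.0]), 1.0, prior, 2)
    for ang in (0.0, 2.0, -2.5):
        assert at_mu0 >= log_prior_mu_tau(to_cartesian([ang]), 1.0, prior, 2)


def test_log_prior_is_minus_inf_for_nonpositive_tau():
    for s in (1, 3):
        spec = scenario_spec(s)
        om = ParamState.from_angles([1.0], -0.5, [0.0])
        assert log_prior(om, spec) == -np.inf


# --- likelihood -------------------------------------------------------------

def test_likelihood_equals_pointwise_density_sum(circle_data_50):
    om = ParamState.from_angles([2.7], 0.9, [1.3])
    l1 = log_likelihood(circle_data_50, om)
    l2 = float(sfvml_logpdf(circle_data_50.cartesian(),
                            SFvMLParams(om.mu, om.tau, om.gamma)).sum())
    assert l1 == pytest.approx(l2, abs=1e-10)


def test_likelihood_gamma_zero_is_symmetric_fvml(circle_data_50):
    from skewsphere.densities import fvml_logpdf

    om = ParamState.from_angles([2.7], 0.9, [0.0])
    l1 = log_likelihood(circle_data_50, om)
    l2 = float(fvml_logpdf(circle_data_50.cartesian(), om.mu, om.tau).sum())
    assert l1 == pytest.approx(l2, abs=1e-10)


def test_likelihood_single_point_at_mu():
    from skewsphere.densities import log_norm_const

    data = DirectionSample(angles=np.array([1.0]))
    om = ParamState.from_angles([1.0], 2.0, [3.0])
    expect = np.log(2) + log_norm_const(2.0, 2) + 2.0 + stats.norm.logcdf(0.0)
    assert log_likelihood(data, om) == pytest.approx(expect, abs=1e-10)


# --- full conditionals ------------------------------------------------------

@pytest.mark.parametrize("s", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("block", ["mu", "tau", "gamma"])
def test_full_conditional_proportional_to_joint(s, block, circle_data_50):
    """Each conditional differs from loglik + logprior by a block constant."""
    spec = scenario_spec(s)
    rest = ParamState.from_angles([2.5], 0.8, [0.7])
    diffs = []
    for v in np.linspace(0.1, 2.9, 50):
        if block == "mu":
            om = ParamState.from_angles([v], rest.tau, rest.gamma)
            value = om.mu
        elif block == "tau":
            om = ParamState(rest.mu, v, rest.gamma)
            value = v
        else:
            om = ParamState(rest.mu, rest.tau, [v - 1.5])
            value = [v - 1.5]
        fc = log_full_conditional(block, value, rest, circle_data_50, spec)
        diffs.append(fc - log_posterior(circle_data_50, om, spec))
    assert np.std(diffs) < 1e-9


def test_full_conditional_sphere_scenario(truth_sphere, stream):
    from skewsphere.samplers import sample_sfvml

    data = sample_sfvml(40, truth_sphere, stream.child("p3-cond"))
    spec = ScenarioSpec.from_scenario(3, p=3, mu0=[1.0, 2.0], tau0=5.0,
                                      alpha=12.0, beta=2.0, xi=[1.0, -2.0], sigma=[2.0, 2.0])
    rest = ParamState.from_angles([1.1, 1.9], 2.2, [0.5, -0.5])
    for block in ("mu", "tau", "gamma"):
        diffs = []
        for v in np.linspace(0.2, 2.8, 30):
            if block == "mu":
                om = ParamState.from_angles([v, 1.9], rest.tau, rest.gamma)
                value = om.mu
            elif block == "tau":
                om = ParamState(rest.mu, v, rest.gamma)
                value = v
            else:
                om = ParamState(rest.mu, rest.tau, [v, -0.5])
                value = [v, -0.5]
            fc = log_full_conditional(block, value, rest, data, spec)
            diffs.append(fc - log_posterior(data, om, spec))
        assert np.std(diffs) < 1e-9, block


def test_tau_conditional_mode_matches_numerical_derivative(circle_data_50):
    # FvML-gamma tau kernel with alpha > 1: interior mode, vanishing slope
    # (with alpha < 1 the tau^{alpha-1} factor is unbounded at 0 and the
    # kernel has no interior stationary point)
    spec = scenario_spec(3, alpha=12.0, beta=2.0)
    rest = ParamState.from_angles([3.0], 1.0, [1.0])
    taus = np.linspace(0.05, 10, 4000)
    vals = np.array([log_full_conditional("tau", t, rest, circle_data_50, spec)
                     for t in taus])
    i = int(np.argmax(vals))
    assert 0 < i < taus.size - 1
    h = taus[1] - taus[0]
    deriv = (vals[i + 1] - vals[i - 1]) / (2 * h)
    assert abs(deriv) < 0.05


def test_gamma_conditional_with_no_data_is_prior():
    spec = scenario_spec(2)
    empty = DirectionSample(angles=np.empty((0, 1)))
    rest = ParamState.from_angles([1.0], 1.0, [0.0])
    from skewsphere.priors import log_prior_gamma

    for g in (-1.0, 0.0, 2.0):
        fc = log_full_conditional("gamma", [g], rest, empty, spec)
        assert fc == pytest.approx(log_prior_gamma(np.array([g]), spec.gamma_prior))


# --- prior sampling ---------------------------------------------------------

def test_fvml_gamma_prior_moments():
    spec = scenario_spec(3)
    mu, tau, g = sample_prior_arrays(spec, 50_000, RandomStream(12))
    assert tau.mean() == pytest.approx(0.5 / 5.0, abs=3 * np.sqrt(0.5 / 25 / 50_000))
    assert g.mean() == pytest.approx(-4.0, abs=3 / np.sqrt(50_000))


def test_nag_concentration_increases_with_eta():
    mu0 = to_cartesian([1.0])
    spreads = []
    for eta in (0.5, 3.0, 8.0):
        spec = ScenarioSpec(scenario=1,
                            mu_tau_prior=NAGPrior(mu0=[1.0], zeta=10.0, eta=eta),
                            gamma_prior=NormalPrior(xi=[0.0], sigma=[1.0]))
        mu, tau, _ = sample_prior_arrays(spec, 20_000, RandomStream(13))
        spreads.append(1.0 - np.mean(mu @ mu0))  # circular variance about mu0
    assert spreads[0] > spreads[1] > spreads[2]


def test_skew_normal_prior_skewness_sign():
    for lam, sign in ((-2.0, -1), (3.0, +1)):
        spec = ScenarioSpec.from_scenario(2, mu0=[1.0], zeta=10, eta=0.5,
                                          xi=0.5, sigma=0.5, lam=lam)
        _, _, g = sample_prior_arrays(spec, 50_000, RandomStream(14))
        assert np.sign(stats.skew(g[:, 0])) == sign


def test_nag_exact_sampler_matches_slice_sampler():
    """The grid inverse-CDF composition and the joint slice sampler draw from
    the same joint prior."""
    spec = scenario_spec(2)
    mu_e, tau_e, _ = sample_prior_arrays(spec, 4000, RandomStream(15).child("e"))
    mu_s, tau_s, _ = sample_prior_arrays(spec, 800, RandomStream(15).child("s"),
                                         method="slice")
    assert stats.ks_2samp(tau_e, tau_s).pvalue > 1e-3
    ang_e = np.arctan2(mu_e[:, 1], mu_e[:, 0])
    ang_s = np.arctan2(mu_s[:, 1], mu_s[:, 0])
    assert stats.ks_2samp(ang_e, ang_s).pvalue > 1e-3


def test_flat_prior_sampling_bounds():
    spec = ScenarioSpec(scenario=0, mu_tau_prior=FlatPrior(tau_max=7.0),
                        gamma_prior=NormalPrior(xi=[0.0], sigma=[5.0]))
    mu, tau, _ = sample_prior_arrays(spec, 5000, RandomStream(16))
    assert np.all((tau > 0) & (tau <= 7.0))
    ang = np.arctan2(mu[:, 1], mu[:, 0])
    assert stats.kstest(ang, stats.uniform(-np.pi, 2 * np.pi).cdf).pvalue > 0.01


def test_sample_prior_returns_param_states():
    states = sample_prior(scenario_spec(4), 5, RandomStream(17))
    assert len(states) == 5
    assert all(isinstance(s, ParamState) and s.tau > 0 for s in states)
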