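# skewsphere

Bayesian inference for **skew-rotationally-symmetric Fisher–von
Mises–Langevin (FvML) distributions** on the circle and sphere — for
statisticians and quantitative scientists working with directional data
(animal movement bearings, geological orientations, times-of-day on the
24-hour clock, compositional rays) whose distributions are visibly
asymmetric about their preferred direction.

## The model

The symmetric building block is the FvML density on S^{p−1}

```
f(x; μ, τ) = C(τ) exp(τ μᵀx),      C(τ) = (2π)^{−p/2} τ^{p/2−1} / I_{p/2−1}(τ),
```

with location μ and concentration τ ≥ 0 (von Mises on the circle, Fisher on
the sphere).  Modulating it with a skewing function Π (monotone,
Π(t) + Π(−t) = 1) gives the skew-FvML family

```
2 C(τ) exp(τ xᵀμ) Π(√(1 − (xᵀμ)²) γᵀU_μ(x)),
```

where U_μ(x) is the unit tangent sign vector of x about μ and γ ∈ R^{p−1}
the skewness (γ = 0 recovers symmetry).  On the circle with Π = Φ, the
standard normal CDF, this is the skew-von Mises density
`exp(τ cos(θ−μ)) Φ(γ sin(θ−μ)) / (π I₀(τ))`.

The package provides, with Ω = (μ, τ, γ) fully unknown:

- exact samplers (sign-flip construction; no rejection step) and log-densities;
- four prior scenarios — a conjugate-style joint (μ, τ) prior or independent
  FvML × Gamma priors, crossed with normal or skew-normal priors on γ —
  plus a flat baseline, with their posteriors and full conditionals;
- a **sampling-resampling Gibbs sampler**: per block, k candidates from the
  prior are scored by the full-conditional-to-prior ratio and the argmax is
  selected (a weighted-bootstrap scheme that needs only prior draws);
- loss-based Bayes estimators (posterior mean / median / mode for squared /
  absolute / zero-one loss), chain diagnostics (running means, whole-vs-tail
  density overlap, rank-normalized split R̂), and a maximum-likelihood fitter;
- the second-sine-moment test of reflective symmetry on the circle;
- the **Wasserstein Impact Measure (WIM)**: the 1-Wasserstein distance
  between posteriors produced by two competing priors on the same data, as a
  practical guide for prior selection.

See `docs/methods.md` for the full methodological account.

## Worked example

Fit the skew-von Mises model to 500 synthetic bearings drawn from
(μ, τ, γ) = (2, 1, −1):

```python
import skewsphere as sk

stream = sk.RandomStream(42)
truth = sk.SFvMLParams(mu=sk.to_cartesian([2.0]), tau=1.0, gamma=[-1.0])
data = sk.sample_sfvml(500, truth, stream.child("data"))

test = sk.pewsey_symmetry_test(data.theta)
print(f"b2 = {test.b2bar:.4f}, z = {test.z:.2f}, p = {test.p_value:.4f}")

spec = sk.ScenarioSpec.from_scenario(1, mu0=[1.0], zeta=10, eta=0.5, xi=-4, sigma=1)
est = sk.BayesianSFvML(scenario_spec=spec, burnin=1000, n_keep=500, k=500, seed=42)
est.fit(data.theta)
print(est.summary_.round(4))

mle = sk.SkewFvMLMLE().fit(data.theta)
print(f"MLE: mu={mle.mu_:.4f} tau={mle.tau_:.4f} gamma={float(mle.gamma_[0]):.4f}")
```

prints

```
b2 = 0.0424, z = 1.66, p = 0.0977
             mean      sd      q1  median      q3    mode
parameter
mu         2.1824  0.1166  2.1054  2.1856  2.2649  2.1882
tau        0.7017  0.1252  0.6188  0.6972  0.7832  0.6871
gamma     -1.3051  0.1537 -1.3936 -1.3084 -1.2145 -1.3215
MLE: mu=1.9671 tau=0.9126 gamma=-1.0124
```

Reading this: the symmetry test statistic is the studentized second sine
moment about the mean direction; at this mild skewness (γ = −1) it does not
reach the 5% level — single-dataset skewness evidence is weak even at
n = 500, which is exactly why informative priors earn their keep here.  The
summary rows are the three Bayes estimates per parameter (mean / median /
mode for squared / absolute / zero-one loss) with posterior sd and
quartiles: location and skewness are recovered near the truth (2, −1), with
the concentration shrunk toward the prior.  The maximum-likelihood point
estimate agrees.  `BayesianSFvML` and `SkewFvMLMLE` follow the
scikit-learn estimator contract (`get_params`/`fit`/fitted attributes) and
compose with sklearn tooling; the same functionality is available
functionally (`run_chain`, `summarize_chain`, `mle_fit`) and from the shell:

```
skewsphere simulate --p 2 --mu 2 --tau 1 --gamma -1 --n 500 --seed 42 --out data.csv
skewsphere fit --data data.csv --config scenario.yml --out chain.csv
skewsphere summarize --chain chain.csv --out summary.csv
skewsphere symmetry --data data.csv
```

where `scenario.yml` holds the prior scenario and chain sizes, e.g.

```yaml
scenario: 1
mu0: [1.0]
zeta: 10
eta: 0.5
xi: [-4]
sigma: [1]
burnin: 1000
N: 500
k: 500
seed: 42
```

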