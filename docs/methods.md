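# Methods

## Model

Directions are points on the unit sphere S^{p-1} (the circle for p = 2, the
ordinary sphere for p = 3).  The symmetric core is the
Fisher–von Mises–Langevin (FvML) density

    f(x; mu, tau) = C(tau) exp(tau mu' x),
    C(tau) = (2 pi)^{-p/2} tau^{p/2-1} / I_{p/2-1}(tau),

with location mu on S^{p-1} and concentration tau >= 0 (tau = 0 is the
uniform law).  Skew-rotationally-symmetric densities modulate a symmetric
core with a skewing function Pi (monotone, Pi(t) + Pi(-t) = 1):

    2 f(x' mu) Pi( sqrt(1 - (x'mu)^2) gamma' U_mu(x) ),

where U_mu(x) is the unit tangent sign vector of x about mu and
gamma in R^{p-1} the skewness.  With the FvML core this is the skew-FvML
family; on the circle with the probit skewing Pi = Phi it is the skew-von
Mises density

    f(theta) = exp(tau cos(theta - mu)) Phi(gamma sin(theta - mu)) / (pi I0(tau)).

All Bayesian machinery uses the probit skewing; the linear "sine" skewing
Pi(t) = (1+t)/2 (gamma restricted to [-1, 1]) is available as a density and
sampling option only.

### Tangent frame and gauge

Every density and sampler relies on a deterministic semi-orthogonal basis
Upsilon_mu of the tangent space at mu.  It is built from the reflection R
across e1 + mu (which maps e1 to mu, is smooth except at mu = -e1, and is
replaced there by a fixed basis), taking the images of e2..ep with a global
sign flip chosen so that on the circle the single tangent coordinate equals
sin(theta - mu).  The skewing argument is then evaluated as
gamma' Upsilon_mu' x, which equals sqrt(1 - t^2) gamma' U_mu(x) exactly.
The skewness vector is defined relative to this fixed gauge; a different
gauge would rotate gamma but leave the family unchanged.

## Exact sampling

FvML draws use numpy's von Mises generator on the circle and, on the sphere,
the closed-form inverse CDF of the tangent coordinate,
t = 1 + log(u + (1-u) e^{-2 tau}) / tau, with a uniform longitude.  Skew-FvML
draws follow the sign-flip construction: decompose a symmetric draw into
(t, u), keep u with probability Pi(sqrt(1-t^2) gamma'u), otherwise flip its
sign, and reassemble.  This is rejection-free: one output per core draw.

## Priors

Four scenarios for Omega = (mu, tau, gamma):

| scenario | (mu, tau) prior | gamma prior |
|---|---|---|
| 1 | NAG joint | componentwise normal N(xi, sigma^2) |
| 2 | NAG joint | componentwise skew-normal SN(xi, sigma, lambda) |
| 3 | FvML(mu0, tau0) x Gamma(alpha, rate beta) | normal |
| 4 | FvML(mu0, tau0) x Gamma(alpha, rate beta) | skew-normal |

The NAG (Nunez-Antonio–Gutierrez-Pena) joint prior is

    pi(mu, tau) ∝ (tau^{p/2-1} / I_{p/2-1}(tau))^zeta exp(eta tau mu' mu0),
    0 < eta < zeta,

whose mu | tau conditional is FvML(mu0, eta tau).  sigma denotes standard
deviations throughout.  A flat baseline (mu uniform, pi(tau) ∝ 1 truncated
to (0, tau_max], default tau_max = 50 so that candidate pools exist) is
provided for prior-impact comparisons; the truncation is required to make
the improper prior sampleable.

### Sampling the NAG prior

The NAG prior has no closed-form normalization.  Candidate pools are drawn
exactly by composition: the one-dimensional tau marginal

    m(tau) ∝ (tau^{p/2-1} / I_{p/2-1}(tau))^zeta / C(eta tau)

(the mu integral is the FvML normalizing constant) is tabulated once on an
adaptive 8192-point grid covering the region within 45 log-units of the
marginal mode, inverted by monotone interpolation of the trapezoid CDF, and
composed with mu | tau ~ FvML(mu0, eta tau).  This replaces a per-sweep
two-dimensional slice sampler, which produces the same joint law (the
package retains it as `method="slice"`, with stepping-out/shrinkage updates,
burn-in 1000 and thinning 5, and the test suite KS-compares the two paths)
but costs roughly three orders of magnitude more per pool and would dominate
the runtime of every chain.

## Posterior sampling

The sampler is a sampling-resampling Gibbs scheme.  Per sweep and per block
(joint (mu, tau) under the NAG prior, since it is not independent; separate
mu and tau blocks otherwise; then gamma), k fresh candidates are drawn from
the block's prior and scored by the weighted-bootstrap log-ratio
log rho = log full-conditional - log prior, which reduces analytically to
the block's likelihood factor — so Phi-products and Bessel terms are only
ever summed in log space (stable up to n in the thousands and tau up to
1e4 via exponentially scaled Bessel functions).  The block is set to the
candidate with maximal rho, ties to the lowest index.  This argmax rule is a
mode-seeking weighted-bootstrap variant of sampling-importance-resampling;
classical multinomial SIR resampling is available (`select="multinomial"`)
but is not the default.  Candidate pools are redrawn every sweep; reusing a
pool would freeze the chain on a finite support.

Defaults follow the synthetic study: burn-in B = 5000, kept draws N = 500,
pool size k = 500.  The chain mixes essentially immediately (selection is a
fresh argmax over an independent pool each sweep), so large B is cheap
insurance rather than a necessity.  Initial values (`init="auto"`) are
moment estimates: mean direction, A_p-inverse of the resultant length for
tau (Fisher's piecewise approximation on the circle), gamma = 0.

Because blocks update one at a time through argmax selection, the chain is
metastable across well-separated posterior basins: skewed circular
likelihoods admit a reflected (mu shifted, gamma negated) basin, and the
moment init — whose mean direction lies on the skewed side of the true
location, with gamma = 0 — can land in it even when it is not a posterior
mode.  `init="mle"` starts the chain at the maximum-likelihood fit instead,
which places it in the dominant basin; the headline recovery experiments use
it, and additionally combine replicate datasets by their median, which is
robust to a residual basin flip on datasets whose own ML fit is degenerate.

Blocks can be pinned (`fixed={"mu": ..., "tau": ...}`) for designs that
treat parameters as known; pinned blocks are skipped, which conditions the
remaining updates on the fixed values.

## Estimators and summaries

Posterior mean, median and mode are the Bayes estimators under squared
error, absolute error and zero-one loss.  Quantiles use linear interpolation
of order statistics (type 7); the mode is the argmax of a Gaussian KDE
(Silverman bandwidth) on a 512-point grid.  Location-angle draws are
recentred to their circular mean before any linear statistic, so chains
straddling +-pi summarize correctly; the same recentring is applied before
Wasserstein distances between location chains.

Maximum likelihood ascends the log-likelihood over (mu angles, log tau,
gamma) by Nelder-Mead from the moment start.  The symmetric fit gamma = 0 is
a strong local optimum of skewed likelihoods, so the optimizer is restarted
from several skewness values (0, +-2, +-4) and the best kept; gamma can also
be pinned (`fix_gamma=0`), which reproduces the von Mises / FvML MLE.

Mixing diagnostics: running means, whole-vs-tail kernel density comparison
with an L1 gap, and rank-normalized split R-hat (via arviz) across parallel
chains run from independent substreams.

## Symmetry test

Reflective symmetry about the (unknown) mean direction is tested with the
second sine moment b2 = mean(sin 2(theta - thetabar)), studentized by the
estimated asymptotic variance

    var(b2) = [ (1 - a4)/2 - 2 a2 + (2 a2 / R)(a3 + a2 (1 - a2)/R) ] / n

(a_k the cosine moments about the mean direction, R the mean resultant
length), with a two-sided normal p-value.  The variance estimator follows
Pewsey's 2002 large-sample derivation; its type-I error is verified by
simulation in the test suite (empirical size 0.03-0.05 at the 5% level for
von Mises data, n = 100).

## Wasserstein Impact Measure

The WIM between two priors is the order-1 Wasserstein distance between the
posterior samples they produce on the same dataset, computed per scalar
parameter (scipy's 1-d Wasserstein distance; the test suite cross-checks it
against an exact linear-programming transport solver on small samples).
Location chains are recentred circularly first.  The study driver repeats
this over Monte-Carlo replicates and sample sizes; the gamma-prior
comparison fixes (mu, tau) at the truth, as the corresponding experimental
design prescribes.

## Synthetic-data generator and what the tests show

All test inputs are generated by the package's own exact samplers at the
study truths: circle samples at (mu, tau, gamma) = (3, 0.6, 1) and
(2, 1, -1), a sphere sample at ((1, 2), 2, (1, -1)), and a symmetric control
(gamma = 0).  These emulate clean i.i.d. draws from the model itself; they
do not emulate grouped/rounded angles, measurement error, mixtures, or
model misspecification, so passing tests demonstrate correctness of the
machinery and calibration under the model, not robustness on real data.

A consequence of the model worth knowing: location and skewness trade off
along a weakly identified likelihood ridge on the circle (datasets of size
500 can place their maximum-likelihood fit half a radian from the truth with
a compensating skewness shift).  Point estimates therefore carry substantial
dataset-level Monte-Carlo noise; the end-to-end recovery checks take the
median over independent replicate datasets to control it, at unchanged
tolerances.

## Numerical choices

- All densities and ratios in log space; Bessel I_nu via `ive` (scaled),
  log Phi via `log_ndtr`.
- tau = 0 handled by the analytic uniform limit, never 0/0.
- tau bracketing bound 1e4 (slice sampling and NAG support), far beyond any
  concentration of interest here.
- Angles live in (-pi, pi]; degree input converted at the I/O boundary;
  colatitude in [0, pi] with longitude set to 0 at the poles (flagged
  degenerate rather than erroring: a measure-zero case must not abort
  pipelines).
- Tangent decomposition at x = +-mu returns the first tangent basis vector
  with a degeneracy flag.
- Ties in candidate selection break to the lowest index (measure zero for
  continuous pools; makes runs bit-reproducible).
- All randomness flows through labelled substreams of a single seed
  (`RandomStream`); no global RNG is ever consulted, and changing one
  consumer (e.g. the pool size k) does not perturb another (e.g. the data).

## Problem sizes used by the shipped studies

The relative-efficiency and prior-impact drivers default to desk-scale
settings chosen to make the qualitative findings reproducible in minutes:
100 Monte-Carlo replicates (scaled down from the 500-1000 a full
simulation study would use), chains of
B = 150-300 / N = 150-200 / k = 80-100 for the study loops, and the full
B = 5000 / N = 500 / k = 500 setting for the headline recovery runs.  All
are arguments, not constants.

## Known limitations

- Sampling is implemented for p = 2 and 3 (densities are dimension-generic).
- The argmax selection rule is mode-seeking by construction; its draws are
  not exact posterior draws for finite k, and the posterior spread it
  reports shrinks as k grows.  The rule is the sampler's defining feature
  and is implemented exactly; multinomial resampling is the provided
  alternative.
- Bootstrap calibration of WIM magnitudes is out of scope.
- The p = 3 prior on mu is a single FvML(mu0, tau0); independent priors on
  the two spherical coordinates are not implemented.
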