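"""The modified sampling-resampling Gibbs sampler.

Each sweep updates the parameter blocks in order.  For a block, k fresh
candidates are drawn from that block's *prior*; each candidate i receives the
weighted-bootstrap log-ratio

    log rho_i = log full-conditional(candidate_i | rest) - log prior(candidate_i),

which, by construction of the full conditionals, is the block's likelihood
factor (the prior cancels analytically, so no Bessel/Phi underflow is ever
exponentiated); the block is set to the candidate with maximal rho (ties to
the lowest index).  Under the NAG prior (scenarios 1-2) the (mu, tau) blocks
are drawn and selected jointly, since their prior is not independent; under
the FvML-gamma and flat priors mu and tau are separate blocks.

This argmax selection is a mode-seeking weighted-bootstrap variant of
sampling-importance-resampling; a standard multinomial SIR resample is
available as ``select="multinomial"`` for comparison, but the argmax rule is
the default.  Candidate pools are redrawn fresh at every sweep; the chain's
stochasticity comes from the pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .densities import log_norm_const
from .geometry import to_angles, wrap_angle
from .priors import (
    FlatPrior,
    NAGPrior,
    ParamState,
    ScenarioSpec,
    sample_gamma_prior,
    sample_prior_arrays,
    upsilon_gamma,
)
from .samplers import DirectionSample, RandomStream, _as_generator, sample_fvml

__all__ = ["Chain", "gibbs_step", "run_chain", "run_parallel_chains", "rhat"]


@dataclass
class Chain:
    """Ordered posterior draws Omega^(1..B+N) with burn-in marker.

    ``mu`` holds unit vectors (B+N, p); ``selected_logrho`` the per-sweep
    selected log importance ratio for each block (joint (mu,tau) under the
    NAG prior occupies the first column).
    """

    mu: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray
    burnin: int
    k: int
    seed: object
    spec: ScenarioSpec
    selected_logrho: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __len__(self):
        return self.tau.size

    @property
    def p(self) -> int:
        return self.mu.shape[1]

    @property
    def kept(self) -> slice:
        return slice(self.burnin, None)

    @property
    def mu_angles(self) -> np.ndarray:
        return np.atleast_2d(to_angles(self.mu))

    def parameter_names(self) -> list:
        if self.p == 2:
            return ["mu", "tau", "gamma"]
        return ["mu1", "mu2", "tau", "gamma1", "gamma2"]

    def to_frame(self, kept_only: bool = False) -> pd.DataFrame:
        """Tidy per-iteration table: iter, phase, parameter columns."""
        ang = self.mu_angles
        cols = {}
        if self.p == 2:
            cols["mu"] = ang[:, 0]
        else:
            cols["mu1"], cols["mu2"] = ang[:, 0], ang[:, 1]
        cols["tau"] = self.tau
        if self.p == 2:
            cols["gamma"] = self.gamma[:, 0]
        else:
            cols["gamma1"], cols["gamma2"] = self.gamma[:, 0], self.gamma[:, 1]
        df = pd.DataFrame(cols)
        df.insert(0, "iter", np.arange(1, len(self) + 1))
        df.insert(1, "phase", np.where(df["iter"] <= self.burnin, "burnin", "keep"))
        return df[df["phase"] == "keep"].reset_index(drop=True) if kept_only else df

    def kept_values(self, parameter: str) -> np.ndarray:
        """Post-burn-in draws of one named scalar parameter."""
        return self.to_frame(kept_only=True)[parameter].to_numpy()


class _GibbsEngine:
    """Vectorized candidate scoring for one dataset under one scenario."""

    def __init__(self, data: DirectionSample, spec: ScenarioSpec, k: int, rng,
                 fixed: dict | None = None, select: str = "argmax"):
        self.X = data.cartesian() if data.n else np.zeros((0, spec.p))
        self.S = self.X.sum(axis=0)
        self.n = self.X.shape[0]
        self.spec = spec
        self.k = int(k)
        self.rng = rng
        self.fixed = dict(fixed or {})
        if select not in ("argmax", "multinomial"):
            raise ValueError("select must be 'argmax' or 'multinomial'")
        self.select = select
        self.joint_mu_tau = isinstance(spec.mu_tau_prior, NAGPrior)
        self.nu = spec.p / 2.0 - 1.0

    def _pick(self, logrho: np.ndarray, block: str) -> int:
        best = np.max(logrho)
        if not np.isfinite(best):
            raise RuntimeError(
                f"all {self.k} candidate log-ratios are -inf for block {block!r} "
                f"(scenario {self.spec.scenario})"
            )
        if self.select == "argmax":
            return int(np.argmax(logrho))
        w = np.exp(logrho - best)
        return int(self.rng.choice(logrho.size, p=w / w.sum()))

    def _phi_colsums(self, G: np.ndarray) -> np.ndarray:
        """sum_i log Phi(x_i @ G_j) for candidate skew directions G (k, p)."""
        if self.n == 0:
            return np.zeros(G.shape[0])
        return log_ndtr(self.X @ G.T).sum(axis=0)

    def step(self, state: ParamState) -> tuple:
        """One full sweep; returns (new state, selected log-rho per block)."""
        spec, rng, k = self.spec, self.rng, self.k
        mu, tau, gamma = state.mu, state.tau, state.gamma
        logrho_sel = []

        if "mu" in self.fixed and "tau" in self.fixed:
            mu = np.asarray(self.fixed["mu"], dtype=float)
            tau = float(self.fixed["tau"])
            logrho_sel += [np.nan, np.nan]
        elif self.joint_mu_tau:
            mu_c, tau_c, _ = sample_prior_arrays(spec, k, rng)
            # rho = full conditional / prior = the full likelihood factor
            G = upsilon_gamma(mu_c, np.broadcast_to(gamma, (k, spec.p - 1)))
            lr = (
                self.n * log_norm_const(tau_c, spec.p)
                + tau_c * (mu_c @ self.S)
                + self._phi_colsums(G)
            )
            i = self._pick(lr, "mu-tau")
            mu, tau = mu_c[i], float(tau_c[i])
            logrho_sel += [float(lr[i]), np.nan]
        else:
            prior = spec.mu_tau_prior
            # mu block: candidates from the mu prior; rho = tau mu @ S + Phi terms
            if "mu" in self.fixed:
                mu = np.asarray(self.fixed["mu"], dtype=float)
                logrho_sel.append(np.nan)
            else:
                if isinstance(prior, FlatPrior):
                    mu_c = sample_fvml(k, _e1(spec.p), 0.0, rng).cartesian()
                else:
                    mu_c = sample_fvml(k, prior.mu0_cartesian(spec.p), prior.tau0, rng).cartesian()
                G = upsilon_gamma(mu_c, np.broadcast_to(gamma, (k, spec.p - 1)))
                lr = tau * (mu_c @ self.S) + self._phi_colsums(G)
                i = self._pick(lr, "mu")
                mu = mu_c[i]
                logrho_sel.append(float(lr[i]))
            # tau block: rho = n [nu log tau - log I_nu(tau)] + tau mu @ S
            if "tau" in self.fixed:
                tau = float(self.fixed["tau"])
                logrho_sel.append(np.nan)
            else:
                if isinstance(prior, FlatPrior):
                    tau_c = (1.0 - rng.random(k)) * prior.tau_max
                else:
                    tau_c = rng.gamma(prior.alpha, 1.0 / prior.beta, k)
                c = float(mu @ self.S)
                lr = self.n * log_norm_const(tau_c, spec.p) + tau_c * c
                i = self._pick(lr, "tau")
                tau = float(tau_c[i])
                logrho_sel.append(float(lr[i]))

        # gamma block: rho = Phi-product terms only
        if "gamma" in self.fixed:
            gamma = np.atleast_1d(np.asarray(self.fixed["gamma"], dtype=float))
            logrho_sel.append(np.nan)
        else:
            g_c = sample_gamma_prior(spec.gamma_prior, k, rng)
            G = upsilon_gamma(np.broadcast_to(mu, (k, spec.p)), g_c)
            lr = self._phi_colsums(G)
            i = self._pick(lr, "gamma")
            gamma = g_c[i]
            logrho_sel.append(float(lr[i]))

        return ParamState(mu=mu, tau=tau, gamma=gamma), np.asarray(logrho_sel)


def _e1(p: int) -> np.ndarray:
    e = np.zeros(p)
    e[0] = 1.0
    return e


def gibbs_step(omega: ParamState, data: DirectionSample, spec: ScenarioSpec, k: int,
               stream, fixed: dict | None = None, select: str = "argmax") -> ParamState:
    """One sweep of the sampling-resampling Gibbs update from ``omega``."""
    eng = _GibbsEngine(data, spec, k, _as_generator(stream), fixed=fixed, select=select)
    state, _ = eng.step(omega)
    return state


def auto_init(data: DirectionSample, p: int) -> ParamState:
    """Moment-based starting point: mean direction, A_p-inverse of the
    resultant length for tau, gamma = 0."""
    X = data.cartesian()
    m = X.mean(axis=0)
    R = float(np.linalg.norm(m))
    R = min(R, 0.999)
    if R < 1e-9:
        mu = _e1(p)
    else:
        mu = m / R
    if p == 2:  # Fisher's piecewise approximation to A_2^{-1}
        if R < 0.53:
            tau = 2 * R + R**3 + 5 * R**5 / 6
        elif R < 0.85:
            tau = -0.4 + 1.39 * R + 0.43 / (1 - R)
        else:
            tau = 1.0 / (R**3 - 4 * R**2 + 3 * R)
    else:
        tau = R * (3 - R**2) / (1 - R**2)
    return ParamState(mu=mu, tau=max(tau, 1e-3), gamma=np.zeros(p - 1))


def run_chain(data: DirectionSample, spec: ScenarioSpec, B: int, N: int, k: int,
              stream, init="auto", fixed: dict | None = None,
              select: str = "argmax") -> Chain:
    """Run the sampler for B + N sweeps from ``init`` and return the chain.

    ``fixed`` may pin blocks (e.g. ``{"mu": ..., "tau": ...}``) so only the
    remaining blocks are updated — used when some parameters are treated as
    known.  ``stream`` is a RandomStream, Generator or integer seed.

    ``init="auto"`` starts from moment estimates (mean direction, moment
    tau, gamma = 0); ``init="mle"`` starts from the maximum-likelihood fit,
    which places the chain in the basin of the dominant posterior mode when
    the skewed likelihood is multimodal (location and skewness can trade off
    along a reflected ridge).  A ParamState is used as-is.
    """
    if B < 0 or N < 1 or k < 1:
        raise ValueError("require B >= 0, N >= 1, k >= 1")
    if isinstance(stream, RandomStream):
        seed, rng = stream, stream.child("gibbs").generator()
    else:
        seed, rng = stream, _as_generator(stream)
    if isinstance(init, str):
        if init == "mle" and not fixed:
            from .summarize import mle_fit

            fit = mle_fit(data).params
            state = ParamState(mu=fit.mu, tau=max(fit.tau, 1e-3), gamma=fit.gamma)
        else:
            state = auto_init(data, spec.p)
    else:
        state = init
    if fixed:
        state = ParamState(
            mu=np.asarray(fixed.get("mu", state.mu), dtype=float),
            tau=float(fixed.get("tau", state.tau)),
            gamma=np.atleast_1d(np.asarray(fixed.get("gamma", state.gamma), dtype=float)),
        )
    eng = _GibbsEngine(data, spec, k, rng, fixed=fixed, select=select)
    total = B + N
    mu = np.empty((total, spec.p))
    tau = np.empty(total)
    gamma = np.empty((total, spec.p - 1))
    logrho = np.empty((total, 3))
    for it in range(total):
        try:
            state, lr = eng.step(state)
        except RuntimeError as err:
            raise RuntimeError(f"iteration {it + 1}: {err}") from err
        mu[it], tau[it], gamma[it], logrho[it] = state.mu, state.tau, state.gamma, lr
    return Chain(mu=mu, tau=tau, gamma=gamma, burnin=B, k=k, seed=seed,
                 spec=spec, selected_logrho=logrho, fixed=dict(fixed or {}))


def run_parallel_chains(data: DirectionSample, spec: ScenarioSpec, n_chains: int,
                        B: int, N: int, k: int, stream, **kwargs):
    """Run independent chains from substreams; returns (chains, R-hat table)."""
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for mixing diagnostics")
    if not isinstance(stream, RandomStream):
        stream = RandomStream(int(stream))
    chains = [
        run_chain(data, spec, B, N, k, stream.child(f"chain-{i}"), **kwargs)
        for i in range(n_chains)
    ]
    return chains, rhat(chains)


def rhat(chains) -> dict:
    """Rank-normalized split R-hat per parameter across kept draws."""
    import warnings

    import arviz as az

    names = chains[0].parameter_names()
    # mu angles are recentred to the pooled circular mean before ranking so a
    # chain straddling +-pi does not inflate the diagnostic
    data = {}
    for name in names:
        draws = np.stack([c.kept_values(name) for c in chains])
        if name.startswith("mu"):
            pooled = np.arctan2(np.sin(draws).mean(), np.cos(draws).mean())
            draws = pooled + wrap_angle(draws - pooled)
        data[name] = draws
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(data))
    return {name: float(r[name].values) for name in names}
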