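"""Log-densities of the FvML, skew-FvML and skew-von Mises families.

The rotationally symmetric core is the Fisher-von Mises-Langevin (FvML) law

    f(x; mu, tau) = C(tau) * exp(tau * mu @ x),      x, mu on S^{p-1},

with C(tau) = (2 pi)^{-p/2} tau^{p/2-1} / I_{p/2-1}(tau) and tau >= 0 the
concentration (tau = 0 is the uniform law on the sphere).  Skewing a
rotationally symmetric core f with a function Pi: R -> [0,1] satisfying
Pi(t) + Pi(-t) = 1 gives the skew-rotationally-symmetric density

    2 f(x @ mu) * Pi(sqrt(1 - (x@mu)^2) * gamma @ U_mu(x)),

which for the FvML core is the skew-FvML (SFvML) family; on the circle with
the probit skewing it is the skew-von Mises (SvM) density

    f(theta) = exp(tau cos(theta - mu)) * Pi(gamma sin(theta - mu)) / (pi I0(tau)).

All densities are computed and returned in log space; Bessel functions are
evaluated in exponentially scaled form so large concentrations do not
overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ive, log_ndtr

from .geometry import as_unit_vector, tangent_frame

__all__ = [
    "SFvMLParams",
    "log_bessel_i",
    "log_norm_const",
    "fvml_logpdf",
    "sfvml_logpdf",
    "svm_logpdf",
    "log_skewing",
]

_SKEWINGS = ("probit", "sine")


def log_bessel_i(nu: float, x) -> np.ndarray:
    """log I_nu(x) for x >= 0 via the exponentially scaled Bessel function."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(ive(nu, x)) + x
    return out


def log_skewing(t, skewing: str = "probit"):
    """log Pi(t) for the supported skewing functions.

    ``probit`` is the standard normal CDF (numerically stable log-CDF);
    ``sine`` is Pi(t) = (1 + t)/2 on [-1, 1], the linear skewing that turns
    the von Mises into the sine-skewed von Mises.
    """
    t = np.asarray(t, dtype=float)
    if skewing == "probit":
        return log_ndtr(t)
    if skewing == "sine":
        if np.any(t < -1 - 1e-12) or np.any(t > 1 + 1e-12):
            raise ValueError("sine skewing argument must lie in [-1, 1]")
        with np.errstate(divide="ignore"):
            return np.log1p(np.clip(t, -1.0, 1.0)) - np.log(2.0)
    raise ValueError(f"unknown skewing {skewing!r}")


@dataclass(frozen=True)
class SFvMLParams:
    """Parameters Omega = (mu, tau, gamma) of a skew-FvML distribution.

    ``mu`` is the location on S^{p-1} (Cartesian), ``tau >= 0`` the
    concentration, ``gamma`` the length-(p-1) skewness vector and ``skewing``
    the choice of Pi.  ``gamma = 0`` recovers the symmetric FvML law.
    """

    mu: np.ndarray
    tau: float
    gamma: np.ndarray
    skewing: str = field(default="probit")

    def __post_init__(self):
        mu = as_unit_vector(self.mu)
        gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if gamma.size != mu.size - 1 or not np.all(np.isfinite(gamma)):
            raise ValueError("gamma must be a finite vector of length p-1")
        if self.skewing not in _SKEWINGS:
            raise ValueError(f"unknown skewing {self.skewing!r}")
        if self.skewing == "sine":
            if mu.size != 2:
                raise ValueError("sine skewing is only defined for p=2")
            if abs(gamma[0]) > 1:
                raise ValueError("sine skewing requires gamma in [-1, 1]")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "tau", float(self.tau))

    @property
    def p(self) -> int:
        return self.mu.size


def log_norm_const(tau, p: int):
    """log C(tau) of the FvML density on S^{p-1}.

    The tau -> 0 limit is the uniform density, C(0) = Gamma(p/2) / (2 pi^{p/2})
    (one over the surface area of S^{p-1}).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if p < 2:
        raise ValueError("p must be >= 2")
    nu = p / 2.0 - 1.0
    log_uniform = gammaln(p / 2.0) - np.log(2.0) - (p / 2.0) * np.log(np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        general = (
            -(p / 2.0) * np.log(2.0 * np.pi)
            + nu * np.log(tau)
            - log_bessel_i(nu, tau)
        )
    out = np.where(tau == 0.0, log_uniform, general)
    return out if out.ndim else float(out)


def fvml_logpdf(x, mu, tau: float):
    """Log-density of the FvML distribution at unit vector(s) ``x``."""
    mu = as_unit_vector(mu)
    X = np.asarray(x, dtype=float)
    dots = X @ mu
    out = log_norm_const(tau, mu.size) + tau * dots
    return out if np.ndim(out) else float(out)


def sfvml_logpdf(x, params: SFvMLParams):
    """Log-density of the skew-FvML distribution at unit vector(s) ``x``.

    The skewing argument sqrt(1 - t^2) * gamma @ U_mu(x) equals
    gamma @ Upsilon_mu.T @ x, which is how it is evaluated (gauge fixed by the
    deterministic tangent frame of :mod:`skewsphere.geometry`).
    """
    frame = tangent_frame(params.mu)
    X = np.asarray(x, dtype=float)
    arg = X @ (frame.upsilon @ params.gamma)
    out = (
        np.log(2.0)
        + fvml_logpdf(X, params.mu, params.tau)
        + log_skewing(arg, params.skewing)
    )
    return out if np.ndim(out) else float(out)


def svm_logpdf(theta, mu_angle: float, tau: float, gamma: float, skewing: str = "probit"):
    """Log-density of the skew-von Mises distribution on the circle.

    ``theta`` and ``mu_angle`` are angles in (-pi, pi]; ``gamma = 0`` gives the
    von Mises log-density.  With ``skewing="sine"`` this is the sine-skewed
    von Mises (gamma restricted to [-1, 1]).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if skewing == "sine" and abs(gamma) > 1:
        raise ValueError("sine skewing requires gamma in [-1, 1]")
    theta = np.asarray(theta, dtype=float)
    d = theta - mu_angle
    out = (
        -np.log(np.pi)
        - log_bessel_i(0.0, tau)
        + tau * np.cos(d)
        + log_skewing(gamma * np.sin(d), skewing)
    )
    return out if out.ndim else float(out)
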