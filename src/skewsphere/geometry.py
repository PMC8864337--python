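"""Coordinate conventions on the circle and sphere.

Everything downstream (densities, samplers, the Gibbs machinery) relies on the
tangent-normal decomposition of a unit vector ``x`` about a location ``mu``:

    x = t * mu + sqrt(1 - t**2) * Upsilon_mu @ u,   t = x @ mu,

where ``Upsilon_mu`` is a p x (p-1) semi-orthogonal matrix spanning the tangent
space at ``mu`` (``Upsilon.T @ Upsilon = I_{p-1}``,
``Upsilon @ Upsilon.T = I_p - mu mu.T``) and ``u`` is the unit "sign vector" of
the tangent component, uniformly distributed on S^{p-2} under rotational
symmetry.

Angles live in radians.  On the circle the angle interval is ``(-pi, pi]``; on
the sphere the colatitude ``theta1`` is in ``[0, pi]`` and the longitude
``theta2`` in ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitVector",
    "TangentFrame",
    "TangentDecomposition",
    "wrap_angle",
    "to_cartesian",
    "to_angles",
    "tangent_frame",
    "tangent_decompose",
    "as_unit_vector",
]

_UNIT_TOL = 1e-12


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval ``(-pi, pi]``."""
    a = np.asarray(a, dtype=float)
    out = np.pi - np.remainder(np.pi - a, 2.0 * np.pi)
    return out if out.ndim else float(out)


def as_unit_vector(x, tol: float = 1e-8) -> np.ndarray:
    """Validate and renormalize a vector expected to lie on the unit sphere."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("a unit vector must be 1-d with p >= 2 components")
    if not np.all(np.isfinite(x)):
        raise ValueError("unit vector has non-finite components")
    nrm = float(np.linalg.norm(x))
    if abs(nrm - 1.0) > tol:
        raise ValueError(f"vector norm {nrm!r} is not 1 within {tol}")
    return x / nrm


@dataclass(frozen=True)
class UnitVector:
    """A point on S^{p-1}; thin validated wrapper around an ndarray."""

    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "coords", as_unit_vector(self.coords, _UNIT_TOL * 10))

    @property
    def p(self) -> int:
        return self.coords.size


@dataclass(frozen=True)
class TangentFrame:
    """Location ``mu`` together with its tangent-space basis ``upsilon``."""

    mu: np.ndarray
    upsilon: np.ndarray


@dataclass(frozen=True)
class TangentDecomposition:
    """Tangent-normal coordinates of a point about a location.

    ``t`` is the cosine of the angular distance to ``mu``; ``u`` the unit sign
    vector in the tangent space (a scalar in {-1, +1} for p=2, exposed as a
    length-1 array).  ``degenerate`` marks x = +-mu, where ``u`` is set to the
    first tangent basis vector by convention.
    """

    t: float
    u: np.ndarray
    degenerate: bool = field(default=False)


def to_cartesian(angles) -> np.ndarray:
    """Spherical angles -> Cartesian unit vector(s), standard cosine transform.

    p=2: ``theta -> (cos theta, sin theta)``;
    p=3: ``(theta1, theta2) -> (cos t1, sin t1 cos t2, sin t1 sin t2)``.

    Accepts a single angle vector of length p-1 or an (n, p-1) batch.
    """
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    if a.shape[1] == 1:
        x = np.column_stack([np.cos(a[:, 0]), np.sin(a[:, 0])])
    elif a.shape[1] == 2:
        s1 = np.sin(a[:, 0])
        x = np.column_stack([np.cos(a[:, 0]), s1 * np.cos(a[:, 1]), s1 * np.sin(a[:, 1])])
    else:
        raise ValueError("only p=2 and p=3 are supported")
    return x[0] if np.ndim(angles) <= 1 else x


def to_angles(x) -> np.ndarray:
    """Inverse of :func:`to_cartesian`.

    p=2 returns ``theta`` in ``(-pi, pi]``; p=3 returns ``(theta1, theta2)``
    with ``theta1`` in ``[0, pi]`` and ``theta2`` in ``(-pi, pi]``.  At a pole
    (|x1| = 1, p=3) the longitude is undefined and set to 0 by convention.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] == 2:
        th = np.arctan2(X[:, 1], X[:, 0])
        th = np.where(th <= -np.pi, np.pi, th)
        out = th[:, None]
    elif X.shape[1] == 3:
        t1 = np.arccos(np.clip(X[:, 0], -1.0, 1.0))
        t2 = np.arctan2(X[:, 2], X[:, 1])
        at_pole = np.abs(X[:, 0]) >= 1.0 - 1e-15  # longitude undefined
        t2 = np.where(at_pole, 0.0, t2)
        t2 = np.where(t2 <= -np.pi, np.pi, t2)
        out = np.column_stack([t1, t2])
    else:
        raise ValueError("only p=2 and p=3 are supported")
    return out[0] if np.ndim(x) == 1 else out


def tangent_frame(mu) -> TangentFrame:
    """Deterministic semi-orthogonal tangent basis at ``mu``.

    Built from the reflection R mapping e1 -> mu (Householder across
    ``e1 + mu``), taking the images of e2..ep with a global sign flip.  The
    sign is fixed so that for p=2 the single column is the +90-degree rotation
    of mu, i.e. ``upsilon.T @ x(theta) = sin(theta - mu_angle)``.  Smooth in mu
    except at mu = -e1, where a fixed basis is used.
    """
    mu = as_unit_vector(mu)
    p = mu.size
    if 1.0 + mu[0] < 1e-14:  # mu = -e1: reflection degenerates
        ups = np.zeros((p, p - 1))
        ups[1, 0] = -1.0
        for j in range(2, p):
            ups[j, j - 1] = 1.0
        return TangentFrame(mu=mu, upsilon=ups)
    v = mu.copy()
    v[0] += 1.0
    # R e_j = 2 v v_j / (v^T v) - e_j ;  Upsilon = -R[:, 1:] = E - v w^T
    w = v[1:] * (2.0 / (v @ v))
    ups = -np.outer(v, w)
    ups[1:, :] += np.eye(p - 1)
    return TangentFrame(mu=mu, upsilon=ups)


def tangent_decompose(x, frame: TangentFrame) -> TangentDecomposition:
    """Tangent-normal coordinates of ``x`` with respect to ``frame``."""
    x = as_unit_vector(x)
    t = float(np.clip(x @ frame.mu, -1.0, 1.0))
    w = frame.upsilon.T @ x
    nw = float(np.linalg.norm(w))
    if nw < 1e-14:
        u = np.zeros(frame.upsilon.shape[1])
        u[0] = 1.0
        return TangentDecomposition(t=t, u=u, degenerate=True)
    return TangentDecomposition(t=t, u=w / nw, degenerate=False)
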