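"""Exact random generation for FvML / skew-FvML, plus a generic slice sampler.

Skew-FvML variates are produced by the sign-flip construction: draw Y from the
symmetric FvML core, decompose it into (t, u) about mu, and keep the tangent
sign vector u with probability Pi(sqrt(1-t^2) gamma @ u), otherwise flip it.
The output X = t mu + sqrt(1-t^2) Upsilon u'' has the skew-FvML law, with
exactly one output per core draw (no rejection).

All randomness flows through :class:`RandomStream`, a labelled-substream
wrapper over numpy's SeedSequence: the same seed yields bit-identical draw
sequences per consumer, so e.g. changing the Gibbs candidate-pool size does
not perturb the synthetic data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .densities import SFvMLParams, log_skewing
from .geometry import tangent_frame, to_angles, to_cartesian, wrap_angle

__all__ = [
    "RandomStream",
    "DirectionSample",
    "sample_fvml",
    "sample_sfvml",
    "slice_sample",
]


class RandomStream:
    """Seeded RNG with deterministic, labelled substreams.

    ``child(label)`` derives an independent stream from the label's CRC32, so
    consumers ("data", "chain", ...) can be re-ordered or added without
    perturbing each other.  ``generator()`` returns a fresh numpy Generator;
    calling it twice gives the same sequence again.
    """

    def __init__(self, seed: int, _path: tuple = ()):  # noqa: D401
        self.seed = int(seed)
        self._path = tuple(_path)

    def child(self, label: str) -> "RandomStream":
        return RandomStream(self.seed, self._path + (zlib.crc32(label.encode()),))

    def spawn(self, n: int) -> list:
        return [self.child(f"spawn-{i}") for i in range(n)]

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=self._path))

    def __repr__(self):
        return f"RandomStream(seed={self.seed}, path={self._path})"


def _as_generator(stream) -> np.random.Generator:
    if isinstance(stream, RandomStream):
        return stream.generator()
    if isinstance(stream, np.random.Generator):
        return stream
    return RandomStream(int(stream)).generator()


@dataclass(frozen=True)
class DirectionSample:
    """n observations on S^{p-1}, stored as angles with a Cartesian view."""

    angles: np.ndarray  # (n, p-1)

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.ndim != 2 or a.shape[1] not in (1, 2):
            raise ValueError("angles must be (n,) / (n,1) for p=2 or (n,2) for p=3")
        object.__setattr__(self, "angles", a)

    @classmethod
    def from_cartesian(cls, x) -> "DirectionSample":
        return cls(angles=to_angles(np.atleast_2d(np.asarray(x, dtype=float))))

    @property
    def n(self) -> int:
        return self.angles.shape[0]

    @property
    def p(self) -> int:
        return self.angles.shape[1] + 1

    @property
    def theta(self) -> np.ndarray:
        """Circular angles (p=2 convenience view)."""
        if self.p != 2:
            raise ValueError("theta is only defined for p=2")
        return self.angles[:, 0]

    def cartesian(self) -> np.ndarray:
        return to_cartesian(self.angles)


def sample_fvml(n: int, mu, tau, stream) -> DirectionSample:
    """i.i.d. draws from the FvML distribution on S^{p-1} (p = 2 or 3).

    p=2 uses numpy's von Mises generator (Best-Fisher rejection); p=3 uses the
    closed-form inverse CDF of the tangent coordinate
    ``t = 1 + log(u + (1-u) e^{-2 tau}) / tau`` plus a uniform longitude.
    ``tau`` may be a scalar or a length-n array (used by prior samplers).
    """
    rng = _as_generator(stream)
    mu = np.asarray(mu, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    p = mu.size
    if p == 2:
        mu_angle = float(to_angles(mu)[0])
        th = wrap_angle(rng.vonmises(mu_angle, np.broadcast_to(tau_arr, (n,))))
        return DirectionSample(angles=np.asarray(th))
    if p == 3:
        tau_b = np.broadcast_to(tau_arr, (n,))
        u = rng.random(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * tau_b)) / tau_b
        t = np.where(tau_b == 0.0, 2.0 * u - 1.0, t)
        psi = rng.uniform(-np.pi, np.pi, n)
        frame = tangent_frame(mu)
        s = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
        tang = np.column_stack([np.cos(psi), np.sin(psi)]) @ frame.upsilon.T
        x = t[:, None] * mu + s[:, None] * tang
        return DirectionSample.from_cartesian(x)
    raise ValueError("only p=2 and p=3 are supported")


def sample_sfvml(n: int, params: SFvMLParams, stream) -> DirectionSample:
    """i.i.d. draws from the skew-FvML law via the sign-flip construction."""
    rng = _as_generator(stream)
    p = params.p
    frame = tangent_frame(params.mu)
    core = sample_fvml(n, params.mu, params.tau, rng).cartesian()
    t = np.clip(core @ params.mu, -1.0, 1.0)
    s = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    w = core @ frame.upsilon  # (n, p-1) tangent components = s * u
    nw = np.linalg.norm(w, axis=1)
    u = np.zeros_like(w)
    u[:, 0] = 1.0  # convention at the poles (measure zero)
    ok = nw > 1e-14
    u[ok] = w[ok] / nw[ok, None]
    arg = s * (u @ params.gamma)
    flip = np.log(rng.random(n)) > log_skewing(arg, params.skewing)
    u[flip] *= -1.0
    x = t[:, None] * params.mu + s[:, None] * (u @ frame.upsilon.T)
    # renormalize against accumulated rounding
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    return DirectionSample.from_cartesian(x)


def slice_sample(
    log_target,
    x0,
    n: int,
    width: float = 1.0,
    stream=None,
    burnin: int = 0,
    thin: int = 1,
    max_doublings: int = 50,
) -> np.ndarray:
    """Univariate-update slice sampler (stepping-out then shrinkage).

    Cycles the coordinates of ``x0`` and returns ``n`` states after ``burnin``
    iterations, keeping every ``thin``-th state.  ``log_target`` maps a 1-d
    point to an unnormalized log-density and may return -inf outside the
    support; a NaN aborts with a diagnostic naming the offending point.
    """
    rng = _as_generator(stream)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError(f"log_target not finite at the initial point {x!r}")
    out = np.empty((n, d))
    kept = 0
    it = 0
    while kept < n:
        for j in range(d):
            lp = _slice_update(log_target, x, j, lp, width, max_doublings, rng)
        it += 1
        if it > burnin and (it - burnin) % thin == 0:
            out[kept] = x
            kept += 1
    return out


def _slice_update(log_target, x, j, lp, width, max_doublings, rng):
    """One Neal (2003) stepping-out/shrinkage update of coordinate j in place."""
    y = lp + np.log(rng.random())
    lo = x[j] - width * rng.random()
    hi = lo + width
    xj0 = x[j]

    def f(v):
        x[j] = v
        val = float(log_target(x))
        if np.isnan(val):
            raise FloatingPointError(f"log_target returned NaN at {x!r}")
        return val

    k = max_doublings
    while k > 0 and f(lo) > y:
        lo -= width
        k -= 1
    k = max_doublings
    while k > 0 and f(hi) > y:
        hi += width
        k -= 1
    while True:
        v = rng.uniform(lo, hi)
        val = f(v)
        if val > y:
            x[j] = v
            return val
        if v < xj0:
            lo = v
        else:
            hi = v
        if hi - lo < 1e-300:
            x[j] = xj0
            return lp
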