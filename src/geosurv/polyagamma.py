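"""Exact Pólya-Gamma PG(1, z) sampling for logit data augmentation.

A PG(1, z) variable tilts the Jacobi distribution J*(1, z/2)/4.  Draws use
the alternating-series rejection sampler of Devroye: propose from a mixture
of a truncated inverse-Gaussian (left of 0.64) and an exponential tail, then
accept via partial sums of the Jacobi density series.  The per-draw loops are
compiled with numba; a vector of n draws costs O(n) with a small constant.

Seeding uses numba's own global legacy RNG (``np.random.seed`` inside jitted
code), so the caller must pass an explicit 32-bit seed per vector of draws.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # Devroye's crossing point between the two series regimes


@njit(cache=True, fastmath=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True, fastmath=True)
def _mass_texpon(z):
    """Probability that a J*(1, z) draw falls in the exponential tail."""
    t = _TRUNC
    fz = math.pi * math.pi / 8.0 + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    cb = _norm_cdf(b)
    ca = _norm_cdf(a)
    xb = x0 - z + math.log(cb) if cb > 0.0 else -np.inf
    xa = x0 + z + math.log(ca) if ca > 0.0 else -np.inf
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True, fastmath=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC]."""
    t = _TRUNC
    if z < 1.0 / t:  # mu > t: rejection from truncated inverse-chi-square
        while True:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True, fastmath=True)
def _a_coef(n, x):
    """n-th term of the alternating Jacobi density series at x."""
    npl = n + 0.5
    if x > _TRUNC:
        return math.pi * npl * math.exp(-0.5 * npl * npl * math.pi * math.pi * x)
    return math.pi * npl * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * npl * npl / x)


@njit(cache=True, fastmath=True)
def _sample_jstar(z):
    """One draw from the tilted Jacobi J*(1, z), z >= 0."""
    fz = math.pi * math.pi / 8.0 + 0.5 * z * z
    p_texp = _mass_texpon(z)
    while True:
        if np.random.random() < p_texp:
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True, fastmath=True)
def _pg_fill(z, seed, out):
    np.random.seed(seed)
    for i in range(z.shape[0]):
        out[i] = 0.25 * _sample_jstar(0.5 * abs(z[i]))


def polya_gamma(z, seed):
    """Draw PG(1, z_i) for every tilt in ``z``.

    Parameters
    ----------
    z : array-like
        Tilting parameters (the linear predictor in logit models).
    seed : int
        Non-negative 32-bit seed; identical (z, seed) pairs reproduce
        identical draws.
    """
    z = np.ascontiguousarray(z, dtype=np.float64)
    out = np.empty_like(z)
    _pg_fill(z, np.uint32(seed), out)
    return out
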