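"""Matérn Gaussian random fields over participant locations.

The spatial random effect models contextual unobserved confounders (for
example material deprivation) that vary smoothly in space.  The covariance
family is Matérn with marginal standard deviation ``sd``, range ``rho`` and
smoothness ``nu``:

    C(d) = sd^2 * 2^(1-nu)/Gamma(nu) * (sqrt(2 nu) d / rho)^nu
           * K_nu(sqrt(2 nu) d / rho)

so that nu = 1/2 reduces to the exponential covariance sd^2 exp(-d/rho).
Fields are simulated by dense Cholesky factorisation over the (deduplicated)
location set; coincident locations share one field value by construction of
the covariance (correlation 1).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import kv


def matern_correlation(dist: np.ndarray, rho: float, nu: float) -> np.ndarray:
    """Matérn correlation at distances ``dist`` (range ``rho``, smoothness ``nu``)."""
    if rho <= 0:
        raise ValueError("range must be positive")
    if nu <= 0:
        raise ValueError("smoothness must be positive")
    d = np.asarray(dist, dtype=float)
    scaled = np.sqrt(2.0 * nu) * d / rho
    out = np.ones_like(scaled)
    pos = scaled > 0
    s = scaled[pos]
    out[pos] = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * (s ** nu) * kv(nu, s)
    # K_nu underflows for very large arguments; the limit is 0 correlation
    out[~np.isfinite(out)] = 0.0
    return out


def matern_covariance(coords: np.ndarray, sd: float, rho: float,
                      nu: float = 1.0) -> np.ndarray:
    """Dense Matérn covariance matrix over an (m, 2) coordinate array."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    dist = cdist(coords, coords)
    return sd ** 2 * matern_correlation(dist, rho, nu)


def simulate_matern_field(coords: np.ndarray, sd: float, rho: float,
                          nu: float = 1.0,
                          rng: np.random.Generator | int | None = None,
                          max_jitter_tries: int = 6) -> np.ndarray:
    """Draw one zero-mean Gaussian field with Matérn covariance at ``coords``.

    Duplicate coordinates receive identical values.  If the covariance is
    numerically indefinite the diagonal is jittered (starting at 1e-10 of
    the marginal variance, growing tenfold) before giving up.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(rng)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m = coords.shape[0]
    if m == 0:
        raise ValueError("need at least one location")
    if sd == 0:
        return np.zeros(m)
    cov = matern_covariance(coords, sd, rho, nu)
    jitter = 1e-10 * sd ** 2
    for _ in range(max_jitter_tries):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(m))
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
    else:
        raise np.linalg.LinAlgError(
            "Matérn covariance not positive definite even after jittering")
    z = rng.standard_normal(m)
    field = chol @ z
    # force exact equality on coincident locations (jitter breaks the tie)
    _, first_idx, inverse = np.unique(coords, axis=0, return_index=True,
                                      return_inverse=True)
    return field[first_idx][inverse]
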