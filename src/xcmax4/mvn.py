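"""Multivariate-normal rectangle probabilities by randomized quasi-Monte
Carlo (Genz's separation-of-variables transform over scrambled Sobol
points).

Used as the numerical cross-check for the analytic rhombus bound. The
covariance may be singular (the 4x4 correlation matrix of the canonical
codings always is); a PSD-aware Cholesky handles that case.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

__all__ = ["mvn_rectangle_probability"]


def _chol_psd(Sig: np.ndarray, jitter: float = 1e-12) -> np.ndarray:
    """Lower-triangular factor L with L L' ~= Sig, tolerating PSD input."""
    Sig = np.asarray(Sig, dtype=float)
    k = Sig.shape[0]
    try:
        return np.linalg.cholesky(Sig + jitter * np.eye(k))
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(Sig)
        if w.min() < -1e-8:
            raise np.linalg.LinAlgError(
                f"covariance is not positive semidefinite (min eigenvalue {w.min():.2e})"
            )
        A = Q * np.sqrt(np.clip(w, 1e-12, None))
        r = np.linalg.qr(A.T, mode="r")
        L = r.T
        return L * np.sign(np.diag(L))  # fix QR sign ambiguity


def mvn_rectangle_probability(
    lower: np.ndarray,
    upper: np.ndarray,
    sigma: np.ndarray,
    n_points: int = 2**17,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 8,
) -> tuple[float, float]:
    """Estimate P(lower <= Y <= upper) for Y ~ N(0, sigma).

    Parameters
    ----------
    n_points : int
        Total quasi-random points, split over ``n_replicates`` independently
        scrambled Sobol sequences; the spread of the replicate means gives
        the standard-error estimate.
    seed : int or Generator
        Seeds the Sobol scrambling; the estimate is reproducible given the
        seed.

    Returns
    -------
    (estimate, standard_error)
    """
    sigma = np.asarray(sigma, dtype=float)
    k = sigma.shape[0]
    a = np.broadcast_to(np.asarray(lower, dtype=float), (k,))
    b = np.broadcast_to(np.asarray(upper, dtype=float), (k,))
    L = _chol_psd(sigma)
    if k == 1:
        return float(ndtr(b[0] / L[0, 0]) - ndtr(a[0] / L[0, 0])), 0.0

    rng = np.random.default_rng(seed)
    m = max(1, n_points // n_replicates)
    ests = np.empty(n_replicates)
    for rep in range(n_replicates):
        sob = qmc.Sobol(d=k - 1, scramble=True, rng=rng)
        u = sob.random(m)
        d = ndtr(np.full(m, a[0] / L[0, 0]))
        e = ndtr(np.full(m, b[0] / L[0, 0]))
        f = e - d
        y = np.empty((m, k - 1))
        for i in range(1, k):
            q = np.clip(d + u[:, i - 1] * (e - d), 1e-16, 1.0 - 1e-16)
            y[:, i - 1] = ndtri(q)
            mu = y[:, :i] @ L[i, :i]
            d = ndtr((a[i] - mu) / L[i, i])
            e = ndtr((b[i] - mu) / L[i, i])
            f = f * np.clip(e - d, 0.0, None)
        ests[rep] = f.mean()
    return float(ests.mean()), float(ests.std(ddof=1) / np.sqrt(n_replicates))
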