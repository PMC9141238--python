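"""Maximum-likelihood fit of the null logistic model (covariates only).

Every score statistic shares one null fit: the model ``logit Pr(D=1|X) =
X'alpha`` is fitted once per dataset, and the fitted probabilities feed the
score function, the information blocks and the correlation matrix for all
genotype codings. A tightly converged fit matters because downstream
p-values can be as small as 1e-22; the Newton iteration below is run to a
max-gradient of 1e-8 (absolute, also satisfying the relative contract
``max|X'(D - p)| <= 1e-8 * n``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CaseControlData
from .errors import ConvergenceError, SeparationError, ValidationError

__all__ = ["NullFit", "fit_null"]

MAX_ITER = 50
GRAD_TOL = 1e-8
LL_RELTOL = 1e-10
SEP_TOL = 1e-10


@dataclass
class NullFit:
    """Fitted null model.

    Attributes
    ----------
    alpha_hat : ndarray
        Coefficients of the covariate-only logistic model.
    p_hat : ndarray
        Per-subject fitted disease probability Pr(D=1|X).
    w : ndarray
        Per-subject weight p_hat * (1 - p_hat).
    loglik : float
        Maximized log-likelihood.
    converged : bool
    iterations : int
    """

    alpha_hat: np.ndarray
    p_hat: np.ndarray
    w: np.ndarray
    loglik: float
    converged: bool
    iterations: int


def _loglik(d, eta):
    # log L = sum d*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(d * eta - np.logaddexp(0.0, eta)))


def fit_null(data: CaseControlData) -> NullFit:
    """Newton (IRLS) fit of ``logit Pr(D=1) = X'alpha``.

    Deterministic given the data; raises :class:`SeparationError` when the
    fit drifts towards perfect separation (fitted probabilities within 1e-10
    of 0/1 with diverging coefficients) and :class:`ConvergenceError` when 50
    iterations do not reach tolerance.
    """
    X = data.covariates
    d = data.phenotype.astype(np.float64)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("covariate matrix is rank deficient")

    alpha = np.zeros(p)
    # intercept-only warm start keeps the first step well-scaled
    dbar = d.mean()
    alpha[0] = np.log(dbar / (1.0 - dbar))
    eta = X @ alpha
    ll = _loglik(d, eta)
    # a converged fit whose probabilities sit this close to 0/1 (|eta| > 18)
    # is separation that met the gradient tolerance, not a usable null model
    sep_final = 1e-8

    def _finish(alpha, mu, ll, its):
        if np.any(mu <= sep_final) or np.any(mu >= 1.0 - sep_final):
            raise SeparationError(
                "separation detected: fitted probabilities at the 0/1 boundary"
            )
        return NullFit(alpha, mu, mu * (1.0 - mu), ll, True, its)

    for it in range(1, MAX_ITER + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (d - mu)
        if np.max(np.abs(grad)) <= GRAD_TOL:
            return _finish(alpha, mu, ll, it - 1)
        w = mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("separation detected (singular information)") from exc
        # damped Newton: halve until the log-likelihood does not decrease
        t = 1.0
        for _ in range(30):
            cand = alpha + t * step
            eta_c = X @ cand
            ll_c = _loglik(d, eta_c)
            if ll_c >= ll - 1e-12:
                break
            t *= 0.5
        rel_change = abs(ll_c - ll) / max(1.0, abs(ll_c))
        alpha, eta, ll = cand, eta_c, ll_c
        mu = 1.0 / (1.0 + np.exp(-eta))
        at_boundary = (mu < SEP_TOL) | (mu > 1.0 - SEP_TOL)
        if at_boundary.any() and np.max(np.abs(alpha)) > 1e2:
            raise SeparationError("separation detected")
        if rel_change < LL_RELTOL and np.max(np.abs(X.T @ (d - mu))) <= GRAD_TOL * n:
            return _finish(alpha, mu, ll, it)
    raise ConvergenceError(f"null logistic fit did not converge in {MAX_ITER} iterations")
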