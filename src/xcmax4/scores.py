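"""Score statistics for X-chromosome codings and their correlation matrix.

For a coding (Z1, Z2) the genotypic score is G = 2*I(female AA) +
Z1*I(female Aa) + Z2*I(male A). With the shared null fit p_hat, the score
function is U = sum_i G_i (D_i - p_hat_i) and its variance the covariate-
projected information

    V = I_b - I_ba I_a^{-1} I_ba',

with I_b = sum G^2 w, I_ba = sum X G w, I_a = X' W X and w = p_hat(1-p_hat).
The standardized statistic S = U / sqrt(V) is asymptotically standard normal
under no association. Running several codings jointly in one two-effect
model yields the covariance matrix C between score functions, hence the
correlation matrix Sigma of the component statistics.

The 4x4 Sigma of the canonical codings is always singular (rank <= 3): the
four score vectors live in the span of the three indicators {female AA,
female Aa, male A}. All downstream consumers therefore treat Sigma as
positive *semi*-definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CANONICAL_CODINGS, CaseControlData, XciCoding
from .errors import DegenerateStatisticError, ValidationError
from .null_model import NullFit

__all__ = [
    "ScoreStatistic",
    "CorrelationMatrix",
    "genotypic_score",
    "score_U",
    "score_variance",
    "component_statistics",
    "pairwise_covariance",
    "correlation_matrix",
]

DEGENERATE_EPS = 1e-12
CLIP_EPS = 1e-8


@dataclass
class ScoreStatistic:
    """Score test of one coding: U, V, S = U/sqrt(V) and W = S^2."""

    coding: XciCoding
    U: float
    V: float
    degenerate: bool = False

    @property
    def S(self) -> float:
        return self.U / np.sqrt(self.V) if not self.degenerate else np.nan

    @property
    def W(self) -> float:
        return self.U**2 / self.V if not self.degenerate else np.nan


@dataclass
class CorrelationMatrix:
    """Correlation matrix Sigma of the component statistics, in the fixed
    coding order (0,2), (1,2), (2,2), (1,1)."""

    sigma: np.ndarray
    codings: tuple[XciCoding, ...] = CANONICAL_CODINGS
    clipped: bool = False


def genotypic_score(data: CaseControlData, coding: XciCoding) -> np.ndarray:
    """Per-subject genotypic score under ``coding``."""
    female = data.sex == 1
    G = np.zeros(data.n)
    G[female & (data.genotype == 2)] = 2.0
    G[female & (data.genotype == 1)] = coding.z1
    G[~female & (data.genotype == 1)] = coding.z2
    return G


def score_U(G: np.ndarray, fit: NullFit, D: np.ndarray) -> float:
    """Score function U = sum G (D - p_hat)."""
    return float(G @ (np.asarray(D, dtype=float) - fit.p_hat))


def _projected_covariance(Gmat: np.ndarray, fit: NullFit, X: np.ndarray) -> np.ndarray:
    """Covariance of the score functions of the columns of ``Gmat``:
    G'WG - (G'WX)(X'WX)^{-1}(X'WG)."""
    w = fit.w
    XtWX = X.T @ (w[:, None] * X)
    GtWX = Gmat.T @ (w[:, None] * X)
    GtWG = Gmat.T @ (w[:, None] * Gmat)
    try:
        sol = np.linalg.solve(XtWX, GtWX.T)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariate information matrix is singular") from exc
    C = GtWG - GtWX @ sol
    return 0.5 * (C + C.T)


def score_variance(G: np.ndarray, fit: NullFit, X: np.ndarray) -> float:
    """Variance V of the score function (Schur complement of the covariate
    block in the full information matrix)."""
    V = float(_projected_covariance(G[:, None], fit, X)[0, 0])
    # exact containment of G in span(X) can leave tiny negative noise
    if V < 0:
        I_b = float((G * G) @ fit.w)
        if V < -1e-10 * max(I_b, 1.0):
            raise ValidationError(f"negative score variance {V}")
        V = 0.0
    return V


def pairwise_covariance(
    G1: np.ndarray, G2: np.ndarray, fit: NullFit, X: np.ndarray
) -> np.ndarray:
    """2x2 covariance matrix C of the score functions of two codings, from
    the joint two-effect model."""
    return _projected_covariance(np.column_stack([G1, G2]), fit, X)


def component_statistics(
    data: CaseControlData,
    fit: NullFit,
    codings: tuple[XciCoding, ...] = CANONICAL_CODINGS,
) -> list[ScoreStatistic]:
    """Score statistics for each coding, sharing the single null fit.

    A component is flagged degenerate when its projected variance is at most
    ``1e-12 * I_b`` (e.g. a monomorphic SNP, or a coding entirely contained
    in the covariate span).
    """
    D = data.phenotype.astype(float)
    X = data.covariates
    Gmat = np.column_stack([genotypic_score(data, c) for c in codings])
    C = _projected_covariance(Gmat, fit, X)
    out = []
    for j, coding in enumerate(codings):
        U = float(Gmat[:, j] @ (D - fit.p_hat))
        V = float(C[j, j])
        I_b = float((Gmat[:, j] ** 2) @ fit.w)
        degen = V <= DEGENERATE_EPS * max(I_b, 1.0)
        out.append(ScoreStatistic(coding, U, max(V, 0.0), degenerate=degen))
    return out


def correlation_matrix(
    data: CaseControlData,
    fit: NullFit,
    codings: tuple[XciCoding, ...] = CANONICAL_CODINGS,
) -> CorrelationMatrix:
    """Estimated correlation matrix Sigma of the component statistics.

    Entries are rho = C_jk / sqrt(C_jj C_kk) from the joint-model covariance.
    Values outside [-1, 1] by less than 1e-8 are clipped (floating-point
    guard); larger excursions raise. Degenerate components (zero variance)
    make Sigma undefined and raise — callers should deduplicate or drop them
    first (see the max-test module).
    """
    Gmat = np.column_stack([genotypic_score(data, c) for c in codings])
    C = _projected_covariance(Gmat, fit, data.covariates)
    V = np.diag(C).copy()
    I_b = np.einsum("ij,ij,i->j", Gmat, Gmat, fit.w)
    if np.any(V <= DEGENERATE_EPS * np.maximum(I_b, 1.0)):
        raise DegenerateStatisticError(
            "degenerate component statistic: deduplicate or drop degenerate "
            "codings before estimating Sigma"
        )
    sigma = C / np.sqrt(np.outer(V, V))
    excess = np.max(np.abs(sigma)) - 1.0
    clipped = False
    if excess > CLIP_EPS:
        raise ValidationError(f"correlation outside [-1, 1] by {excess:.2e}")
    if excess > 0:
        sigma = np.clip(sigma, -1.0, 1.0)
        clipped = True
    np.fill_diagonal(sigma, 1.0)
    return CorrelationMatrix(sigma=sigma, codings=tuple(codings), clipped=clipped)
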