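"""XWAS-style covariate-adjusted comparator tests.

FM01 and FM02 are single logistic regressions of disease on the covariates
plus a fixed genotype coding — females 0/1/2 in both, males 0/1 in FM01
(escape-like, autosomal coding) and 0/2 in FM02 (dosage compensation, males
as homozygous females). FMF and FMS fit sex-stratified logistic regressions
(dropping the sex column, keeping other covariates) and combine the two
p-values by Fisher's method (chi-square, 4 df) or Stouffer's method. FMS
combines signed per-sex z-scores so that opposite-direction effects cancel;
stratum weights default to sqrt(sample size), the convention under which the
published Graves' disease results are reproduced (equal weights are
available via ``weights="equal"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .data import CaseControlData, XCI_E, XCI_R, XciCoding
from .errors import SeparationError, ValidationError
from .scores import genotypic_score

__all__ = ["ComparatorResult", "fm01", "fm02", "fmf", "fms"]


@dataclass
class ComparatorResult:
    method: str
    statistic: float
    p_value: float
    per_sex: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "flags": ";".join(self.flags),
            **{f"{k}_{k2}": v2 for k, v in self.per_sex.items() for k2, v2 in v.items()},
        }


def _logit_genotype_test(d, X, G, test: str):
    """Two-sided test of the genotype coefficient in logit(d) ~ X + G.

    Returns (z_signed, p, flags). ``test`` is "wald" or "lrt" (the LRT keeps
    the Wald sign for direction-aware combination).
    """
    flags: list[str] = []
    if np.ptp(G) == 0:
        return 0.0, 1.0, ["degenerate_genotype"]
    Xfull = np.column_stack([X, G])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        return 0.0, 1.0, ["degenerate_genotype"]
    try:
        m1 = sm.Logit(d, Xfull).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
    except Exception as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not m1.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (separation?)")
    beta = m1.params[-1]
    se = m1.bse[-1]
    zval = beta / se
    if test == "wald":
        p = 2.0 * norm.sf(abs(zval))
        stat = zval
    elif test == "lrt":
        m0 = sm.Logit(d, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
        lr = 2.0 * (m1.llf - m0.llf)
        p = float(chi2.sf(max(lr, 0.0), 1))
        stat = np.sign(beta) * np.sqrt(max(lr, 0.0))
    else:
        raise ValidationError(f"unknown test convention {test!r}")
    return float(stat), float(p), flags


def _fm(data: CaseControlData, coding: XciCoding, method: str, test: str) -> ComparatorResult:
    G = genotypic_score(data, coding)
    stat, p, flags = _logit_genotype_test(
        data.phenotype.astype(float), data.covariates, G, test
    )
    return ComparatorResult(method=method, statistic=stat, p_value=p, flags=flags)


def fm01(data: CaseControlData, test: str = "wald") -> ComparatorResult:
    """Logistic regression with females 0/1/2 and males 0/1 (coding (1,1))."""
    return _fm(data, XCI_E, "FM01", test)


def fm02(data: CaseControlData, test: str = "wald") -> ComparatorResult:
    """Logistic regression with females 0/1/2 and males 0/2 (coding (1,2))."""
    return _fm(data, XCI_R, "FM02", test)


def _stratified(data: CaseControlData, test: str):
    """Per-sex genotype tests with the sex column dropped from X."""
    per_sex = {}
    for label, s in (("female", 1), ("male", 0)):
        m = data.sex == s
        if m.sum() == 0 or len(np.unique(data.phenotype[m])) < 2:
            raise ValidationError(
                f"{label} stratum lacks both phenotype classes; sex-stratified "
                "combination is undefined"
            )
        # drop the sex column (constant within stratum), keep other covariates
        X = np.delete(data.covariates[m], 1, axis=1)
        keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
        X = X[:, keep]
        G = data.genotype[m].astype(float)
        z, p, flags = _logit_genotype_test(data.phenotype[m].astype(float), X, G, test)
        per_sex[label] = {"z": z, "p": p, "n": int(m.sum()), "flags": ";".join(flags)}
    return per_sex


def fmf(data: CaseControlData, test: str = "wald") -> ComparatorResult:
    """Fisher combination of the per-sex two-sided p-values, chi-square 4 df."""
    per_sex = _stratified(data, test)
    pF, pM = per_sex["female"]["p"], per_sex["male"]["p"]
    stat = -2.0 * (np.log(pF) + np.log(pM))
    return ComparatorResult(
        method="FMF", statistic=float(stat), p_value=float(chi2.sf(stat, 4)), per_sex=per_sex
    )


def fms(data: CaseControlData, test: str = "wald", weights: str = "sqrt_n") -> ComparatorResult:
    """Stouffer combination of signed per-sex z-scores.

    ``weights``: "sqrt_n" (default; stratum weight proportional to the square
    root of its sample size) or "equal". The combined z is renormalized to
    unit variance and referred to the standard normal, two-sided.
    """
    per_sex = _stratified(data, test)
    zF, zM = per_sex["female"]["z"], per_sex["male"]["z"]
    if weights == "sqrt_n":
        wF, wM = np.sqrt(per_sex["female"]["n"]), np.sqrt(per_sex["male"]["n"])
    elif weights == "equal":
        wF = wM = 1.0
    else:
        raise ValidationError(f"unknown weights {weights!r}")
    z = (wF * zF + wM * zM) / np.sqrt(wF**2 + wM**2)
    return ComparatorResult(
        method="FMS", statistic=float(z), p_value=float(2.0 * norm.sf(abs(z))), per_sex=per_sex
    )
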