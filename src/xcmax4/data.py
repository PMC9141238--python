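"""Domain types for X-chromosome case-control data.

Genotypes are counts of the risk allele A: females carry 0/1/2 copies
(aa/Aa/AA), hemizygous males carry 0/1 (a/A). Sex enters the analysis both as
the covariate x2 (1 = female, 0 = male) and through the genotypic coding. The
covariate matrix always has an intercept as its first column and sex as its
second; further columns are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "XciCoding",
    "XCI_SN",
    "XCI_R",
    "XCI_SR",
    "XCI_E",
    "CANONICAL_CODINGS",
    "CaseControlData",
    "CountTable",
    "StratifiedCountTable",
    "ValidationReport",
    "expand_counts",
    "validate",
    "read_tabular",
    "read_count_table",
    "read_vcf",
]


@dataclass(frozen=True)
class XciCoding:
    """A genotypic-score scheme (Z1, Z2).

    Z1 is the score given to heterozygous females (Aa), Z2 the score given to
    hemizygous males carrying the risk allele. Female AA is always 2, female
    aa and male a always 0. The four canonical schemes correspond to the four
    X-inactivation patterns: full skew towards silencing the risk allele
    (XCI-SN), random inactivation (XCI-R), full skew towards the normal
    allele (XCI-SR), and escape from inactivation (XCI-E).
    """

    z1: float
    z2: float
    label: str = "custom"

    @classmethod
    def from_gamma(cls, gamma: float) -> "XciCoding":
        """Coding for an SNP undergoing XCI with skewness ``gamma`` in [0, 2].

        gamma plays the role of Z1 while males stay dosage-compensated
        (Z2 = 2). gamma = 0, 1, 2 give XCI-SN, XCI-R, XCI-SR.
        """
        if not 0.0 <= gamma <= 2.0:
            raise ValidationError(f"gamma must lie in [0, 2], got {gamma}")
        canonical = {0.0: "XCI-SN", 1.0: "XCI-R", 2.0: "XCI-SR"}
        return cls(float(gamma), 2.0, canonical.get(float(gamma), f"XCI-S(gamma={gamma:g})"))


XCI_SN = XciCoding(0, 2, "XCI-SN")
XCI_R = XciCoding(1, 2, "XCI-R")
XCI_SR = XciCoding(2, 2, "XCI-SR")
XCI_E = XciCoding(1, 1, "XCI-E")

#: Fixed component order used throughout: (0,2), (1,2), (2,2), (1,1).
CANONICAL_CODINGS: tuple[XciCoding, ...] = (XCI_SN, XCI_R, XCI_SR, XCI_E)


@dataclass
class CaseControlData:
    """Individual-level data consumed by every test.

    Attributes
    ----------
    genotype : ndarray of int
        Risk-allele copies; females in {0, 1, 2}, males in {0, 1}.
    sex : ndarray of int
        1 = female, 0 = male (covariate x2).
    phenotype : ndarray of int
        1 = case, 0 = control.
    covariates : ndarray, shape (n, p)
        Column 0 is the intercept, column 1 is sex; extra columns optional.
    ids : ndarray of str, optional
        Subject identifiers (generated if absent).
    label : str
        Dataset tag carried through to results.
    n_dropped_missing : int
        Rows removed by listwise deletion before construction (reported by
        the readers; analysis formulas assume complete data).
    """

    genotype: np.ndarray
    sex: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray
    ids: np.ndarray | None = None
    label: str = ""
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.covariates = np.asarray(self.covariates, dtype=np.float64)
        n = self.genotype.shape[0]
        if not (self.sex.shape[0] == self.phenotype.shape[0] == n == self.covariates.shape[0]):
            raise ValidationError("genotype, sex, phenotype and covariates must have equal length")
        if self.covariates.ndim != 2:
            raise ValidationError("covariates must be a 2-D matrix")
        if n == 0:
            raise ValidationError("empty dataset")
        if not np.all(np.isin(self.sex, [0, 1])):
            raise ValidationError("sex must be coded 0 (male) / 1 (female)")
        if not np.all(np.isin(self.phenotype, [0, 1])):
            raise ValidationError("phenotype must be coded 0 (control) / 1 (case)")
        bad_f = ~np.isin(self.genotype[self.sex == 1], [0, 1, 2])
        bad_m = ~np.isin(self.genotype[self.sex == 0], [0, 1])
        if bad_f.any():
            raise ValidationError("female genotypes must be 0, 1 or 2 risk-allele copies")
        if bad_m.any():
            raise ValidationError("male genotypes must be 0 or 1 risk-allele copies")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise ValidationError("first covariate column must be the intercept (all ones)")
        if self.phenotype.min() == self.phenotype.max():
            raise ValidationError("phenotype must contain at least one case and one control")

    @property
    def n(self) -> int:
        return self.genotype.shape[0]

    @property
    def subject_ids(self) -> np.ndarray:
        """Subject identifiers (generated as s0, s1, ... when none given)."""
        if self.ids is None:
            self.ids = np.array([f"s{i}" for i in range(self.n)])
        return self.ids

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.phenotype.sum())

    def subset(self, mask: np.ndarray) -> "CaseControlData":
        return CaseControlData(
            genotype=self.genotype[mask],
            sex=self.sex[mask],
            phenotype=self.phenotype[mask],
            covariates=self.covariates[mask],
            ids=self.ids[mask] if self.ids is not None else None,
            label=self.label,
        )

    def with_covariate(self, column: np.ndarray, name: str = "") -> "CaseControlData":
        """Return a copy with an extra covariate column appended."""
        col = np.asarray(column, dtype=np.float64).reshape(-1, 1)
        return replace(self, covariates=np.hstack([self.covariates, col]))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genotype: str = "genotype",
        sex: str = "sex",
        phenotype: str = "phenotype",
        covariates: list[str] | None = None,
        id_col: str | None = None,
        label: str = "",
    ) -> "CaseControlData":
        """Build from a tidy per-subject table, with listwise deletion.

        Rows with any missing value among the used columns are dropped and
        counted. Male genotypes recorded as 2 (diploid-homozygous coding) are
        mapped to 1 copy.
        """
        cols = [genotype, sex, phenotype] + list(covariates or [])
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        sub = df[cols].apply(pd.to_numeric, errors="coerce")
        keep = sub.notna().all(axis=1)
        n_dropped = int((~keep).sum())
        sub = sub[keep]
        if len(sub) == 0:
            raise ValidationError("empty dataset after listwise deletion")
        g = sub[genotype].to_numpy()
        s = sub[sex].to_numpy().astype(np.int64)
        g = np.where((s == 0) & (g == 2), 1, g)  # diploid-coded hemizygous males
        X = np.column_stack(
            [np.ones(len(sub)), s.astype(float)]
            + [sub[c].to_numpy(dtype=float) for c in (covariates or [])]
        )
        ids = df.loc[keep.index[keep], id_col].astype(str).to_numpy() if id_col else None
        return cls(
            genotype=g.astype(np.int64),
            sex=s,
            phenotype=sub[phenotype].to_numpy().astype(np.int64),
            covariates=X,
            ids=ids,
            label=label,
            n_dropped_missing=n_dropped,
        )


def _check_counts(counts, k, what):
    arr = np.asarray(counts)
    if arr.shape != (k,):
        raise ValidationError(f"{what} must have {k} entries")
    if not np.all(arr == np.floor(arr)) or (arr < 0).any():
        raise ValidationError(f"{what} must be non-negative integers")
    return tuple(int(c) for c in arr)


@dataclass(frozen=True)
class CountTable:
    """Sex-stratified case/control genotype counts for one SNP.

    Female counts are ordered (AA, Aa, aa) by risk-allele copies 2/1/0, male
    counts (A, a) by copies 1/0. ``allele_labels`` maps the risk and normal
    alleles to their nucleotide names for reporting (the risk allele is
    internally always "A").
    """

    female_case: tuple[int, int, int]
    male_case: tuple[int, int]
    female_control: tuple[int, int, int]
    male_control: tuple[int, int]
    risk_allele: str = "A"
    normal_allele: str = "a"
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "female_case", _check_counts(self.female_case, 3, "female_case"))
        object.__setattr__(self, "male_case", _check_counts(self.male_case, 2, "male_case"))
        object.__setattr__(
            self, "female_control", _check_counts(self.female_control, 3, "female_control")
        )
        object.__setattr__(self, "male_control", _check_counts(self.male_control, 2, "male_control"))

    @property
    def n_total(self) -> int:
        return (
            sum(self.female_case)
            + sum(self.male_case)
            + sum(self.female_control)
            + sum(self.male_control)
        )


@dataclass(frozen=True)
class StratifiedCountTable:
    """Several count tables pooled with a data-source indicator covariate."""

    tables: tuple[CountTable, ...]
    label: str = ""

    @property
    def n_total(self) -> int:
        return sum(t.n_total for t in self.tables)


def expand_counts(table: CountTable | StratifiedCountTable) -> CaseControlData:
    """Expand a count table into one record per counted subject.

    Row order is deterministic: cases before controls, females before males,
    genotype descending. Pooled (stratified) tables are expanded stratum by
    stratum and receive a 0/1/... data-source indicator as an extra covariate
    column after intercept and sex.
    """
    if isinstance(table, StratifiedCountTable):
        parts = [expand_counts(t) for t in table.tables]
        g = np.concatenate([p.genotype for p in parts])
        s = np.concatenate([p.sex for p in parts])
        d = np.concatenate([p.phenotype for p in parts])
        src = np.concatenate([np.full(p.n, i, dtype=float) for i, p in enumerate(parts)])
        X = np.column_stack([np.ones(len(g)), s.astype(float), src])
        return CaseControlData(g, s, d, X, label=table.label)

    if table.n_total == 0:
        raise ValidationError("empty dataset")
    g, s, d = [], [], []
    for pheno, fem, male in [
        (1, table.female_case, table.male_case),
        (0, table.female_control, table.male_control),
    ]:
        for geno, cnt in zip((2, 1, 0), fem):
            g += [geno] * cnt
            s += [1] * cnt
            d += [pheno] * cnt
        for geno, cnt in zip((1, 0), male):
            g += [geno] * cnt
            s += [0] * cnt
            d += [pheno] * cnt
    g = np.array(g, dtype=np.int64)
    s = np.array(s, dtype=np.int64)
    d = np.array(d, dtype=np.int64)
    X = np.column_stack([np.ones(len(g)), s.astype(float)])
    return CaseControlData(g, s, d, X, label=table.label)


def tabulate(data: CaseControlData) -> CountTable:
    """Re-tabulate individual-level data into a CountTable (inverse of
    :func:`expand_counts` for unpooled tables)."""

    def fem(d):
        m = (data.sex == 1) & (data.phenotype == d)
        return tuple(int(((data.genotype[m]) == k).sum()) for k in (2, 1, 0))

    def male(d):
        m = (data.sex == 0) & (data.phenotype == d)
        return tuple(int(((data.genotype[m]) == k).sum()) for k in (1, 0))

    return CountTable(fem(1), male(1), fem(0), male(0), label=data.label)


@dataclass
class ValidationReport:
    """Report-only diagnostics for a dataset; never raises."""

    n: int
    n_cases: int
    n_controls: int
    n_dropped_missing: int
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate(data: CaseControlData) -> ValidationReport:
    """Diagnose rank deficiency, monomorphism and class imbalance.

    Idempotent and side-effect free; structural errors (wrong codes, missing
    intercept) are raised at construction time, everything else is reported
    here as flags.
    """
    flags: list[str] = []
    if data.genotype.min() == data.genotype.max():
        flags.append("monomorphic: score variance will be zero")
    rank = np.linalg.matrix_rank(data.covariates)
    if rank < data.covariates.shape[1]:
        flags.append("rank deficient")
    return ValidationReport(
        n=data.n,
        n_cases=data.n_cases,
        n_controls=data.n_controls,
        n_dropped_missing=data.n_dropped_missing,
        flags=flags,
    )


def read_tabular(
    path,
    sep: str = None,
    genotype: str = "genotype",
    sex: str = "sex",
    phenotype: str = "phenotype",
    covariates: list[str] | None = None,
    id_col: str | None = "id",
    label: str = "",
) -> CaseControlData:
    """Read a delimited per-subject file with named columns.

    Listwise deletion is applied to rows with missing fields; diploid-coded
    hemizygous males (genotype 2) are mapped to one copy.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if id_col is not None and id_col not in df.columns:
        id_col = None
    return CaseControlData.from_dataframe(
        df, genotype=genotype, sex=sex, phenotype=phenotype,
        covariates=covariates, id_col=id_col, label=label or str(path),
    )


def read_count_table(path, label: str = "") -> CountTable:
    """Read a small CSV of sex-stratified genotype counts.

    Expected columns: group (female_case, male_case, female_control,
    male_control) followed by counts in genotype order AA, Aa, aa for females
    and A, a for males. Optional columns risk_allele / normal_allele name the
    alleles.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    rows = {str(r["group"]).strip(): r for _, r in df.iterrows()}
    need = ["female_case", "male_case", "female_control", "male_control"]
    missing = [g for g in need if g not in rows]
    if missing:
        raise ValidationError(f"count table missing groups: {missing}")

    def counts(row, k):
        vals = [row.get(c) for c in (["AA", "Aa", "aa"] if k == 3 else ["A", "a"])]
        if any(pd.isna(v) for v in vals):
            raise ValidationError("count table has missing counts")
        return tuple(vals)

    ra = str(df["risk_allele"].iloc[0]) if "risk_allele" in df.columns else "A"
    na = str(df["normal_allele"].iloc[0]) if "normal_allele" in df.columns else "a"
    return CountTable(
        female_case=counts(rows["female_case"], 3),
        male_case=counts(rows["male_case"], 2),
        female_control=counts(rows["female_control"], 3),
        male_control=counts(rows["male_control"], 2),
        risk_allele=ra,
        normal_allele=na,
        label=label or str(path),
    )


def read_vcf(
    vcf_path,
    sample_info: pd.DataFrame,
    snp_id: str | None = None,
    risk_allele: str | None = None,
    label: str = "",
) -> CaseControlData:
    """Read one biallelic X-chromosome SNP from a VCF.

    Parameters
    ----------
    vcf_path : str
        VCF file (plain or bgzipped; requires the optional cyvcf2 dependency).
    sample_info : DataFrame
        Indexed by sample name (or with a ``sample`` column), providing
        ``sex`` (1 = female, 0 = male), ``phenotype`` (1 = case) and optional
        extra covariate columns.
    snp_id : str, optional
        Record ID to extract; default: the first biallelic record.
    risk_allele : str, optional
        Which allele counts as the risk allele; defaults to ALT.

    Males may be haploid (``1``) or diploid-homozygous (``1/1``); both map to
    one copy. Heterozygous male calls are hemizygosity artifacts and are set
    missing, then removed by listwise deletion along with any other
    incomplete rows.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the optional dependency cyvcf2") from exc

    if "sample" in sample_info.columns:
        sample_info = sample_info.set_index("sample")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rec = None
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if snp_id is None or v.ID == snp_id:
            rec = v
            break
    if rec is None:
        raise ValidationError(f"SNP {snp_id!r} not found in {vcf_path}")
    if risk_allele is None:
        risk_allele = rec.ALT[0]
    if risk_allele not in (rec.REF, rec.ALT[0]):
        raise ValidationError(f"risk allele {risk_allele!r} is neither REF nor ALT")
    alt_is_risk = risk_allele == rec.ALT[0]

    unknown = [s for s in samples if s not in sample_info.index]
    if unknown:
        raise ValidationError(f"samples missing from sample_info: {unknown[:5]}")
    sex = sample_info.loc[samples, "sex"].to_numpy()

    geno = np.full(len(samples), np.nan)
    for i, gt in enumerate(rec.genotypes):
        alleles = [a for a in gt[:-1] if a >= 0]
        if not alleles:
            continue
        dose = sum(alleles) if alt_is_risk else sum(1 - a for a in alleles)
        if sex[i] == 0:  # hemizygous male
            if len(alleles) == 2 and alleles[0] != alleles[1]:
                continue  # heterozygous male call: artifact, treat as missing
            dose = 1 if dose > 0 else 0
        geno[i] = dose

    df = sample_info.loc[samples].copy()
    df["genotype"] = geno
    df["sample"] = samples
    covs = [c for c in sample_info.columns if c not in ("sex", "phenotype")]
    return CaseControlData.from_dataframe(
        df, covariates=covs or None, id_col="sample", label=label or str(vcf_path)
    )
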