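"""Packaged Graves' disease genotype counts for rs3827400.

Two independent case-control studies of Graves' disease (an autoimmune
hyperthyroidism with a strong female preponderance) genotyped rs3827400, an
X-chromosomal SNP in GPR174: a two-stage study in the Han Chinese
population and two Caucasian cohorts (Warsaw, Gliwice). T is the risk
allele. The pooled fixtures concatenate the two datasets of a population
and carry a binary data-source indicator that enters the model as an
additional covariate.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import CountTable, StratifiedCountTable
from .errors import ValidationError

__all__ = ["FIXTURE_NAMES", "load_fixture"]

_SINGLE = ("chu_stage1", "chu_stage2", "szymanski_warsaw", "szymanski_gliwice")
_POOLED = {
    "han_pooled": ("chu_stage1", "chu_stage2"),
    "caucasian_pooled": ("szymanski_warsaw", "szymanski_gliwice"),
}
FIXTURE_NAMES = _SINGLE + tuple(_POOLED)


def _raw() -> pd.DataFrame:
    path = resources.files("xcmax4").joinpath("data/graves_rs3827400.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def _single(name: str) -> CountTable:
    df = _raw()
    sub = df[df["dataset"] == name].set_index("group")

    def fem(group):
        r = sub.loc[group]
        return (int(r["AA"]), int(r["Aa"]), int(r["aa"]))

    def male(group):
        r = sub.loc[group]
        return (int(r["A"]), int(r["a"]))

    return CountTable(
        female_case=fem("female_case"),
        male_case=male("male_case"),
        female_control=fem("female_control"),
        male_control=male("male_control"),
        risk_allele="T",
        normal_allele="C",
        label=name,
    )


def load_fixture(name: str) -> CountTable | StratifiedCountTable:
    """Load a packaged count table by name.

    Single datasets: chu_stage1, chu_stage2, szymanski_warsaw,
    szymanski_gliwice. Pooled: han_pooled (stage I + II), caucasian_pooled
    (Warsaw + Gliwice); pooled tables expand with a data-source indicator
    covariate.
    """
    if name in _SINGLE:
        return _single(name)
    if name in _POOLED:
        return StratifiedCountTable(
            tables=tuple(_single(part) for part in _POOLED[name]), label=name
        )
    raise ValidationError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
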