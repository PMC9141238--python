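"""Case-control simulator for X-chromosomal SNPs, and size/power harnesses.

A large population is generated under the disease model

    logit Pr(D=1 | G, x2, x3) = a1 + a2*x2 + a3*x3 + beta*G,

where x2 is sex (Bernoulli(0.5), 1 = female), x3 ~ Uniform(0, 1), female
genotypes follow the trinomial (qf0, qf1, qf2) implied by the female
risk-allele frequency qf and inbreeding coefficient F,

    qf0 = (1-qf)^2 + F qf (1-qf),
    qf1 = 2 (1-F) qf (1-qf),
    qf2 = qf^2 + F qf (1-qf),

male genotypes are Bernoulli(qm), and G is the genotypic score under the
*true* XCI pattern of the scenario. The requested numbers of cases and
controls are then sampled from the population. With the default intercept
a1 = -5 cases are rare (about 1-2%), so the population is generated in
chunks and cases/controls accumulated until both quotas are met
(rejection-free, bounded memory).

Reproducibility: a root seed spawns per-replicate child seeds by a
counter-based scheme, so replicate r is reproducible in isolation and
results are independent of chunking and of how replicates are distributed
over workers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .data import CaseControlData, XciCoding
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "female_genotype_probs",
    "simulate_dataset",
    "estimate_size",
    "estimate_power",
    "replicate_seed",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters.

    Defaults are the reference scenario of the evaluation study: allele
    frequencies qf = qm = 0.3, Hardy-Weinberg equilibrium (F = 0),
    covariate effects (a1, a2, a3) = (-5, 0.4005, 0.5), random XCI
    (gamma = 1), and 2500 cases + 2500 controls.
    """

    qf: float = 0.3
    qm: float = 0.3
    F: float = 0.0
    alpha: tuple[float, float, float] = (-5.0, 0.4005, 0.5)
    beta: float = 0.0
    xci: XciCoding | float = 1.0
    n_cases: int = 2500
    n_controls: int = 2500
    chunk_size: int = 65536
    max_population: int = 50_000_000

    def coding(self) -> XciCoding:
        if isinstance(self.xci, XciCoding):
            return self.xci
        return XciCoding.from_gamma(float(self.xci))

    def __post_init__(self):
        if not (0.0 < self.qf < 1.0 and 0.0 < self.qm < 1.0):
            raise ValidationError("allele frequencies must lie in (0, 1)")
        if not 0.0 <= self.F < 1.0:
            raise ValidationError("inbreeding coefficient F must lie in [0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")


def female_genotype_probs(qf: float, F: float) -> tuple[float, float, float]:
    """Female genotype probabilities (qf0, qf1, qf2) for aa/Aa/AA under
    inbreeding coefficient F (F = 0: Hardy-Weinberg equilibrium)."""
    if not 0.0 < qf < 1.0:
        raise ValidationError("qf must lie in (0, 1)")
    if not 0.0 <= F <= 1.0:
        raise ValidationError("F must lie in [0, 1]")
    het = qf * (1.0 - qf)
    qf0 = (1.0 - qf) ** 2 + F * het
    qf1 = 2.0 * (1.0 - F) * het
    qf2 = qf**2 + F * het
    return qf0, qf1, qf2


def replicate_seed(root_seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based child seed: replicate r is reproducible in isolation."""
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(replicate,))


# uniforms consumed per population member: sex, x3, genotype, disease
_DRAWS_PER_SUBJECT = 4


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _expected_rates(cfg: SimulationConfig, coding: XciCoding, probs) -> float:
    """Marginal disease probability in the simulated population, in closed
    form: E over x3 ~ U(0,1) of expit(c + a3 x3) is
    [softplus(c + a3) - softplus(c)] / a3."""
    a1, a2, a3 = cfg.alpha
    rate = 0.0
    strata = (
        # (probability, sex, genotypic score)
        (0.5 * probs[0], 1, 0.0),
        (0.5 * probs[1], 1, coding.z1),
        (0.5 * probs[2], 1, 2.0),
        (0.5 * (1.0 - cfg.qm), 0, 0.0),
        (0.5 * cfg.qm, 0, coding.z2),
    )
    for pr, sex, G in strata:
        c = a1 + a2 * sex + cfg.beta * G
        if a3 == 0.0:
            rate += pr / (1.0 + np.exp(-c))
        else:
            rate += pr * (_softplus(c + a3) - _softplus(c)) / a3
    return rate


def _sim_chunk(cfg: SimulationConfig, coding: XciCoding, probs, seed_seq, offset, size):
    """Population members [offset, offset+size) of the conceptual infinite
    population. Counter-based: subject i always consumes uniforms
    [4i, 4i+4) of the keyed stream, so chunk boundaries never change the
    data."""
    bg = np.random.PCG64(seed=seed_seq).advance(_DRAWS_PER_SUBJECT * offset)
    u = np.random.Generator(bg).random((size, _DRAWS_PER_SUBJECT))
    sex = (u[:, 0] < 0.5).astype(np.int64)  # 1 = female
    fem = sex == 1
    x3 = u[:, 1]
    ug = u[:, 2]
    # female genotype by trinomial cdf; male by Bernoulli(qm)
    g_f = (ug > probs[0]).astype(np.int64) + (ug > probs[0] + probs[1]).astype(np.int64)
    g_m = (ug < cfg.qm).astype(np.int64)
    g = np.where(fem, g_f, g_m)
    score_f = np.choose(g_f, [0.0, coding.z1, 2.0])
    G = np.where(fem, score_f, g_m * coding.z2)
    a1, a2, a3 = cfg.alpha
    eta = a1 + a2 * sex + a3 * x3 + cfg.beta * G
    d = (u[:, 3] < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
    return g, sex, x3, d


def simulate_dataset(config: SimulationConfig, seed=None) -> CaseControlData:
    """Simulate one case-control dataset.

    The population is generated in chunks until the case and control quotas
    are both met; the first ``n_cases`` cases and ``n_controls`` controls in
    generation order are retained, which for i.i.d. subjects is a random
    sample of each class. Bit-identical for a given seed regardless of
    chunk size (each population member owns a fixed slice of a counter-based
    random stream).
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    coding = config.coding()
    probs = female_genotype_probs(config.qf, config.F)
    rate = _expected_rates(config, coding, probs)
    got_cases = got_controls = 0
    case_parts: list[tuple] = []
    ctrl_parts: list[tuple] = []
    total = 0
    while got_cases < config.n_cases or got_controls < config.n_controls:
        if total >= config.max_population:
            raise ValidationError(
                f"case/control quota unreachable within max_population={config.max_population}"
            )
        # size the chunk to the expected remaining need (with slack), so the
        # common case is a single pass; the counter-based stream keeps the
        # result independent of this sizing
        need = max(
            (config.n_cases - got_cases) / max(rate, 1e-12),
            (config.n_controls - got_controls) / max(1.0 - rate, 1e-12),
        )
        size = int(min(min(config.chunk_size, 1.15 * need + 512),
                       config.max_population - total))
        g, sex, x3, d = _sim_chunk(config, coding, probs, seed_seq, total, size)
        total += size
        case_idx = np.flatnonzero(d == 1)[: config.n_cases - got_cases]
        ctrl_idx = np.flatnonzero(d == 0)[: config.n_controls - got_controls]
        case_parts.append((g[case_idx], sex[case_idx], x3[case_idx]))
        ctrl_parts.append((g[ctrl_idx], sex[ctrl_idx], x3[ctrl_idx]))
        got_cases += case_idx.size
        got_controls += ctrl_idx.size
    # cases first, then controls, each in population-generation order: the
    # row order is then independent of chunk boundaries
    g = np.concatenate([p[0] for p in case_parts] + [p[0] for p in ctrl_parts])
    sex = np.concatenate([p[1] for p in case_parts] + [p[1] for p in ctrl_parts])
    x3 = np.concatenate([p[2] for p in case_parts] + [p[2] for p in ctrl_parts])
    d = np.concatenate([np.ones(config.n_cases, dtype=np.int64),
                        np.zeros(config.n_controls, dtype=np.int64)])
    X = np.column_stack([np.ones(g.size), sex.astype(float), x3])
    return CaseControlData(g, sex, d, X, label="simulated")


def _binom_ci(k: int, n: int, level: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _resolve_tests(tests) -> dict[str, Callable[[CaseControlData], float]]:
    """Map test names (or callables returning a p-value) to callables."""
    from .comparators import fm01, fm02, fmf, fms
    from .max_test import run_xcmax4

    named: dict[str, Callable] = {
        "xcmax4": lambda d: run_xcmax4(d).p_value,
        "fm01": lambda d: fm01(d).p_value,
        "fm02": lambda d: fm02(d).p_value,
        "fmf": lambda d: fmf(d).p_value,
        "fms": lambda d: fms(d).p_value,
    }
    out = {}
    if isinstance(tests, Mapping):
        return dict(tests)
    for t in tests:
        if callable(t):
            out[getattr(t, "__name__", str(t))] = t
        else:
            key = str(t).lower()
            if key not in named:
                raise ValidationError(f"unknown test {t!r}")
            out[key] = named[key]
    return out


def estimate_size(
    config: SimulationConfig,
    tests: Sequence | Mapping = ("xcmax4",),
    n_reps: int = 10_000,
    alpha_levels: Sequence[float] = (0.01,),
    seed: int = 0,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Empirical type-I error of each test under the null (beta = 0).

    Returns one row per (test, nominal level) with the rejection proportion
    and its exact binomial confidence interval. Replicate r uses the
    counter-based child seed of ``seed``, so the result is independent of
    execution order or worker count.
    """
    if config.beta != 0.0:
        raise ValidationError("size estimation requires beta = 0")
    funcs = _resolve_tests(tests)
    alpha_levels = list(alpha_levels)
    pvals = {name: np.empty(n_reps) for name in funcs}
    for r in range(n_reps):
        data = simulate_dataset(config, seed=replicate_seed(seed, r))
        for name, fn in funcs.items():
            pvals[name][r] = fn(data)
    rows = []
    for name in funcs:
        for a in alpha_levels:
            k = int((pvals[name] <= a).sum())
            lo, hi = _binom_ci(k, n_reps, ci_level)
            rows.append(
                dict(test=name, alpha=a, n_reps=n_reps, rejections=k,
                     size=k / n_reps, ci_low=lo, ci_high=hi)
            )
    return pd.DataFrame(rows)


def estimate_power(
    configs: Iterable[SimulationConfig],
    tests: Sequence | Mapping = ("xcmax4", "fm01", "fm02", "fmf", "fms"),
    n_reps: int = 1000,
    alpha: float = 1e-4,
    seed: int = 0,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Empirical power of each test over a grid of scenarios.

    Each scenario (one :class:`SimulationConfig`, beta != 0) is simulated
    ``n_reps`` times; rows report the rejection proportion at level
    ``alpha`` per test with exact binomial confidence intervals.
    """
    funcs = _resolve_tests(tests)
    rows = []
    for s_idx, cfg in enumerate(configs):
        if cfg.beta == 0.0:
            raise ValidationError("power estimation requires beta != 0")
        rej = {name: 0 for name in funcs}
        for r in range(n_reps):
            data = simulate_dataset(cfg, seed=replicate_seed(seed, s_idx * n_reps + r))
            for name, fn in funcs.items():
                rej[name] += fn(data) <= alpha
        coding = cfg.coding()
        for name, k in rej.items():
            lo, hi = _binom_ci(int(k), n_reps, ci_level)
            rows.append(
                dict(scenario=s_idx, xci=coding.label, z1=coding.z1, z2=coding.z2,
                     qf=cfg.qf, qm=cfg.qm, alpha2=cfg.alpha[1], alpha3=cfg.alpha[2],
                     beta=cfg.beta, test=name, alpha=alpha, n_reps=n_reps,
                     power=int(k) / n_reps, ci_low=lo, ci_high=hi)
            )
    return pd.DataFrame(rows)
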