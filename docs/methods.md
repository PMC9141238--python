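# Methods

## Model and test

Let D be a binary disease indicator, X = (x1, …, xp)' the covariates with
x1 ≡ 1 and x2 the sex indicator (1 = female), and G the genotypic score of
an X-linked SNP with risk allele A. The working model is the logistic
regression

    logit Pr(D_i = 1 | G_i, X_i) = X_i'α + β G_i.

Because male hemizygosity and X-inactivation (XCI) make the effective
female genotype dose ambiguous, G is parameterized as
G(Z1, Z2) = 2·I(female AA) + Z1·I(female Aa) + Z2·I(male A), female aa and
male a scoring 0. Four codings span the biologically motivated patterns:

| coding (Z1, Z2) | pattern | interpretation |
|---|---|---|
| (0, 2) | XCI-SN | skewed inactivation silencing the risk allele |
| (1, 2) | XCI-R  | random inactivation, males dosage-compensated |
| (2, 2) | XCI-SR | skewed inactivation silencing the normal allele |
| (1, 1) | XCI-E  | escape from inactivation, autosome-like |

For XCI scenarios generally, Z1 = γ ∈ [0, 2] measures the skewness and
Z2 = 2.

The score test of β = 0 uses a single null fit (covariates only) shared by
all codings and all SNPs with the same covariates: with p̂_i the fitted
null probabilities and w_i = p̂_i(1 − p̂_i),

    U = Σ G_i (D_i − p̂_i),
    V = I_β − I_βα I_α⁻¹ I_βα',   I_β = Σ G_i² w_i,  I_βα = Σ G_i X_i' w_i,
    S = U/√V.

XCMAX4 = max over the four codings of |S|. The componentwise |S| reading is
used throughout: it is the statistic whose tail equals the complement of
the symmetric rectangle probability used for the p-value, and it is the
reading under which the published Graves' disease tables reproduce.

## Correlation matrix and p-value

Jointly the four components are asymptotically N(0, Σ). The covariance of
two score functions comes from the joint two-coding model: C = G'WG −
(G'WX)(X'WX)⁻¹(X'WG) for the n×2 matrix of the two scores, and
ρ = C₁₂/√(C₁₁C₂₂). The implementation computes the 4×4 projected covariance
in one pass; its 2×2 blocks equal the pairwise definition exactly, and its
diagonal equals the per-coding variances.

Σ is always singular for the canonical codings: the four score vectors lie
in the 3-dimensional span of the indicators {female AA, female Aa, male A}.
Everything downstream therefore treats Σ as positive semidefinite
(eigenvalue floor −1e-8; the QMC factorization uses an eigenvalue-clipped
Cholesky). Correlations outside [−1, 1] by less than 1e-8 are clipped
(floating-point guard); larger excursions raise.

For an observed maximum z, the reported p-value is the rhombus-formula
upper bound on P(max|S| > z), for k chained components

    (k−2)(Φ(z) − Φ(−z) − 1) + (4φ(z)/z) Σ_{i=1}^{k−1} [Φ(L_i z/2) + Φ((π−L_i) z/2) − 1],

with L_i = arccos ρ of consecutive components, minimized over orderings
(all 4! permutations are enumerated; reversal symmetry makes 12 distinct
values). The leading term is negative (−2·2Φ(−z) at k = 4) and the pair sum
supplies the mass; for perfectly correlated components the bound approaches
the exact two-sided normal tail, and as z → ∞ it approaches the exact tail
8Φ(−z) + O(Φ(−z)/z²) for any fixed Σ with all |ρ| < 1.

Components with |ρ| > 1 − 1e-8 are deduplicated before the bound is formed
(keeping the first of each group; the maximum statistic is unchanged
because tied components have equal |S|). With k = 1 surviving component the
exact two-sided normal p-value is used. This arises in degenerate designs —
e.g. no heterozygous females and no males makes all four codings identical.

Accuracy: the bound is an upper bound, hence the test is conservative, and
its relative slack shrinks as z grows. Against a validated quasi-Monte-Carlo
oracle the min-ordering bound runs some 7–45% above the exact tail
(median ≈ 13%) for p between 1e-4 and 1e-2 on the strongly positively
correlated Σ this method produces (off-diagonals typically 0.5–0.97),
tightening further into the tail; on the −log10 scale the two agree within
about 2% throughout. Results with p > 0.01 carry an explicit accuracy-caveat flag; at
conventional GWAS thresholds the bound is for practical purposes exact on
the log10 scale (within ~0.1 of a log10 unit at p ≈ 1e-3, far less at
genome-wide p). One practical consequence: at a nominal level as loose as
0.01 the test's empirical size runs a little below nominal (about 0.008 in
the harness), which is the price of never being anti-conservative.

### QMC cross-check

`mvn_pvalue` estimates 1 − P(all components in [−z, z]) by the
separation-of-variables transform over scrambled Sobol points, split into 8
independently scrambled replicates whose spread gives the standard error
(default 2^17 points total, seeded and reproducible). It is a cross-check,
never the reported p-value: below roughly 1e-5 the rectangle complement is
beyond QMC resolution at this point count, while the analytic bound only
gets tighter there. The estimator was validated against closed forms
(independence, perfect correlation) and a 4×10⁸-sample plain Monte Carlo.

## Null model fit

Damped Newton (IRLS) with an intercept-only warm start; convergence when
the max score-equation residual is ≤ 1e-8 (absolute; also well within the
1e-8·n contract) or the relative log-likelihood change is < 1e-10 with the
gradient condition, max 50 iterations. Such tight tolerances matter because
downstream p-values reach 1e-22. Separation is detected both during
iteration (probabilities within 1e-10 of 0/1 with coefficients beyond 100)
and at convergence (any fitted probability within 1e-8 of 0/1, i.e.
|linear predictor| > 18, which no usable null model produces); both raise
rather than returning a silently meaningless fit.

## Comparators

FM01 and FM02 are single logistic regressions of D on [X, G] with G fixed
at coding (1,1) and (1,2) respectively; the genotype coefficient is tested
two-sided. The Wald form is the default because it is the convention under
which the published stage I values reproduce (Wald 9.52e-8 vs printed
9.513e-8 for FM01; the likelihood-ratio alternative gives 8.16e-8 and is
available via `test="lrt"`).

FMF and FMS fit per-sex regressions (females 0/1/2, males 0/1; the sex
column is dropped within strata, other covariates kept) and combine the
two-sided per-sex p-values: Fisher's −2(ln p_F + ln p_M) against chi-square
with 4 df, or Stouffer's weighted sum of signed z-scores (signs from the
genotype coefficient, so opposite-direction effects cancel). Stouffer
stratum weights default to √n_stratum — the convention that reproduces the
published stage I FMS value (1.731e-8; equal weights give 3.39e-9) — with
equal weights behind `weights="equal"`.

## Simulator

The generator emulates the reference evaluation design: sex ~
Bernoulli(0.5); female genotypes trinomial with qf0 = (1−qf)² + F·qf(1−qf),
qf1 = 2(1−F)qf(1−qf), qf2 = qf² + F·qf(1−qf) (F the inbreeding
coefficient, F = 0 being Hardy–Weinberg equilibrium); male genotypes
Bernoulli(qm); one continuous covariate x3 ~ U(0,1); disease from
logit Pr(D=1) = α1 + α2·sex + α3·x3 + β·G with G scored under the *true*
XCI pattern of the scenario (γ mapped to (γ, 2), escape to (1, 1)).
Defaults: qf = qm = 0.3, F = 0, (α1, α2, α3) = (−5, 0.4005, 0.5), β = 0,
2500 cases + 2500 controls — the reference scenario of the evaluation
design (α1 = −5 makes disease prevalence ≈ 1–2%, and |α2| = 0.4005 moves
the female share of cases through roughly 40–60%).

Case-control sampling is rejection-free: the population is generated in
chunks and the first n_cases cases and n_controls controls in generation
order are kept (a random sample of each class for i.i.d. subjects). Chunks
are sized from the closed-form expected disease rate (the integral of the
logistic over x3 is analytic), so the common case is a single pass.
Reproducibility is counter-based: each population member owns a fixed
4-draw slice of a PCG64 stream positioned by `advance`, so datasets are
bit-identical for a given seed regardless of chunk size, and replicate r of
a harness uses the child seed `SeedSequence(root, spawn_key=(r,))`, making
every replicate reproducible in isolation and results independent of
execution order or worker count.

What the generator does not emulate: genotyping error, missingness,
population stratification beyond the single binary source indicator,
linkage between SNPs, or the pseudo-autosomal region. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those artifacts.

## Harness scales and numerical choices

The type-I-error check in the test suite runs 10⁵ null replicates of the
reference design reduced to 500 cases + 500 controls at nominal α = 0.01;
the power-ordering check uses 1000 + 1000 subjects, β = 0.15, α = 0.01 and
800 replicates per scenario (3000 for the escape-pattern scenario, whose
FM01-vs-FMS gap is small and needs the extra resolution). These sizes keep
the default suite at desk scale; the full published design (2500 + 2500,
10⁶ replicates, α down to 1e-5) is available in
`scripts/full_scale_size.py`. The Σ-versus-permutation check refits the
null model for every permuted phenotype vector — estimating the nuisance
coefficients is precisely what induces the covariate projection in the
score covariance, and skipping the refit visibly biases the empirical
correlations.

Degenerate inputs: monomorphic SNPs yield zero score variance and an
explicit degenerate flag (all four components degenerate raises "no usable
genotype signal"); genotype codings contained in the covariate span project
to zero variance; a missing phenotype class in a sex stratum makes the
stratified combinations undefined and raises. Missing data are handled by
listwise deletion at read time and reported, as the complete-data formulas
assume. Hemizygous males may arrive haploid (0/1) or diploid-homozygous
(0/2) and are mapped to copy number; heterozygous male calls are treated as
artifacts and set missing. The risk allele must be designated explicitly
(ALT by default in VCF input) — allele-frequency-based auto-detection is
deliberately avoided since it is ill-defined at frequency 0.5.

## Known limitations

- The rhombus bound's conservatism is material for p in roughly
  [0.01, 0.6]; the flag `p_above_0.01_accuracy_caveat` marks such results,
  and the QMC integral can be requested when an accurate non-small p is
  needed.
- Asymptotic normality of the components is relied on throughout; no
  small-sample correction (e.g. Firth) is provided, and separation aborts
  the analysis rather than being penalized away.
- Single-SNP scope: multi-allelic sites, imputation dosages, phasing and
  genome-wide multiplicity handling are out of scope.
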