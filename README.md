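# xcmax4

Robust association testing for X-chromosomal SNPs in case-control studies,
with covariate adjustment and no assumption about X-chromosome inactivation
(XCI).

## The problem

Genome-wide association studies routinely skip the X chromosome because its
analysis is genuinely awkward: males are hemizygous (genotypes a/A) while
females carry two copies (aa/Aa/AA), and the effective female genotype dose
depends on which XCI pattern governs the locus — random inactivation
(XCI-R), skewed inactivation towards either allele (XCI-SN/XCI-SR), or
escape from inactivation (XCI-E). Tests that fix one coding (such as the
XWAS suite's FM01/FM02) lose power when their XCI assumption is wrong, and
sex is a confounder whenever allele frequencies differ between the sexes,
so covariate adjustment is not optional.

## The method

For the logistic model

    logit Pr(D_i = 1 | G_i, X_i) = X_i'α + β G_i,

each XCI hypothesis corresponds to a genotypic score
`G(Z1, Z2) = 2·I(female AA) + Z1·I(female Aa) + Z2·I(male A)` with
(Z1, Z2) ∈ {(0,2), (1,2), (2,2), (1,1)}. Testing β = 0 by a score test
needs only one null fit shared by all codings:

    U = Σ_i G_i (D_i − p̂_i),      V = I_β − I_βα I_α⁻¹ I_βα',
    S = U / √V  ~  N(0, 1) under the null.

XCMAX4 is the maximum of |S| over the four codings. Its p-value comes from
the joint asymptotic normality of the four components with correlation
matrix Σ (estimated from a two-coding joint model): the tail of the maximum
is bounded analytically by the rhombus formula

    P(max|S| > z) ≤ 2(Φ(z) − Φ(−z) − 1)
                   + (4 φ(z)/z) Σ_{i=1}^{3} [Φ(L_i z/2) + Φ((π−L_i) z/2) − 1],

with L_i = arccos ρ_{i,i+1} for consecutive components, minimized over the
12 distinct orderings. The bound is deterministic, cheap (no permutations,
one null fit per covariate set), asymptotically exact as z grows, and never
anti-conservative. A quasi-Monte-Carlo integral of the multivariate-normal
rectangle is available as an opt-in cross-check.

The package also implements the four XWAS-style comparators (FM01, FM02,
and the sex-stratified Fisher/Stouffer combinations FMF, FMS), a
case-control simulator for X-linked SNPs with Hardy–Weinberg-disequilibrium
support, and size/power harnesses.

## Worked example

The packaged fixtures hold the rs3827400 genotype counts from two Graves'
disease case-control studies (T is the risk allele):

```python
>>> from xcmax4 import expand_counts, load_fixture, run_xcmax4
>>> data = expand_counts(load_fixture("chu_stage1"))   # 2941 subjects
>>> res = run_xcmax4(data)                             # sex as covariate
>>> res.statistic, res.attained_coding
(5.8650143088600455, 'XCI-R')
>>> res.p_value
1.5726741779531726e-08
```

The four component statistics are S = (5.25, 5.87, 5.00, 5.35) for the
codings (0,2), (1,2), (2,2), (1,1); the maximum 5.87 is reached under the
random-inactivation coding, and the min-ordering rhombus bound turns it
into p = 1.573e-08 — genome-wide-suggestive evidence that rs3827400-T is
associated with Graves' disease, robust to whichever XCI pattern holds.
`examples/` contains this reanalysis for all six datasets plus scripts
showing the component anatomy, the simulator, and tabular/VCF input. A thin
CLI wraps the same calls:

```sh
xcmax4 test --fixture chu_stage1 --methods xcmax4,fm01,fm02,fmf,fms
xcmax4 simulate --qf 0.1 -F 0 --check-freqs
```

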