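# Methods

## The problem and the model

A genetic study can only genotype its participants, so any genetic
contribution to the decision to participate is invisible to a conventional
case/control design — there is no genotyped "non-participant" group. The
IBD-footprint approach exploits a second-order consequence of genetic
participation effects: an allele that raises participation probability is
more strongly enriched in genomic segments carried *twice* among
participants (shared identical by descent, IBD, between two related
participants) than in segments carried once. Comparing shared against
not-shared alleles within pairs of related participants therefore measures
participation-associated allele-frequency shifts using participants'
genotypes alone, captures only direct genetic effects, and is immune to
population stratification (the comparison is within-family).

Participation is modelled with a liability-threshold model. Individual
*j* in family *i* carries a liability

    X_ij = Σ_k w1_k g_ijk + wA A_i + wB B_ij ,

where `g` are standardized genotype codes of causal SNPs (additive,
dominant or recessive coding), `A_i` is a family-shared standard-normal
component (shared environment plus untracked shared genetics), `B_ij` an
individual component, and `Σ w1_k² + wA² + wB² = 1` so `var(X) = 1`.
An individual participates iff `X > τ = Φ⁻¹(1 − α)` for participation
rate α. Because siblings' standardized genotypes correlate 1/2, the
sibling liability correlation is `ρ = wA² + Σ w1_k²/2`. Given α, ρ fixes
the sibling recurrence participation rate ratio

    λ_S = P(X₁ > τ, X₂ > τ) / α² ,

a bivariate-normal orthant probability. All closed-form quantities of this
model live in `ibdfootprint.liability`.

## The three allele comparisons

For a biallelic SNP with alleles coded 0/1 (allele 1 frequency `f`):

* **TNTC** (transmitted/nontransmitted): in an ascertained parent–offspring
  pair, the parental allele transmitted to the offspring (T) is shared, the
  untransmitted one (NT) is not; Mendelian transmission makes `F_T − F_NT`
  a valid test with the pair as the matched unit. The offspring's allele
  from the other parent is not used.
* **WSPC** (within sib pair): at loci where a sib pair shares exactly one
  allele IBD, the shared allele S is compared with the two not-shared
  alleles: `F_IBD1S − F_IBD1NS`.
* **BSPC** (between sib pairs): allele frequency among pairs sharing both
  alleles IBD versus pairs sharing none: `F_IBD2 − F_IBD0`. No genotype
  splitting is required, which is why data-processing errors leave it
  clean.

TNTC and WSPC are one-sample t-tests on per-pair differences
(`d = T − NT`, `d = S − (NS₁+NS₂)/2`); BSPC is a Welch two-sample t-test
on per-pair allele frequencies (an IBD2 pair contributes the frequency of
its two distinct-by-descent alleles, an IBD0 pair of its four). Per-pair
units are used throughout; no Hardy–Weinberg or within-pair independence
assumption enters the standard errors. The exact spelling of these
constructions is isolated in `association.one_sample_block` /
`two_sample_block` so it can be swapped wholesale. Statistics are combined
across comparisons by Stouffer weighting with √(effective pair count),
with the harmonic-mean pair count for the two-sample comparison — chosen
as the optimal weighting under equal per-pair information; the combination
rule is deliberately a single function (`association.combine`).

Sign convention everywhere: positive means allele 1 is enriched in the
shared / doubly-participating stratum.

## The simulator

`cohort_sim.simulate_cohort` draws nuclear families (two founders, two
offspring): founder haplotypes in Hardy–Weinberg equilibrium at the
specified frequencies; offspring by Mendelian transmission with Haldane
recombination over user-supplied cM positions (chromosome changes assort
independently); liabilities per the model above; participation by
thresholding. Grandparental origin of every transmitted allele is tracked,
so per-SNP sib IBD state and the identity of the shared allele are known
exactly. Truth IBD segments are maximal runs of constant transmission
pattern — note that runs are broken when the shared *parent* changes even
if the IBD state count does not, because phase information does not cross
such a change.

Parent–offspring cohorts reuse the same family structure; a family with
both parents and the offspring ascertained contributes two pairs, which is
valid because the two transmissions are independent.

Ratio experiments (`experiments.ratio_point` / `ratio_curve`) need
billions of pairs, so a streaming single-SNP path
(`cohort_sim.single_snp_summary`) draws founder alleles and transmissions
exactly as the full simulator but integrates the Gaussian liability
components out analytically: given the genotype pair, the joint
participation outcome of the two siblings is a four-category draw whose
probabilities are conditional bivariate-normal orthant probabilities. This
is exact sampling from the same generative model (not an approximation)
and is cross-checked statistically against the full simulator in the test
suite.

### Error injection

`cohort_sim.inject_errors` derives a "called" genotype layer from the
truth layer; the truth is never modified. Three channels:

* **Genotype replacement** — with probability `genotype_error_rate` per
  individual per SNP, the genotype is replaced by a fresh Hardy–Weinberg
  draw. This leaves the marginal distribution of called genotypes exactly
  unchanged, yet biases the genotype-splitting comparisons: an erroneous
  genotype is classified against a partner that still carries the truth,
  and the asymmetric classification arithmetic overcalls the minor allele
  into the not-shared pool.
* **Phasing switch errors** — between consecutive heterozygous sites of an
  individual, haplotype orientation flips with probability
  `phasing_switch_rate`; genotypes are untouched.
* **Direct double-heterozygote miscalls** — at double-het IBD1 sites the
  truly shared allele 1 is miscalled with probability ε(f), a truly shared
  0 with ε(1−f), implemented by flipping the site's phase in both members.
  ε is supplied as a piecewise-linear table
  (`bias_adjust.make_eps_interpolator`) because in practice it is measured
  empirically from trios, not derived. The induced bias of the called
  shared-allele frequency is `f·ε(1−f) − (1−f)·ε(f)`
  (`bias_adjust.phasing_bias`), positive for the major allele when
  ε(f)/ε(1−f) < f/(1−f).

## Classification of observed data

`ibd.classify_sib_alleles` enumerates the five unordered IBD1 genotype
combinations; all but the double heterozygote are forced by descent. The
double heterozygote is resolved from phase: the nearest SNP within the
same (trimmed) segment at which exactly one member is heterozygous pins
the shared haplotype, which is read off at the target SNP. Ties between
equidistant neighbors break toward the lower index; the search never
crosses a segment boundary, and it is not distance-capped (a cap can be
imposed by the caller by shrinking the bounds). Parent–offspring pairs go
through the same code with the transmitted allele as "shared" — with the
caveat, faithful to real data, that a crossover in the parent between
target and neighbor yields a wrong call; this is precisely the phasing
error channel above. Mendelian-inconsistent sites are skipped per pair,
not globally. Inferred segments from real data should be trimmed
(`ibd.trim_segments`, default 250 SNPs per end) because breakpoint calls
are least reliable at segment ends; simulation-truth segments need no
trimming.

## Two-step adjustment and diagnostics

Genotyping and phasing errors produce a major-allele bias in TNTC and
WSPC. The adjustment (`bias_adjust.two_step_adjust`) follows a fixed
order: (1) regress t on centred allele frequency `cf = f − 1/2` through
the origin and keep residuals; (2) regress the resulting χ² on a cubic
polynomial of MAF (raw powers, with intercept), divide by the fitted
values, and rescale so the adjusted χ² average is exactly 1 (plain
division leaves the mean only approximately 1; the explicit rescale makes
the postcondition exact). The final score is sign(adjusted t)·√(adjusted
χ²). The cf regression pools SNPs across chromosomes.
`bias_adjust.bias_diagnostics` reports cor(t, cf), χ² inflation by MAF
stratum, and SNPs significant in a splitting comparison but flat in BSPC —
the signature of data artefacts in difficult regions.

## Polygenic scores and heritability

A participation polygenic score is the genotype dosage matrix times the
scan z-statistics, standardized to variance 1 in the evaluation sample —
deliberately without LD pruning or shrinkage. Association with phenotypes
uses OLS/logit with caller-supplied covariates; the squared statistic is
deflated by a caller-supplied LD-score-regression intercept (default 1)
before the χ²₁ p-value. Intercepts are inputs, never estimated here.

An observed-scale heritability of the 0/1 participation indicator (e.g.
from LDSC on BSPC statistics, fed with n_cases = n_IBD2 and
n_controls = 2·n_IBD0) converts to the liability scale through three
factors (`liability.primary_h2_chain`):

1. `1/cor²(X, I)` with `cor(X, I) = φ(τ)/√(α(1−α))` — thresholding loss;
2. `[1/c + 1/(1−c)] / [1/α + 1/(1−α)]` — the IBD2:IBD0 design (c ≈ 1/3)
   is far more balanced than the α:(1−α) participation split;
3. `(1/(r·(1−α)))²`, where `r ≈ 0.86` is the simulated expectation of
   `(F_IBD2 − F_IBD0)/(F_samp − f_pop)` at λ_S = 2 — the IBD contrast is
   attenuated relative to the participant/nonparticipant contrast, and
   efficiency scales with effect².

All intermediates are kept at full precision; products are not rounded
before multiplication. For a *secondary* participation event (participation
in a follow-up component, observed directly for all genotyped individuals)
factors 2 and 3 are exactly 1 (`liability.secondary_h2_chain`). A
liability-scale result above 1 warns rather than raises, since noisy
observed-scale inputs can legitimately produce it.

Useful corollaries: the mean of the genetic component among participants is
`√h² · φ(τ)/α` s.d. of the genetic component, and direct genetics accounts
for a share `(h²/2)/ρ` of the sibling liability correlation.

## Numerical choices

* Orthant probabilities by adaptive quadrature of the conditional tail
  (`φ(x)·Φ̄((t₂ − ρx)/√(1−ρ²))`), absolute tolerance ~1e−12; λ_S values are
  quoted to 3 significant figures, so quadrature rather than Monte-Carlo.
  Monte-Carlo and `scipy` multivariate-normal CDFs serve as oracles in
  tests only.
* `liability_corr_for_lambda` inverts λ_S(ρ) by Brent root finding to
  1e−10; λ_S outside [1, 1/α] is a domain error.
* Closed-form operations treat X as exactly standard normal even with a
  SNP term (exact at w1 = 0 and accurate for small variance shares); the
  simulator carries the exact mixture.
* One root seed per run, split into independent child streams (founders,
  meioses, environment, errors) via `numpy` `SeedSequence`, so the error
  layer is reproducible independently of the cohort draw.
* Ratio aggregation over replicates is the mean of per-replicate ratios.
  This estimator is sensitive to denominator noise, so replicates must be
  large: at 16M pairs per replicate the per-replicate denominator
  coefficient of variation is ~2% and the ratio bias is below 1e−3.
  (Ratio-of-means aggregation gives indistinguishable results at these
  sizes but a different finite-sample bias profile.)
* Degenerate inputs: empty frequency strata yield NaN, not errors;
  zero-variance difference sets yield an undefined t flagged by
  `ComparisonBlock.defined`; all-zero PGS weights raise.

## Simulation sizes used in the checks

The reference ratio experiment (α = 0.055, ρ = 0.193 ⇒ λ_S = 2, f = 0.5,
variance share 0.1%) uses 96 replicates × 16M sib pairs in the acceptance
script (72 × 16M in the test suite), giving a Monte-Carlo s.e. of ~0.012
on the IBD2/IBD0 ratio — the package's desk-scale choice for a target
quoted to two decimals. Mode-specific gap checks (dominant/recessive) use
40 × 6M per mode; calibration nulls use hundreds of small replicate
cohorts. The dominant/recessive relative gaps are parameter-sensitive:
they grow with the SNP variance share (≈−29%/+30% at a 1% share versus
≈−15%/+17% observed at the reference 0.1% share), so gap checks are run
only at the reference share.

## What the synthetic data does and does not emulate

The generator reproduces exactly the statistical structure the method
assumes: HWE founders, Mendelian transmission with recombination,
liability-threshold ascertainment with a shared family component, tracked
IBD, and the three error channels. It does **not** emulate population-level
LD between SNPs, allele-frequency spectra, assortative mating, population
structure, multi-generation pedigrees, the X chromosome, genotyping-error
heterogeneity across platforms, or IBD-calling errors of real inference
tools (truth segments stand in for inferred ones; real segments are
accepted as TSV input). Passing tests therefore validate the statistical
machinery and its error responses, not the upstream data-processing of any
particular biobank.

## Known limitations

* LD-score regression itself is out of scope: observed-scale h² and
  intercepts are consumed as numbers.
* IBD inference from genotypes is not reimplemented; segments come from
  simulation truth or from an external caller's TSV.
* The Stouffer weights and the one-/two-sample s.e. constructions are the
  package's own concrete choices where the method family admits
  alternatives; both are isolated behind single functions.
* The double-het ε(f) curve must be measured externally (e.g. from trios);
  only its representation and consequences are implemented.
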