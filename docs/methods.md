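# Methods

## Two-locus LD model

A pair of biallelic SNPs A (causal) and B (marker) with allele-1 frequencies
`f_A`, `f_B` and haplotype correlation `r` fully determines the four-haplotype
distribution through the covariance identity
`Pr(11) = f_A f_B + r sqrt(f_A(1-f_A) f_B(1-f_B))`. The feasible range of r
follows from the Fréchet bounds on Pr(11); the upper bound reaches 1 only when
the two frequencies are equal, and negative r is supported throughout (a
correlation in either direction makes the marker informative). Conditional
allele probabilities `q0 = Pr(A=1|B=0)`, `q1 = Pr(A=1|B=1)` satisfy
`q1 f_B + q0 (1-f_B) = f_A` and `q1 - q0 = r sqrt(f_A(1-f_A)/(f_B(1-f_B)))`.
Diplotypes assume Hardy-Weinberg equilibrium for haplotypes, so the causal
genotype given the marker genotype is Binomial(2, q0), Bernoulli(q0) +
Bernoulli(q1), or Binomial(2, q1) for marker genotype 0/1/2. Probability
cells within 1e-12 of [0, 1] are clamped; anything worse raises an error
rather than being silently clipped.

## Disease models

Risk is modelled on the log scale: `log p = mu + beta*G + gamma*1{G=1}` for a
single SNP (multiplicative gamma = 0, dominant gamma = beta, recessive
gamma = -beta; named models are built from the homozygous relative risk via
`beta = 0.5 log(hom RR)`), and for two SNPs a haplotype model in which a
haplotype carrying alleles (a, a') contributes `beta1*a + beta2*a' + tau*a*a'`
and an individual's log risk sums its two haplotypes. Log risk rather than
log odds is the working link because with cohort (population) controls a
case-control logistic regression estimates log-risk parameters exactly; with
genuinely disease-free controls the two links agree closely at low prevalence.
The baseline `mu` defaults to log(0.01); every case-control quantity of
interest is free of it, but carrying it keeps penetrances well defined and the
validity constraint (all penetrances ≤ 1) checkable at construction.

## Distortion at marker SNPs

Marker penetrances are LD-weighted mixtures of causal ones,
`p_B(g) = sum_j Pr(G_A=j | G_B=g) p_A(j)` (genotype-level mixing via the
diplotype law for the general model; haplotype-level mixing matrices for the
multiplicative and interaction models, where the model factorizes over
haplotypes). Two distortion identities are exact, not asymptotic:

* second differences scale by `(q1-q0)^2`;
* the 2×2 interaction penetrance-matrix determinant scales by
  `(q1-q0)(q1'-q0')`.

The exact marker parameters invert the marker penetrances
(`mu_B = log p_B0`, `beta_B = 0.5 log(p_B2/p_B0)`,
`gamma_B = log p_B1 - mu_B - beta_B`). The small-effect approximations are
`beta_B ≈ c beta_A` (multiplicative model) and `gamma_B ≈ c^2 gamma_A` with
`c = q1 - q0`. One subtlety the exact computation exposes: under a
*non-multiplicative* truth the additive marker effect also carries a
first-order dominance-leakage term,

```
beta_B ≈ c*beta_A + c*(1 - q0 - q1)*gamma_A,
```

which vanishes at r = 1 (q0→0, q1→1) and under multiplicative truths but not
otherwise, even as effect sizes shrink. The linear-in-r rule should therefore
be read as the multiplicative-model law; the package's tests check it in that
setting and check the quadratic law for gamma, where no such leakage exists.

The effective additive parameter β′ — the population limit of the additive
coefficient when the (possibly misspecified) multiplicative logistic model is
fitted — is computed by maximizing the weighted likelihood of the theoretical
case/control genotype frequencies treated as fractional counts (cases
proportional to `Pr(G) p(G)`, controls the population frequencies, weighted
φ : 1-φ with φ = 0.5 by default). With cohort controls this makes β′ = β exact
for multiplicative truths. These fits use an in-package damped Newton solver
(≤ 9 cells, convergence tolerance 1e-13) because downstream checks need the
optimum to near machine precision.

## Power theory

Each test is the 1-df Wald test of one coefficient of a case-control logistic
regression: the additive coefficient of the multiplicative model (trend — its
score-test counterpart is the Cochran-Armitage test), the dominance
coefficient of the general model (deviation), and the product-term coefficient
of the two-SNP haplotype model (interaction). The noncentrality parameter is
computed as `eta = N theta*^2 / v`, with theta* the population-limit
coefficient of the weighted fit described above and v the per-individual
variance from the expected Fisher information with nuisance parameters
profiled out. For the deviation and interaction tests the working model is
saturated on the observed cells, so theta* equals the log-risk parameter at
the SNP exactly; for the trend test theta* = β′. The interaction NCP is
computed at the haplotype level (2N haplotypes for N individuals), using the
factorization of an individual's risk over its two haplotypes, with the two
causal loci assumed independent of each other.

Monte-Carlo validation (mean Wald statistic = df + ncp; empirical rejection
rates vs noncentral chi-square tails) backs these expressions across a grid of
models and frequencies; combined with the distortion laws they reproduce the
three sample-size rules `N/r^2`, `N/r^4` and `N/(r r')^2` — log-log slopes of
2.00, 4.00 and 2.00 at homozygous RR 1.05², within 0.05/0.10/0.05.

## Finite-sample tests

Tests operate on case/control genotype count tables. The trend test is the
closed-form Cochran-Armitage statistic with scores (0, 1, 2) in its score-test
normalization (variance divisor N), identical to the logistic score test. The
deviation test is the Wald test of gamma from the general-model fit; because
that fit is saturated on a 3-cell table it has a closed form (logit contrasts
and 1/count variances) that the vectorized simulator path uses, and which the
statsmodels GLM fit reproduces. The general test is the 2-df likelihood-ratio
test against the null; the interaction test is the Wald test of the product
term on a 3×3 table. Model fitting for users goes through
`CaseControlGenotypeModel` / results objects backed by statsmodels GLM
(binomial counts), with `summary()` for inspection. Zero phenotype-by-genotype
cells make the saturated fit undefined: no continuity correction is applied
(it would change test size); the affected test raises, and the simulation
pipeline counts such replicates as non-significant.

## Simulation engine

The haplotype panel generator produces, by default, 100,000 phased haplotypes
at 1,000 SNPs over 500 kb — the density of a fully resequenced region and a
panel large enough that an 8,000-haplotype study barely depletes it. Three
layers, all driven by one decay parameter (`ld_decay`, default 2e-5 per bp,
chosen so that common SNPs typically have a best chip tag around r² ≈ 0.8 and
r² decays to near zero beyond ~50 kb):

1. target minor-allele frequencies follow a Beta(0.6, 1.8)/2 spectrum (skewed
   toward rare variants) with local AR(1) correlation along the region
   (correlation length 10 kb), because high r² between neighbours requires
   similar frequencies;
2. a founder pool (100 haplotypes) built from per-founder latent Gaussian
   AR(1) chains thresholded at the target frequencies — a Gaussian-copula
   Markov chain that preserves the marginal spectrum while correlating nearby
   columns;
3. panel haplotypes are first-order mosaics copying from random founders with
   distance-dependent switch probability `1 - exp(-d * ld_decay)` and a small
   copy-error rate (0.002).

The generator emulates the LD *spectrum* of real resequenced panels (MAF
skew, distance-decaying r², good but imperfect chip tagging). It does not
model recombination hotspots, gene conversion, population structure, allele
ages or selection, so passing pipeline tests demonstrate correctness of the
study machinery under realistic LD, not numeric agreement with any particular
empirical region; outcome percentages on real panels depend on the empirical
LD and chip and will differ.

Studies follow the two-stage GWAS design: controls are uniform haplotype
pairs (an unphenotyped cohort); cases draw their causal genotype with
probabilities proportional to `((1-f)^2, 2f(1-f)alpha1, f^2 alpha2)` and then
uniform consistent haplotype pairs; all draws are without replacement within a
study (scan and replication share the pool; the panel is restored between
studies). The scan trend-tests every chip SNP (chip = SNPs with MAF ≥ 0.05
retained independently with probability 0.5); the smallest-p SNP is the hit
(ties broken deterministically by lowest index), and the cascade
10⁻⁶ → 0.01 → 0.05 classifies each study as undetected, association only, or
association + deviation. Default experiment: every polymorphic SNP is presumed
causal in turn, once per allele orientation (dominant/recessive models are not
allele-symmetric). Study-level seeds are spawned from the experiment seed, so
outcome tables reproduce byte-for-byte.

Because sampling is without replacement from a finite panel, the sampling
fraction matters: consuming a large share of the panel depletes the control
pool of risk alleles and biases effect estimates upward. The default
configuration (8,000 haplotypes per study from 100,000) keeps this negligible;
the bridge tests that compare simulation with asymptotic theory use bespoke
two-SNP panels of 400,000+ haplotypes for the same reason.

## Problem sizes used in the checks

The calibration check runs the full pipeline at the design's study sizes
(2,000 + 2,000 scan, 2,000 + 2,000 replication) over one default panel —
2,000 studies, giving 500–700 detected associations under a multiplicative
truth at hom RR 1.4². The theory↔simulation bridge uses 2,000 replicates per
(model, r) setting at four settings including r = 1, plus the N/r⁴
equivalence pair. Identity checks use 1,000 random scenarios each at 1e-12.

## Known limitations

* The power theory uses expected-information Wald asymptotics; under strong
  misspecification (large non-multiplicative effects analysed with the trend
  test) a sandwich variance would differ slightly — the Monte-Carlo oracles
  bound this in the regimes tested.
* The interaction machinery works at the haplotype level and assumes the two
  causal loci are unlinked.
* No covariates, genotyping error, imputation dosages, or multi-allelic
  markers; phase is taken as known within the simulator's panels.
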