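# Methods

## The quantities

All coefficients are identity-by-descent probabilities relative to the
pedigree's founder generation, at one autosomal locus in a diploid,
non-sex-linked genome.

**Kinship** k(i, j) is the probability that one allele drawn at random from
*i* and one from *j* are identical by descent; **inbreeding** f_i is the
kinship of *i*'s parents. Founders — including immigrants — are assumed
unrelated and non-inbred; that assumption fixes the base population and is
the only consistent reference for relative coefficients. An individual with
a single recorded parent is treated as if the missing parent were a unique
phantom founder: the known half of the genealogy is retained and the unknown
half contributes nothing. Adding such a phantom can never increase a
kinship coefficient.

Kinship is computed by the classic recursion on a topological order
(memoized, robust to inbreeding loops and overlapping generations; O(n²)
worst case, which is ample at field-study scale):

    k(i, j) = [k(sire_i, j) + k(dam_i, j)] / 2      (i not an ancestor of j)
    k(i, i) = [1 + f_i] / 2,   f_i = k(sire_i, dam_i)

with missing parents contributing zero. An independent Monte Carlo
**gene-dropping** estimator (uniquely labelled founder alleles transmitted
down the genealogy; match frequency over the four ordered allele draws per
replicate; SE ≤ ½/√reps) serves as an oracle in the test suite — the two
routes agree within ±0.01 at 2×10⁵ replicates on random looped pedigrees.

**Brood allelic values.** For a social pair (male *i*, female *j*) with
brood size BS, each offspring is within-pair (WPO, sired by *i*) or
extra-pair (EPO, sired by *q*). Per-offspring relatedness:

    r_iWPO = ½ + k_ij + ½f_i        r_iEPO = k_ij + k_iq
    r_jWPO = ½ + k_ij + ½f_j        r_jEPO = ½ + k_jq + ½f_j

TAV_i and TAV_j sum these over the brood. PAV = BS·r_iWPO is the male's
potential allelic value had he sired everything, and LAV = PAV − TAV_i is
what extra-pair paternity cost him, discounted by his kinship to the
cuckolders. PAV = TAV_i + LAV is an exact identity. When every k and f is
zero the statistics collapse to the classical forms ½N_WPO, ½BS and
½BS·P_EPO. The PAV formula is the direct substitution of r_iWPO for every
offspring; the source analysis defines PAV only verbally ("had he sired the
entire brood"), so this reading is flagged here as the package's own.

**TAV_z** standardizes TAV within each brood-size class
((TAV − μ_BS)/σ_BS, sample SD), isolating relatedness variation from the
brood-size gradient. Conventions where the analysis is otherwise silent:
σ is the n−1 sample SD; a class with one brood or zero dispersion gets
TAV_z = 0 (centred, no dispersion information); standardization runs over
the full supplied brood set, not per year. An offspring with an unresolved
genetic sire is treated by default as sired by an unrelated phantom founder
(with a warning); a strict mode drops the brood instead.

## The model comparison

Feeding rate (feeds/hour, one row per 1-hour session per parent) is
modelled with Gaussian linear mixed models. The null model contains
nestling age, lay date, time of day (reference: morning), nest social
status (reference: monogamous), the mate's simultaneously observed feeding
rate, and mate-rate × status interactions; crossed random intercepts for
focal individual, social mate and nest appear in every model. Focal models
add one predictor — BS, TAV, TAV_z (with or without BS as a four-level
factor), LAV, P_EPO, pair kinship k_ij, or own inbreeding f — the latter
four with BS as an additional covariate; optional status-interaction
variants centre their focal covariate, as is done for every continuous
variable inside an interaction.

Support is judged by AICc = −2logL + 2k + 2k(k+1)/(n−k−1), with a focal
model *supported* when its AICc undercuts the null's by ≥ 2 units.
Decisions where the design was genuinely open:

- **ML, not REML.** Compared models differ in fixed effects; REML
  likelihoods are not comparable across fixed-effect structures. Output
  tables are therefore ML-based throughout.
- **k counts** fixed effects + three variance components + residual.
- **Random effects** are independent intercepts (no cross-correlations),
  matching the three named identity effects. They are fitted with
  statsmodels MixedLM as variance components inside a single
  all-encompassing group, which represents arbitrary crossing exactly.
- **Optimization.** L-BFGS first; if it reports non-convergence, a
  derivative-free Powell pass restarts from its solution and the better
  likelihood is kept. L-BFGS can stall when a variance component sits on
  the zero boundary. A variance component estimated at zero is reported as
  a `boundary` flag, not a failure; true non-convergence is flagged and
  such fits are excluded from comparison tables with a warning (the
  comparison errors out only if the null itself fails).
- **Intervals and contrasts** are Wald: estimate ± z·SE, with the status
  contrasts reported at 85% by default (a config knob, `ci_level`).
  Marginal (least-square) means evaluate each factor level at the mean of
  continuous covariates with balanced weights over other factors.
- Pearson correlations come from scipy; degenerate inputs error loudly.

## The synthetic generator

The generator emulates the design of a small island songbird study:
~138 nests in a 79:30:29 monogamous / primary-polygynous /
secondary-polygynous split, broods of 1–4, per-offspring extra-pair
probability 0.28 (~44% of broods affected at these brood sizes), 1–7
one-hour sessions per nest with median 2, and a resident population small
enough (20 founders, 50 offspring per generation for 7 overlapping
generations, ~1 immigrant founder per generation) that pairwise kinship and
inbreeding are substantial. Mate and extra-pair-sire sampling are weighted
by (0.01 + k)^kin_bias; kin_bias = 0.7 both in the pedigree layer and in
social pairing, which reproduces mate-kinship and inbreeding distributions
of the order reported for such systems (k_ij ≈ 0.07 ± 0.06,
f ≈ 0.07 ± 0.06 across seeds). The tails are fatter than island data
because close-kin matings are not excluded; the generator makes no claim
of demographic realism (no survival, territory or multi-year dynamics).

Feeding rates are truncated-Gaussian draws from a linear predictor —
intercept, TAV slope (both sexes), LAV and pair-kinship slopes (males),
nestling-age/lay-date/time-of-day/status effects — plus independent
Gaussian random intercepts for individual, mate and nest, and session
residual. This matches the Gaussian LMM the analysis fits rather than a
count process: passing recovery tests demonstrates the estimator works
under its own assumptions, not that real provisioning data are Gaussian.
Mate-rate dependence is unidirectional by construction (female latent rate
drawn first; the male's observed rate adds 0.2× it), a deliberate
simplification that avoids a simultaneous-equations generator; the causal
structure of real mate coordination is unknown. Default effect sizes (e.g.
TAV slopes of 0.9 feeds/hour per allelic-value unit, male status shifts
0/−0.5/−3.5) sit in the range reported for wild passerine provisioning.
All randomness flows from one root seed, split per stage, so every
generator is bit-reproducible.

## Problem sizes in the tests

The oracle-agreement test uses 20 random pedigrees of 30–60 individuals
with 2×10⁵ gene-dropping replicates per checked pair. Recovery and
model-selection tests use 100 replicates of 200-nest datasets (~450
sessions each), fitting one to three mixed models per replicate. The
OLS-collapse check uses ~1,800 sessions. With truth-zero variance
components the ML estimates hover slightly above zero rather than vanishing,
so that check asserts agreement with OLS to 0.02 on slopes, not to machine
precision.

## Known limitations

- Coefficients are pedigree expectations, not realized (marker-based)
  relatedness; genomic estimation is out of scope.
- X-linked inheritance, pedigree reconstruction and parentage assignment
  are out of scope; parentage is taken as given.
- The AICc threshold rule is the only multiplicity control, mirroring the
  comparative design it implements.
- Truncation at zero feeding rates slightly biases generated means upward
  at low intercepts; defaults keep rates well away from the bound.
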