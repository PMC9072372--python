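# Methods

`breedtrace` implements the statistical machinery used to ask whether a
pig (or any diploid, biallelically genotyped animal) can be traced back
to its breed of origin from SNP-chip genotypes: genotype QC, principal
component analysis, maximum-likelihood admixture, and discriminant
analysis of principal components (DAPC) evaluated under two
external-validation designs. This note records the models, the numerical
choices, and what the built-in simulator can and cannot tell you.

## Genotype substrate and QC

Genotypes are allele-B dosages g ∈ {0, 1, 2} with an explicit missing
code, carried with sample (animal id, breed) and SNP (id, chromosome,
position, alleles) metadata. Both PLINK dialects are supported; the
breed label travels in the family-ID column, the only label-bearing slot
the format offers. Two caveats inherent to the formats: the text dialect
stores alleles only in the genotype body, so a SNP whose column never
shows both alleles cannot have the unobserved allele's identity
recovered on re-read; the binary dialect has no such loss.

Panel merging intersects SNP ids, restricts to autosomes 1–18 (the pig
karyotype), and harmonizes allele frames: swapped labels are recoded
g → 2 − g, opposite-strand labels are complemented first, and
strand-ambiguous SNPs (A/T, C/G) whose labels disagree are dropped —
strand cannot disambiguate them.

The missingness filter removes samples with **more than** 10% missing
calls, then recomputes SNP missingness on the survivors and removes SNPs
with **more than** 5% missing. Both thresholds are strict (boundary
values retained) and configurable. Samples-first ordering is a
convention, exposed rather than hidden; a single pass after merging is
applied, not an iterative one. Missing cells that survive QC are
mean-imputed per SNP before any linear algebra; imputation never uses
validation data (prediction imputes with *training* means).

## Synthetic panels (what the simulator emulates)

The generator is Balding–Nichols with admixture:

* ancestral allele frequency p_j ~ Uniform(0.1, 0.5) per SNP;
* population frequency f_kj ~ Beta(p_j(1−F_k)/F_k, (1−p_j)(1−F_k)/F_k),
  so F_k is the FST of population k against the ancestral pool
  (verified against a Weir–Cockerham estimator in the tests);
* individual ancestry q_i ~ Dirichlet(c · profile) around the breed's
  ancestry profile; an infinite concentration c makes the breed exactly
  pure (used for ground-truth one-hot breeds);
* genotype g_ij ~ Binomial(2, q_i·f_j); missing cells i.i.d.

One explicit RNG stream per call, seeded; same seed ⇒ bit-identical
output.

The study-scale preset builds 24 labeled groups of 50 animals
(~1,200 total): 20 near-pure breeds (concentration 200, per-breed FST
0.12–0.24), three mosaic breeds mixing four donor ancestries plus an
outgroup component (concentration 15 — visible within-breed ancestry
variance), and one diffuse outgroup at FST 0.25 standing in for a
multi-country wild-boar sample. Defaults of 2,000 SNPs keep desk-scale
runs fast; the real chips carry tens of thousands.

The simulator deliberately omits linkage disequilibrium, pedigree
structure, genotyping error and selection. Passing tests therefore
demonstrate correctness of the estimators under the generative model
they assume, not field performance on real chip data, where LD and
relatedness inflate apparent separation.

## Admixture

The likelihood is the standard binomial admixture model: animal i's
genotype at SNP j is Binomial(2, a_ij), a_ij = Σ_k q_ik f_kj, with Q
(n×K) row-stochastic ancestry proportions and F (K×m) ancestral allele
frequencies. The binomial coefficient is constant in (Q, F) and omitted
from all reported log-likelihoods. Missing cells contribute nothing to
the likelihood or the update sums.

Estimation is plain EM with multiplicative updates (the FRAPPE
formulation). EM shares its stationary points with the quasi-Newton
acceleration used by the well-known reference tool but is simpler to
verify: the log-likelihood is non-decreasing at every iteration (a
property the tests assert at relative tolerance 1e-8) and the simplex /
box constraints are preserved by construction. The cost is slower
convergence, acceptable at the problem sizes used here.

Numerical choices: Q initialized Dirichlet(1,…,1) per row, F ~
Uniform(0.05, 0.95); F clipped to [1e-8, 1−1e-8] and doses clipped to
[1e-12, 1−1e-12] inside logs; convergence when the relative
log-likelihood gain drops below `tol` (1e-6 for final fits, 1e-5 inside
cross-validation, where ranking K does not require deep convergence);
`max_iter` 2000; three random restarts for final fits (best likelihood
kept), one per CV fold. A component whose Q column loses all mass is
reseeded once, then left alone with a warning.

The number of ancestral populations K is chosen by masked-cell
cross-validation: observed genotype *cells* (not individuals) are
partitioned into five folds; each fold in turn is hidden, the model
refit, and the mean binomial deviance
d = g ln(g/2â) + (2−g) ln((2−g)/(2−2â)) (0·ln 0 = 0) of the hidden
cells recorded; the smallest K attaining the minimal mean error wins.
Label switching between fits, or between a fit and simulator ground
truth, is resolved by optimal assignment (Hungarian) on the correlation
of allele-frequency rows.

## PCA

Centered, unscaled by default — the convention of R's `prcomp`, which
breed-structure studies typically follow; unit-variance scaling sits
behind a flag. Computation is SVD of the centered matrix (stable for
n ≪ m); eigenvalue k equals the variance (divisor n−1) of score column
k, and the full-rank eigenvalue sum equals the total data variance, so
variance-explained fractions are exact. External samples are projected
with training means/scales/loadings only. Loading signs are fixed by
making each column's largest-magnitude entry positive, so independent
runs are comparable.

## DAPC

PC scores feed a linear discriminant analysis: axes solve the
generalized eigenproblem B v = λ W v with W the pooled within-group and
B the between-group covariance of the retained scores, normalized to
vᵀWv = 1 (unit within-group variance, so discriminant-space Euclidean
distance is Mahalanobis under the shared covariance). At most
(groups − 1) axes exist. A singular W gets a ridge of
1e-8·trace(W)/n_pcs with a warning — relevant when groups−1 approaches
the retained-PC count in small CV folds.

Assignment of an external animal: impute with training means, center
with training means, project through training loadings and axes, and
take posterior ∝ exp(−d²/2) over group centroids (shared-covariance
Gaussian in the whitened space), argmax with lexical tie-break. No
statistic of the validation genotypes influences the model — asserted
in the tests by mutating validation data and comparing models
bit-for-bit.

The retained-PC count is tuned by repeated stratified k-fold CV with
mean prediction error (1 − fraction correctly assigned) as the default
objective; mean success is available as the alternative. Defaults
follow common practice for this design: 10 folds, 30 repeats, candidate
grid 25, 50, …, 300 capped at min(n−1, m). Inside each fold the PCA is
computed once at the largest candidate and truncated per candidate —
algebraically identical, much cheaper. Partitions that would leave a
breed with fewer than two training members are redrawn (up to 10
attempts).

## Validation scenarios

* **Scenario 1 (semi-supervised)**: per repeat, a stratified 80/20
  split — validation size per breed is round-half-up of 20% with a floor
  of one animal; retained-PC count tuned on the training side only;
  overall success is the micro-average over pooled validation animals.
* **Scenario 2 (un-supervised)**: each breed in turn is entirely held
  out; training is all other breeds (optionally subsampled, stratified);
  the retained-PC count is re-tuned per left-out breed because the
  training set changes. The confusion diagonal is structurally zero.
  Repeat-level proportions are averaged by default; pooling individuals
  across repeats is available as a flag (the two differ only when breed
  sizes vary across repeats).
* **Subsampling curve**: stratified subsamples at fractions 0.3–1.0
  (minimum three animals per breed for scenario 1: two train, one
  validation), one scenario repeat per subsample draw; fraction 1.0
  reproduces the plain scenario bit-for-bit at equal seed.

Determinism: every scenario consumes one explicit RNG seeded from
(config seed, scenario tag); identical data + config + seed give
byte-identical CSV outputs.

## Problem sizes in the shipped tests and acceptance script

Unit tests run on 200–500-SNP panels. The pipeline-level checks use the
sizes the estimators were designed around: the K=3 recovery panel
(3×60 pure + 30 admixed animals, 2,000 SNPs, FST 0.2) for admixture
recovery and CV choice of K (K searched over 2–6, ten seeds), and the
24-group study-scale preset (1,200 animals, 2,000 SNPs) for the
traceability scenarios and the sample-size robustness comparison
(fractions 0.3 vs 1.0, ten repeats, fixed 100 retained PCs; the tuning
grid is reduced to a few candidates where the full grid would not change
the outcome). These are the package's own desk-scale choices; the
estimators accept the full-size problems unchanged.

## Known limitations

* The EM admixture fit is unaccelerated; tens of thousands of SNPs with
  K above ~10 will be slow compared to specialized tools.
* No LD pruning or kinship correction; both PCA and DAPC treat SNPs as
  exchangeable and individuals as unrelated.
* Mean imputation is the only missing-data policy; heavy, non-random
  missingness should be filtered, not imputed.
* The text PLINK dialect cannot round-trip allele identities of
  monomorphic SNPs (format limitation, see above).
* Scenario success on simulated panels is typically near-perfect at
  realistic FST; the simulator understates the within-breed noise of
  real chip data.
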