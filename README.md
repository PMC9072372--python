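# breedtrace

Breed traceability from SNP genotypes: can an animal be assigned back to
its breed of origin from a genotyping-chip panel?

`breedtrace` packages the analysis chain used in livestock
breed-of-origin studies — built around the setting of two dozen European
pig breeds genotyped on ~50K-SNP chips — as a tested, reusable Python
library with a command-line interface:

* **Genotype I/O and QC** — PLINK text (.ped/.map) and binary
  (.bed/.bim/.fam) readers and writers, panel merging to a common
  autosomal SNP set with allele-frame harmonization, and missingness
  filters (samples > 10%, then SNPs > 5%, both strict and configurable).
* **PCA** — centered, unscaled by default (à la `prcomp`), with exact
  variance-explained accounting and projection of external samples
  using training statistics only.
* **Admixture** — maximum-likelihood estimation of ancestry proportions
  Q (n×K) and ancestral allele frequencies F (K×m) under the binomial
  model g_ij ~ Binomial(2, Σ_k q_ik f_kj), by EM with guaranteed
  log-likelihood ascent; the number of ancestries K is chosen by
  masked-genotype cross-validation (binomial deviance on hidden cells).
* **DAPC** — linear discriminant analysis on retained PC scores
  (generalized eigenproblem B v = λ W v), with the retained-PC count
  tuned by repeated stratified k-fold CV (grid capped at 300 PCs,
  minimum prediction error as default objective).
* **Validation scenarios** — Scenario 1: stratified 80/20 hold-out,
  repeated; Scenario 2: leave-one-breed-out, forcing held-out animals
  onto the remaining breeds; plus a sample-size robustness curve
  (stratified subsamples from 30% to 100%).
* **Synthetic panels** — a Balding–Nichols simulator with known ground
  truth (true Q and F), including a 24-group, ~1,200-animal preset with
  near-pure breeds, mosaic admixed breeds and a diffuse outgroup, so
  every stage can be checked against truth.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

```python
import numpy as np
from breedtrace import (
    ScenarioConfig, cv_choose_k, fit_admixture, align_components,
    run_scenario1, run_scenario2,
)
from breedtrace.synthetic import make_admixture_test_panel

# three pure source breeds (60 each) + one evenly admixed group (30),
# 2,000 SNPs at FST 0.2, with known ground truth
panel, truth = make_admixture_test_panel(seed=1, n_snps=2000)

curve = cv_choose_k(panel, ks=range(2, 7), folds=5, seed=0)
print("chosen K:", curve.chosen_k)

fit = fit_admixture(panel, K=3, seed=0)
perm = align_components(fit, truth)
q_err = np.abs(fit.Q[:, np.argsort(perm)] - truth.Q_true).mean()
print("mean |Q - Q_true|:", round(q_err, 3))

cfg = ScenarioConfig(repeats=10, pc_grid=[20, 40, 60], cv_folds=5,
                     cv_repeats=1, seed=0)
res = run_scenario1(panel, panel.breeds, cfg)
print("scenario 1 overall success:", res.overall_success)
```

Output:

```
chosen K: 3
mean |Q - Q_true|: 0.02
scenario 1 overall success: 1.0
```

The cross-validated deviance picks the generative K = 3; the estimated
ancestry proportions sit within ~0.02 of the simulator's truth after
resolving label switching; and the stratified hold-out assigns every
validation animal to its breed — at FST 0.2 even the evenly admixed
group is separable from its sources once it is represented in training
(hold it out of training instead, as scenario 2 does, and its animals
fall back onto the source breeds).

The same stages are available from the shell:

```sh
breedtrace simulate --out-prefix run/panel --preset study --seed 1
breedtrace qc --in-prefix run/panel --out-prefix run/clean
breedtrace pca --in-prefix run/clean --out run/scores.csv
breedtrace admixture --in-prefix run/clean --out-dir run/adm --k 21 --seed 1
breedtrace scenario1 --in-prefix run/clean --out-dir run/s1 --seed 1
breedtrace scenario2 --in-prefix run/clean --out-dir run/s2 --n-pcs 100 --seed 1
```

Each command writes CSV/JSON outputs plus a `manifest.json` recording
the resolved options, seed and package version.

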