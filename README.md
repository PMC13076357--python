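# methclock

Epigenetic age clocks from reduced-representation bisulphite sequencing
(RRBS), built for long-lived, non-model mammals.  The package takes
per-CpG methylated/total read counts (Bismark-style coverage files),
applies the standard site filters and imputation, fits a penalized
regression clock with individual-aware cross-validation, and runs the
downstream analyses an ageing study needs: within-individual
longitudinal change, life-stage comparisons, sex effects, and
CpG-island/genic context annotation.  A synthetic-cohort generator with
known per-site ground truth makes the whole pipeline testable without
access to restricted animal data.

The design mirrors blood-based clock studies in species such as the
Asian elephant: a few dozen individuals spanning the lifespan, repeated
samples for a longitudinal subset, a strongly skewed sex ratio, and
~10^5 candidate CpGs of which a small fraction track age.

## The model

At CpG *j* in sample *i* the methylation ratio is
`m_ij = methylated reads / total reads`.  After filtering (mean coverage
≥ 5×, mean methylation in [0.1, 0.9], missingness < 5%) and k-nearest-
neighbour imputation, each sample is quantile-normalized to a standard
normal by rank (the `qqnorm` convention), independently of every other
sample.  Sites whose normalized methylation correlates with
chronological age (|r| > 0.5, Pearson) become clock candidates, and age
is modelled as

    age_i = b0 + sum_j beta_j x_ij

with the elastic-net penalty `lambda * (alpha*||beta||_1 +
(1-alpha)/2*||beta||_2^2)`.  The mixing parameter alpha is grid-searched
on cross-validated R²; lambda is chosen per alpha by internal n-fold
cross-validation on MSE.  Because individuals are sampled repeatedly,
evaluation uses **leave-one-individual-out cross-validation (LOIOCV)**:
each fold holds out every sample of one individual, so repeated
measures never leak between training and validation.  Age acceleration
(Δage) is the residual of DNAm age regressed on chronological age.

The elastic-net solver is implemented in-package (cyclic coordinate
descent with soft-thresholding, plus an exact active-set refinement)
and certifies every final fit by its Karush–Kuhn–Tucker residual
(< 10⁻⁷).

## Worked example

```python
import numpy as np
from methclock import CohortSpec, simulate_cohort, run_clock_pipeline
from methclock.longitudinal import extract_first_last, filter_pairs, test_delta

spec = CohortSpec(n_individuals=30, n_sites=5000, p_age=0.015, seed=42)
dataset, truth = simulate_cohort(spec)

result = run_clock_pipeline(dataset,
                            alpha_grid=np.round(np.arange(0, 1.01, 0.1), 2),
                            seed=42)
pairs = filter_pairs(extract_first_last(result.predictions))
res = test_delta(pairs)
```

prints (via the fields used above):

```
cohort: 5000 CpG sites x 91 samples from 30 individuals
retained after filtering: 4436 sites
clock CpGs (|r| > 0.5): 66
tuned alpha = 0.2, lambda = 0.345
LOIOCV: r = 0.996, MAE = 1.06 y, relative error = 1.34%
longitudinal: n = 21 individuals, mean delta = 5.66 y, t = 5.66, df = 20, one-sided p = 7.7e-06
```

Reading this: of 5,000 simulated CpGs, 4,436 survive the coverage/
methylation/missingness filters and 66 pass the age-correlation screen;
the tuned clock predicts the age of held-out individuals with a Pearson
correlation of 0.996 and a mean absolute error of about one year
(relative error = 100·MAE / 79.6 y, the maximum recorded Asian-elephant
lifespan).  Between first and last sampling, epigenetic age rises in
step with elapsed time (mean increase 5.66 y over a mean ~5-y interval;
one-sample one-sided t-test against zero change).

The same workflow is scriptable from the shell:

```sh
methclock simulate --spec cohort.yaml -o fixtures/
methclock assemble --coverage-dir fixtures/coverage --metadata fixtures/metadata.tsv -o ds.npz
methclock preprocess --in ds.npz -o matrix.npz
methclock train --matrix matrix.npz --seed 1 -o model.json
methclock predict --model model.json --coverage sample.cov
methclock annotate --model model.json --islands islands.bed --genes genes.bed12 -o context.tsv
```

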