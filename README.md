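# solvemat

Structured orthogonal latent-variable estimation (SOLVE) for matrix
outcomes.

## The problem

In pharmacogenomic screens and similar designs, an outcome matrix
Y (n samples × m items — say, cell lines × drugs) is observed together
with features of the rows, X (n×p, e.g. expression of screened genes),
and features of the columns, Z (q×m, e.g. molecular descriptors of the
compounds; q may be zero). A naive bilinear GLM
`g(E[Y]) = XA + BZ` is distorted by *latent factors*: unmeasured
variables — a survival-pathway dependency, a batch effect, an
uncharacterized compound potency — that imprint systematic low-rank
structure on Y and bias the coefficient estimates.

`solvemat` fits the model

```
g(E[Y]) = X A + B Z + C,      rank(C) ≤ r,
subject to  P_X B = 0,   P_X C = 0,   C P_Zᵀ = 0,
```

where C is a low-rank latent component and P_X, P_Zᵀ are the orthogonal
projectors onto the column space of X and the row space of Z. The
orthogonality constraints make the decomposition identifiable: C absorbs
only variation the measured predictors cannot explain, so A and B can be
interpreted (and tested) as the unique effects of the observed features.

Key properties:

* **Exact solver for regression.** Under squared loss the constrained,
  rank-restricted problem has a *global closed-form* optimum: the latent
  kernel is the truncated SVD of the doubly projected outcome
  `S(P_X⊥ Y P_Zᵀ⊥; r)`, and A, B are pseudoinverse regressions.
* **Monotone MM solver for other losses.** For any loss with a
  Lipschitz-gradient (built in: Bernoulli-logistic), a
  majorization–minimization scheme applies the closed form to the
  pseudo-response `ξ = η − ∇l(η)/ρ` each pass; the loss never increases
  for ρ ≥ L.
* **Data-driven rank choice.** An AIC-type criterion
  `IC(r) = deviance + 2·DF(r)` with `DF(r) = pm + nq + r(n+m−r)` is
  scored over a rank grid, and the rank is picked at the *elbow* of the
  curve (maximum perpendicular distance to the chord on normalized axes),
  which resists the overfitting of plain IC minimization.
* **Bootstrap inference.** Wild (Rademacher) bootstrap for gaussian
  outcomes and parametric Bernoulli bootstrap for binary ones give
  entrywise standard errors, percentile CIs and p-values for A and B.
* **A reproducible simulation benchmark** emulating the structure of
  pharmacogenomic data, with parameter-recovery and rank-recovery metrics.

## Worked example

```python
import numpy as np
from solvemat import (SimulationSpec, generate_dataset, rank_path,
                      wild_bootstrap_gaussian, summarize_bootstrap,
                      latent_loadings, relative_error)

# a synthetic screen: 200 samples x 150 items, 10 row features,
# 8 column features, a rank-4 latent component, gaussian noise sd 3
spec = SimulationSpec(n=200, m=150, p=10, q=8, true_rank=4, sigma2=9.0,
                      seed=0)
sim = generate_dataset(spec, replicate_index=0)
data = sim.to_design("gaussian")

path = rank_path(data, grid=range(1, 11))      # fit + score each rank
print(f"selected rank: {path.selected_rank}")

fit = path.selected_fit
print(f"error on A:   {relative_error(fit.A, sim.A_star):.2f}%")
print(f"error on B:   {relative_error(fit.B, sim.B_star):.2f}%")
print(f"error on eta: {relative_error(fit.eta, sim.eta_star):.2f}%")

U, s, V = latent_loadings(fit)                 # SVD of the fitted C
print(f"latent singular values: {np.round(s, 1)}")

res = wild_bootstrap_gaussian(fit, data, B=200, seed=1)
table = summarize_bootstrap(res, level=0.95, p_method="normal").table
print(table.sort_values("p_value").head(3).to_string(index=False))
```

Output:

```
selected rank: 4
error on A:   7.59%
error on B:   8.77%
error on eta: 9.20%
latent singular values: [201.5 197.1 174.  147.3]
 row  col  estimate       se  ci_lower  ci_upper  p_value p_method
   5   74 -6.691912 0.173772 -7.011893 -6.358895      0.0   normal
   9   96 -6.264024 0.161370 -6.587464 -5.951291      0.0   normal
   4   50  8.097712 0.197467  7.764827  8.467398      0.0   normal
```

The elbow rule recovers the generating rank (4); the relative errors of
the coefficient blocks sit at the level the closed-form theory predicts
for this noise level (≈ 7.5–9%); the four latent singular values stand
clearly above the noise; and the bootstrap table flags the strongest
row-feature/item effects with tight intervals (row/col are matrix indices
here — with file input they are your sample/item identifiers).

The same workflow is available from the shell on delimited text matrices
(row ids in the first column, column ids in the header):

```
solvemat simulate --outdir sim/
solvemat select-rank --y sim/Y.csv --x sim/X.csv --z sim/Z.csv --grid 1:10 --outdir sel/
solvemat fit        --y sim/Y.csv --x sim/X.csv --z sim/Z.csv --rank 4 --outdir fit/
solvemat bootstrap  --y sim/Y.csv --x sim/X.csv --z sim/Z.csv --rank 4 -B 200 --outdir boot/
solvemat replicate  --sigma2 9 --n-replicates 50 --outdir rep/
```

`fit` writes A/B/C/eta matrices and a fit summary (loss trace tail,
convergence, constraint residuals); `bootstrap` writes a volcano-ready
per-entry table; every run logs its options and seed for exact
reproducibility.

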