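# bpa — Bayesian Probability of Association

Association testing for paired numeric series that separates
**information** from **noise**.  Classical correlation coefficients treat
a variable as one lump; `bpa` models each observed variable as the sum of
a latent *information* component (the part that can be shared with the
other variable) and an independent *noise* component, and asks a binary
question: *are the two information components linked by a relationship
function f, or not?*

The package is for anyone who needs to call associations in noisy paired
measurements — epidemiological covariates, physiological channel pairs,
ecological or financial series — especially when the relationship may be
non-linear or the noise level high enough to defeat Pearson-style
coefficients.

## The model

Each standardised variable decomposes as

```
X = I_X + N_X          Y = I_Y + N_Y
```

with zero-mean normal components and Var I_X = α_X, Var N_X = 1 − α_X
(likewise Y), so a single proportion α ∈ (0, 1) per variable fixes the
split of its unit variance.  Two mutually exclusive hypotheses are
compared, conditional on a relationship function f:

* **H1 (associated):** I_Y = f(I_X)
* **H2 (independent):** I_X and I_Y were generated independently

For one observation (x, y) the likelihoods are

```
L(x,y|H1) = ½ ∫ p_IX(i) p_NX(x−i) p_NY(y−f(i)) di
          + ½ ∫ p_IY(i) p_NX(x−f⁻¹(i)) p_NY(y−i) di

L(x,y|H2) = [∫ p_IX(i) p_NX(x−i) di] · [∫ p_IY(i) p_NY(y−i) di]
```

with the H1 integrals restricted to f's domain and range.  Starting from
equal priors P(H1) = P(H2) = 0.5, each datapoint updates the posterior
by Bayes' rule; the final posterior probability of H1 is the **Bayesian
Probability of Association (BPA)**.  Opposite-sign extremes force a
large noise residual under H1 and push the posterior down; concordant
extremes are doubly improbable under H2 and push it up.

Since the true proportions are unknown, BPA is evaluated over a grid of
assumed proportions (α′_X, α′_Y); the pair is called **associated** when
any cell reaches a near-1 threshold (default 0.99).  Because the
posterior collapses once an assumed proportion exceeds the true one, the
BPA-weighted sums S_X = Σ α′_X·BPA and S_Y = Σ α′_Y·BPA over the grid
compare the information content of the two variables and give a
causal-direction heuristic (higher score → more information → more
likely the cause).  A panel of classical measures — Pearson (with
p-value), Spearman, Kendall, and a histogram normalized mutual
information — is computed alongside for comparison.

## Worked example

```python
from bpa import (AlphaGrid, baseline_panel, compute_bpa, generate_pair,
                 identity_function, scan_alphas)

# a noisy associated pair: 61% of each variable's variance is shared
pair = generate_pair(n=100, alpha_x=0.61, alpha_y=0.61,
                     associated=True, seed=7)
res = scan_alphas(pair.x, pair.y, identity_function(), AlphaGrid.synthetic())
print(res.associated, round(res.max_bpa, 4))        # True 1.0
panel = baseline_panel(pair.x, pair.y)
print(round(panel.pearson, 3), round(panel.nmi, 3))  # 0.626 0.154
```

The scan saturates (BPA = 1.0 in every cell with assumed proportions at
or below the truth) and calls the association decisively, while Pearson
reports a middling 0.626 on the same data.  The contrast is sharper for
a non-monotone relationship — the symmetric parabola pair from the
non-linear benchmark:

```python
from bpa import generate_nonlinear_suite
quad = generate_nonlinear_suite(100, seed=0)[1]       # y = x² member
panel = baseline_panel(quad.x, quad.y)
print(round(panel.pearson, 3), round(panel.spearman, 3))  # 0.173 0.098
res = scan_alphas(quad.x, quad.y, quad.relationship, AlphaGrid.synthetic())
print(res.associated)                                  # True (max BPA 1.0)
print(round(compute_bpa(quad.x, quad.y, 2/3, 2/3,
                        identity_function()).bpa, 4))  # 0.0
```

Correlations are near zero, yet with the correct relationship function
the association is certain — and assuming the *wrong* function (identity)
correctly yields no association, since BPA is always conditional on f.

The same pipeline is available from the shell:

```sh
bpa simulate pairs/ --suite grid --seed 3        # synthetic benchmark CSVs
bpa scan pairs/pair_000.csv --has-header \
    --grid synthetic --heatmap-csv heat.csv      # JSON report + heatmap
bpa compute data.csv --relationship quadratic --alpha-x 0.5 --alpha-y 0.5
bpa baselines data.csv
```

`bpa scan` fits a linear relationship by least squares unless
`--relationship` names a builtin (identity, linear, quadratic, cubic,
exponential, sinusoidal); exit codes are 0 (success), 2 (input error),
3 (numerical failure).

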