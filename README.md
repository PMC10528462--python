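# ncrm — concurrent functional regression with SS-ANOVA component selection

`ncrm` models a functional response against functional covariates that are
observed *concurrently*: at every time `t`, subject `i` carries a response
value `y_i(t)` and, for each of `q` covariates, a whole profile
`x_ij(t, ·)` over an inner argument `s` (for example a frequency spectrum
of a movement sensor recorded at each clinical visit).  The model is

    y_i(t) = f(t, x_i(t, ·)) + ε_i(t),     t ∈ [0, 1],

with `f` estimated nonparametrically in a tensor product of
reproducing-kernel Hilbert spaces: a second-order Sobolev space in `t`
(reproducing kernels built from the scaled Bernoulli polynomials
`k1, k2, k4`) and one Gaussian-kernel RKHS per functional covariate,
`K(u, u′) = exp(−‖u − u′‖²_{L2}/2)`.  Expanding the product gives a
smoothing-spline ANOVA decomposition

    f = d1 + d2·k1(t) + Σ_v f_v,

where the `f_v` are main effects of `t` and of each covariate and their
interactions.  The estimator of interest minimizes a penalized least
squares with an L1-type *budget* on the per-component scales `θ_v`,

    (1/n)‖Y − Td − Σ(θ)c‖² + λ1Σ w1k|d_k| + τ0 cᵀΣ(θ)c,
        θ ≥ 0,  w2ᵀθ ≤ M,

solved by block backfitting (ridge solve in `c`, weighted lasso in `d`,
nonnegative budget-constrained quadratic program in `θ`).  Components with
`θ̂_v = 0` are removed — the fit *selects* which main effects and
interactions of the functional covariates drive the response.  A ridge
estimator keeping all components (`L2`) and a select-then-refit two-stage
estimator (`L1+L2`) are included, as is a simulation harness that measures
test RMSE and selection accuracy (specificity / sensitivity / F1) on
Gaussian-process generated covariates under three reference designs
(M1–M3).  Audience: statisticians and biomedical data analysts working
with densely observed functional data, e.g. movement-sensor rehabilitation
studies.

See `docs/methods.md` for the model, algorithm, and design choices.

## Worked example

```python
import numpy as np
from ncrm import FunctionalANOVARegressor, SimulationConfig, gen_dataset, rmse

# one replicate of the M3 design: f = 1 + 5cos(2πt) + 10∫x1x2 ds, n=80
cfg = SimulationConfig(model="M3", n=80, sigma=0.22)
train, test, f_true = gen_dataset(cfg, np.random.default_rng(7))

est = FunctionalANOVARegressor(
    penalty="l1", scheme="full_q2",
    tau0_grid=(1e-3, 1e-2), efpc_K=4, efpc_frac=0.995, random_state=0,
).fit(train.x, train.y)

print("selected:", est.selected_labels_)
print("theta:   ", np.round(est.theta_, 3))
print("RMSE:    ", round(rmse(f_true, est.predict(test.x), train.t_grid), 3))
```

Output from this exact script:

```
selected: ['t_np', 'u1:u2']
theta:    [1.332 0.    0.    0.    0.    0.    0.    1.83  0.    0.   ]
RMSE:     0.495
```

The fit recovers exactly the two truly active components — the
nonparametric main effect of `t` (the `cos(2πt)` trend) and the
nonparametric interaction of the two covariates (`10∫x1x2 ds`) — with all
eight other `θ_v` exactly zero, and predicts the true regression function
on 50 unseen test subjects with root mean squared `L2` error 0.495
(the response curves themselves have `L2` norms around 4).

A command-line interface covers the same workflow on long-format CSV
files: `ncrm fit`, `ncrm predict`, `ncrm simulate`, `ncrm evaluate`
(see `ncrm --help`).

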