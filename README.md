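# modfluct

Simulation and verification of **moderately interacting particle systems**
with mollified attractive/repulsive Riesz potentials — the stochastic
many-particle picture behind aggregation–diffusion (Keller–Segel-type)
equations — together with the statistics that make their mean-field and
fluctuation theory measurable at desk scale.

## Who this is for

Researchers in interacting particle systems, stochastic analysis, and
mathematical biology who want a reproducible numerical companion to
mean-field limit and central-limit-theorem results: simulate the particle
system, solve the companion PDEs, and check the predicted convergence rates
and Gaussian fluctuations on one CPU in minutes.

## The model

$N$ particles on a periodic box follow

$$
\mathrm{d}X_i = \frac{\kappa}{N}\sum_{j=1}^{N}\nabla V^\eta(X_i - X_j)\,
\mathrm{d}t + \sqrt{2\sigma}\,\mathrm{d}W_i, \qquad
V^\eta = \xi^\eta * \xi^\eta * \Phi, \quad \Phi(x) = |x|^{-\lambda},
$$

with a sub-Coulomb exponent $0 < \lambda < d-2$ ($d \ge 3$), a smooth bump
mollifier at radius $\eta = N^{-\beta}$ (the *moderate regime*), aggregation
($\kappa = +1$) or repulsion ($\kappa = -1$), and diffusion $\sigma > 0$.
The empirical measure $\mu^\eta = \frac1N\sum_i \delta_{X_i}$ tracks the
intermediate nonlocal diffusion equation

$$
\partial_t \bar u^\eta = \sigma\Delta \bar u^\eta -
\kappa\,\mathrm{div}\bigl(\bar u^\eta\, \nabla V^\eta * \bar u^\eta\bigr),
$$

and the fluctuation field $\mathcal{F}^\eta = \sqrt{N}(\mu^\eta - \bar u^\eta)$
becomes Gaussian as $N \to \infty$, with variance determined by the dual
backward linearization of the limiting equation.  The potential's
convolution-square structure $V^\eta = Z^\eta * Z^\eta$,
$Z^\eta = \xi^\eta * \Psi$, $\Psi * \Psi = \Phi$, turns quadratic interaction
functionals into $L^2$ norms of the smoothed fields
$f^\eta = Z^\eta * \mu^\eta$ and $g^\eta = Z^\eta * \bar u^\eta$ — the
quantities whose mean-square distance decays like $N^{-1/2-\varepsilon}$.

The package provides: mollified-kernel construction with exact spectral
factorization (`modfluct.kernels`); torus fields and particle-mesh transfer
(`modfluct.grid`); Euler–Maruyama ensembles with optional shared-noise
coupling (`modfluct.dynamics`); pseudo-spectral solvers for the
intermediate, limiting, and dual backward equations (`modfluct.pde`); the
rate, CLT, coupling, and law-of-large-numbers statistics
(`modfluct.fluctstats`); and validated, reproducible experiment plans
(`modfluct.runner` and the thin `modfluct` CLI).

## Worked example

Measure the decay of the smoothed empirical-measure error under the study
conditions $d=3$, $\lambda=\tfrac12$, $\kappa=+1$, $\sigma=1$,
$\beta=0.05$:

```python
from modfluct import SimulationConfig
from modfluct.fluctstats import estimate_rate

config = SimulationConfig(N=64, d=3, lam=0.5, kappa=1, sigma=1.0,
                          beta=0.05, dt=0.01, T=0.5, seed=1)
fit = estimate_rate(config, [64, 128, 256, 512], replicas=8)
for N, est, se in zip(fit.N_list, fit.estimates, fit.standard_errors):
    print(f"N = {N:4d}:  E sup_t ||f - g||^2 = {est:.5f} +/- {se:.5f}")
print(f"fitted decay exponent r = {fit.slope:.3f} +/- {fit.slope_se:.3f}")
```

prints

```
N =   64:  E sup_t ||f - g||^2 = 0.01280 +/- 0.00081
N =  128:  E sup_t ||f - g||^2 = 0.00743 +/- 0.00047
N =  256:  E sup_t ||f - g||^2 = 0.00311 +/- 0.00020
N =  512:  E sup_t ||f - g||^2 = 0.00174 +/- 0.00015
fitted decay exponent r = 0.996 +/- 0.046
```

Each line is the Monte-Carlo mean (8 replicas) of
$\sup_t \|f^\eta - g^\eta\|_{L^2}^2$ at that $N$ with its standard error;
the fitted exponent $r \approx 1.0$ comfortably exceeds the theoretical
floor $r \ge 1/2$ — at these sizes the i.i.d. sampling contribution
$\propto N^{-1+\beta\lambda}$ dominates the error budget.

The `examples/` directory holds one short script per capability: kernel
factorization, particle-vs-PDE simulation, the rate experiment, the dynamic
central limit theorem, and the pathwise coupling diagnostics.  The CLI runs
the same experiments from JSON plans, e.g.
`modfluct rate --config plan.json --out results/`.

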