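# Methods

## Model

`modfluct` simulates a system of $N$ diffusing particles on a periodic box
that interact through a mollified Riesz potential,

$$
\mathrm{d}X_i = \frac{\kappa}{N}\sum_{j=1}^{N}\nabla V^\eta(X_i - X_j)\,
\mathrm{d}t + \sqrt{2\sigma}\,\mathrm{d}W_i ,
$$

with $\kappa = +1$ (aggregation, the chemotaxis-like regime) or $\kappa = -1$
(repulsion), diffusion constant $\sigma > 0$, and i.i.d. initial positions
with density $u_0$.  The potential is built from the sub-Coulomb Riesz kernel
$\Phi(x) = |x|^{-\lambda}$, $0 < \lambda < d - 2$, $d \ge 3$, mollified at
radius $\eta$:

$$
V^\eta = \xi^\eta * \xi^\eta * \Phi, \qquad
\xi^\eta(x) = \eta^{-d}\,\xi(x/\eta),
$$

where $\xi$ is the canonical smooth bump
$c_\xi \exp(-1/(1-|x|^2))$ on the unit ball, normalized to unit mass.  In the
*moderate regime* the mollification radius shrinks with the population,
$\eta = N^{-\beta}$, so the interaction localizes as $N$ grows.

Two companion PDEs are solved pseudo-spectrally: the intermediate nonlocal
diffusion equation
$\partial_t \bar u^\eta = \sigma\Delta\bar u^\eta -
\kappa\,\mathrm{div}(\bar u^\eta\, \nabla V^\eta * \bar u^\eta)$, which is the
mean-field limit at fixed $\eta$ and the reference density for the
fluctuation field, and the limiting aggregation–diffusion equation with the
bare kernel $\Phi$.

Three quantitative statements are made measurable:

1. **Mean-square rate.**  With the half kernel $Z^\eta = \xi^\eta * \Psi$,
   $\Psi(x) = c_{d,\lambda}|x|^{-(\lambda+d)/2}$, $V^\eta = Z^\eta * Z^\eta$,
   the smoothed fields $f^\eta = Z^\eta * \mu^\eta$ and
   $g^\eta = Z^\eta * \bar u^\eta$ satisfy
   $\mathbb{E}\sup_t \|f^\eta - g^\eta\|_{L^2}^2 \lesssim N^{-1/2-\varepsilon}$
   for $\beta < 1/(8\lambda + 12)$.  The package estimates the decay exponent
   by Monte-Carlo over a ladder of $N$ and weighted log–log regression.
2. **Central limit theorem.**  The pairing
   $\langle \mathcal{F}^\eta(t), \phi\rangle$ of the fluctuation field
   $\mathcal{F}^\eta = \sqrt{N}(\mu^\eta - \bar u^\eta)$ with a smooth test
   function is asymptotically
   $\mathcal{N}\bigl(0,\ \langle u_0, T^t_\phi(0)^2\rangle -
   \langle u_0, T^t_\phi(0)\rangle^2 +
   2\sigma\int_0^t \langle u(s), |\nabla T^t_\phi(s)|^2\rangle \mathrm{d}s\bigr)$,
   where $T^t_\phi$ solves the dual backward linearized equation
   $-\partial_s v - \sigma\Delta v = \kappa(\nabla\Phi * u)\cdot\nabla v -
   \kappa\nabla\Phi*(u\nabla v)$, $v(t) = \phi$, and $u$ solves the limit
   equation.  The unconditional ($s = 0$) form is tested: replicates with
   fresh initial data against the predicted centered normal.
3. **Coupling and law of large numbers.**  Driving the interacting and
   intermediate systems with shared Brownian increments makes
   $\max_i |X_i - \bar X_i|$ observable; its exceedance probability over
   $N^{-\alpha}$ (admissible window
   $\beta(\lambda+3) < \alpha < 1/2 - \beta(\lambda+1)$) and the
   law-of-large-numbers deviation probability over $N^{-\theta}$ are
   estimated over replicas and checked for decay in $N$.

## Torus truncation

The theory lives on $\mathbb{R}^d$; the implementation works on the periodic
box $[-L/2, L/2)^d$ with all kernels defined through their continuum Fourier
symbols sampled on the discrete wavenumber lattice and the zero mode set to
zero.  Real-space periodization of $\Psi$ or $\Phi$ diverges (they are not
integrable at infinity); the zero-mode convention is immaterial for every
statistic computed here because kernels are always paired against mean-free
signals ($\mu^\eta - \bar u^\eta$, $f^\eta - g^\eta$).

Two distinct kernel representations are kept deliberately:

* **Spectral symbols** drive all field-level convolutions (PDE transport
  terms, smoothing with $Z^\eta$).  The Gamma-function formula
  $\widehat{|x|^{-s}} = 2^{d-s}\pi^{d/2}
  \frac{\Gamma((d-s)/2)}{\Gamma(s/2)}|k|^{s-d}$ fixes the symbols of $\Phi$
  and $\Psi$, and the factorization constant
  $c_{d,\lambda} = \sqrt{A_d(\lambda)}/A_d((d+\lambda)/2)$ (positive root, so
  $\Psi \ge 0$).  The identity $\widehat{V^\eta} = (\widehat{Z^\eta})^2$ then
  holds to machine precision by construction and is asserted at $10^{-10}$.
* **Radial force tables** for the particle drift are computed from the
  *continuum* symbol by one-dimensional Hankel quadrature (graded
  Gauss–Legendre panels absorbing the integrable $k^{\lambda-1}$ singularity,
  cut off where the bump transform is below $10^{-8}$).  This gives the exact
  whole-space $V^\eta(r)$, $(V^\eta)'(r)$ with no periodization artifacts:
  the far field matches $\Phi$ identically, and $(V^\eta)'(0) = 0$ holds
  analytically (it is also enforced).  Pairwise forces use these tables with
  linear interpolation at resolution $h/4$ and the minimum-image convention.
  An independent real-space verification route
  (`kernels.convolution_square_values`) evaluates $(\Psi * \Psi)(r)$ by
  radial quadrature with an analytic tail resummation and confirms the
  factorization constant without touching Fourier symbols.  (A box-local FFT
  convolution cannot verify this identity: $\Psi$ decays too slowly for the
  convolution integral to localize, and truncation loses tens of percent.)

## Numerical schemes

* **SDE integrator**: Euler–Maruyama with fixed $\Delta t$ (default $0.01$);
  drift magnitudes at the default parameters give
  $\|b\|\Delta t \ll h$, well under one grid cell per step.  The self term
  $j = i$ contributes exactly zero through $(V^\eta)'(0) = 0$.  Brownian
  increments are drawn per step in particle-major order from a
  `numpy` `SeedSequence`-derived generator, which makes the shared-noise
  coupling well defined and every run bit-exactly reproducible.
* **PDE integrator**: integrating-factor scheme with the exact diffusion
  factor $e^{-\sigma|k|^2\Delta t}$ and Heun (RK2) for the quadratic
  transport term, dealiased by the 2/3 rule.  The transport term has zero
  mean mode, so total mass is conserved exactly (asserted at $10^{-12}$).
  Positivity is not enforced; each snapshot records its minimum, and runs
  flag (not raise) a blow-up when the sup-norm exceeds a ceiling.
* **Dual backward equation**: substituting $\tau = t - s$ yields a forward
  problem integrated with the same scheme; the coefficients $u(s)$ are
  interpolated linearly in time between stored snapshots.  The defining
  adjointness — constancy of $\langle h(s), T^t_\phi(s)\rangle$ for $h$
  solving the *linearized* forward equation — holds at snapshot times to
  machine precision in this discretization (for $\kappa = 0$ the same holds
  with $u$ itself, the heat flow being self-adjoint; for $\kappa \ne 0$ the
  nonlinear solution is not a linearized solution and its pairing is not
  conserved).
* **Particle–mesh transfer**: cloud-in-cell deposition and interpolation
  (adjoint of each other); for smoothed-measure statistics the CIC transfer
  function $\prod_j \mathrm{sinc}^2(k_j h/2)$ is deconvolved in Fourier
  space, the standard particle-mesh compensation, so the i.i.d. sampling
  identity
  $\mathbb{E}\|Z^\eta*(\mu - u)\|_{L^2}^2 =
  \tfrac1N(\|Z^\eta\|_{L^2}^2 - \|Z^\eta * u\|_{L^2}^2)$
  is reproduced without assignment bias.  Nearest-grid-point deposition is
  retained for unit tests.

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| $d$ | 3 | spatial dimension (theory needs $d \ge 3$) |
| $\lambda$ | 0.5 | Riesz exponent, sub-Coulomb ($< d-2$) |
| $\kappa$ | $+1$ | aggregation (the harder, attractive case) |
| $\sigma$ | 1.0 | diffusion constant |
| $\beta$ | 0.05 | moderate exponent; admissible for the rate result ($< 1/16$) |
| $L$, $n$ | 10, 32 | box edge and grid points per dimension (box units) |
| $\Delta t$, $T$ | 0.01, 0.5 | time step and horizon |
| $s_0$ | 1.0 | width of the isotropic Gaussian $u_0$ (wrapped onto the torus) |
| snapshot stride | 10 | steps between saved states; $\sup_t$ is the max over saved times |

The ladders $N \in \{64, 128, 256, 512\}$ (rate), $N = 500$ with 100
replicates (dynamic CLT), and $N \in \{128, 256, 512\}$ with 24–32 replicas
(coupling/LLN) are the package's desk-scale choices: large enough that the
predicted decays and Gaussianity are visible against Monte-Carlo noise,
small enough that the full battery completes in minutes on one CPU.  With
$\beta = 0.05$ these $N$ give $\eta \in [0.73, 0.81]$ box units.

**Resolution rule.**  The mollifier support *diameter* $2\eta$ must span at
least four grid cells ($\eta \ge 2h$), so the regularized kernel core is
resolved by the mesh; configurations violating this are rejected at
validation.  Test functions are Gaussians (standing in for Schwartz
functions) of width $\ge 3$ cells, evaluated with the minimum-image
convention both on the grid and at particles so the two quadratures agree.

**Initial data.**  Sampling and the PDE initial condition both use the
*wrapped* Gaussian, so they represent the same torus density exactly.  A
guard (`tail_tol`, default $10^{-5}$) bounds the mass the unwrapped Gaussian
would place outside the box — a fidelity bound for comparing with
whole-space theory, not a correctness condition ($s_0 = 1$, $L = 10$ gives
$\approx 1.7\times10^{-6}$).  The smallness condition on
$\|u_0\|_{L^{p^*}}$, $p^* = d/(d-\lambda)$, involves a non-explicit
constant; the package logs the norm rather than enforcing an unverifiable
bound.

## What the synthetic experiments do and do not show

All data are generated internally; there is no external input.  The
generator realizes exactly the study conditions above: i.i.d. Gaussian
initial data, isotropic diffusion, a single attractive or repulsive species.
Passing tests therefore demonstrate the *internal consistency* of the
method chain (particles ↔ intermediate PDE ↔ limit PDE ↔ dual equation) at
desk scale — they do not probe near-blow-up concentration, anisotropic or
multimodal initial data, the Coulomb endpoint $\lambda = d-2$, or
whole-space effects beyond the periodic box.  The CLT prediction uses the
limit-equation density $u$ while the particles feel $V^\eta$ at finite
$\eta \approx 0.73$; the residual $O(\eta)$ corrections are absorbed by the
statistical tolerances (3 standard errors, KS level 0.01) and shrink with
$N$.

## Numerical choices and edge cases

* Weighted least squares on $\log \bar E$ vs $\log N$ with weights from the
  per-$N$ standard errors propagated to the log scale; the fit degenerates
  (raises) if any estimate is nonpositive.
* The Kolmogorov–Smirnov test uses the *predicted* normal (no parameter
  estimation), one pre-registered test per experiment at level 0.01, no
  multiple-testing corrections across exploratory runs.  When the predicted
  variance vanishes (constant observable) the test degenerates and the
  replicates are required to vanish instead.
* $\sup_t$ statistics are maxima over saved snapshots (stride 10 by
  default); continuous-time suprema are unobservable and the records carry
  their stride.
* Linear time interpolation between snapshots is used wherever a field is
  needed off the save grid; comparisons against closed forms at $10^{-3}$
  accuracy use stride 1.
* Degenerate inputs: $\kappa = 0$ and $\sigma = 0$ are test modes (flagged
  explicitly); $N = 1$ has zero drift; constant observables pair to zero by
  mass cancellation at machine precision.

## Known limitations

* $O(N^2)$ pairwise forces (vectorized, row-chunked); fine for
  $N \lesssim 10^4$, no tree/multipole acceleration.
* First-order weak accuracy in the SDE time step; sufficient for the
  statistics tested, not for pathwise strong-error studies.
* The spectral solver is not positivity-preserving; strongly attractive
  configurations near blow-up are flagged, not continued adaptively.
* The admissibility windows for $(\alpha, \beta, \theta)$ involve unknown
  constants; the decay diagnostics are qualitative (monotonicity), not
  estimates of those constants.
* The real-space factorization oracle is implemented for $d = 3$ (the
  angular integral is closed-form there); other dimensions rely on the
  symbol identity.
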