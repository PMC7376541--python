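# Methods

## Model and assumptions

Each cell carries three state variables: Delta ligand `D`, inactive Notch
receptor `N`, and activated (cleaved) Notch `A`, all in dimensionless
concentration units.  Signalling is strictly juxtacrine: a cell's Delta acts
only on the Notch of its graph neighbours, and the activation input to a
cell is the product of its own receptor level with the summed Delta of its
neighbours, saturating with constant `b` (a Hill-type term of order one).
Activated Notch feeds back by repressing Delta production in the same cell
through the factor `1/(1 + θ^α A)`.  All three species degrade at one common
rate `d`.  Binding *increases* the receptor equation through
`+f^α Σ_j D_j N_i`; this sign follows the model as stated and makes receptor
accumulation, not depletion, the read-out of received Delta signal.

The fractional order `α ∈ (0, 1]` is applied uniformly to all equations,
and every kinetic constant enters as `k^α`, which keeps the units of the
Caputo derivative (concentration · time^−α) consistent and makes the
integer-order classical model the exact `α = 1` special case.  Memory is
global: the state at time `t` depends on the whole history through the
convolution kernel of the Caputo derivative.

Boundedness: summing the two-cell equations cancels the binding terms and
bounds production by `2λ^α + 2λ_N^α + 2a^α`, giving the invariant ceiling
`max(w(0), (2λ^α + 2λ_N^α + 2a^α)/d^α)` on the total mass `w` that the test
suite checks on simulated trajectories.

## Numerical scheme

The integrator is the Grünwald-Letnikov product scheme with history weights
`c_j^{(q)} = (−1)^j C(q, j)`, generated by the recurrence
`c_0 = 1, c_j = (1 − (1+q)/j) c_{j−1}`.  One subtlety matters: applied to
the raw state, the GL sum approximates the Riemann-Liouville derivative,
which differs from the Caputo derivative by an initial-condition term
`x(0) t^{−q}/Γ(1−q)`.  The solver therefore steps the *deviation*
`z(t) = x(t) − x(0)`:

    z(t_k) = f(x(t_{k−1})) h^q − Σ_{j=1}^{k} c_j^{(q)} z(t_{k−j}),

which is the discrete Caputo problem with the correct initial data.  On the
scalar test `D^q x = −x, x(0) = 1, q = 0.9` this reproduces
`E_q(−t^q)` with sup-error `1.7e−4` at `h = 1e−3` (first-order in `h`),
whereas the raw-state variant starts at `x_1 ≈ q·x0` and is wrong by O(1).
At `q = 1` the weights collapse to `(1, −1, 0, …)` and the code switches to
a literal forward-Euler loop so the reduction holds to the last bit, not
just to truncation error.

Choices and defaults:

* Step size: `h = 0.1` for two-cell runs, `h = 0.5` for the 60-cell
  lattice, horizon `t_end = 4000`, initial state 0.5 in every component.
  The scheme is O(h) and the trajectories are smooth and strongly damped,
  so these steps resolve the dynamics; both are user-overridable and an
  h-halving check is part of the test suite.
* Memory: full by default (`memory_window = 0`).  A finite window
  implements the short-memory principle; endpoint error decreases
  monotonically as the window grows (measured: window 50 → 3.7, 1000 →
  0.05 on the two-cell default scenario), so truncation is an explicit
  accuracy/speed trade the user opts into.
* The memory sum is evaluated as one BLAS dot per step against the stored
  history, so a 60-cell, 8000-step run takes a few seconds on one core.
  Recorded output may be thinned (`record_stride`) but the internal history
  is always kept at full resolution because the convolution needs it.
* Divergence guard: any non-finite component or magnitude above `1e12`
  aborts with the offending time, cell and species named.  No clipping is
  ever applied; small negative excursions, if they occurred, would be
  visible (the packaged scenarios stay above `−1e−12`).

`mittag_leffler` sums the defining series in arbitrary precision (mpmath)
with working digits scaled to `|z|^{1/α}`, because the terms grow to
`~exp(|z|^{1/α})` before cancelling and float64 summation loses all digits
already for moderate arguments.  The `α·k` gamma arguments are formed in
working precision for the same reason.  Tests cross-check it against the
relaxation spectral representation (a completely monotone integral oracle)
and against `e^z` at `α = 1`.

## Equilibria

The no-Delta equilibrium is closed-form.  For the Delta-expressing
equilibrium the package eliminates `D` and `A` through the receptor and
activation fixed-point equations,

    D(N) = (d^α N − λ_N^α)/(f^α N),
    A(N) = (a^α/d^α) · D N / (b^α + D N),

and solves the remaining scalar equation for `N` above the no-Delta baseline
`λ_N^α/d^α` by bracketed bisection.  A classical cubic reduction
(coefficients `B1..B4`, Cardano formula with a trigonometric fallback for
the three-real-root case) is also implemented and exposed; however, direct
substitution shows the textbook closed forms for this model are not mutually
consistent with the fixed-point equations (their `D` and `A` expressions
use `d^α` where the receptor equation has `f^α`, and the cubic carries a
sign error in its `λ_N^α f^α N` term), so cubic roots are treated as
*starting points only*.  Every reported equilibrium is polished by damped
Newton iteration (analytic Jacobian, step halving, at most 50 iterations)
and certified by its residual: the max-norm of the right-hand side must be
below `1e−9`, and in practice lands near `1e−17`.  At the default constants
the certified fixed point is `(D, N, A) ≈ (0.39224, 9.48109, 0.03062)` per
cell.  Admissibility means componentwise positivity; if several admissible
points survive refinement all are reported and the smallest-residual one is
returned, and if none survives the error lists the real cubic roots.

## Stability

The per-cell 3×3 Jacobian block (valid on the symmetric subspace of the
two-cell system) yields the monic characteristic cubic in `ξ = s^α`.  The
package evaluates: the Routh-Hurwitz conditions (`a₂, a₁, a₀ > 0`,
`a₂a₁ − a₃a₀ > 0`), the closed-form sufficient ratio
`(d^{3α} + f^{2α}d^α)/(4f^{2α}λ_N^α + 2f^αd^{2α})` whose value below 1
certifies them, and the fractional sector condition `|arg ξ| > απ/2`
applied to the cubic's roots — the verdict always comes from the sector
condition, with margins below `1e−10` reported as inconclusive rather than
forced to a side.  Because Routh-Hurwitz stability places all roots in the
open left half-plane, it implies the sector condition for every
`α ∈ (0, 1]`; the tests verify this implication, the agreement between
polynomial roots and numeric Jacobian eigenvalues, and that the reduced
spectrum is a subset of the spectrum of the full 6×6 system.  The no-Delta
equilibrium has eigenvalues `(−d^α, −d^α, −λ_N^αf^α/d^α − d^α)`, negative
real for every valid parameter set, hence unconditionally stable.

## Sensitivity screening

Morris elementary effects use forward differences
`d_i = (f(x + Δe_i) − f(x))/Δ` and the mean absolute effect
`S_i = (1/R) Σ_j |d_i(j)|`.  The design is deliberately simple: `R = 10`
independent base points drawn uniformly within ±10% of the nominal
constants (seed 20200723), perturbations Δ of 1% of each nominal (α capped
at 1), and response output `N₁(t_end)` of the two-cell Delta-expressing
scenario.  Effects are dimensional, so the sensitivities span about twelve
orders of magnitude and only the *ranking* is meaningful; on the packaged
design it is `d ≫ f, a, λ_N, α ≫ b ≫ λ ≫ θ`.  The embedded simulations run
at `h = 0.5`: a screening needs `(n+1)·R = 90` runs and compares responses
across parameter draws, for which the O(h) scheme bias is irrelevant.  The
base response is computed once per draw and shared across the eight
effects.  One caveat the sweep utilities make explicit: "insensitive" is
relative — sweeping `λ` over ±40% still moves the terminal receptor level
by ~15%, but the per-unit-perturbation response to `d` is several hundred
times larger.

## Lattice phenotypes

The tissue scenario is a 5×12 grid (von Neumann 4-neighbourhood,
non-periodic by default, with an optional horizontally periodic "tube"
mode), Delta production `λ = 1000` in rows 1–3 and `0` in rows 4–5, and the
terminal receptor matrix `N` at `t_end = 4000` as the intensity read-out.
Row means are normalised to the largest row mean and banded at 1/3 and 2/3
into light/medium/deep (thresholds configurable).  Named patterns: one deep
row at the grid centre = wild-type; rows 1–3 deep, 4–5 not = mutant; all
deep = complete mutant; anything else = other.  When several maps are
compared (the order-comparison experiment) they are classified under one
shared intensity scale, as paired heatmaps are drawn — a globally dimmer
map then correctly reads lighter.  Classification is scale-invariant and
the deep-row count is monotone as `d` decreases through
`{0.018, 0.012, 0.001}` (1 → 3 → 5 deep rows).

Known limitations of this read-out, measured at the defaults:

* The model concentrates receptor in the *second* row — the centre of the
  three-row Delta-producing domain — not in the third (grid-centre) row.
  At `d = 0.018` the normalised row profile is `(0.66, 1.00, 0.63, 0.44,
  0.36)`, i.e. bands `(medium, deep, medium, medium, medium)`, so the
  strict wild-type pattern (deep only at the grid centre, others light) is
  not produced; the classifier returns "other".  This is robust: it
  persists across vertical-only and Moore neighbourhoods, horizontal
  periodicity, either sign of the receptor binding term, and all three
  read-out species.  The biologically meaningful statement the model does
  support is "a single deep band inside the Delta domain, light ventral
  rows".
* At `d = 0.012` rows 4–5 sit at intensities 0.52/0.43 — medium, not
  light — so the mutant pattern matches in its deep rows but not in its
  light rows at the default thresholds.
* The read-out is classified at `t_end = 4000` although fractional
  trajectories approach equilibrium with slow `t^{−α}` tails; at
  `t = 2000` the `d = 0.018` profile still reads `(deep, deep, deep,
  medium, medium)` and sharpens toward the single-band profile by
  `t = 4000` and beyond.  The `d = 0.012` and `d = 0.001` classifications
  are identical at 2000 and 4000.
* In the order comparison at `d = 0.004`, rows 4–5 classify light at
  `α = 0.7` versus medium at `α = 1` *under the shared scale*; per-grid
  normalisation would invert that reading, which is why the shared scale
  is the default for comparisons only.

## Synthetic data

The package generates all of its own inputs; there is no external data.
The scenarios emulate the tissue geometry only as a regular contact graph
with row-wise production rates — no cell division, movement, anatomical
curvature, stochastic gene expression, or measurement noise.  Passing tests
therefore demonstrate properties of the stated dynamical model and its
numerics, not agreement with images of real intestines.

## Reproducibility

The solver is deterministic; the only random stream is the Morris sampler,
seeded from its design (CLI `--seed` overrides).  Every CLI run writes a
manifest with the resolved configuration, its SHA-256 hash and the package
version, and trajectory CSVs round-trip bit-exactly.
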