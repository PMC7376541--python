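# notchfde

A simulation and analysis toolkit for a fractional-order model of
Delta-Notch lateral inhibition, built around the boundary-formation system of
the *Drosophila* large intestine.  The hindgut's large intestine is split
into dorsal and ventral domains separated by a one-cell-wide strand of
boundary cells, and that strand is patterned by juxtacrine Delta-Notch
signalling: Delta ligand on one cell binds Notch receptor on its neighbours,
cleaved (activated) Notch accumulates in the receiving cell, and activated
Notch represses Delta production in its own cell.  Because Notch signalling
shows strong memory/heredity effects, the dynamics are posed with Caputo
fractional derivatives of order `0 < α ≤ 1`; the classical ODE model is the
special case `α = 1`.

The package is aimed at systems-biology modellers who want a small,
well-tested reference implementation of: a Grünwald-Letnikov (GL) fractional
integrator, equilibrium and local-stability analysis of the two-cell system,
Morris elementary-effects sensitivity screening, and multi-cell lattice
"phenotype" experiments with heatmap read-outs.

## Model

For cell `i` with neighbours `NG(i)`, writing `D_i, N_i, A_i` for Delta,
inactive Notch and activated Notch, every kinetic constant `k` enters as
`k^α`:

    D^α D_i = λ_i^α / (1 + θ^α A_i) − Σ_{j∈NG(i)} f^α D_i N_j − d^α D_i
    D^α N_i = λ_N^α + Σ_{j∈NG(i)} f^α D_j N_i − d^α N_i
    D^α A_i = a^α S_i / (b^α + S_i) − d^α A_i,   S_i = (Σ_{j∈NG(i)} D_j) N_i

with production rates `λ` (Delta; may differ per cell) and `λ_N` (Notch),
binding rate `f`, common degradation rate `d`, activation rate `a`,
saturation constant `b`, and inhibition coefficient `θ`.  The packaged
default constants are `λ ∈ {0, 1000}`, `f = d = 0.01`, `λ_N = 0.07`,
`a = 0.01`, `b = 200`, `θ = 10⁶`, `α = 0.9`.

The two-cell system has two fixed points: the no-Delta equilibrium
`E0 = (0, λ_N^α/d^α, 0)` per cell, and a Delta-expressing equilibrium `E1`
found from a scalar reduction in the Notch level and polished by damped
Newton iteration until the fixed-point residual is below `1e−9`.  Local
stability uses the characteristic cubic `ξ³ + a₂ξ² + a₁ξ + a₀` in
`ξ = s^α`, the Routh-Hurwitz conditions, and the fractional sector
criterion `|arg ξ| > απ/2`.

## Worked example

```sh
$ notchfde equilibria --preset table1-lambda1000 --out out/
E0: per-cell (D, N, A) = [0.       5.762199 0.      ] (residual 0)
E1: per-cell (D, N, A) = [0.392243 9.481093 0.030618] (residual 1.21e-17)

$ notchfde stability --preset table1-lambda1000 --out out/
E0: verdict=stable sufficient_ratio=0.07984
E1: verdict=stable sufficient_ratio=0.07984
```

With no Delta production the cells settle to Notch level
`λ_N^α/d^α = 7^0.9 ≈ 5.762` with zero Delta and zero activated Notch.  With
`λ = 1000` both cells converge to the symmetric fixed point
`(D, N, A) ≈ (0.392, 9.481, 0.031)`; the residual is the max-norm of the
right-hand side there, so the value is a certified equilibrium rather than a
finite-time simulation endpoint.  Both equilibria are locally asymptotically
stable: all eigenvalues lie outside the `απ/2` sector, and the closed-form
sufficient ratio `(d^{3α} + f^{2α}d^α)/(4f^{2α}λ_N^α + 2f^αd^{2α}) ≈ 0.080`
is below 1.

The same interface drives trajectory simulation, Morris screening,
parameter sweeps and the 5×12-cell lattice experiments:

```sh
$ notchfde morris --out out/
ranking (most sensitive first): d, f, a, lambda_notch, alpha, b, lambda_delta, theta

$ notchfde phenotype --preset lattice-complete --out out/
phenotype: complete-mutant (rows: deep, deep, deep, deep, deep)

$ notchfde compare-orders --preset lattice-order-compare --alphas 0.7,1.0 --out out/
```

The degradation rate `d` dominates the sensitivity ranking while `λ` and `θ`
are orders of magnitude weaker — which is why the lattice phenotypes are
driven by `d` (presets `lattice-wildtype`, `lattice-mutant`,
`lattice-complete` use `d = 0.018, 0.012, 0.001`).  See `docs/methods.md`
for the numerical scheme, design choices and known limitations of the
phenotype read-out.

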