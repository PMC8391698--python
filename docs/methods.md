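# Methods

This note records the mathematical conventions, model definitions,
default parameters and numerical choices behind `bayesmech`, in the
package's own terms.

## 1. Stationary stochastic systems (`nessflow`)

A system is the triple `(I, Q, Γ)`: a surprisal function
`I(x) = -ln p(x)` whose normalised exponential is the steady-state
density, an antisymmetric solenoidal matrix `Q`, and a diagonal
positive-definite dissipation matrix `Γ`.  The drift is

```
f(x) = (Q - Γ) ∇I(x)
```

and the noise convention is `cov(dw) = 2Γ dt`.  Under this convention
the Fokker–Planck stationarity of `p` holds for *any* constant
antisymmetric `Q`: the dissipative part `-Γ∇I` balances the diffusion
`Γ∇·∇`, and the solenoidal part `Q∇I` is divergence-free with respect to
`p` (it transports probability along level sets of `I`).  For Gaussian
systems `I(x) = ½ (x-m)ᵀ H (x-m) + const` with `H` the precision
(symmetric positive definite), the drift is linear with Jacobian
`J = (Q - Γ) H`, the stationary covariance is `Σ = H⁻¹`, and
stationarity is exactly the Lyapunov identity `JΣ + ΣJᵀ + 2Γ = 0` —
an algebraic identity the test suite checks to 1e-10 on random systems.

In three dimensions the solenoidal flow is a curl: `Q∇I = ∇×A` with
vector potential `A(x) = (-Q₃₂, Q₃₁, -Q₂₁) · I(x)`, which
`vector_potential` evaluates and the tests verify against a
finite-difference curl.

**Integrator.** Euler–Maruyama: `x ← x + f(x) dt + √(2 diag(Γ) dt) ξ`,
`ξ ~ N(0, I)`, seeded through `numpy.random.default_rng`.  First order:
against a tight `solve_ivp` reference on the (noise-free) Lorenz system
the error halves when `dt` halves.  A divergence guard truncates runs
whose state magnitude exceeds `1e6` and warns, rather than propagating
NaNs.  Stationary statistics use a 20% burn-in by default; standard
errors for stationary moments use the effective sample size
`n_eff = N·dt / (2τ)` with `τ` the slowest relaxation time
`1 / min |Re eig(J)|`.

## 2. Partitions and blanket structure (`blanket`)

A `StatePartition` names four disjoint covering index sets: external η,
sensory s, active a, internal μ; derived sets are the blanket
`b = s ∪ a`, autonomous `α = a ∪ μ` and particular `π = b ∪ μ` states.
Internal and external sets must be nonempty; the package allows empty s
or a (with the corresponding checks degenerating gracefully).

Three nested structural conditions are checked on Gaussian systems:

1. **Flow constraint**: `J[μ,η] = 0` and `J[a,η] = 0` — autonomous
   dynamics blind to external states.
2. **Blanket condition**: `H[μ,η] = 0` — conditional independence of
   internal and external states given the blanket (exact for Gaussians:
   zero precision block ⇔ zero partial correlation).
3. **Sparse functional form**: `H` has zero blocks {η–a, η–μ, s–μ} and
   `Q` has zero blocks {η–a, η–μ, s–a, s–μ}.  This implies both
   conditions above, plus the Jacobian zeros {η–μ, s–μ, a–η, μ–η}
   through displayed identities (e.g. `J[μ,η] = Q[μ,a]H[a,η] -
   Γ[μ,μ]H[μ,η] + Q[μ,μ]H[μ,η] = 0` block by block).  A strictly
   stronger variant — block-diagonal `Q` over (η, b, μ) — is reported
   separately and is *not* required by the rest of the package.

Conditions 1 and 2 are logically independent.  The packaged
counterexamples witness both directions: a tuned solenoidal entry can
cancel a genuine `H[μ,η]` coupling out of the Jacobian (flow constraint
without blanket), and a solenoidal η–μ coupling can drag external
gradients into the internal flow despite `H[μ,η] = 0` (blanket without
flow constraint).

Under the sparse form, `autonomous_flow` evaluates the α-rows of the
drift from particular states alone — `f_α(π) = (Q-Γ)[α,α] H[α,π]
(x_π - m_π)` — and the tests confirm it matches the full drift exactly
while being invariant to arbitrary external perturbations.

`find_admissible_partitions` searches all labelings of up to 12
coordinates for sparse-form-compatible partitions, pruning by pairwise
coupling constraints; it is exact but exponential, hence the dimension
cap (a deliberate package choice, not a theoretical limit).

## 3. Free energy (`inference`)

For a Gaussian system, a partition, a particular state `π` and a
Gaussian variational density `q(η) = N(m_q, S_q)` (possibly a function
of the blanket through a `params_of` callback), `free_energy` returns
all terms of

```
F = E_q[I(η,π)] - H[q]                    (energy - entropy)
  = I(π) + KL[q ‖ p(η|b)]                 (surprisal + bound)
  = E_q[I(π|η)] + KL[q ‖ p(η)]            (inaccuracy + complexity)
```

in closed form (Gaussian expectations of quadratics; Schur-complement
conditionals).  The energy–entropy and inaccuracy–complexity readings
are unconditional; the surprisal-plus-bound reading additionally uses
`p(η|π) = p(η|b)`, i.e. the blanket condition, so the identity tests
construct blanket-compliant systems.  A 1-D quadrature oracle
(`scipy.integrate.quad` on the defining integrals) agrees with the
closed forms to 1e-6.

The inferential coordinate on the internal manifold is the conditional
expectation `E[μ|b]` (not raw μ).  Three regimes of the evidence bound
`c = KL[q ‖ p(η|b)]` are distinguished and tested:

- exact posterior `q`: `c ≡ 0` and `∇F = ∇I` exactly;
- variance-inflated, posterior-mean `q` on a homoscedastic system:
  `c > 0` but constant over the blanket, so `∇F = ∇I` still holds —
  free-energy gradients do not require exact inference;
- blanket-dependent `c` (possible only when the posterior depends on
  active states, i.e. `H[η,a] ≠ 0`, so such witnesses satisfy the
  blanket condition but not the full sparse form): the gradient gap
  `∇F - ∇I` equals `∇c`, verified against finite differences.

`desired_steady_state_flow` engineers `f_α = (Q_αα - Γ_αα) ∇_α F` for a
*target* steady state; integrating it (for partitions with an empty
sensory set) drives empirical moments to the target within Monte-Carlo
error, which the tests check at three standard errors.

## 4. The soup (`soup`)

**Generator.** `n = 9` macromolecules on a rod: rest sites on a line
with spacing `coupling_length`, centred at the origin.  Molecule `i`
carries chemistry `c_i ∈ R³` and planar position/velocity `p_i, v_i`.
Dynamics (Euler–Maruyama, step `dt`):

- chemistry: Lorenz drift (σ = 10, ρ = 28, β = 8/3, the classical
  chaotic regime) plus diffusive coupling
  `Σ_j K_ij (c_j - c_i)` with Gaussian kernel
  `K_ij = g·exp(-d_ij²/2ℓ²)`, plus noise of sd `chem_noise`;
- motion: damping `-λv`, harmonic tether `-κ(p_i - p_i^rest)`, and a
  force `force_gain · Σ_j K_ij (w·(c_i - c_j)) û_ij` along the
  inter-molecule axis, where `w` projects the chemistry difference
  (default: third Lorenz coordinate), plus noise of sd `motion_noise`.

Defaults: `g = 2.0`, `ℓ = 1.5`, `force_gain = 0.02`, `λ = 0.5`,
`κ = 0.2`, `chem_noise = 0.5`, `motion_noise = 0.1`, `dt = 0.005`,
`t_total = 576` with the last 512 time units analysed; `mini()` shrinks
the horizon to 64/48 for tests.  These are package choices tuned for
three properties: the ensemble stays cohesive (tether), the coupling
kernel stays active (spacing ≈ ℓ), and the coupling is strong enough to
synchronise chemistry across neighbours yet weak enough that each
molecule remains recognisably Lorenz.  Units are the dimensionless
Lorenz time and an arbitrary length unit; no physical realism is
claimed — the generator is a minimal testbed for the analysis pipeline,
not a model of chemistry.

Per-molecule noise streams are spawned from one `SeedSequence`, with a
fixed draw order (initial condition, chemistry block, motion block), so
the decoupled limit of the coupled simulator reproduces isolated
single-molecule runs bit for bit — the basis of the decoupling tests.

**Partition.** Time-averaged positions over the analysis window define
distances; molecules are adjacent below `1.5 × coupling_length`.  The
most central molecule (plus connected neighbours, if more are requested)
is internal; its graph boundary is active; the boundary's boundary is
sensory; the rest are external.  This is a geometric *detection* rule —
the simulation nowhere contains labelled roles.

**Canonical correlations.** In-package CCA by SVD of the whitened
cross-covariance (eigendecomposition whitening with a relative ridge on
near-singular within-set covariances, warning on rank deficiency), sign
convention: first nonzero loading entry positive.  Cross-checked against
`sklearn.cross_decomposition.CCA` in the tests.  Significance is
assessed against a permutation null (row-shuffling one side, default
1000 shuffles), which destroys temporal alignment while preserving
marginals.  Shuffling ignores autocorrelation, so the null is
anti-conservative for slowly varying signals; the observed effects
exceed the 95th percentile by an order of magnitude, which is why this
simple null is accepted.

**Synchronisation manifold.** Polynomial least squares (default order
5) from the first internal to the first external canonical variate, on
a standardised abscissa for conditioning; `t`-based pointwise prediction
intervals (default 90%), ridge fallback with a warning on
ill-conditioned designs.  Order 5 is a package choice: enough curvature
for a folded Lorenz-driven map, few enough coefficients for the short
horizons used in tests.

**Event-related averages.** Events are the greedy largest local maxima
of the internal canonical variate with an exclusion radius equal to the
epoch length (default 6 events, 1 s before to 3 s after); channels are
internal chemistry plus the external variate.  Averaging K independent
noisy epochs attenuates noise by `1/√K`, which the tests verify at
three standard errors.

## 5. IO, fixtures, provenance (`io`, `cli`)

System specs are YAML/JSON mappings (`dim`, `H`, `Q`, `Gamma` as
diagonal list or full matrix, optional `mean`), validated on load with
errors naming the violated invariant.  Trajectories and soup states use
HDF5 (CSV fallback for trajectories).  All fixtures are generated
programmatically by `make_fixture` — nothing binary is shipped — and
each is a few hundred bytes of text.  Every CLI command writes a
manifest (package version, seed, order-insensitive config hash, output
list) so any artefact can be regenerated.

## 6. Known limitations

- Closed-form inference is Gaussian-only; non-Gaussian surprisals get
  flows and integration but not free-energy decompositions.
- The partition search is exhaustive and capped at 12 coordinates.
- The Euler–Maruyama scheme is first order; statistical tolerances in
  the tests are set with that bias in mind (small `dt`, 3-SE bands).
- The soup's empirical blanket is approximate: a Gaussian partial-
  correlation reading of a chaotic system shows internal–external
  couplings suppressed relative to direct couplings, not exactly zero.
- The permutation null for CCA ignores autocorrelation (see above).
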