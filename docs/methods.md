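# Methods

## Model

The system is a two-dimensional periodic lattice gas: `K > 2` lanes, each a
ring of `L` sites, stacked into a torus (lane `i + K` ≡ lane `i`), carrying
`N` hard-core particles.  A particle at site `(i, j)` attempts three moves,
each blocked unless the target is empty:

* forward, `(i, j) → (i, j+1 mod L)`, at rate `p_i`;
* up, `(i, j) → (i−1, j)`, at the upward switching rate `ω_i^u`;
* down, `(i, j) → (i+1, j)`, at the downward switching rate `ω_i^d`.

"Asymmetric heterogeneous" means all `3K` rates are free parameters —
`ω_i^u ≠ ω_i^d` in general and every lane may differ.  Two special cases
recover earlier models: symmetric switching `ω_i^u = ω_i^d = χ_i` (the
partly heterogeneous case) and all rates equal (homogeneous).  All rates
must be strictly positive: a zero switching rate disconnects the lane ring
and the stationary-weight construction below divides by every rate.
Global density is always reported as the fill fraction
`ρ̄ = N/(K·L) ∈ [0, 1]`; formulas written in terms of the per-lane-length
particle count `N/L` use `N/L = K·ρ̄`.

## Stationary theory

The analytic layer assumes a lane-factorized stationary measure
`P{τ} ∝ Π_i f_i^{M_i}` (`M_i` = particles in lane `i`) with density weights
fixed by the ring balance

    f_{i+1} ω_{i+1}^u + f_{i−1} ω_{i−1}^d − f_i (ω_i^u + ω_i^d) = 0 .

The balance operator `W` (tridiagonal with periodic corners) has rank
`K − 1` for positive rates, so the weights are unique up to scale; the
normalization constant is set to 1.  The explicit solution is

    f_i = (1/(2K ω_i^d)) (1 + Σ_{j=1}^{K−1} Π_{m=1}^{j} ω_{i+m}^u / ω_{i+m}^d)
        + (1/(2K ω_i^u)) (1 + Σ_{j=1}^{K−1} Π_{m=1}^{j} ω_{i+K−m}^d / ω_{i+K−m}^u) ,

indices mod `K`; for symmetric switching it collapses to `f_i = 1/χ_i`.
The global scale is physically irrelevant: rescaling `f → c·f` rescales the
fugacity to `z/c` and leaves every observable unchanged (tested).

In the large-`L` limit a single fugacity `z` fixes the filling through
`Σ_i z f_i/(1 + z f_i) = K ρ̄`, and then

    ρ_i = z f_i / (1 + z f_i),      J_i = p_i ρ_i (1 − ρ_i),
    ⟨n_i⟩ = L ρ_i,                  D⟨n_i⟩ = L ρ_i (1 − ρ_i).

The left side of the fugacity equation is strictly increasing in `z` from 0
to `K`, so the root is unique; it is bracketed by doubling/halving from
`z = 1`, solved by Brent's method at relative tolerance 1e-12, and polished
with a few Newton steps so that the lane-density sum matches `K ρ̄` to
better than 1e-10 even for badly scaled weights.  The empty and full
lattice are exact limits (`ρ_i = 0` at `z = 0`, `ρ_i = 1` as `z → ∞`) and
bypass the solver.

Each lane seen from the rest of the torus is equivalent to a TASEP coupled
to a particle reservoir with Langmuir attachment rate `ω_A = z` and
detachment rate `ω_D = 1/f_i`; the Langmuir equilibrium density
`(ω_A/ω_D)/(1 + ω_A/ω_D)` is exactly the lane density.

### Validity of the factorized ansatz

The package treats the factorized measure as what it is: exact in special
cases, an approximation in general.  The exact enumeration oracle
establishes on desk-size lattices that

* for **symmetric** switching (`ω_i^u = ω_i^d`) the factorized measure is
  the true stationary law to machine precision (total-variation distance
  ~1e-16), as in the earlier multi-lane literature;
* for a **single particle** the lane marginal is exactly `∝ f_i` (the ring
  balance is the exact stationarity condition of the lane random walk);
* for **asymmetric** switching with many particles the factorized measure
  is *not* stationary: on 3-lane tori the total-variation distance is of
  order 0.1–0.2 and does not shrink as `L` grows, and kinetic Monte Carlo
  on the packaged 10-lane reference rates shows lane-density biases of
  order 0.1 that are identical at `L = 50` and `L = 200`.  The grouped
  balance combination that motivates the ring-balance equation vanishes
  identically under the factorized measure, but only on its special
  configuration class — it does not imply stationarity configuration by
  configuration.

Consequently, passing analytic tests certify internal consistency of the
closed-form theory (conservation, monotonicity, unimodal currents with
peak `0.25 p_i`, scale invariance), not agreement with the true stationary
law at strongly asymmetric rates.  Where the dynamics itself is the
question, use the oracle (exact, tiny lattices) or the simulator (any
size, statistical).  The within-lane relation `J_i = p_i ρ_i (1 − ρ_i)`
does hold in simulation with the *measured* `ρ_i` to high accuracy; the
approximation error is confined to predicting the lane densities from the
rates.

### Optimal total current

Maximizing `J_total = Σ p_i x_i (1 − x_i)` over lane densities
`x_i ∈ [0, 1]` at fixed `Σ x_i = K ρ̄` gives, by Lagrange stationarity,
`x_i* = ½ (1 − λ/p_i)`; imposing the filling constraint fixes the
multiplier `λ = K (1 − 2ρ̄) / Σ_i (1/p_i)` and

    J_max = Σ_i ¼ p_i (1 − (λ/p_i)²) .

This is verified in the tests against an independent SLSQP
constrained-optimization oracle.  At `ρ̄ = ½`, `λ = 0`, every lane sits at
density ½, and `J_max = ¼ Σ p_i` — which the homogeneous system already
attains, so the optimum envelope touches the homogeneous total-current
curve exactly at half filling.  When some `x_i*` leaves `[0, 1]` (very
empty or very full tori with widely spread forward rates) the interior
assumption fails; the result is flagged (`interior=False`, with a
`RuntimeWarning`) rather than rejected, since the expression still bounds
the interior-feasible current from above.

## Exact fixed-N ensembles

At finite `(L, N)` the factorized measure's observables are ratios of
constrained sums; the partition function is the coefficient of `x^N` in
`Π_i (1 + f_i x)^L`.  These coefficients are computed exactly by iterated
polynomial convolution; lane-resolved quantities replace one lane's
polynomial with the marked versions (occupied site: `f_i x (1 + f_i x)^{L−1}`;
occupied site with empty successor: `f_i x (1 + f_i x)^{L−2}`).
Coefficient vectors are renormalized to unit maximum with a running
log-magnitude, so partition functions that overflow float64 are handled
transparently and only ratios are ever exponentiated.  Prefix/suffix
products over lanes give all `K` lane observables in `O(K)` convolutions.
The default size cap (`L ≤ 200`, `K ≤ 50`) keeps a full solve to seconds;
both bounds are explicit keyword arguments.  The saddle-point prefactor of
the large-`L` analysis cancels in every observable ratio and is never
computed.  The convergence report evaluates the max-over-lanes discrepancy
between these exact values and the fugacity-limit formulas over a list of
`L` (the particle number is rounded to `round(K·L·ρ̄)` and the rounded
filling recorded); the gap shrinks as `O(1/L)`.  Note the comparison is
between the *fixed-N* and *grand-canonical* versions of the same
factorized measure — it says nothing about the ansatz's validity for the
dynamics (see above).

## Master-equation oracle

For lattices with `C(K·L, N) ≤ 2·10^5` configurations the generator of the
full Markov chain is built explicitly (sparse, one off-diagonal entry per
allowed move) and the stationary law solved from `π Q = 0` with a
normalization row — densely below 3000 states, by sparse LU above.  The
solve is rejected if the residual `‖π Q‖_∞` exceeds `1e-12 · n · max|Q|`.
Reported diagnostics: site-resolved densities, per-lane currents (site
independence is itself a test), the total-variation distance to the
factorized measure, the per-boundary mismatch `f_i ω_i^u − f_{i−1} ω_{i−1}^d`
(zero only when per-transition reversibility holds), and the grouped
balance combination evaluated under both measures.

## Simulation

Two schemes realize the same continuous-time dynamics:

* `kmc` (default): exact continuous-time sampling by thinning.  Candidate
  events form a Poisson stream at rate `3KL·r_max` (`r_max` = largest
  rate); each event picks one of the `3KL` (site, move) pairs uniformly
  and accepts with probability `rate/r_max`.  Every enabled move therefore
  fires at exactly its nominal rate with exponential waiting times.
  Because the candidate stream is Poisson and state-independent, sampling
  the configuration at candidate epochs is unbiased for time averages.
* `random_sequential`: the discrete-time counterpart — same proposal and
  acceptance, fixed time increment; `K·L` micro-steps form one sweep, and
  one sweep corresponds to physical time `1/(3 r_max)`.

The two must (and do) agree within statistical error; the cross-check
guards against update-rule ambiguities.  The initial condition is a
uniformly random `N`-subset of sites under the run seed; the chain is
irreducible for `0 < N < KL`, so initialization affects only burn-in
(first 10% of the run by default, discarded).  Runs are bitwise
reproducible given the seed.  Particle number is verified at every
snapshot (toggleable).

Standard errors use batch means over 20 batches (configurable) to absorb
autocorrelation.  Currents are estimated both from accepted forward-hop
counts per unit time and from the snapshot pair estimator
`p_i ⟨τ_{i,j}(1 − τ_{i,j+1})⟩`; the comparison report states z-scores of
lane densities against the fugacity-limit values and of currents against
the finite-size-adjusted `p_i ρ_i (1 − ρ_i) · KL/(KL−1)` (the exact
uniform-measure correction in the homogeneous case), plus a profile
flatness statistic (max site deviation from the lane mean in binomial
noise units).

Test and validation problem sizes are chosen to make each check sharp at
desk scale: exact-law comparisons use tori with ≲10^3 enumerable states;
scheme cross-checks use `K=4, L=50` at 3·10^4 sweeps; the heterogeneous
reference comparison uses `K=10, L=200` at 10^5 sweeps, where the
Monte-Carlo standard error (~10^-3) is far below the ansatz bias it
measures (~10^-1).

## Random model generator

`build_random` draws all `3K` rates i.i.d. uniform on `(lo, hi)` (default
`(0, 1)`, matching the random-rate experiments), clipped upward at 1e-6 to
preserve positivity, from a seeded generator.  It emulates the *study
conditions* — arbitrary heterogeneous rate tables — not any empirical
transport system: real molecular-motor or traffic lanes have correlated,
time-varying and possibly density-dependent rates, open boundaries, and
finite reservoirs, none of which are modelled.  Conclusions from passing
tests are about the mathematics of this lattice gas, not about fitted
biological parameters.

## Design choices

* Lane and site indices are 0-based in code, 1-based in all printed tables
  and CSV output.
* Packaged rate tables are stored to the 3-decimal precision of their
  source captions; where a table's forward rates are unstated they default
  to `p_i = 1`.
* The total-current increment ΔJ is defined against a caller-supplied
  baseline rate set; the perturbation sweep uses the all-lanes
  `(ω^u, ω^d) = (0.15, 0.35)` system as baseline, so ΔJ vanishes exactly
  when the perturbed rate returns to 0.15.
* The "partly heterogeneous" class in the class comparison is built as
  symmetric per-lane rates `χ_i` drawn i.i.d. uniform (distinct across
  lanes) with shared seeded forward rates; other constructions of partial
  heterogeneity exist, and the comparison documents this concrete one.
* |ΔJ| as a function of the perturbed rate is emitted as a curve, not
  asserted monotone: it is exactly zero at the interior baseline point, so
  global monotonicity cannot hold.

## Known limitations

* Closed boundaries only (no injection/extraction ends), no site-dependent
  forward rates within a lane, no parallel/sublattice updates.
* The closed-form lane densities are biased at strongly asymmetric
  switching rates (see "Validity" above); the package quantifies but does
  not correct this bias.
* The optimal-current bound assumes an interior optimum; outside it the
  result is flagged and the bound is not tight.
* Exact modules are capped (2·10^5 states; polynomial degree `K·L ≤ 10^4`)
  — raise the caps only with matching patience.
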