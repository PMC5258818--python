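# Methods

## Scope and model family

`critdom` computes critical domain sizes and extinction probabilities for
populations with distinct dispersal and reproduction stages living on a
bounded one-dimensional habitat `[-L/2, L/2]` surrounded by uninhabitable
terrain. The deterministic baseline is the linear integrodifference
recursion

    N_n(x) = ∫_{-L/2}^{L/2} k(x, y) r N_{n-1}(y) dy,

whose critical length `L*` is the smallest `L` at which the dominant
eigenvalue of the operator reaches 1. Around that baseline the package
provides four stochastic treatments:

1. an **individual-based model (IBM)**: each individual draws an offspring
   count from a finite pmf `{p_i}` (parental survival folded into the
   count), each offspring disperses by a kernel displacement from the
   parent's location, and settlers outside the habitat die;
2. a **population-level approximation**: a scalar recursion
   `N̄_n = Ā r̄ N̄_{n-1}` whose factors are normal draws justified by the
   Central Limit Theorem;
3. a **dispersal-modified Galton–Watson process**: reproduction followed by
   independent loss of each offspring with probability `F`, giving the
   extinction recursion `d_n = f((1-F) d_{n-1} + F)`;
4. a **branching process in iid random environments (BPRE)**: one
   environmental state drawn per generation sets that generation's
   offspring pmf; classification follows the Smith–Wilkinson condition on
   `E[ln ξ]`.

All lengths are measured in units of the mean dispersal distance `b`
(`b = √(D/α)` for the Laplace kernel, which is the default and the only
kernel with closed forms; arbitrary symmetric kernels are supported
through quadrature).

## Dispersal success and its inversion

The settlement probability `s(y) = ∫_{-L/2}^{L/2} k(x, y) dx`, its domain
average `S`, and the modified average `Ŝ = (1/(L S)) ∫ s(y)² dy` (which
reweights locations by the expected settler density `s(y)/S`) are the
bridge between explicit space and the spatially implicit models: the loss
fraction is `F = 1 - Ŝ(L)`. `Ŝ` is strictly increasing in `L` with range
(0, 1), so criticality conditions expressed as a target retention invert
uniquely; the inversion uses bracketed Brent root finding with residual
below 1e-10.

The variance summaries are the integrals

    σ_S² = ∫ (s(y) - S)² dy,     σ_Ŝ² = ∫ (s(y)²/S - Ŝ)² dy,

kept deliberately in this un-normalized form (a `normalized=True` flag
divides both by `L`, the variance under a uniformly drawn location). A
closed-form expression for `σ_Ŝ²` at `b = 1` circulates alongside the
modified-success approximation; it disagrees with the defining integral by
about 0.4% at `L = 2.703` and is therefore only checked loosely in the
test suite — quadrature is authoritative throughout.

## Numerical choices

- **Quadrature**: adaptive Gauss–Kronrod (`scipy.integrate.quad`) with
  absolute/relative tolerance 1e-10; Laplace closed forms short-circuit
  the quadrature and are cross-checked against it in tests to 1e-8.
- **Eigenproblem**: Nyström discretization on Gauss–Legendre nodes. The
  Laplace kernel has a kink along `x = y`, which slows global polynomial
  quadrature, so the node count scales with the domain:
  `min(6000, max(1200, 400 L/b))`. The largest eigenvalue of the
  symmetrized weighted matrix is obtained by a Lanczos solve
  (`scipy.sparse.linalg.eigsh`). Doubling the node count moves the
  critical length by < 1e-4, and the solver agrees with the Laplace
  dispersion relation `tan(√(r-1) L/(2b)) = 1/√(r-1)` to 1e-4 over
  `r ∈ [1.1, 5]`.
- **Root finding**: Brent's method on `[1e-6 b, 100 b]` for `Ŝ` inversion
  (geometric bracket growth if needed), `xtol = 1e-12`; fixed-point
  iteration from `d_0 = 0` for ultimate extinction, which converges
  monotonically to the smallest root, tolerance 1e-12. Subcritical and
  critical cases (`E[r](1-F) ≤ 1`) return exactly 1 without iterating, so
  no floating-point dust accumulates near certain extinction.
- **Boundary**: settlement exactly at ±L/2 counts as inside (closed
  interval); a measure-zero choice.
- **Degenerate inputs**: `L ≤ 0`, `b ≤ 0`, invalid probabilities, loss
  fractions outside [0, 1], and retention targets outside (0, 1) raise
  `ValueError`; an ensemble whose loss-free `E[ln ξ]` is non-positive has
  no finite critical length and the solver says so rather than returning
  a degenerate root.

## The individual-based simulator

`extinction_curve_ibm` advances all Monte-Carlo replicates simultaneously
in flat arrays (positions plus replicate indices) from a single seeded
`numpy` Generator. This is a deliberate deviation from per-replicate seed
streams: it keeps 10,000-replicate ensembles in the sub-second range
while preserving bit-for-bit reproducibility under a fixed seed. The
initial condition is deterministic equal spacing (centers of `N0` equal
subintervals), with a uniform-random option; the deterministic default
maximizes test reproducibility.

Long-horizon runs (e.g. 200-generation approximations to ultimate
extinction) apply a `survival_cap` (default 2000): a replicate whose
population exceeds the cap is counted as surviving forever and dropped
from simulation. The induced bias is at most `d^cap`, which is
numerically zero for every configuration used; without the cap a
supercritical replicate grows geometrically and exhausts memory.

Problem sizes used in the shipped tests and experiment presets: 10,000
replicates, initial population 10, 20 generations, domains 2.6–2.8 mean
dispersal distances — matching the published experiment design; the
`reps` argument scales everything down for quick exploration.

## Population-level draws

Per generation, `r̄ ~ Normal(ξ, σ_r²/N̄)` and `Ā ~ Normal(Ŝ, σ_Ŝ²/N̄)`.
Negative growth draws are **censored** to 0 (the literal reading of
"probabilities of a negative distribution assigned to zero"); a
truncate-and-redraw option is provided. Retention draws are clipped into
[0, 1], since a retained proportion outside that range is meaningless.
The population is real-valued with quasi-extinction threshold 1
(configurable): extinction is first passage below the threshold, which is
absorbing. In environmental mode one state is drawn per generation and
its `(ξ^j, Var^j)` used; `F` (hence `Ā`'s mean) does not depend on the
environment. The composite variant draws a single
`B̄ ~ Normal(E[B], σ_B²/N̄)` per generation; the `Var(B̄) = 0.3`
time-to-extinction experiment interprets 0.3 as `σ_B²` with the 1/N̄ CLT
scaling (an unscaled mode is available).

### Known limitation

The retention variance `σ_Ŝ²` captures only the location-induced
variability of `s(y)`: the binomial noise of each offspring's individual
settlement outcome is not part of it. Consequently the population-level
model under-predicts the IBM's cumulative extinction by up to ~0.08 at
generation 20 for domains near the critical length (the IBM itself
matches the branching recursion `d_n^z` within 0.005 there, so the gap is
attributable to the approximation, not the simulator). Replacing the
variance with the CLT-consistent binomial form `Ŝ(1-Ŝ)/(r̄N̄)` matches the
per-individual variance of the thinned offspring law exactly but
over-predicts extinction by a similar margin, because the normal
approximation is symmetric where the true small-population law is
right-skewed. The shipped default keeps the `σ_Ŝ²` form; treat the
population-level curves as indicative near criticality and use the
branching recursion when quantitative extinction probabilities are
needed.

## Branching processes

The modified extinction recursion uses the generating-function
composition `d_n = f((1-F) d_{n-1} + F)` rather than the equivalent
double sum over settlement outcomes; equivalence with exhaustive
enumeration of per-offspring Bernoulli outcomes, and with the classical
recursion applied to the binomially thinned law
`p̃_q = Σ_v C(v,q) p_v (1-F)^q F^{v-q}`, is enforced in tests (two
independent code paths, 1e-10). The mean identity `ξ = E[r](1-F)` is
asserted to 1e-12 over randomized pmfs. Offspring supports are finite by
construction.

The conservation-goal solver inverts the chain: a tolerated population
extinction probability `goal` for `z` independent founders requires
`d = goal^(1/z)` per lineage; `d = f((1-F)d + F)` is solved for `F` by
Brent (the left side is increasing in `F`), and `Ŝ(L) = 1 - F` for `L`.
Goals below the non-spatial bound `(d_min)^z` are rejected with the bound
named.

For the BPRE, only the criticality boundary is analytic
(`E[ln ξ] = Σ h_j ln ξ^j + ln(1-F)`, plus the no-catastrophe condition
`E|ln(1-p̃_0)| < ∞`, which with finite supports reduces to `p̃_0^j < 1` in
every occurring environment). Finite-horizon extinction probabilities
have no closed form, so `extinction_curve_bpre` Monte-Carlo-averages the
conditional time-inhomogeneous recursion `d_k = f^{ς_k}((1-F) d_{k-1} + F)`
over iid environment sequences; environments are exchangeable, so
averaging the forward-prepended recursion is distributionally exact for
each horizon.

## What the synthetic presets do and do not show

The two presets (`{0.1, 0.3, 0.6}`; three environments with
h = {0.4, 0.4, 0.2} and pmfs {0.1, 0.2, 0.7}, {0.1, 0.3, 0.6},
{0.2, 0.3, 0.5}) are deliberately small: two-offspring maxima, means
1.3–1.6, near-critical domains. Passing tests on them demonstrates
internal consistency of the model chain (IBM ↔ thinned branching ↔
criticality solvers) and correct numerics, not realism: real populations
have density dependence, stage structure, asymmetric or fat-tailed
dispersal, environment-dependent dispersal, and non-iid environmental
sequences, all of which are out of scope here. The critical lengths
reported are conservative in the sense that nothing survives outside the
domain.

## Reproducibility

Every stochastic routine takes an explicit integer seed (or a
`numpy.random.Generator`); repeated calls with the same seed are
bit-for-bit identical. `scripts/acceptance.py` recomputes the headline
numbers of both presets from scratch; all ten are analytic or
deterministic solves and complete in seconds.
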