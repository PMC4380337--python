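# Methods

## Model and scope

`dsrstab` analyzes local steady-state stability of autonomous first-order
ODE networks `dx_j/dt = Σ_k v_k(x) s_jk` through their influence topology:
the signed directed bipartite graph whose species→reaction edges carry the
sign and magnitude of each monotonic reaction dependence `∂v_k/∂x_i`
evaluated at the steady state under study, and whose reaction→species edges
carry the signed stoichiometric scalars `s_jk`.  Everything the package
computes — principal minors, Hurwitz determinants, unstable-root counts,
phase-space zones — is a function of this graph alone.  The assumptions
are those of first-order perturbation theory: the verdicts concern a
particular steady state, hold in its neighbourhood, and say nothing about
basins, global attractors, or limit-cycle existence (a Hopf *candidate*
flag is a necessary condition only).  The reaction decomposition of a given
ODE system is a modelling choice, not unique, and different decompositions
of the same equations can yield influence topologies of different reduced
dimensionality; the package analyzes whichever decomposition it is given.

Row convention: `H_ij = ∂f_j/∂x_i`, i.e. rows are indexed by the perturbed
(input) species so that index chains read as directed cycles.  Spectra are
transpose-invariant, so no stability result depends on this; it is fixed
and documented to avoid silent transposition bugs.

## Exact arithmetic and zero detection

The Routh degenerate-case rules branch on *exact* zeros, so the whole
symbolic path (cycle weights, minors, Hurwitz determinants via fraction-free
Bareiss elimination) stays in rational/symbolic arithmetic; floats are
admitted only at the numeric oracles.  `count_unstable_roots` treats
rational inputs exactly and float inputs with a relative zero tolerance of
`1e-9·(1 + running magnitude)`.  Grid scans never evaluate polynomials in
floating point: each ζ grid coordinate is mapped through `ρ = tan(πζ/2)` at
40 significant digits and *rationalized once*; determinant signs at that
exact rational point are then decided in `fractions.Fraction` arithmetic
(the in-package `_ratpoly` evaluator; sympy substitution is exact but far
too slow per grid point).  The sign pattern reported is therefore exact for
the rationalized grid, which is all a sign-zone map requires.

Degenerate Routh inputs: an all-zero determinant vector (any topology whose
cycles are all of even length) is reported as *indeterminate at first
order* — a distinguished status, not `k = 0`.  A zero pattern outside the
classical rules (even-length interior strings, strings abutting the end)
raises rather than guessing; the scanner records such cells with a separate
sentinel.

## Parameter reduction

* **Stoichiometric scaling.**  One output edge per reaction is rescaled to
  ±1, the factor absorbed into that reaction's Jacobian edges.  The choice
  interacts with compaction and can change the final dimensionality, so by
  default all per-reaction selections are searched exhaustively (guarded at
  10^5 combinations) and ties break lexicographically over (reaction order,
  output species id) — the tie-break is a convention of this package.
* **Cycle compaction.**  Edges are grouped by their cycle-membership
  barcode; each group with non-unit magnitude becomes one parameter (sign =
  product of member signs).  This is exact: every cycle weight re-expressed
  over group parameters equals its original edge product, which is asserted
  in the test suite.  Parameters on edges lying in no cycle vanish from all
  stability expressions and are counted as removed.
* **Temporal scaling.**  Time is measured in units of `β = |q_0|^{1/z}` for
  a chosen group with `z ≥ 1` Jacobian edges, dividing every eigenvalue by
  `β > 0`.  The default unit is the parameter group containing a Jacobian
  edge with the lexicographically smallest barcode; the choice is arbitrary
  (any unit reparametrizes the same phase space) and overridable — the
  bundled networks override it to match their conventional ρ numbering.

Final dimensionality: `d = (S − m) + J − c − 1`, with `c` the dimensions
removed by compaction; the suite checks that `d` equals the number of free
symbols actually left in the reduced minors for every bundled network.

Exchange symmetries are detected by brute-force permutation testing (all
permutations up to 6 parameters, generated-group closure above), each
verified by simultaneous substitution into every minor; orbit sums are
suggested as aggregates Ψ.  Hurwitz reductions (single-parameter aggregates
Γ that linearize an instability boundary, such as ρ2/ρ1 for the Liénard
oscillator) are visible in the factored determinants the reports print, but
no general extraction algorithm is attempted — none is known to us that is
both sound and complete.

## Phase-space maps

Grids default to 201 points per axis at `ζ_i = i/(R+1)` (a convention;
no canonical resolution exists for sign-zone maps) over one or two ρ axes
with the rest pinned.  Zones are 4-connected components of constant
determinant-sign vector; each carries its Routh count.  Hopf-candidate
cells require `Δ_{n−1} < 0`, `Δ_n < 0`, all earlier determinants positive,
and 4-adjacency to an all-positive cell.  The test suite uses resolutions
21–41, chosen as the package's own balance between boundary localization
(asserted to within one grid cell against the analytic Brusselator
boundary) and exact-arithmetic cost; zone topology is asserted stable under
refinement.

## Canonicalization

Negating a species (`x → −x`) or reaction (`v → −v`) flips every incident
edge sign but preserves every cycle sign, hence all minors and
determinants; topologies in one negation orbit are the same stability
problem.  A greedy per-node sweep is not orbit-invariant (negation masks
interact), so for up to 16 nodes the canonical form is the exact orbit
minimum over all `2^(n+m)` negation subsets of the edge-sign vector read in
canonical edge order (Jacobian edges sorted by (species, reaction), then
stoichiometric by (reaction, species), '+' before '−'); beyond 16 nodes a
deterministic greedy fixpoint is used and documented as such.  The general
relationship between node-based sign degeneracy and within-group sign
degeneracy is not resolved here, and no enumeration of all
overlapping-cycle topologies is attempted.

## Bundled networks and what they do (not) represent

The factory ships six classical networks — governor (Jenkin–Maxwell),
Liénard-form van der Pol, Lotka–Volterra with generalized predation
stoichiometry, Brusselator, Sel'kov, repressilator (plus its
positive-ring variant) — and single n-cycles of any length.  Each bundle
stores *transcribed reference expressions* for its minors and determinants
alongside the pipeline's own derivation, so discrepancies stay visible
instead of being silently corrected.  Two such discrepancies are flagged:

* **Sel'kov `b_2`.**  The commonly quoted form carries `−σ2ρ1ρ3` where
  direct expansion of the stated rate laws gives `+σ2ρ1ρ3` (the 2-cycle
  through the product-recycling reaction enters with coefficient −1 applied
  to a negative cycle weight).  The bundle keeps the quoted string flagged
  `matches_pipeline=False`; all tests assert the pipeline's own expansion.
* **Odd n-cycle closed forms.**  The often-stated pattern
  `Δ_{n−1} = (−1)^{(n+1)/2} c^{(n−1)/2}` holds for n = 3, 5 but not beyond:
  exact expansion of the Hurwitz matrices (verified through n = 13, and
  against the eigenvalue oracle) gives a sign with period 4 in `(n−1)/2`
  (+, −, −, +, …), with `Δ_n = −c·Δ_{n−1}`.  `ncycle_expected_deltas`
  implements the verified pattern.  The closed-form unstable count
  `k = (n + (−1)^{(n−1)/2} c)/2` is correct for all odd n tested (≤ 9) and
  is asserted as such.

The Lotka–Volterra steady-state projection uses the conventional reduced
coordinates `ρ3 = 1/σ1`, `ρ1 = ρ2 = k1/(σ1 k3)`.  A caveat worth knowing:
direct linearization at the σ1-dependent steady state `x1* = k3/(σ1 k2)`
gives `trace(H) = 0` identically — the generalized system maps onto the
σ1 = 1 system by rescaling `x1`, so its true spectrum is purely imaginary
for *every* σ1.  The projection is therefore best read as a family of
points in the reduced phase space (it is the standard one for these
coordinates), not as the literal spectrum of the classical rate laws; at
σ1 = 1 both readings coincide (Δ1 = Δ2 = 0).  The Brusselator map is
derived from its stated rate laws (steady state `x1* = k0/a`), and the
repressilator has no closed-form projection (steady states depend on the
Hill coefficients; a numeric solver is provided instead).

The explicit rate laws attached to each bundle exist for cross-checks
(finite-difference Jacobians, eigenvalue oracles, qualitative trajectory
demonstrations via fixed-step RK4, default step 1e-3).  They are minimal
textbook forms: mass-action or Hill kinetics with unit-order coefficients.
Passing tests on them validates the topology-to-determinant machinery, not
any claim about real biochemical parameter ranges, measurement noise, or
model misspecification — real networks also require choosing a reaction
decomposition, which is outside the package's scope.

Random test ensembles (`random_topology`, `random_instantiation`) draw
uniform graphs at desk scale (n ≤ 5 species, m ≤ 6 reactions) with
log-uniform edge magnitudes on [0.1, 10], rationalized at 6 decimal digits
so downstream arithmetic stays exact; ensemble sizes (200 topologies for
the Sachs equivalence, 500 matrices for the Routh-vs-eigenvalue check) are
the package's own choice of statistical weight at interactive runtimes.
Seeds are fixed in the suite for reproducibility.

## Known limitations

* First-order information only: even-cycle-only topologies, and any point
  with all determinants zero, are honestly indeterminate.
* Cycle enumeration is exponential in the worst case; a guard refuses
  beyond 10,000 cycles, and the scaling search beyond 10^5 selections.
* Only 1D/2D scans are built in; higher-dimensional sweeps are batches of
  2D slices.
* No numerical continuation or bifurcation tracking — sign-zone mapping
  only.
* SBML import and parsing of raw ODE text are out of scope; networks enter
  through the JSON dialect or the Python API.
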