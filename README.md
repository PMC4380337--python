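# dsrstab

Steady-state stability of reaction networks, read off their topology.

`dsrstab` is for modellers in systems and synthetic biology (and anyone
working with autonomous ODE networks — ecology, chemistry, control,
electronics) who want to know *which stability behaviours a network can
exhibit at all* before committing to rate laws and parameter values.  It
implements a hierarchical, topology-then-algebra workflow: express the
governing equations as reactions times stoichiometric scalars, keep only
the signs and magnitudes of the reaction monotonicities and
stoichiometries — the network's **influence topology**, a signed directed
bipartite species–reaction (DSR) graph — and derive the complete
Routh–Hurwitz stability picture from that graph alone.

## The mathematics

For `dx_j/dt = f_j(x) = Σ_k v_k(x) s_jk`, linearization at a steady state
gives the transition matrix `H_ij = Σ_k (∂v_k/∂x_i) s_jk`, the product of a
Jacobian and a stoichiometry matrix.  The characteristic polynomial's
coefficients are signed principal minors, `a_q = (−1)^q b_q`, and each
`b_q` is a signed sum over combinations of **non-overlapping bipartite
cycles** whose species lengths total `q` (Sachs' theorem; on the bipartite
graph, cycles in a combination may share neither a species nor a reaction —
reaction-repeating terms cancel identically).  The steady state is stable
iff every Hurwitz determinant `Δ_1 … Δ_n` of the `a_q` is positive; when
some are negative, the sign changes of the Routh array
`(a_0, Δ_1, Δ_2/Δ_1, …, Δ_n/Δ_{n−1})` count the unstable eigenvalues, with
the classical zero-string rules for degenerate cases.  `Δ_{n−1}` and `Δ_n`
vanish together exactly when a purely imaginary pair appears — the
necessary condition for a Hopf bifurcation.

Three exact reductions shrink the parameter count: **stoichiometric
scaling** (one output per reaction set to ±1), **cycle compaction** (edges
sharing a cycle-membership barcode collapse into one parameter), and
**temporal scaling** (time measured in units of one Jacobian-bearing
parameter).  What survives are a few strictly positive parameters
`ρ_1 … ρ_d`, and the signs of `Δ_q(ρ)` over `(0, ∞)^d` form the network's
**stability phase space** — every algebraic realization of the topology
projects onto it.

## Worked example

```python
import sympy as sp
from dsrstab import count_unstable_roots, detect_exchange_symmetries
from dsrstab.fixtures import make_classical_network

bundle = make_classical_network("jenkin_maxwell")   # the 1868 governor
red = bundle.reduced
print(red.d, red.beta)           # 2  r3*sigma1*sigma2
print([m.value for m in red.minors()])
# [1, -rho1 - rho2, rho1*rho2, -rho1*rho2]
print([sp.factor(d) for d in red.hurwitz().deltas])
# [rho1 + rho2, rho1*rho2*(rho1 + rho2 - 1), rho1**2*rho2**2*(rho1 + rho2 - 1)]
```

Five edge weights reduce to two positive parameters, and the whole
stability question collapses to the sign of `ρ1 + ρ2 − 1` (the swap
symmetry `ρ1 ↔ ρ2` reduces it further to one aggregate `Ψ = ρ1 + ρ2`).
Inside `ρ1 + ρ2 < 1`:

```python
point = {sp.Symbol("rho1", positive=True): sp.Rational(1, 4),
         sp.Symbol("rho2", positive=True): sp.Rational(1, 4)}
deltas = [sp.Rational(d.subs(point)) for d in red.hurwitz().deltas]
print(deltas, count_unstable_roots(1, deltas).k)
# [1/2, -1/32, -1/512] 2
```

`Δ_2` and `Δ_3` are negative and the Routh array has two sign changes: two
eigenvalues sit in the right half plane, and because the last two
determinants cross zero together at the boundary, the instability is born
as a Hopf bifurcation — the governor "hunts" instead of regulating.  The
only negative monomial in `Δ_2` is `−ρ1ρ2`, the product of the feedback
3-cycle with the empty set: that multiplicative topology *is* the
destabilizing structure.

More in `examples/`: phase-space scanning with zone and Hopf labels
(`scan_repressilator.py`), upstream/downstream level decomposition with
trajectories (`levels_two_tier.py`), custom networks in the JSON dialect
with unknown-sign expansion and canonical forms (`custom_network_json.py`),
and the single-cycle taxonomy (`ncycle_taxonomy.py`).  A thin CLI wraps the
same calls: `dsrstab analyze --fixture jenkin_maxwell`,
`dsrstab scan --fixture repressilator --axes rho1,rho2 --fix rho3=1 --out grid.csv`.

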