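"""Symbolic stability analysis of the Jenkin-Maxwell governor network.

Builds the three-species influence topology (two damping loops plus a
negative feedback 3-cycle through the flywheel), reduces its five weights
to two parameters, and prints the principal minors, Hurwitz determinants,
destabilizing monomials and the exchange symmetry.
"""

import sympy as sp

from dsrstab import count_unstable_roots, detect_exchange_symmetries
from dsrstab.fixtures import make_classical_network

bundle = make_classical_network("jenkin_maxwell")
red = bundle.reduced

print(bundle.topology)
print(f"reduced dimensionality d = {red.d}; temporal scale beta = {red.beta}")
for sym, definition in red.definitions.items():
    print(f"  {sym} = {definition}")

minors = red.minors()
for m in minors:
    print(f"b_{m.q} = {m.value}")

hur = red.hurwitz()
for q, (delta, neg) in enumerate(zip(hur.deltas, hur.negative_terms), start=1):
    print(f"Delta_{q} = {sp.factor(delta)}")
    if neg:
        print(f"  destabilizing monomials: {[str(t) for t in neg]}")

sym = detect_exchange_symmetries(minors, red.params)
print(f"exchange symmetries: {sym.permutations}; aggregates Psi: {sym.psi_candidates}")

# Inside rho1 + rho2 < 1 the governor "hunts": a pair of eigenvalues crosses
# into the right half plane (Hopf).  Outside, all trajectories converge.
point = {sp.Symbol("rho1", positive=True): sp.Rational(1, 4), sp.Symbol("rho2", positive=True): sp.Rational(1, 4)}
deltas = [sp.Rational(d.subs(point)) for d in hur.deltas]
print(f"at rho1 = rho2 = 1/4: Delta signs {[sp.sign(d) for d in deltas]}, "
      f"k = {count_unstable_roots(1, deltas).k} unstable roots")
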