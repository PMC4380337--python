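"""Single-cycle networks: the complete first-order taxonomy.

1-cycles: the sign product of the stoichiometric and Jacobian edges decides
stability outright.  Even cycles carry no first-order information (all
Hurwitz determinants vanish).  Odd n-cycles have a closed-form unstable
count k = (n + (-1)^((n-1)/2) c)/2 for cycle sign c.
"""

import sympy as sp

from dsrstab import count_unstable_roots, reduce_topology
from dsrstab.fixtures import make_ncycle, ncycle_expected_unstable, one_cycle_network

print("1-cycle networks (stoichiometric sign, monotonicity sign):")
for variant in ("I", "II", "III", "IV"):
    red = reduce_topology(one_cycle_network(variant))
    (delta1,) = red.hurwitz().deltas
    verdict = "stable" if delta1 > 0 else "unstable"
    print(f"  {variant}: Delta_1 = {int(delta1):+d} -> {verdict}")

print("\nsingle n-cycles after compaction and temporal scaling:")
for n in (2, 3, 4, 5, 7):
    for sign in (1, -1):
        deltas = make_ncycle(n, sign).reduced.hurwitz().deltas
        rc = count_unstable_roots(1, [sp.Integer(d) for d in deltas])
        if rc.indeterminate:
            print(f"  n={n}, c={sign:+d}: all Delta = 0 (no first-order information)")
        else:
            closed = ncycle_expected_unstable(n, sign)
            print(f"  n={n}, c={sign:+d}: Delta = {tuple(int(d) for d in deltas)}, "
                  f"k = {rc.k} unstable roots (closed form {closed})")
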