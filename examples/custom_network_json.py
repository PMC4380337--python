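"""Working with user-defined networks in the JSON dialect.

Builds a small network with one unknown monotonicity, expands the '?' into
its two fixed-sign topologies, analyzes each, serializes to JSON/DOT, and
shows the node-negation canonical form.
"""

from dsrstab import (
    build_topology,
    canonical_sign_form,
    count_unstable_roots,
    expand_sign_assignments,
    reduce_topology,
    save_topology,
    to_dot,
)

spec = {
    "species": ["a", "b"],
    "reactions": [
        {"id": "grow", "inputs": {"a": "?"}, "outputs": {"a": 1}},
        {"id": "convert", "inputs": {"a": "+"}, "outputs": {"a": -1, "b": 1}},
        {"id": "clear", "inputs": {"b": "+"}, "outputs": {"b": -1}},
    ],
}
ambiguous = build_topology(spec)
print(f"{ambiguous!r} with {len(ambiguous.unknown_sign_edges)} unknown sign(s)")

for fixed in expand_sign_assignments(ambiguous):
    sign = next(e.sign for e in fixed.jac_edges if e.reaction == "grow")
    red = reduce_topology(fixed)
    deltas = red.hurwitz().deltas
    verdict = "sign-dependent"
    if all(d.is_positive for d in deltas):
        verdict = "stable for every weight"
    print(f"grow monotonicity {sign:+d}: d = {red.d}, Delta = {deltas} -> {verdict}")

fixed = expand_sign_assignments(ambiguous)[1]
canon = canonical_sign_form(fixed)
print(f"canonical form negates nodes {canon.negated_nodes}")
print(save_topology(fixed))
print(to_dot(fixed))
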