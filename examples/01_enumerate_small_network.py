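"""Enumerate the extreme pathways of a tiny metabolic network.

The "diamond" network imports A, converts it to B by either of two internal
reactions, and exports B.  Its flux cone has exactly two edges — one per
internal route — and the brute-force oracle agrees.
"""

import expanet as ex

net = ex.fixture_networks()["diamond"]
print("reactions:", net.reaction_ids)

expas = ex.enumerate_extreme_pathways(ex.split_reversible(net))
print(f"{len(expas)} extreme pathways:")
for p in expas:
    print(" ", dict(zip(net.reaction_ids, p.flux)), "class", p.expa_class)

oracle = ex.brute_force_elementary_modes(net)
print("matches brute-force oracle:", expas.vectors() == oracle.vectors())

# Each pathway is a minimal self-consistent steady-state route: flux enters
# through Ein, takes exactly one of r1/r2, and leaves through Eout.
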