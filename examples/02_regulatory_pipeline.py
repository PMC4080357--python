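"""Compile a Boolean regulatory model and enumerate its transcriptional states.

The worked example has four stimuli and two gene products:
Protein1 needs A and B together; Protein2 needs C or D.  Compilation yields
6 internal rule reactions (3 forward conjunctions + 3 converses), one output
exchange per product state, and two input columns per stimulus (presence,
absence) — so a single enumeration covers all 16 environments at once.
"""

import expanet as ex

model = ex.toy_trn()
print(model.to_rule_text())

net = ex.assemble_rnew(model)
print(f"R*_new: {net.n_species} component states x {net.n_reactions} reactions")

universe = ex.compute_trn_expa_set(model)
s = universe.summary()
print(f"raw pathways {s['raw']}, internal cycles removed {s['class3_removed']}, "
      f"conflicting inputs removed {s['conflicting_removed']}, feasible {s['feasible']}")

ids = universe.network.reaction_ids
for v in universe.feasible:
    active = [rid for rid, x in zip(ids, v) if x]
    print("  ", " + ".join(active))

# Each feasible pathway is one transcriptional state: which stimuli must be
# present/absent (In_*/In_NOT_*), which rule fires, and which product state
# is expressed (Ex_*).
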