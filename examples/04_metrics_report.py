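"""Compute the comparison metrics for a pathway set.

P/R measures redundancy (how many systemically independent routes per
reaction), lengths measure route complexity, RPR flags load-bearing
reactions, CoSets find always-co-occurring reactions, and the crosstalk
matrix classifies pathway pairs by whether their inputs/outputs are
identical, overlapped or disjoint.
"""

import expanet as ex

universe = ex.compute_trn_expa_set(ex.toy_trn())
expas = universe.as_expa_set()
report = ex.metrics_report(expas, exclude_top_exchange_fraction=0.0)

print(f"pathways: {report.n_expas}, reactions: {report.n_reactions}, "
      f"P/R = {report.pr_ratio:.3f}")
ln = report.lengths
print(f"length avg {ln.avg:.2f} (min {ln.min}, max {ln.max}, mode {ln.mode}), "
      f"L/R = {ln.lr_percent:.2f}%")

print("top participation rates:")
print(report.rpr.head(5).to_string(index=False))

print(f"CoSets: {len(report.cosets.cosets)}, adjacent ratio "
      f"{report.cosets.adjacent_ratio:.0f}%")
print("crosstalk (% of pathway pairs):")
print(report.crosstalk.to_frame().round(1).to_string())

# A high disjoint/disjoint crosstalk cell means most transcriptional states
# respond to different stimuli and express different products — the network
# is specific rather than redundant.
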