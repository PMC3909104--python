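"""Detect oligomers in constructed multi-chain snapshots: a cross-beta sheet
passes all three oligomerization criteria, and fixtures violating exactly one
criterion are rejected."""

from prionmc import detect_oligomers, get_peptide, make_dispersed, make_sheet_assembly
from prionmc.synthetic import make_crossed_pair, make_pseudo_extended_pair

seq = get_peptide("109-122")

sheet = make_sheet_assembly(seq, n_chains=3, architecture="antiparallel")
for o in detect_oligomers(sheet):
    print(f"sheet fixture: oligomer of {o.size} chains, links:",
          [f"{a}-{b} {ori}" for a, b, ori in o.links])
    print("  inter-chain H-bonds per link:", dict(o.pair_hbond_counts))

print("\nfixtures violating one criterion each (all should report nothing):")
print("  dispersed helices     ->", detect_oligomers(make_dispersed(seq, 4, 0, component="helix")))
print("  low sheet fraction    ->", detect_oligomers(make_pseudo_extended_pair(seq)))
print("  crossed strand axes   ->", detect_oligomers(make_crossed_pair(seq)))
# An oligomer requires >= 3 inter-chain H-bonds, >= 50% strand content on
# both chains and (anti)parallel axes within 30 degrees - simultaneously.
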