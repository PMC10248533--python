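"""The full analysis: from synthetic proteomes to a subfamily atlas.

Runs harvest, tiered clustering, seed-anchored alignment, ML phylogeny
with bootstrap, MRCA rooting, 70% collapse, evolutionary placement of
non-representatives, and anchor-based clade assignment, then prints the
genus-level presence/absence matrix and copy-number tally.
"""
import get3atlas as g

sim = g.simulate_family(seed=4)
res = g.run_family_analysis(sim, seed=4)

print(f"harvested {len(res.domains)} domains -> "
      f"{len(res.representatives)} representatives; "
      f"{len(res.placements)} placed by EPA")
print("\ngenus x subfamily presence (True = at least one member):")
print(res.atlas.presence)
print("\nper-species copy numbers:")
print(res.atlas.copy_counts)

ev = g.evaluate_against_truth(sim, res)
print(f"\nlabel recovery vs simulation truth: {ev['label_recovery']:.1%}")
print(f"forced absences recovered:          {ev['forced_absence_recovery']:.1%}")
# The aCD-bearing subfamily (Get3d) is absent from the single-celled-plant
# genera by construction (simulated gene loss); a correct run shows False
# in those presence cells and recovers every other subfamily across genera.
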