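"""Consensus disulfide connectivity from a prediction ensemble.

External predictors disagree; the consensus takes, for each of the three
bridges homologous to every ICK class, the partner winning the majority
vote, with published reference maps breaking ties.
"""

import ickkit as ik

core = [(1, 4), (2, 5), (3, 6)]
ensemble = ik.PredictionEnsemble("rep_6.0", n_cys=6)
ensemble.add("disulfind_alt1", ik.DisulfideMap.from_pairs(6, core))
ensemble.add("disulfind_alt2", ik.DisulfideMap.from_pairs(6, [(1, 2), (3, 4), (5, 6)]))
ensemble.add("cyscon", ik.DisulfideMap.from_pairs(6, core))
ensemble.add("crisp_model1", ik.DisulfideMap.from_pairs(6, [(1, 4), (2, 6), (3, 5)]))
ensemble.add("arachnoserver", ik.DisulfideMap.from_pairs(6, core), reference=True)

consensus = ik.consensus_connectivity(ensemble)
print("consensus bridges:", sorted(consensus.bonds))
# (1,4), (2,5), (3,6) is the canonical ICK core: bridge 3-6 threads the
# macrocycle closed by the other two bridges and the backbone.

chords = ik.chord_export(ensemble)
print("chord votes for C1:", chords["chords"]["1"])
print("total votes:", chords["total_votes"], "(= 2 x bonds across all maps)")

n = 8
print(f"complete pairings of {n} cysteines: {len(ik.enumerate_pairings(n))} "
      f"(the (n-1)!! explosion that motivates consensus over enumeration)")
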