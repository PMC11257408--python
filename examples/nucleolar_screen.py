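"""One-nucleolus percent effect, hit calling and 5-EU percent inhibition.

Simulates a screening plate: 16 negative and 2 positive control wells plus
one test treatment with a strong one-nucleolus phenotype; effects are
rescaled so the negative control is 0% and the positive 100%, and hits
need a mean effect at or above +3 SD of the negative-control wells.
"""

import editscan as es

wells = es.simulate_screen_wells(16, 2, {"siCandidate": 0.392},
                                 cells_per_well=3000, seed=21)
fractions = wells.groupby(["well", "role"])["nucleoli"].apply(
    lambda counts: es.one_nucleolus_fraction(counts.to_numpy()))
neg = fractions.xs("negative", level="role")
pos_mean = fractions.xs("positive", level="role").mean()
neg_mean = neg.mean()

effect = es.percent_effect(float(fractions.xs("test", level="role").iloc[0]),
                           neg_mean, pos_mean)
neg_effects = [es.percent_effect(x, neg_mean, pos_mean) for x in neg]
hits = es.call_hits({"siCandidate": {1: effect}}, {1: neg_effects})
info = hits["siCandidate"]
print(f"one-nucleolus fractions: neg {neg_mean:.3f}, pos {pos_mean:.3f}")
print(f"siCandidate percent effect {info['mean_effect']:.1f}% "
      f"(hit cutoff {info['threshold']:.1f}%), hit: {info['hit']}")

inhibition, mechanism = es.percent_inhibition(eu_test=59.4, eu_neg=100.0,
                                              eu_pos=20.0)
print(f"5-EU percent inhibition {inhibition:.1f}% -> {mechanism}")
# An effect beyond 100% means a phenotype stronger than the positive
# control; inhibition between 50 and 80 points at pre-rRNA
# processing/maturation rather than transcription.
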