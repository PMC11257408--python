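"""UC dinucleotide density along transcripts, against the 6.25 baseline.

Counts UC motifs in the bundled human 5S rRNA and profiles a mock 47S-like
pre-rRNA in 100-nt windows; under equiprobable bases a random 100-nt
window is expected to hold 100 x (1/4)^2 = 6.25 UC motifs.
"""

import editscan as es

r5s = es.load_human_5s_rrna()
print(f"{r5s.name.split()[0]} ({len(r5s)} nt): "
      f"{es.count_motif(r5s.sequence, 'UC')} UC motifs "
      f"(random expectation {es.expected_motif_count(len(r5s), [0.25]*4, 'UC'):.2f})")

pre = es.preribosome_reference(seed=3)
profiles = es.windowed_motif_profile(pre.sequence, "UC", window=100)
enriched = [p for p in profiles if p.enrichment > 1.6]
print(f"mock pre-rRNA: {len(profiles)} windows, "
      f"{len(enriched)} with UC density > 1.6x the 6.25 baseline")

# Context matrix of synthetic UC-preceded edit sites
sites = es.plant_edit_sites(pre, 16, require_uc=True, seed=3)
contexts = [pre.context(s.position, flank=10) for s in sites]
pfm = es.build_pfm(contexts)
enr = es.preceding_base_enrichment(contexts)
print(f"{enr['count']}/{enr['n']} edit contexts preceded by U "
      f"(expected {enr['expected']:.1f} at random), two-sided p = {enr['p_value']:.2g}")
# A p-value below 0.05 with count above expectation flags the UC preference.
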