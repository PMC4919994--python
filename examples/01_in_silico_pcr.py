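"""In silico PCR with the packaged AOB primer sets.

Builds a perfectly primed synthetic 16S template and one Cluster-6A-like amoA
template with planted mismatches, then extracts the predicted products.
"""

import numpy as np

from primerscope import PlantSpec, default_primer_sets, in_silico_pcr, make_template

sets = default_primer_sets()
ps16, psamoa = sets["CTO189-RT1r"], sets["amoA1F-2R"]
rng = np.random.default_rng(0)

template = make_template(PlantSpec("6A", "16S", 1, (0, 0), (0, 0)), ps16, rng, "aob-16s")
amp = in_silico_pcr(template, ps16, max_mismatch=1)
print(f"16S product: {amp.total_length} bp total, "
      f"{amp.inter_primer_length} bases between the priming sites")
# 116 bp product with a 75-base inter-primer region: too short for reliable
# phylogenetic placement of the cloned sequences.

template = make_template(PlantSpec("6A", "amoA", 1, (2, 2), (1, 2)), psamoa, rng, "6a-amoa")
amp = in_silico_pcr(template, psamoa, max_mismatch=4)
total = amp.forward_match.mismatch_total + amp.reverse_match.mismatch_total
print(f"amoA product: {amp.total_length} bp, primer-set mismatches: {total} "
      f"(fwd {amp.forward_match.mismatch_total}, rev {amp.reverse_match.mismatch_total})")
# Cluster 6A templates carry 2-4 mismatches to the amoA primer set, the root
# of the amplification bias this package models.
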