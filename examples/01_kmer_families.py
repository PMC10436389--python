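"""Canonical k-mer families: strand collapse, counting, and the choice of k.

Builds a small random genome, counts center-pyrimidine 11-mer families, and
prints the uniform-model design statistics that motivate k = 11 over k = 13.
"""

import numpy as np

import locmut as lm

# A genomic window and its reverse complement are one family, named by the
# orientation whose center base is a pyrimidine.
canon, was_rc = lm.canonicalize_kmer("AAAGAAGTTTC")
print(f"AAAGAAGTTTC collapses to {canon} (reverse-complemented: {was_rc})")

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=50_000, p=[0.295, 0.205, 0.205, 0.295]))
genome = lm.GenomeSequence({"chr1": seq})
table = lm.count_kmer_families(genome, k=11)
print(f"{len(table.families)} 11-mer families over {table.total_span} windows")

# Design statistics at human-genome scale: expected instances and SNVs per
# possible k-mer if both were uniform.  The tradeoff: longer k-mers resolve
# more context but leave too few instances for stable rate estimates.
for k in (9, 11, 13):
    possible, inst, snv = lm.kmer_design_stats(k, 2_684_570_106, 41_318_716)
    print(f"k={k:2d}: {possible:>12,} possible families, "
          f"{inst:8.0f} instances and {snv:5.1f} SNVs expected per family")
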