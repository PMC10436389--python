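"""KL information logos and signature-induced background 11-mer sets.

Builds the logo of a small 11-mer set against the genomic base composition,
then constructs the background distribution a signature induces over genomic
11-mers and uses it for a binomial positional enrichment test.
"""

import numpy as np
import pandas as pd

import locmut as lm
from locmut.motifs import background_positional_composition
from locmut.simulate import focused_signature

# Logo of a motif-bearing set: letter height = frequency x positional KL
# divergence (bits) from the genome background (A=T=29.5%, C=G=20.5%).
kmers = ["GAAACTTCTTT", "TGAAACTTCTT", "AAAACTTATGC", "AGAACTTCGAG"]
comp = lm.positional_composition(kmers, weights=[10, 8, 3, 2])
logo = lm.kl_logo(comp, lm.GENOME_BASE_FREQS)
print("bits per position (center = 0):")
print(logo.bits.round(2).to_string())

# A signature's trinucleotide profile induces a distribution over 11-mers:
# P(m|s) = sum over compatible types u of P(u|s) P(m) / P(trinuc(m)).
rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=100_000, p=[0.295, 0.205, 0.205, 0.295]))
genome = lm.GenomeSequence({"chr1": seq})
table = lm.count_kmer_families(genome, 11)
sig = focused_signature("sig_localized", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
background = lm.signature_background_set(sig, table)
print(f"\nbackground set: {int((background > 0).sum())} 11-mers, "
      f"total probability {background.sum():.6f}")
print("center trinucleotides in the background:",
      sorted({m[4:7] for m in background[background > 0].index}))

# Enrichment of an observed set against that background: one exact binomial
# test per position/base and per sub-k-mer, z capped at 38.5 (p = 1e-300).
observed = pd.Series({m: c for m, c in zip(kmers, [40, 30, 10, 5])})
support = background[background > 0]
base_z, kmer_best = lm.positional_enrichment(observed, support, max_k=4)
print("\nmost significant sub-k-mer per start position:")
print(kmer_best[["kmer", "z", "fold"]].round(2).to_string())
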