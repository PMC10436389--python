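# Methods

## The model

`locmut` treats the genome as a set of strand-symmetric k-mer *families*:
every odd-length window and its reverse complement are one family, named by
the orientation whose center base is a pyrimidine. For odd k a window never
shares a center pyrimidine with its reverse complement, so the 4^k k-mers
partition into exactly 4^k/2 families; this is property-tested. The family's
genomic instance count is its *span*, the denominator of its mutation rate

    mu_m = n_m^SNV / (n_patients * n_m^instances) * 1e6   [SNV/Mb/patient]

and sets of families pool numerators and denominators (a weighted average),
so any partition of a catalog reproduces the catalog-wide rate exactly.

The default k is 11 (±5 bp around the mutated base). At human-genome scale
this leaves ~1280 expected instances and ~20 expected SNVs per possible
family — enough for rate estimation — whereas k = 13 leaves ~80 instances;
`kmer_design_stats` exposes this tradeoff, with an optional observed-family
denominator next to the theoretical 4^k/2.

Significance of a rate increase is an exact one-sided upper-tail binomial
test: n = n_patients × span trials with the reference per-site per-patient
probability (rate × 1e-6). Because the tail is strictly decreasing in the
count, the "fraction of qualifying counts that are significant" is a
deterministic quantity: 100% exactly when the minimal count implying the
fold increase is itself significant, otherwise the fraction over a window of
qualifying counts (default 1000). Confidence intervals are exact
Clopper–Pearson at 99%; the method is not dictated by the rate definition,
and the exact interval was chosen over a normal approximation because family
counts can be very small. Multiple testing uses Bonferroni with an explicit
test count; 817 is the documented reference constant for a full-catalog run,
but the pipeline defaults to the number of comparisons it actually performs.

### Signatures and 11-mer assignment

Signatures are SBS96 distributions (96 pyrimidine-centered substitution
types in trinucleotide context). A patient belongs to a signature's
*exposure cohort* when that signature explains ≥ 5% of the patient's
attributed mutations (load is always a fraction; absolute thresholds are not
supported). Per-SNV posteriors combine exposure and prior:

    P(s | snv) ∝ exposure[patient, s] * P(type(snv) | s)

normalized over signatures; SNVs impossible under every exposed signature
are flagged unassignable and dropped. This product form is the package's
choice of posterior; externally computed per-SNV posteriors can be swapped
in, since every downstream step takes the posterior frame as an argument.

11-mer assignment averages posteriors in two levels: first a position-wise
mean over the patients mutated at each genomic position (so a hotspot with
many identical SNVs counts once), then a mean over the family's mutated
positions; the argmax signature is the assignment, with ties broken to the
lexicographically smallest id and logged. Welch's t-test (conservative under
unequal variances) compares APOBEC3A- vs APOBEC3B-motif log rates.

### Hotspots and the ascertainment control

Recurrence is the number of distinct patients with an SNV at a position,
irrespective of the alternate allele by default (an allele-aware mode takes
the maximum over alleles). A family's recurrence is the maximum over its
mutated instances; the 1+/2+/5+ sets are nested by construction. Because
selecting families *by* their hotspots inflates their apparent rate, the
ascertainment control removes all SNVs at positions whose recurrence reaches
the set's level and re-estimates the rate over the unchanged span; a
surviving elevation is driven by independent singleton mutations.

### Logos, backgrounds and enrichment

Information logos use the per-position Kullback–Leibler divergence in bits
between observed and expected base frequencies; letter heights are
frequency × divergence and sum to the divergence per position. The default
background is the hg19 autosomal composition (A = T = 29.5%, C = G = 20.5%).
Logos can weight members by SNV count (mutation-centric) or by genomic
instance count (set-centric); both modes are explicit because they answer
different questions, and the mutation-centric mode is the pipeline default.

A signature induces a background distribution over 11-mers via

    P(u in m | s) = P(u|s) * P(m) / P(trinuc(m))
    P(m | s) = sum over {u : trinuc(u) = trinuc(m)} of P(u in m | s)

with P(m) the genomic family frequency. Signature mass on trinucleotides
absent from the genome is flagged and the distribution renormalized. The
positional enrichment test is a simplified probability-logo statistic: one
exact binomial test per position × residue and per sub-k-mer (k ≤ 4) per
start offset against the background-induced probabilities, reported as
signed z-scores with |z| capped at 38.5 (p = 1e-300) and z = 0 when neither
tail is below 0.5; per start, the most significant sub-k-mer is reported.
Full pLogo/kpLogo reimplementation (residue-level corrected thresholds,
graphics) is out of scope; background sets are exportable for those tools.

### Regions and the nested catalog

Region labels are BED intervals (0-based half-open); membership of an 11-mer
instance is decided by its *center* position, and overlapping labels each
receive the instance independently (per-label rates are not a partition).
The nested decomposition chains cohort → signature-assigned →
hotspot-associated → region, each stage tested against the previous stage's
rate; the region stage picks, among labels with Bonferroni-adjusted
p ≤ 0.01 and fold > 1, the highest-rate label (ties to larger span), and the
chain truncates with a flag when no label qualifies. Spans are
non-increasing along the chain and the total fold equals the product of the
stepwise folds by construction.

## The synthetic-data generator

The generator inverts the background-set construction as a sampler. Per
patient, a Poisson number of mutations is drawn; each mutation draws a
signature from the patient's exposures, a type from that signature's SBS96
profile, and a position uniformly among windows whose canonical center
trinucleotide matches the type — with positions whose canonical 11-mer
matches a planted IUPAC motif (covering the mutated base, optionally
restricted to a region label) weighted up by the process's fold multiplier
when the drawing signature is the process's signature. Hotspots are
emergent, never planted positionally. All randomness flows through one
seeded generator; identical configs give byte-identical outputs.

Reference study conditions (the package's defaults, chosen once):

| parameter | value | rationale |
| --- | --- | --- |
| genome | 1 Mb, single contig, A=T=0.295 / C=G=0.205 | hg19-like composition at desk scale |
| repeat array | GAAACTTCTTT × 200 inside a `repeat` label (0.5%) | gives 11-mer families multi-instance spans, which the ascertainment control requires |
| cohort | 200 patients, Poisson mean burden 30 SNVs | upper-middle of the pan-cancer per-Mb range; enough counts for desk-scale power |
| signatures | flat background + localized (0.5 on A[C>T]T, 0.5 on C[T>G]T) | the localized profile hits the two trinucleotides the AAACTT motif offers |
| exposures | symmetric Dirichlet(2) over the two signatures | realistic patient-to-patient heterogeneity with mean 50/50 |
| planted process | motif AAACTT, fold 8, genome-wide | a six-base extended context producing emergent hotspots |

What the generator does *not* emulate: regional covariates of real mutation
rates (replication timing, transcription), clustered mutations (kataegis),
indels and structural variants, sequencing artifacts, and driver selection.
Passing tests therefore demonstrate that the estimators are correct under
the stated generative model, not that real catalogs satisfy that model.

A deliberate desk-scale artifact: in a 1 Mb random genome almost every
11-mer family has a single instance, so any mutated family's rate is
ascertainment-inflated in a way the human genome's ~1280-instance families
are not. The planted repeat array restores multi-instance families where the
analysis needs them; chain-level rate monotonicity, which holds at genome
scale, is not asserted at desk scale.

## Numerical choices and degenerate inputs

- Windows containing N (or truncated at contig edges) are excluded from both
  counts and spans; no contexts are imputed.
- Family tables use a flat 2-bit-encoded code array per contig (O(4^k)
  addressable, single streaming pass); k > 15 and compressed genome formats
  are unsupported.
- Internal coordinates are 0-based half-open; SNV files are 1-based, BED is
  0-based half-open.
- Zero spans, zero patients, zero-norm profiles, empty observation sets and
  reference per-site probabilities ≥ 1 are rejected with errors rather than
  coerced.
- The binomial tail is always exact (scipy), never a normal approximation;
  z-scores are derived from the exact tail.
- Assignment ties and dropped SNVs (missing context, unassignable type) are
  logged so filter accounting is auditable; the pipeline manifest records
  per-stage counts.

## Problem sizes

The test suite runs the reference scenario once (1 Mb, 200 patients) and
reuses it across acceptance checks; unit tests use ≤ 10 kb genomes where
brute-force oracles (naive window scans, pmf summation, exhaustive
background enumeration) are feasible. The full suite completes in well under
a minute on one CPU.

## Known limitations

- The per-SNV posterior assumes exposures are given per patient and are not
  conditioned on cancer type.
- The "fraction significant" statistic is analytic over integer counts and is
  the default because it is deterministic; `statistical_power` provides the
  sampling-probability alternative (P(X ≥ c_alpha) under a fold-elevated
  truth).
- Overlapping region labels double-count instances by design; callers who
  need a partition must supply disjoint BED intervals.
- FDR procedures other than Bonferroni, NMF signature discovery, and
  annotation derivation (chromatin states, RepeatMasker) are out of scope:
  signatures, exposures and region annotations are inputs.
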