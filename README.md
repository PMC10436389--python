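# locmut

Quantifying **localized mutational processes** in cancer genomes through
strand-symmetric 11-mer sequence families.

Somatic mutational processes often prefer extended sequence contexts beyond
the trinucleotide resolution of standard SBS96 signature analysis, and some
concentrate so strongly in particular contexts that they produce mutational
hotspots — positions mutated recurrently across patients. `locmut` provides
the full analysis stack for characterizing such processes from a reference
genome and a somatic SNV catalog:

- **Canonical k-mer families** — every genomic window and its reverse
  complement collapse to the orientation with a center pyrimidine (C or T),
  partitioning the 4^k k-mers into 4^k/2 strand-symmetric families whose
  genomic instance counts are the spans used as rate denominators.
- **Mutation rates and binomial significance** — for a family or set *M*,
  μ̄_M = Σ n_m^SNV / (n_patients · Σ n_m^instances) · 10⁶ (SNV/Mb/patient),
  tested against a baseline with exact one-sided binomial tails, exact 99%
  (Clopper–Pearson) intervals, power curves over spans and fold increases,
  and Bonferroni correction.
- **Signature machinery** — SBS96 profiles, cosine similarity,
  exposure-defined patient cohorts (≥ 5% load), per-SNV posterior signature
  probabilities (posterior ∝ exposure × P(type|signature)), the two-level
  (position-wise, then family-wise) posterior averaging that assigns 11-mers
  to signatures, and APOBEC3A/3B (YTCA/RTCA) motif classification.
- **Hotspot recurrence** — distinct-patient recurrence per position, nested
  recurrence-stratified 11-mer sets (1+/2+/5+), signature enrichment by
  recurrence level, and an ascertainment control that removes the
  set-defining hotspot SNVs before re-estimating the rate.
- **Motif statistics** — positional composition, Kullback–Leibler
  information logos (height_{a,i} = p_{a,i} · D_KL(p_i, q_i), in bits),
  signature-induced background 11-mer distributions
  P(m|s) = Σ_{u: trinuc(u)=trinuc(m)} P(u|s)·P(m)/P(trinuc(m)), and a
  simplified binomial positional/k-mer enrichment test (z capped at 38.5).
- **Region-stratified rates and the nested catalog** — BED-annotated
  chromatin states or repeat classes, per-label rate comparisons, and the
  four-stage decomposition cohort → signature-assigned 11-mers →
  hotspot-associated 11-mers → best significant region.
- **A synthetic-data generator** — genomes with planted repeat arrays and
  region labels, cohorts with mixed signature exposures, and SNV catalogs
  drawn from signature profiles in which 11-mers matching a planted motif
  mutate at a fold-elevated rate, with full ground truth.

## Worked example

```python
import locmut as lm

baseline = lm.mutation_rate(41_318_716, 2583, 2_684_570_106)
print(f"{baseline.rate:.2f}")          # 5.96  SNV/Mb/patient
family = lm.mutation_rate(85, 2583, 500)
print(f"{family.rate:.1f}")            # 65.8  SNV/Mb/patient

# power of the binomial framework at different spans and fold increases
lm.fraction_fold_significant(100, 5, 1e-2, 2583, baseline.rate)              # 100.0
lm.fraction_fold_significant(5000, 2, 1e-9, 2583, baseline.rate, strict=True)  # 100.0
lm.fraction_fold_significant(100, 2, 1e-2, 2583, baseline.rate)              # 99.8
```

The first two numbers say that a 5-fold rate increase over a 100 bp span, or
any >2-fold increase over 5 kb, is always detected at the stated threshold;
the third says a 2-fold increase on 100 bp is not reliably significant.

End-to-end recovery of a planted localized process
(`python examples/03_planted_process_recovery.py`):

```
simulated 6021 SNVs in 200 patients; {'sig_localized:AAACTT': 623} attributed to the planted process
401 mutated motif families; 98.8% assigned to the planted signature
2+ set: 109 families, 794 bp, 2298 SNV/Mb/patient
2+ set residual rate 668 vs baseline 30.1
recovered fold multiplier: 7.88 (planted: 8)
```

The motif-matching 11-mers are assigned to the correct signature, their
hotspot set mutates two orders of magnitude above baseline even after the
ascertainment control, and the planted 8-fold multiplier is recovered within
2%. The other scripts in `examples/` each demonstrate one capability
(k-mer counting and design statistics, rate/power arithmetic, logos and
signature backgrounds).

A thin CLI mirrors the library: `locmut count-kmers`, `rates`, `power`,
`hotspots`, `motif`, `simulate`, `catalog` (run `locmut --help`).

## Layout

```
src/locmut/      genome, rates, signatures, hotspots, motifs, regions,
                 simulate, pipeline, cli
examples/        one narrative script per capability
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, assumptions, parameter choices, limitations
```
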