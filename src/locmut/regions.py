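"""Region-stratified rate analysis and the nested rate decomposition catalog.

Genomic annotations (chromatin states, repeat classes) come in as labeled
BED intervals (0-based half-open); an 11-mer instance carries every label
whose interval contains its *center* position (the mutated base).  Labels may
overlap, so per-label rates are not a partition of the genome.

The nested decomposition chains four stages of shrinking genomic span for one
signature-exposure cohort — cohort-wide, signature-assigned 11-mers,
hotspot-associated 11-mers, and the best significantly elevated region — with
stepwise fold-changes and Bonferroni-adjusted binomial p-values per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeSequence, KmerInstance, canonical_code_track, encode_kmer
from .hotspots import RecurrenceStratifiedSets
from .motifs import GENOME_BASE_FREQS, LogoMatrix, kl_logo, positional_composition
from .rates import RateComparison, RateEstimate, compare_rates, mutation_rate

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass
class RegionAnnotationSet:
    """Labeled, possibly overlapping intervals (contig, start, end, label)."""

    intervals: list[tuple[str, int, int, str]]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for contig, start, end, label in self.intervals:
            if start >= end:
                raise ValueError(f"malformed interval {contig}:{start}-{end}")
            if not label:
                raise ValueError("interval labels must be non-empty")
        self._trees = {}
        for contig, start, end, label in self.intervals:
            self._trees.setdefault(contig, IntervalTree()).addi(start, end, label)

    @classmethod
    def from_bed(cls, path) -> "RegionAnnotationSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"BED line lacks a label column: {line!r}")
                intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
        return cls(intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig, start, end, label in self.intervals:
                fh.write(f"{contig}\t{start}\t{end}\t{label}\n")

    @property
    def labels(self) -> list[str]:
        return sorted({iv[3] for iv in self.intervals})

    def labels_at(self, contig: str, pos0: int) -> set[str]:
        tree = self._trees.get(contig)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos0)}

    def label_mask(self, contig: str, length: int, label: str) -> np.ndarray:
        """Boolean per-base mask of one label along a contig."""
        mask = np.zeros(length, dtype=bool)
        for c, start, end, lab in self.intervals:
            if c == contig and lab == label:
                mask[max(0, start) : min(length, end)] = True
        return mask


def annotate_instances(
    instances: list[KmerInstance], regions: RegionAnnotationSet, k: int = 11
) -> list[set[str]]:
    """Label set of each instance, decided by its center position.  Instances
    under no interval carry the reserved 'unannotated' label."""
    half = k // 2
    out = []
    for inst in instances:
        labels = regions.labels_at(inst.contig, inst.start + half)
        out.append(labels if labels else {UNANNOTATED})
    return out


def _set_codes(kmers) -> np.ndarray:
    return np.array(sorted(encode_kmer(m) for m in kmers), dtype=np.int64)


def _per_label_spans_and_snvs(
    genome: GenomeSequence,
    k: int,
    kmer_set,
    snvs: pd.DataFrame,
    regions: RegionAnnotationSet,
) -> pd.DataFrame:
    """Span (windows with center in label) and SNV count per label for a set
    of 11-mer families, including the reserved unannotated label."""
    codes = _set_codes(kmer_set)
    labels = regions.labels + [UNANNOTATED]
    spans = {lab: 0 for lab in labels}
    half = k // 2
    for contig, seq in genome.contigs.items():
        track = canonical_code_track(seq, k)
        member = (track >= 0) & np.isin(track, codes)
        if not member.any():
            continue
        centers = np.zeros(len(seq), dtype=bool)
        centers[np.nonzero(member)[0] + half] = True
        covered = np.zeros(len(seq), dtype=bool)
        for lab in regions.labels:
            mask = regions.label_mask(contig, len(seq), lab)
            covered |= mask
            spans[lab] += int((centers & mask).sum())
        spans[UNANNOTATED] += int((centers & ~covered).sum())

    in_set = snvs["kmer"].isin(set(kmer_set))
    snv_counts = {lab: 0 for lab in labels}
    for _, row in snvs.loc[in_set].iterrows():
        labs = regions.labels_at(row["chrom"], int(row["pos"]) - 1)
        for lab in labs if labs else {UNANNOTATED}:
            snv_counts[lab] += 1
    return pd.DataFrame(
        {"span_bp": pd.Series(spans), "n_snv": pd.Series(snv_counts)}
    )


def region_rate_table(
    genome: GenomeSequence,
    k: int,
    kmer_set,
    snvs: pd.DataFrame,
    regions: RegionAnnotationSet,
    reference: RateEstimate,
    n_patients: int,
    n_tests: int = 1,
    min_span: int = 50,
) -> pd.DataFrame:
    """Per-label rate comparison of an 11-mer set against a reference rate.

    Labels with zero span are omitted (logged); labels spanning fewer than
    ``min_span`` windows are kept but flagged low-power.
    """
    table = _per_label_spans_and_snvs(genome, k, kmer_set, snvs, regions)
    rows = []
    for label, row in table.iterrows():
        span, n_snv = int(row["span_bp"]), int(row["n_snv"])
        if span == 0:
            logger.info("region label %s has zero span in the 11-mer set; omitted", label)
            continue
        est = mutation_rate(n_snv, n_patients, span)
        cmp_ = compare_rates(est, reference, n_tests=n_tests)
        rows.append(
            {
                "label": label,
                "span_bp": span,
                "n_snv": n_snv,
                "rate": est.rate,
                "ci_low": est.ci99[0],
                "ci_high": est.ci99[1],
                "fold": cmp_.fold,
                "p": cmp_.p_value,
                "p_adj": cmp_.p_adjusted,
                "low_power": span < min_span,
            }
        )
    return pd.DataFrame(rows).set_index("label")


@dataclass
class CatalogStage:
    name: str
    span_bp: int
    estimate: RateEstimate
    fold_step: float
    p_value: float
    p_adjusted: float
    fold_total: float
    logo: LogoMatrix | None = None
    label: str | None = None


@dataclass
class CatalogEntry:
    """Nested decomposition chain: cohort -> signature -> hotspot -> region."""

    cohort: str
    stages: list[CatalogStage]
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "label": s.label,
                    "span_bp": s.span_bp,
                    "n_snv": s.estimate.n_snv,
                    "rate": s.estimate.rate,
                    "ci_low": s.estimate.ci99[0],
                    "ci_high": s.estimate.ci99[1],
                    "fold_step": s.fold_step,
                    "p": s.p_value,
                    "p_adj": s.p_adjusted,
                    "fold_total": s.fold_total,
                }
                for s in self.stages
            ]
        )


def _stage_logo(snvs: pd.DataFrame, kmer_set=None) -> LogoMatrix | None:
    work = snvs.dropna(subset=["kmer"])
    if kmer_set is not None:
        work = work[work["kmer"].isin(set(kmer_set))]
    if work.empty:
        return None
    counts = work.groupby("kmer").size()
    comp = positional_composition(list(counts.index), counts.to_numpy())
    return kl_logo(comp, GENOME_BASE_FREQS)


def nested_decomposition(
    genome: GenomeSequence,
    snvs: pd.DataFrame,
    family_table,
    assigned_kmers,
    stratified: RecurrenceStratifiedSets,
    regions: RegionAnnotationSet,
    n_patients: int,
    cohort: str,
    hotspot_level: int = 2,
    n_tests: int = 817,
    alpha: float = 0.01,
) -> CatalogEntry:
    """Assemble the four-stage nested rate decomposition for one cohort.

    Stage spans shrink along the chain; each stage's rate is tested against
    the previous stage's rate (one-sided binomial, Bonferroni over
    ``n_tests``).  The region stage picks, among labels with adjusted
    p <= ``alpha``, the one with the highest rate (ties to larger span); if no
    label is significant the chain is truncated at three stages and flagged.
    """
    k = family_table.k
    snvs = snvs.dropna(subset=["kmer"])

    def stage(name, n_snv, span, prev, cohort_rate, logo, label=None):
        est = mutation_rate(n_snv, n_patients, span)
        if prev is None:
            return CatalogStage(name, span, est, 1.0, 1.0, 1.0, 1.0, logo, label)
        cmp_ = compare_rates(est, prev.estimate, n_tests=n_tests)
        total = est.rate / cohort_rate
        return CatalogStage(
            name, span, est, cmp_.fold, cmp_.p_value, cmp_.p_adjusted, total, logo, label
        )

    stages: list[CatalogStage] = []
    s0 = stage("cohort", len(snvs), family_table.total_span, None, None, _stage_logo(snvs))
    stages.append(s0)
    cohort_rate = s0.estimate.rate

    assigned = set(assigned_kmers)
    span1 = sum(family_table.count(m) for m in assigned)
    n1 = int(snvs["kmer"].isin(assigned).sum())
    s1 = stage("signature", n1, span1, s0, cohort_rate, _stage_logo(snvs, assigned))
    stages.append(s1)

    hot = set(stratified[hotspot_level].kmers) & assigned
    span2 = sum(family_table.count(m) for m in hot)
    n2 = int(snvs["kmer"].isin(hot).sum())
    s2 = stage("hotspot", n2, span2, s1, cohort_rate, _stage_logo(snvs, hot))
    stages.append(s2)

    table = region_rate_table(
        genome, k, hot, snvs, regions, s2.estimate, n_patients, n_tests=n_tests
    )
    sig_rows = table[(table["p_adj"] <= alpha) & (table["fold"] > 1)]
    if sig_rows.empty:
        logger.info("cohort %s: no significantly elevated region; chain truncated", cohort)
        return CatalogEntry(cohort=cohort, stages=stages, truncated=True)
    best_label = sig_rows.sort_values(["rate", "span_bp"], ascending=False).index[0]
    row = table.loc[best_label]
    region_snvs = snvs[
        snvs["kmer"].isin(hot)
        & snvs.apply(
            lambda r: best_label in (regions.labels_at(r["chrom"], int(r["pos"]) - 1) or {UNANNOTATED}),
            axis=1,
        )
    ]
    s3 = stage(
        "region",
        int(row["n_snv"]),
        int(row["span_bp"]),
        s2,
        cohort_rate,
        _stage_logo(region_snvs),
        label=best_label,
    )
    stages.append(s3)
    return CatalogEntry(cohort=cohort, stages=stages)
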