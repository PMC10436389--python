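"""Cross-patient SNV recurrence and recurrence-stratified 11-mer sets.

A *hotspot* is a genomic position mutated in two or more patients; its
recurrence is the number of distinct patients with an SNV there (irrespective
of the alternate allele by default).  An 11-mer family is annotated with the
maximal recurrence observed across its mutated instances, producing nested
recurrence-stratified sets (1+, 2+, 5+, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import KmerFamilyTable
from .rates import RateEstimate, mutation_rate

logger = logging.getLogger(__name__)


def compute_recurrence(snvs: pd.DataFrame, allele_aware: bool = False) -> pd.Series:
    """Distinct-patient count per mutated position.

    ``snvs`` needs ``patient``, ``chrom`` and ``pos`` columns (plus ``alt``
    when ``allele_aware``).  A patient contributes at most once per position
    (or per position+allele in allele-aware mode, where the position recurrence
    is the maximum over alleles).
    """
    if allele_aware:
        per_allele = snvs.groupby(["chrom", "pos", "alt"])["patient"].nunique()
        return per_allele.groupby(level=["chrom", "pos"]).max().rename("recurrence")
    return (
        snvs.groupby(["chrom", "pos"])["patient"].nunique().rename("recurrence")
    )


@dataclass(frozen=True)
class StratifiedSet:
    level: int
    kmers: frozenset[str]
    span_bp: int
    n_snv: int


@dataclass
class RecurrenceStratifiedSets:
    """Nested 11-mer sets keyed by minimal instance recurrence."""

    levels: dict[int, StratifiedSet]
    family_recurrence: pd.Series  # kmer -> max recurrence over mutated instances

    def __getitem__(self, level: int) -> StratifiedSet:
        return self.levels[level]


def stratify_by_recurrence(
    recurrence: pd.Series,
    snvs: pd.DataFrame,
    family_table: KmerFamilyTable,
    levels: tuple[int, ...] = (1, 2, 5),
) -> RecurrenceStratifiedSets:
    """Build recurrence-stratified 11-mer sets.

    ``snvs`` must carry a ``kmer`` column (canonical 11-mer of each SNV; rows
    with missing kmers — N context or contig edge — are dropped with a log
    entry).  Set spans are sums of family instance counts from the genome-wide
    family table; SNV totals count all SNVs in member families.
    """
    work = snvs.dropna(subset=["kmer"])
    n_dropped = len(snvs) - len(work)
    if n_dropped:
        logger.info("dropped %d SNVs without a canonical 11-mer context", n_dropped)
    rec = work.join(recurrence, on=["chrom", "pos"])
    fam_rec = rec.groupby("kmer")["recurrence"].max()
    snv_per_family = work.groupby("kmer").size()
    out: dict[int, StratifiedSet] = {}
    for level in sorted(levels):
        members = frozenset(fam_rec.index[fam_rec >= level])
        span = sum(family_table.count(m) for m in members)
        n_snv = int(snv_per_family.reindex(list(members)).fillna(0).sum())
        out[level] = StratifiedSet(level, members, span, n_snv)
    return RecurrenceStratifiedSets(levels=out, family_recurrence=fam_rec)


def signature_enrichment_by_recurrence(
    posteriors: pd.DataFrame,
    snv_recurrence: pd.Series,
    max_level: int = 7,
) -> pd.DataFrame:
    """log2 fold-change of mean signature posterior versus singleton SNVs.

    ``posteriors`` is SNVs x signatures; ``snv_recurrence`` gives each SNV's
    position recurrence (same index).  Levels are binned 1, 2, ..., with the
    top bin collecting ``max_level`` and above ("7+" by default).  The value is
    0 at recurrence 1 by construction; empty bins yield NaN (flagged).
    """
    levels = np.minimum(snv_recurrence.to_numpy(), max_level)
    frame = posteriors.copy()
    frame["_level"] = levels
    means = frame.groupby("_level").mean()
    if 1 not in means.index:
        raise ValueError("no singleton (recurrence 1) SNVs to normalize against")
    base = means.loc[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.log2(means.div(base, axis=1))
    enr.index = [f"{int(l)}+" if l == max_level else str(int(l)) for l in enr.index]
    n_empty = int(enr.isna().any(axis=1).sum())
    if n_empty:
        logger.info("%d recurrence bins contain signatures with empty/zero means", n_empty)
    return enr


def ascertainment_control_rate(
    stratified: StratifiedSet,
    snvs: pd.DataFrame,
    recurrence: pd.Series,
    n_patients: int,
) -> RateEstimate:
    """Set rate after excluding the hotspot SNVs that defined the set.

    SNVs at positions whose recurrence reaches the set's level are removed;
    the genomic span is unchanged, so a surviving elevation cannot be an
    artifact of selecting the set on those same mutations.
    """
    work = snvs.dropna(subset=["kmer"])
    in_set = work["kmer"].isin(stratified.kmers)
    rec = work.join(recurrence, on=["chrom", "pos"])["recurrence"].fillna(0)
    if stratified.level >= 2:
        keep = in_set & (rec < stratified.level)
    else:
        keep = in_set
    return mutation_rate(int(keep.sum()), n_patients, stratified.span_bp)
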