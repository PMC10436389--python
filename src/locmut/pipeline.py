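"""End-to-end orchestration: from FASTA + SNV catalog + signature inputs to
the nested localized-mutational-process catalog, with a run manifest.

All stages are deterministic given the inputs; the single seed recorded in
the manifest only matters when the pipeline is asked to simulate its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genome import GenomeSequence, canonical_context, count_kmer_families
from .hotspots import compute_recurrence, stratify_by_recurrence
from .rates import mutation_rate
from .regions import RegionAnnotationSet, nested_decomposition, region_rate_table
from .signatures import (
    define_exposure_cohorts,
    mutation_type_of,
    read_exposures,
    read_signature_matrix,
    snv_posteriors,
    assign_kmers_to_signatures,
)

logger = logging.getLogger(__name__)

SNV_COLUMNS = ["patient", "chrom", "pos", "ref", "alt"]


class SnvValidationError(ValueError):
    """An SNV row contradicts the reference genome (carries the line number)."""


def read_snvs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNV table is missing columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    return df


def annotate_snvs(genome: GenomeSequence, snvs: pd.DataFrame, k: int = 11) -> pd.DataFrame:
    """Add SBS96 mutation type and canonical k-mer context columns.

    Raises ``SnvValidationError`` (with the 1-based data line number) when a
    row's reference base contradicts the genome.  Rows whose context window
    leaves the contig or spans N get missing type/kmer values and are excluded
    from downstream posterior and motif analyses.
    """
    mtypes: list[str | None] = []
    kmers: list[str | None] = []
    for i, row in enumerate(snvs.itertuples(index=False)):
        contig, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        if contig not in genome.contigs:
            raise SnvValidationError(f"line {i + 2}: unknown contig {contig!r}")
        seq = genome.contigs[contig]
        if not 1 <= pos <= len(seq):
            raise SnvValidationError(f"line {i + 2}: position {pos} outside {contig}")
        if seq[pos - 1] != ref.upper():
            raise SnvValidationError(
                f"line {i + 2}: reference mismatch at {contig}:{pos} "
                f"(genome {seq[pos - 1]!r}, SNV {ref!r})"
            )
        try:
            mtypes.append(mutation_type_of(genome, contig, pos, ref, alt))
        except ValueError:
            mtypes.append(None)
        ctx = canonical_context(genome, contig, pos, k)
        kmers.append(ctx[0] if ctx is not None else None)
    out = snvs.copy()
    out["mtype"] = mtypes
    out["kmer"] = kmers
    return out


@dataclass
class RunConfig:
    fasta: str
    snv: str
    signatures: str
    exposures: str
    regions: str
    cohort: str
    outdir: str
    contigs: tuple[str, ...] | None = None
    k: int = 11
    exposure_threshold: float = 0.05
    recurrence_levels: tuple[int, ...] = (1, 2, 5)
    hotspot_level: int = 2
    alpha_levels: tuple[float, ...] = (1e-2, 1e-5, 1e-9)
    n_tests: int | None = None  # None: count of comparisons performed in the run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("k must be odd and positive")
        if not 0 <= self.exposure_threshold <= 1:
            raise ValueError("exposure threshold must lie in [0, 1]")


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write TSV intermediates plus a JSON manifest.

    Returns the manifest dictionary.  A stage failure aborts with a
    stage-named diagnostic; outputs written so far are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "cohort": config.cohort,
            "k": config.k,
            "exposure_threshold": config.exposure_threshold,
            "recurrence_levels": list(config.recurrence_levels),
            "hotspot_level": config.hotspot_level,
            "seed": config.seed,
        },
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def fail(stage: str, exc: Exception) -> None:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        genome = GenomeSequence.from_fasta(config.fasta, config.contigs)
        record("load_genome", contigs=len(genome.contigs), bp=genome.total_length())
    except Exception as exc:  # noqa: BLE001
        fail("load_genome", exc)

    try:
        table = count_kmer_families(genome, config.k)
        table.to_tsv(out / "kmer_table.tsv")
        record("count_kmers", families=len(table.families), span=table.total_span)
    except Exception as exc:  # noqa: BLE001
        fail("count_kmers", exc)

    try:
        snvs = read_snvs(config.snv)
        snvs = annotate_snvs(genome, snvs, config.k)
        record("annotate_snvs", snvs=len(snvs), with_context=int(snvs["kmer"].notna().sum()))
    except Exception as exc:  # noqa: BLE001
        fail("annotate_snvs", exc)

    try:
        signatures = read_signature_matrix(config.signatures)
        exposures = read_exposures(config.exposures)
        cohorts = define_exposure_cohorts(exposures, config.exposure_threshold)
        if config.cohort not in cohorts:
            raise ValueError(f"cohort signature {config.cohort!r} not in exposure matrix")
        patients = cohorts[config.cohort]
        cohort_snvs = snvs[snvs["patient"].isin(patients)].reset_index(drop=True)
        record("cohort", patients=len(patients), snvs=len(cohort_snvs))
        if cohort_snvs.empty:
            raise ValueError("cohort has no SNVs")
    except Exception as exc:  # noqa: BLE001
        fail("cohort", exc)

    try:
        usable = cohort_snvs.dropna(subset=["mtype", "kmer"]).reset_index(drop=True)
        posteriors = snv_posteriors(usable["mtype"], usable["patient"], exposures, signatures)
        assignment = assign_kmers_to_signatures(usable, posteriors)
        assignment.to_csv(out / "assignments.tsv", sep="\t")
        assigned = set(assignment.index[assignment["assigned"] == config.cohort])
        record("assign", families=len(assignment), assigned_to_cohort=len(assigned))
    except Exception as exc:  # noqa: BLE001
        fail("assign", exc)

    try:
        recurrence = compute_recurrence(usable)
        stratified = stratify_by_recurrence(
            recurrence, usable, table, levels=config.recurrence_levels
        )
        strat_rows = []
        for level, s in stratified.levels.items():
            est = mutation_rate(s.n_snv, len(patients), s.span_bp) if s.span_bp else None
            strat_rows.append(
                {
                    "level": f"{level}+",
                    "n_kmers": len(s.kmers),
                    "span_bp": s.span_bp,
                    "n_snv": s.n_snv,
                    "rate": est.rate if est else float("nan"),
                }
            )
        pd.DataFrame(strat_rows).to_csv(out / "recurrence_sets.tsv", sep="\t", index=False)
        record("hotspots", positions=len(recurrence), hotspots=int((recurrence >= 2).sum()))
    except Exception as exc:  # noqa: BLE001
        fail("hotspots", exc)

    try:
        regions = RegionAnnotationSet.from_bed(config.regions)
        n_tests = config.n_tests if config.n_tests is not None else max(
            1, len(regions.labels) + 3
        )
        entry = nested_decomposition(
            genome,
            usable,
            table,
            assigned,
            stratified,
            regions,
            n_patients=len(patients),
            cohort=config.cohort,
            hotspot_level=config.hotspot_level,
            n_tests=n_tests,
        )
        entry.to_frame().to_csv(out / "catalog.tsv", sep="\t", index=False)
        for st in entry.stages:
            if st.logo is not None:
                st.logo.to_tsv(out / f"logo_{st.name}.tsv")
        hot = set(stratified[config.hotspot_level].kmers) & assigned
        if hot:
            hot_est = mutation_rate(
                int(usable["kmer"].isin(hot).sum()),
                len(patients),
                sum(table.count(m) for m in hot),
            )
            region_rate_table(
                genome, config.k, hot, usable, regions, hot_est,
                len(patients), n_tests=n_tests,
            ).to_csv(out / "region_rates.tsv", sep="\t")
        record("catalog", stages=len(entry.stages), truncated=entry.truncated)
    except Exception as exc:  # noqa: BLE001
        fail("catalog", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
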