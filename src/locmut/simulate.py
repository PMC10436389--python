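"""Synthetic genomes, cohorts and SNV catalogs with planted localized
mutational processes and full ground truth.

The generative model inverts the signature-background construction used in
the analysis: each patient receives a Poisson number of mutations; every
mutation draws a signature from the patient's exposures, a trinucleotide
mutation type from that signature's SBS96 profile, and then a genomic
position uniformly among windows whose canonical center trinucleotide matches
the type — except that positions whose canonical 11-mer matches a *planted
motif* (optionally restricted to a region label) are weighted up by a fold
multiplier when the drawing signature is the planted process's signature.
Hotspots are therefore emergent: a high local rate produces cross-patient
recurrence, never the other way round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    GenomeSequence,
    canonical_code_track,
    decode_kmer,
    encode_kmer,
)
from .regions import RegionAnnotationSet, UNANNOTATED
from .signatures import (
    MUTATION_TYPES_96,
    SignatureProfile,
    alt_of_type,
    trinuc_of_type,
)

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGT", "TGCA")


def motif_matches(kmer: str, motif: str) -> bool:
    """True when the IUPAC motif occurs in the canonical k-mer at an offset
    that covers the center (mutated) position."""
    k, lm = len(kmer), len(motif)
    center = k // 2
    for off in range(k - lm + 1):
        if not off <= center < off + lm:
            continue
        if all(kmer[off + j] in IUPAC[motif[j]] for j in range(lm)):
            return True
    return False


@dataclass(frozen=True)
class PlantedRepeat:
    unit: str
    copies: int
    contig: str = "chr1"
    start: int | None = None  # placed by the generator when None
    region: str | None = None  # place inside this region label's block


@dataclass(frozen=True)
class PlantedProcess:
    signature: str
    motif: str
    fold: float
    region: str | None = None

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold multipliers must be >= 1")
        if len(self.motif) > 11:
            raise ValueError("motif length must be <= 11")
        if any(ch not in IUPAC for ch in self.motif):
            raise ValueError(f"motif {self.motif!r} has non-IUPAC characters")


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    n_contigs: int = 1
    base_composition: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    region_labels: tuple[tuple[str, float], ...] = ()
    n_patients: int = 200
    per_patient_burden: float = 30.0
    signatures: tuple[SignatureProfile, ...] = ()
    exposure_model: tuple = ("dirichlet", 2.0)  # or ("fixed", (w1, w2, ...))
    planted_processes: tuple[PlantedProcess, ...] = ()
    seed: int = 0
    k: int = 11

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if sum(f for _, f in self.region_labels) > 1.0 + 1e-9:
            raise ValueError("region fractions exceed 1")
        sig_ids = {s.id for s in self.signatures}
        for proc in self.planted_processes:
            if proc.signature not in sig_ids:
                raise ValueError(f"planted process references unknown signature {proc.signature}")


@dataclass
class TruthRecord:
    """Ground truth of a simulation: per-process attribution and totals."""

    process_counts: dict[str, int]
    signature_counts: dict[str, int]
    total_snvs: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "process_counts": self.process_counts,
                    "signature_counts": self.signature_counts,
                    "total_snvs": self.total_snvs,
                },
                fh,
                indent=2,
            )


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeSequence
    regions: RegionAnnotationSet
    exposures: pd.DataFrame
    snvs: pd.DataFrame  # patient, chrom, pos (1-based), ref, alt, truth_signature
    truth: TruthRecord
    repeat_loci: list[tuple[str, int, int]]


def flat_signature(sig_id: str = "sig_flat") -> SignatureProfile:
    """Uniform distribution over the 96 mutation types."""
    probs = pd.Series(1.0 / 96, index=list(MUTATION_TYPES_96))
    return SignatureProfile(sig_id, probs)


def focused_signature(sig_id: str, type_probs: dict[str, float]) -> SignatureProfile:
    probs = pd.Series(0.0, index=list(MUTATION_TYPES_96))
    for mtype, p in type_probs.items():
        probs[mtype] = p
    return SignatureProfile(sig_id, probs)


def default_scenario(seed: int = 0) -> SimulationConfig:
    """The package's reference planted scenario.

    A 1 Mb genome at hg19-like base composition carries a tandem
    GAAACTTCTTT x 200 repeat array inside a 'repeat' region; a localized
    signature (mass on A[C>T]T and C[T>G]T) mutates AAACTT-matching 11-mers at
    8-fold the rate of other compatible contexts, across a 200-patient cohort
    with mixed exposures and a mean burden of 30 SNVs per patient.
    """
    sig_loc = focused_signature("sig_localized", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
    return SimulationConfig(
        genome_length=1_000_000,
        base_composition=(0.295, 0.205, 0.205, 0.295),
        planted_repeats=(PlantedRepeat("GAAACTTCTTT", 200, region="repeat"),),
        region_labels=(("repeat", 0.005), ("heterochromatin", 0.4), ("euchromatin", 0.595)),
        n_patients=200,
        per_patient_burden=30.0,
        signatures=(flat_signature("sig_background"), sig_loc),
        exposure_model=("dirichlet", 2.0),
        planted_processes=(PlantedProcess("sig_localized", "AAACTT", 8.0),),
        seed=seed,
    )


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeSequence, RegionAnnotationSet, list[tuple[str, int, int]]]:
    """I.i.d. genome at the configured base composition with planted repeat
    arrays and tiled region labels."""
    per_contig = config.genome_length // config.n_contigs
    contigs: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    blocks: dict[tuple[str, str], tuple[int, int]] = {}
    for ci in range(config.n_contigs):
        name = f"chr{ci + 1}"
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=per_contig,
                           p=list(config.base_composition))
        contigs[name] = bases.tobytes().decode("ascii")
        offset = 0
        for label, frac in config.region_labels:
            size = int(round(frac * per_contig))
            if size > 0:
                intervals.append((name, offset, min(offset + size, per_contig), label))
                blocks[(name, label)] = (offset, min(offset + size, per_contig))
            offset += size
    regions = RegionAnnotationSet(intervals)

    loci: list[tuple[str, int, int]] = []
    for rep in config.planted_repeats:
        array = rep.unit * rep.copies
        contig = rep.contig
        seq = contigs[contig]
        if rep.start is not None:
            start = rep.start
        elif rep.region is not None:
            lo, hi = blocks[(contig, rep.region)]
            if hi - lo < len(array):
                raise ValueError(f"region {rep.region} too small for repeat array")
            start = int(rng.integers(lo, hi - len(array) + 1))
        else:
            start = int(rng.integers(0, len(seq) - len(array) + 1))
        if start + len(array) > len(seq):
            raise ValueError("repeat array runs off the contig")
        contigs[contig] = seq[:start] + array + seq[start + len(array):]
        loci.append((contig, start, start + len(array)))
    return GenomeSequence(contigs), regions, loci


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient signature exposure fractions (rows sum to 1)."""
    if not config.signatures:
        raise ValueError("at least one signature is required")
    sig_ids = [s.id for s in config.signatures]
    n, s = config.n_patients, len(sig_ids)
    kind = config.exposure_model[0]
    if kind == "fixed":
        w = np.asarray(config.exposure_model[1], dtype=float)
        w = w / w.sum()
        mat = np.tile(w, (n, 1))
    elif kind == "dirichlet":
        alpha = float(config.exposure_model[1])
        mat = rng.dirichlet([alpha] * s, size=n)
    else:
        raise ValueError(f"unknown exposure model {kind!r}")
    patients = [f"P{i:04d}" for i in range(n)]
    return pd.DataFrame(mat, index=patients, columns=sig_ids)


@dataclass
class _GenomeIndex:
    """Per-position lookups used by the sampler and by fold recovery."""

    contigs: list[str]
    offsets: np.ndarray  # global offset of each contig's window track
    tri_codes: np.ndarray  # canonical center trinuc code per global position, -1 invalid
    kmer_codes: np.ndarray  # canonical 11-mer code per global position, -1 invalid
    positions: np.ndarray  # 0-based center position within contig
    contig_idx: np.ndarray


def _build_index(genome: GenomeSequence, k: int) -> _GenomeIndex:
    contigs, tri_list, kmer_list, pos_list, cidx_list, offsets = [], [], [], [], [], []
    off = 0
    for i, (name, seq) in enumerate(genome.contigs.items()):
        contigs.append(name)
        offsets.append(off)
        track = canonical_code_track(seq, k)
        tri_track = canonical_code_track(seq, 3)
        half, tri_half = k // 2, 1
        n = track.size
        centers = np.arange(n) + half
        # align the trinuc track to 11-mer window centers
        tri_at_center = np.full(n, -1, dtype=np.int64)
        tri_idx = centers - tri_half
        ok = (tri_idx >= 0) & (tri_idx < tri_track.size)
        tri_at_center[ok] = tri_track[tri_idx[ok]]
        valid = (track >= 0) & (tri_at_center >= 0)
        tri_list.append(tri_at_center[valid])
        kmer_list.append(track[valid])
        pos_list.append(centers[valid])
        cidx_list.append(np.full(int(valid.sum()), i, dtype=np.int32))
        off += int(valid.sum())
    return _GenomeIndex(
        contigs=contigs,
        offsets=np.array(offsets, dtype=np.int64),
        tri_codes=np.concatenate(tri_list) if tri_list else np.empty(0, np.int64),
        kmer_codes=np.concatenate(kmer_list) if kmer_list else np.empty(0, np.int64),
        positions=np.concatenate(pos_list) if pos_list else np.empty(0, np.int64),
        contig_idx=np.concatenate(cidx_list) if cidx_list else np.empty(0, np.int32),
    )


def _motif_mask(index: _GenomeIndex, motif: str, k: int) -> np.ndarray:
    """Positions whose canonical k-mer matches the motif over the center."""
    lm = len(motif)
    center = k // 2
    mask = np.zeros(index.kmer_codes.size, dtype=bool)
    for off in range(k - lm + 1):
        if not off <= center < off + lm:
            continue
        sub = np.ones(index.kmer_codes.size, dtype=bool)
        for j, ch in enumerate(motif):
            digit = (index.kmer_codes >> (2 * (k - 1 - (off + j)))) & 3
            allowed = np.array(["ACGT".index(b) for b in IUPAC[ch]])
            sub &= np.isin(digit, allowed)
            if not sub.any():
                break
        mask |= sub
    return mask


def _region_mask(
    index: _GenomeIndex, regions: RegionAnnotationSet, label: str, genome: GenomeSequence
) -> np.ndarray:
    mask = np.zeros(index.positions.size, dtype=bool)
    for i, name in enumerate(index.contigs):
        sel = index.contig_idx == i
        base_mask = regions.label_mask(name, len(genome.contigs[name]), label)
        mask[sel] = base_mask[index.positions[sel]]
    return mask


def process_match_mask(
    genome: GenomeSequence,
    regions: RegionAnnotationSet,
    process: PlantedProcess,
    k: int = 11,
    index: _GenomeIndex | None = None,
) -> tuple[_GenomeIndex, np.ndarray]:
    """Boolean mask of genome positions targeted by a planted process."""
    if index is None:
        index = _build_index(genome, k)
    mask = _motif_mask(index, process.motif, k)
    if process.region is not None:
        mask &= _region_mask(index, regions, process.region, genome)
    return index, mask


def simulate_snvs(
    genome: GenomeSequence,
    exposures: pd.DataFrame,
    signatures: tuple[SignatureProfile, ...],
    planted_processes: tuple[PlantedProcess, ...],
    per_patient_burden: float,
    rng: np.random.Generator,
    regions: RegionAnnotationSet | None = None,
    k: int = 11,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw an SNV catalog from the generative model; see module docstring."""
    if regions is None:
        regions = RegionAnnotationSet([])
    index = _build_index(genome, k)
    if index.positions.size == 0:
        raise ValueError("genome has no valid windows")
    sig_ids = [s.id for s in signatures]
    profile = {s.id: s.probs for s in signatures}

    # per-signature position weights (fold multipliers stack multiplicatively)
    weights: dict[str, np.ndarray] = {}
    proc_masks: list[np.ndarray] = []
    for proc in planted_processes:
        _, m = process_match_mask(genome, regions, proc, k=k, index=index)
        proc_masks.append(m)
        w = weights.setdefault(proc.signature, np.ones(index.positions.size))
        w[m] *= proc.fold

    # order positions by trinuc class once
    order = np.argsort(index.tri_codes, kind="stable")
    tri_sorted = index.tri_codes[order]
    uniq, first = np.unique(tri_sorted, return_index=True)
    bounds = np.append(first[1:], tri_sorted.size)
    class_bounds = {int(t): (int(lo), int(hi)) for t, lo, hi in zip(uniq, first, bounds)}

    tri_code_of = {mtype: encode_kmer(trinuc_of_type(mtype)) for mtype in MUTATION_TYPES_96}

    # per-patient burdens and signature draws
    burdens = rng.poisson(per_patient_burden, size=len(exposures))
    pat_ids = np.repeat(np.arange(len(exposures)), burdens)
    expo = exposures[sig_ids].to_numpy()
    expo = expo / expo.sum(axis=1, keepdims=True)
    u = rng.random(pat_ids.size)
    cum = np.cumsum(expo, axis=1)
    sig_draw = (u[:, None] > cum[pat_ids]).sum(axis=1)

    # mutation type per draw, from the drawn signature's profile
    type_idx = np.empty(pat_ids.size, dtype=np.int64)
    for si, sid in enumerate(sig_ids):
        sel = np.nonzero(sig_draw == si)[0]
        if sel.size == 0:
            continue
        probs = profile[sid].to_numpy()
        type_idx[sel] = rng.choice(96, size=sel.size, p=probs)

    # positions per (signature, trinuc-class) group
    chosen = np.full(pat_ids.size, -1, dtype=np.int64)
    dropped_mass = 0
    for si, sid in enumerate(sig_ids):
        sig_w = weights.get(sid)
        for t_idx in range(96):
            sel = np.nonzero((sig_draw == si) & (type_idx == t_idx))[0]
            if sel.size == 0:
                continue
            tri = tri_code_of[MUTATION_TYPES_96[t_idx]]
            if tri not in class_bounds:
                dropped_mass += sel.size
                continue
            lo, hi = class_bounds[tri]
            cls_positions = order[lo:hi]
            if sig_w is not None and (sig_w[cls_positions] != 1.0).any():
                w = sig_w[cls_positions]
                chosen[sel] = rng.choice(cls_positions, size=sel.size, p=w / w.sum())
            else:
                chosen[sel] = cls_positions[rng.integers(0, cls_positions.size, size=sel.size)]
    if dropped_mass:
        logger.warning(
            "%d drawn mutations fell on trinucleotides absent from the genome and were redrawn as lost",
            dropped_mass,
        )

    ok = chosen >= 0
    pat_ids, sig_draw, type_idx, chosen = pat_ids[ok], sig_draw[ok], type_idx[ok], chosen[ok]

    contig_names = np.array(index.contigs)
    chroms = contig_names[index.contig_idx[chosen]]
    pos0 = index.positions[chosen]
    mtypes = np.array(MUTATION_TYPES_96)[type_idx]
    refs, alts = [], []
    for c, p, mt in zip(chroms, pos0, mtypes):
        base = genome.contigs[c][p]
        alt = alt_of_type(mt)
        if base in "CT":
            refs.append(base)
            alts.append(alt)
        else:
            refs.append(base)
            alts.append(alt.translate(_COMP))
    patients = exposures.index.to_numpy()[pat_ids]

    df = pd.DataFrame(
        {
            "patient": patients,
            "chrom": chroms,
            "pos": pos0 + 1,
            "ref": refs,
            "alt": alts,
            "truth_signature": np.array(sig_ids)[sig_draw],
            "_global_pos": chosen,
        }
    )
    before = len(df)
    df = df.drop_duplicates(subset=["patient", "chrom", "pos"]).reset_index(drop=True)
    if len(df) < before:
        logger.info("deduplicated %d same-patient same-position draws", before - len(df))

    proc_counts: dict[str, int] = {}
    for proc, m in zip(planted_processes, proc_masks):
        hit = (df["truth_signature"] == proc.signature) & m[df["_global_pos"].to_numpy()]
        proc_counts[f"{proc.signature}:{proc.motif}"] = int(hit.sum())
    sig_counts = df["truth_signature"].value_counts().to_dict()
    truth = TruthRecord(
        process_counts=proc_counts,
        signature_counts={str(k_): int(v) for k_, v in sig_counts.items()},
        total_snvs=len(df),
    )
    df = df.drop(columns=["_global_pos"])
    return df, truth


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator under one seeded generator handle."""
    rng = np.random.default_rng(config.seed)
    genome, regions, loci = simulate_genome(config, rng)
    exposures = simulate_cohort(config, rng)
    snvs, truth = simulate_snvs(
        genome,
        exposures,
        config.signatures,
        config.planted_processes,
        config.per_patient_burden,
        rng,
        regions=regions,
        k=config.k,
    )
    return SimulationResult(config, genome, regions, exposures, snvs, truth, loci)


def recovered_fold(
    result: SimulationResult, process: PlantedProcess, truth_only: bool = True
) -> float:
    """Estimate a planted process's fold multiplier from the simulated catalog.

    Standardized rate ratio: per canonical trinucleotide class, motif-matching
    and non-matching positions are compared, and classes are pooled with
    motif-span weights, which removes the trinucleotide composition confound.
    With ``truth_only`` the estimate uses the SNVs the generator attributed to
    the process's signature (ground-truth attribution).
    """
    index, mask = process_match_mask(result.genome, result.regions, process, k=result.config.k)
    snvs = result.snvs
    if truth_only:
        snvs = snvs[snvs["truth_signature"] == process.signature]
    # map SNVs to global positions
    contig_to_idx = {name: i for i, name in enumerate(index.contigs)}
    key = snvs["chrom"].map(contig_to_idx).to_numpy() * (2**33) + (snvs["pos"].to_numpy() - 1)
    gkey = index.contig_idx.astype(np.int64) * (2**33) + index.positions
    sorter = np.argsort(gkey)
    loc = np.searchsorted(gkey, key, sorter=sorter)
    loc = np.clip(loc, 0, gkey.size - 1)
    gpos = sorter[loc]
    ok = gkey[gpos] == key
    gpos = gpos[ok]

    tri = index.tri_codes
    num = 0.0
    den = 0.0
    for t in np.unique(tri[mask]):
        cls = tri == t
        n_mot = int((cls & mask).sum())
        n_non = int((cls & ~mask).sum())
        if n_mot == 0 or n_non == 0:
            continue
        x_mot = int((mask[gpos] & (tri[gpos] == t)).sum())
        x_non = int((~mask[gpos] & (tri[gpos] == t)).sum())
        num += x_mot
        den += x_non * n_mot / n_non
    if den == 0:
        raise ValueError("no non-motif SNVs available to standardize against")
    return num / den


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write FASTA, BED, SNV/exposure TSVs and the truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.genome.to_fasta(out / "genome.fa")
    result.regions.to_bed(out / "regions.bed")
    result.snvs.to_csv(out / "snvs.tsv", sep="\t", index=False)
    result.exposures.to_csv(out / "exposures.tsv", sep="\t")
    sig_df = pd.DataFrame({s.id: s.probs for s in result.config.signatures})
    sig_df.index.name = "mutation_type"
    sig_df.to_csv(out / "signatures.tsv", sep="\t")
    result.truth.to_json(out / "truth.json")
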