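"""SBS96 mutational-signature machinery.

A signature is a probability distribution over the 96 pyrimidine-centered
single-base-substitution types in trinucleotide context (e.g. ``A[C>T]G``).
Per-SNV posterior signature probabilities combine a patient's signature
exposures with the signatures' type priors:

    posterior(s | snv) ~ exposure[patient, s] * P(type(snv) | s)

11-mer families are assigned to signatures by two-level averaging of these
posteriors: first a position-wise mean over the patients mutated at each
genomic position, then a mean over the family's mutated positions; the argmax
signature is the assignment (lexicographic tie-break).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSequence, PURINES, PYRIMIDINES, revcomp

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

MUTATION_TYPES_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)


def trinuc_of_type(mtype: str) -> str:
    """Reference trinucleotide of a mutation type: 5' base + ref + 3' base."""
    return mtype[0] + mtype[2] + mtype[6]


def alt_of_type(mtype: str) -> str:
    return mtype[4]


@dataclass
class SignatureProfile:
    """A named distribution over the 96 mutation types."""

    id: str
    probs: pd.Series  # indexed by mutation-type strings

    def __post_init__(self) -> None:
        self.probs = self.probs.reindex(MUTATION_TYPES_96).fillna(0.0).astype(float)
        total = float(self.probs.sum())
        if (self.probs < 0).any():
            raise ValueError(f"signature {self.id}: negative probabilities")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"signature {self.id}: probabilities sum to {total}")
        self.probs = self.probs / total


def mutation_type_of(
    genome: GenomeSequence, contig: str, pos1: int, ref: str, alt: str
) -> str:
    """SBS96 type of an SNV at a 1-based position, strand-collapsed to the
    pyrimidine reference."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    seq = genome.contigs[contig]
    i = pos1 - 1
    if not 0 <= i < len(seq):
        raise ValueError(f"position {contig}:{pos1} outside contig")
    if seq[i] != ref:
        raise ValueError(
            f"reference mismatch at {contig}:{pos1}: genome has {seq[i]!r}, SNV says {ref!r}"
        )
    if i - 1 < 0 or i + 1 >= len(seq):
        raise ValueError(f"flank outside contig at {contig}:{pos1}")
    five, three = seq[i - 1], seq[i + 1]
    if any(b not in "ACGT" for b in (five, ref, alt, three)):
        raise ValueError(f"non-ACGT base in context at {contig}:{pos1}")
    if ref in PURINES:
        five, ref, alt, three = revcomp(three), revcomp(ref), revcomp(alt), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def cosine_similarity(a: "SignatureProfile | np.ndarray", b: "SignatureProfile | np.ndarray") -> float:
    va = a.probs.to_numpy() if isinstance(a, SignatureProfile) else np.asarray(a, float)
    vb = b.probs.to_numpy() if isinstance(b, SignatureProfile) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("profiles have different dimensions")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def define_exposure_cohorts(
    exposures: pd.DataFrame, threshold: float = 0.05
) -> dict[str, set[str]]:
    """Patients exposed to each signature.

    ``exposures`` is patients x signatures (attributed counts or fractions);
    rows are normalized to fractions of the patient's total burden.  A patient
    joins the cohort of signature s when its load is >= ``threshold``; patients
    may belong to several cohorts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    totals = exposures.sum(axis=1)
    frac = exposures.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    return {
        sig: set(frac.index[frac[sig] >= threshold].tolist())
        for sig in exposures.columns
    }


def snv_signature_posterior(
    mtype: str, patient_exposures: pd.Series, signatures: pd.DataFrame
) -> pd.Series:
    """Posterior over signatures for a single SNV.

    ``signatures`` is the 96 x S prior matrix (rows indexed by type strings).
    Raises ``ValueError`` when the type is impossible under every exposed
    signature (flagged unassignable).
    """
    prior = signatures.loc[mtype]
    expo = patient_exposures.reindex(signatures.columns).fillna(0.0)
    raw = expo * prior
    total = float(raw.sum())
    if total <= 0:
        raise ValueError(f"mutation type {mtype} unassignable under the patient's exposures")
    return raw / total


def snv_posteriors(
    mtypes: pd.Series, patients: pd.Series, exposures: pd.DataFrame, signatures: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized per-SNV posteriors; unassignable SNVs get all-NaN rows."""
    prior = signatures.reindex(mtypes).to_numpy(dtype=float)
    expo = exposures.reindex(columns=signatures.columns).fillna(0.0)
    expo = expo.reindex(patients).to_numpy(dtype=float)
    raw = prior * expo
    totals = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(totals > 0, raw / totals, np.nan)
    n_bad = int((totals <= 0).sum())
    if n_bad:
        logger.warning("%d SNVs unassignable under their patients' exposures", n_bad)
    return pd.DataFrame(post, index=mtypes.index, columns=signatures.columns)


def assign_kmers_to_signatures(
    snvs: pd.DataFrame, posteriors: pd.DataFrame
) -> pd.DataFrame:
    """Assign each mutated 11-mer family to its best-explaining signature.

    ``snvs`` must carry ``kmer``, ``chrom`` and ``pos`` columns aligned with
    the ``posteriors`` rows.  Averaging is two-level: position-wise mean over
    patients first, then mean over the family's mutated positions, so a
    hotspot with many identical SNVs counts as one position.  Returns a frame
    indexed by kmer with the mean posterior per signature plus ``assigned``
    and ``n_snv`` columns.  Ties break to the lexicographically smallest
    signature id (logged).
    """
    keep = posteriors.notna().all(axis=1)
    if not keep.all():
        logger.info("dropping %d unassignable SNVs from 11-mer assignment", int((~keep).sum()))
    work = posteriors.loc[keep].copy()
    meta = snvs.loc[keep, ["kmer", "chrom", "pos"]]
    work = pd.concat([meta, work], axis=1)
    sig_cols = list(posteriors.columns)
    by_pos = work.groupby(["kmer", "chrom", "pos"], sort=False)[sig_cols].mean()
    by_kmer = by_pos.groupby(level="kmer", sort=False).mean()
    n_snv = work.groupby("kmer", sort=False).size().reindex(by_kmer.index)
    mat = by_kmer.to_numpy()
    best = by_kmer.apply(lambda row: min(row.index[row == row.max()]), axis=1)
    n_tied = int((np.isclose(mat, mat.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if n_tied:
        logger.info("%d 11-mer assignments tied; using lexicographic tie-break", n_tied)
    out = by_kmer.copy()
    out["assigned"] = best
    out["n_snv"] = n_snv.astype(int)
    return out


def classify_apobec_kmer(kmer: str) -> str | None:
    """APOBEC3A / APOBEC3B motif class of a canonical 11-mer.

    Requires a TCA core at positions -1..+1 around the mutated cytosine; the
    base at -2 decides the deaminase: pyrimidine (Y) -> A3A, purine (R) -> A3B.
    Returns None for non-TCA cores.
    """
    if len(kmer) != 11 or any(ch not in "ACGT" for ch in kmer):
        raise ValueError("expected a canonical ACGT 11-mer")
    center = 5
    if kmer[center] not in PYRIMIDINES:
        raise ValueError("11-mer is not canonical (center is a purine)")
    if kmer[center - 1 : center + 2] != "TCA":
        return None
    minus2 = kmer[center - 2]
    return "A3A" if minus2 in PYRIMIDINES else "A3B"


def compare_apobec_rates(
    log_rates_a3a: np.ndarray, log_rates_a3b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test on log mutation rates of A3A- vs A3B-motif
    families.  Non-finite values (zero-rate families) are excluded."""
    a = np.asarray(log_rates_a3a, dtype=float)
    b = np.asarray(log_rates_a3b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two finite log rates")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate variance: both samples are constant")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def read_signature_matrix(path) -> pd.DataFrame:
    """96 x S signature matrix from TSV (rows = COSMIC-style type strings)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(MUTATION_TYPES_96) - set(df.index)
    if missing:
        raise ValueError(f"signature matrix is missing {len(missing)} mutation types")
    return df.reindex(list(MUTATION_TYPES_96)).astype(float)


def read_exposures(path) -> pd.DataFrame:
    """Patient x signature exposure matrix from TSV."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)
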