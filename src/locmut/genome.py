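"""Canonical (strand-symmetric) k-mer families over a reference genome.

Every odd-length genomic window and its reverse complement are collapsed into
one *family*, represented by the orientation whose center base is a pyrimidine
(C or T).  For odd k a window and its reverse complement never share a center
pyrimidine, so the 4^k k-mers partition into exactly 4^k/2 families.  Family
instance counts are the genomic spans used as mutation-rate denominators.

Coordinates are 0-based half-open internally; SNV file interfaces are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

# 2-bit encoding: A=0, C=1, G=2, T=3.  Complement is 3-code and a base is a
# pyrimidine iff its code is odd.
_BASES = "ACGT"
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes; -1 for N or any non-ACGT character."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode_kmer(code: int, k: int) -> str:
    return "".join(_BASES[(code >> 2 * (k - 1 - i)) & 3] for i in range(k))


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        c = _CODE_LUT[ord(ch)]
        if c < 0:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        code = (code << 2) | int(c)
    return code


def _decode_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized decode of an int64 code array to a unicode string array."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.empty((codes.size, k), dtype=np.uint8)
    c = codes.astype(np.int64).copy()
    for i in range(k - 1, -1, -1):
        out[:, i] = lut[(c & 3).astype(np.intp)]
        c >>= 2
    return out.reshape(-1).view(f"S{k}").astype(f"U{k}")


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return rc


def canonicalize_kmer(seq: str) -> tuple[str, bool]:
    """Collapse a k-mer and its reverse complement to the center-pyrimidine form.

    Returns ``(canonical, was_reverse_complemented)``.  Raises ``ValueError``
    for even length or non-ACGT characters (including N).
    """
    k = len(seq)
    if k == 0 or k % 2 == 0:
        raise ValueError(f"k-mer length must be odd, got {k}")
    seq = seq.upper()
    if any(ch not in _BASES for ch in seq):
        raise ValueError(f"k-mer contains non-ACGT characters: {seq!r}")
    if seq[k // 2] in PYRIMIDINES:
        return seq, False
    return revcomp(seq), True


@dataclass
class GenomeSequence:
    """Ordered map of contig name -> uppercase DNA string over {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            self.contigs = {}
        clean: dict[str, str] = {}
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            clean[name] = seq.upper()
        self.contigs = clean

    @classmethod
    def from_fasta(cls, path, contigs: Iterable[str] | None = None) -> "GenomeSequence":
        wanted = set(contigs) if contigs is not None else None
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if wanted is None or rec.id in wanted:
                seqs[rec.id] = str(rec.seq).upper()
        if wanted is not None:
            missing = wanted - seqs.keys()
            if missing:
                raise ValueError(f"contigs not found in FASTA: {sorted(missing)}")
        return cls(seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base(self, contig: str, pos0: int) -> str:
        return self.contigs[contig][pos0]


@dataclass(frozen=True)
class KmerInstance:
    """One genomic window belonging to a k-mer family."""

    contig: str
    start: int  # 0-based offset of the window
    pyrimidine_on_plus: bool


def canonical_code_track(seq: str, k: int) -> np.ndarray:
    """Canonical family code for every window of ``seq``; -1 where the window
    contains a non-ACGT base (or no window exists)."""
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd and positive")
    codes = encode_bases(seq).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        seg = codes[j : j + n]
        win = (win << 2) | np.where(seg < 0, 0, seg)
        valid &= seg >= 0
    center = (win >> (2 * (k // 2))) & 3
    rc = _revcomp_codes(win, k)
    canon = np.where(center & 1 == 1, win, rc)
    canon[~valid] = -1
    return canon


@dataclass
class KmerFamilyTable:
    """Canonical k-mer family -> genomic instance count."""

    k: int
    families: dict[str, int]
    total_span: int

    _code_index: dict[int, int] | None = field(default=None, repr=False, compare=False)

    def count(self, kmer: str) -> int:
        return self.families.get(kmer, 0)

    def probability(self, kmer: str) -> float:
        return self.families.get(kmer, 0) / self.total_span

    def code_set(self) -> set[int]:
        return {encode_kmer(m) for m in self.families}

    def trinuc_marginals(self) -> dict[str, float]:
        """P(center trinucleotide) implied by the family table (k >= 3)."""
        if self.k < 3:
            raise ValueError("trinucleotide marginals require k >= 3")
        c = self.k // 2
        out: dict[str, float] = {}
        for kmer, n in self.families.items():
            tri = kmer[c - 1 : c + 2]
            out[tri] = out.get(tri, 0.0) + n
        return {tri: v / self.total_span for tri, v in out.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcount\n")
            for kmer in sorted(self.families):
                fh.write(f"{kmer}\t{self.families[kmer]}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerFamilyTable":
        families: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("kmer"):
                raise ValueError("family table must have a 'kmer\\tcount' header")
            for line in fh:
                kmer, cnt = line.rstrip("\n").split("\t")
                families[kmer] = int(cnt)
        if not families:
            return cls(k=1, families={}, total_span=0)
        k = len(next(iter(families)))
        return cls(k=k, families=families, total_span=sum(families.values()))


def count_kmer_families(genome: GenomeSequence, k: int) -> KmerFamilyTable:
    """Count canonical k-mer families in a single streaming pass.

    Windows containing N (or truncated at contig ends) are excluded from both
    the counts and ``total_span``.
    """
    agg: dict[int, int] = {}
    total = 0
    for seq in genome.contigs.values():
        track = canonical_code_track(seq, k)
        track = track[track >= 0]
        total += track.size
        codes, counts = np.unique(track, return_counts=True)
        for c, n in zip(codes.tolist(), counts.tolist()):
            agg[c] = agg.get(c, 0) + n
    if not agg:
        return KmerFamilyTable(k=k, families={}, total_span=0)
    codes = np.fromiter(agg.keys(), dtype=np.int64, count=len(agg))
    kmers = _decode_codes(codes, k)
    families = {m: agg[c] for m, c in zip(kmers.tolist(), codes.tolist())}
    return KmerFamilyTable(k=k, families=families, total_span=total)


def iter_instances(
    genome: GenomeSequence, k: int, families: set[str] | None = None
) -> Iterator[tuple[str, KmerInstance]]:
    """Yield ``(canonical_kmer, instance)`` for every valid window.

    Intended for small genomes and targeted family subsets; genome-scale code
    paths work on the code tracks directly.
    """
    codes_wanted = {encode_kmer(m) for m in families} if families is not None else None
    for contig, seq in genome.contigs.items():
        track = canonical_code_track(seq, k)
        raw_center = encode_bases(seq)[k // 2 : k // 2 + track.size]
        for start in np.nonzero(track >= 0)[0].tolist():
            code = int(track[start])
            if codes_wanted is not None and code not in codes_wanted:
                continue
            pyr_on_plus = bool(raw_center[start] & 1)
            yield decode_kmer(code, k), KmerInstance(contig, start, pyr_on_plus)


def canonical_context(
    genome: GenomeSequence, contig: str, pos1: int, k: int = 11
) -> tuple[str, bool] | None:
    """Canonical k-mer of the window centered on a 1-based position.

    Returns ``None`` when the window runs off the contig or contains N.
    The flag is True when the pyrimidine orientation is the plus strand.
    """
    seq = genome.contigs[contig]
    half = k // 2
    start = pos1 - 1 - half
    if start < 0 or start + k > len(seq):
        return None
    window = seq[start : start + k]
    try:
        canon, was_rc = canonicalize_kmer(window)
    except ValueError:
        return None
    return canon, not was_rc


def kmer_design_stats(
    k: int,
    total_span: int,
    total_snvs: int | None = None,
    n_families: int | None = None,
) -> tuple[int, float, float | None]:
    """Uniform-model design statistics for choosing k.

    Returns ``(possible_families, expected_instances_per_family,
    expected_snvs_per_family)``.  ``n_families`` overrides the theoretical
    4^k/2 denominator with an observed family count (e.g. the number of
    distinct 11-mers actually present in a reference genome).
    """
    if total_span <= 0:
        raise ValueError("total_span must be positive")
    if k % 2 == 0 or k < 1:
        raise ValueError("k must be odd and positive")
    possible = 4**k // 2
    denom = n_families if n_families is not None else possible
    exp_instances = total_span / denom
    exp_snvs = total_snvs / denom if total_snvs is not None else None
    return possible, exp_instances, exp_snvs
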