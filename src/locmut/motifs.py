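"""Positional composition, KL information logos, signature-induced background
11-mer sets, and a simplified binomial positional/k-mer enrichment test.

Logos use the Kullback-Leibler divergence (in bits) between the observed and
expected base frequency at each position i around the mutated base:

    D_KL(p_i, q_i) = sum_a p_{a,i} * log2(p_{a,i} / q_{a,i})
    height_{a,i}   = p_{a,i} * D_KL(p_i, q_i)

The default expected distribution is the hg19 autosomal base composition
(A = T = 29.5%, C = G = 20.5%).  Signature-specific backgrounds distribute a
signature's trinucleotide mutation-type probabilities over the genomic 11-mer
families compatible with each type:

    P(u in m | s) = P(u | s) * P(m) / P(trinuc(m))
    P(m | s)      = sum over {u : trinuc(u) = trinuc(m)} of P(u in m | s)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import KmerFamilyTable
from .signatures import MUTATION_TYPES_96, SignatureProfile, trinuc_of_type

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: hg19 autosomal base composition used as the default logo background.
GENOME_BASE_FREQS = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}

#: z-score cap corresponding to p = 1e-300 in the positional enrichment test.
Z_CAP = 38.5
_P_FLOOR = 1e-300


def _positions(k: int) -> list[int]:
    half = k // 2
    return list(range(-half, half + 1))


def positional_composition(
    kmers: "list[str] | pd.Series",
    weights: "list[float] | np.ndarray | None" = None,
) -> pd.DataFrame:
    """Weighted per-position base frequencies of a k-mer set.

    Rows are positions relative to the center (0 = mutated base), columns are
    bases; each row sums to 1.  ``weights`` selects the weighting mode: SNV
    counts for mutation-centric logos, genomic instance counts for logos that
    describe an 11-mer set.
    """
    kmers = list(kmers)
    if not kmers:
        raise ValueError("empty k-mer set")
    k = len(kmers[0])
    if any(len(m) != k for m in kmers):
        raise ValueError("k-mers have inconsistent lengths")
    w = np.ones(len(kmers)) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    arr = np.frombuffer("".join(kmers).encode("ascii"), dtype=np.uint8).reshape(len(kmers), k)
    out = np.zeros((k, 4))
    for j, base in enumerate(BASES):
        out[:, j] = ((arr == ord(base)) * w[:, None]).sum(axis=0)
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=_positions(k), columns=list(BASES))


def _as_background_frame(q, positions: list[int]) -> pd.DataFrame:
    """Coerce a background (dict of base freqs, or a positional frame) to a
    positions x bases frame."""
    if isinstance(q, pd.DataFrame):
        return q.reindex(index=positions, columns=list(BASES))
    row = pd.Series(q, dtype=float).reindex(list(BASES))
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValueError("background base frequencies must sum to 1")
    return pd.DataFrame([row] * len(positions), index=positions)


@dataclass
class LogoMatrix:
    """Per-position KL divergence (bits) and per-base letter heights."""

    heights: pd.DataFrame  # positions x bases
    bits: pd.Series  # per position

    def to_tsv(self, path, frequencies: pd.DataFrame | None = None) -> None:
        rows = []
        for pos in self.heights.index:
            for base in BASES:
                rows.append(
                    {
                        "position": pos,
                        "base": base,
                        "frequency": None if frequencies is None else frequencies.loc[pos, base],
                        "height": self.heights.loc[pos, base],
                        "bits": self.bits.loc[pos],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def kl_logo(p: pd.DataFrame, q=GENOME_BASE_FREQS) -> LogoMatrix:
    """KL information logo of an observed composition against a background.

    ``q`` may be a base->frequency mapping (position-independent) or a
    positions x bases frame (e.g. a signature-induced background composition).
    Positions where p > 0 but q = 0 have infinite divergence and are rejected.
    """
    qf = _as_background_frame(q, list(p.index))
    pv = p.to_numpy(dtype=float)
    qv = qf.to_numpy(dtype=float)
    if ((pv > 0) & (qv <= 0)).any():
        raise ValueError("observed mass where the background is zero: infinite divergence")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pv > 0, pv * np.log2(pv / qv), 0.0)
    bits = pd.Series(terms.sum(axis=1), index=p.index, name="bits")
    heights = p.mul(bits, axis=0)
    return LogoMatrix(heights=heights, bits=bits)


def signature_background_set(
    signature: SignatureProfile, family_table: KmerFamilyTable
) -> pd.Series:
    """Distribution over canonical 11-mers induced by a signature's
    trinucleotide profile and genomic 11-mer availability.

    Signature mass on trinucleotides absent from the genome is flagged and the
    remaining distribution renormalized.
    """
    k = family_table.k
    if k < 3:
        raise ValueError("background sets require k >= 3")
    c = k // 2
    kmers = pd.Index(sorted(family_table.families))
    counts = np.array([family_table.families[m] for m in kmers], dtype=float)
    p_m = counts / family_table.total_span
    tri_m = kmers.str.slice(c - 1, c + 2)
    p_tri = pd.Series(p_m).groupby(tri_m.to_numpy()).sum()
    # total signature mass per reference trinucleotide
    t_mass: dict[str, float] = {}
    for mtype in MUTATION_TYPES_96:
        tri = trinuc_of_type(mtype)
        t_mass[tri] = t_mass.get(tri, 0.0) + float(signature.probs[mtype])
    missing_mass = sum(v for tri, v in t_mass.items() if v > 0 and tri not in p_tri.index)
    if missing_mass > 0:
        logger.warning(
            "signature %s puts mass %.4g on trinucleotides absent from the genome; renormalizing",
            signature.id,
            missing_mass,
        )
    tri_mass_arr = np.array([t_mass.get(t, 0.0) for t in tri_m], dtype=float)
    tri_p_arr = p_tri.reindex(tri_m.to_numpy()).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(tri_p_arr > 0, p_m / tri_p_arr * tri_mass_arr, 0.0)
    total = probs.sum()
    if total <= 0:
        raise ValueError("signature has no mass on any genomic trinucleotide")
    return pd.Series(probs / total, index=kmers, name=signature.id)


def background_positional_composition(background: pd.Series) -> pd.DataFrame:
    """Positional base composition induced by a weighted 11-mer set."""
    return positional_composition(list(background.index), background.to_numpy())


def _signed_z(x: int, n: int, q: float) -> tuple[float, float]:
    """Signed z-score and tail p for observing x of n at background prob q."""
    p_enr = float(stats.binom.sf(x - 1, n, q)) if x > 0 else 1.0
    p_dep = float(stats.binom.cdf(x, n, q))
    if p_enr <= p_dep:
        p, sign = p_enr, 1.0
    else:
        p, sign = p_dep, -1.0
    if p < _P_FLOOR:
        return sign * Z_CAP, p
    z = max(0.0, float(stats.norm.isf(p)))  # p > 0.5 means no surprise: z = 0
    return sign * min(z, Z_CAP), p


def positional_enrichment(
    observed: pd.Series,
    background: pd.Series,
    max_k: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial positional/k-mer enrichment of an observed 11-mer set against
    a background 11-mer distribution (simplified pLogo/kpLogo-style test).

    ``observed`` maps k-mers to integer counts; ``background`` maps k-mers to
    probabilities.  Returns ``(base_z, kmer_best)``: per position x base signed
    z-scores, and per start offset the maximally significant sub-k-mer
    (k <= ``max_k``).  |z| is capped at 38.5 (p = 1e-300).
    """
    observed = observed[observed > 0]
    if observed.empty or observed.sum() <= 0:
        raise ValueError("observed set is empty")
    klen = len(observed.index[0])
    n = int(observed.sum())
    positions = _positions(klen)

    arr = np.frombuffer("".join(observed.index).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(observed), klen)
    w = observed.to_numpy(dtype=float)
    bg_comp = background_positional_composition(background)
    base_z = pd.DataFrame(0.0, index=positions, columns=list(BASES))
    for i, pos in enumerate(positions):
        for base in BASES:
            x = int(((arr[:, i] == ord(base)) * w).sum())
            q = float(bg_comp.loc[pos, base])
            q = min(max(q, 1e-12), 1 - 1e-12)
            base_z.loc[pos, base], _ = _signed_z(x, n, q)

    obs_idx = observed.index
    bg_w = background.to_numpy()
    bg_idx = background.index
    rows = []
    for start in range(klen):
        best = None
        for kk in range(1, max_k + 1):
            if start + kk > klen:
                break
            sub_obs = pd.Series(observed.to_numpy()).groupby(
                obs_idx.str.slice(start, start + kk).to_numpy()
            ).sum()
            sub_bg = pd.Series(bg_w).groupby(
                bg_idx.str.slice(start, start + kk).to_numpy()
            ).sum()
            for sub, x in sub_obs.items():
                q = float(sub_bg.get(sub, 0.0))
                q = min(max(q, 1e-12), 1 - 1e-12)
                z, p = _signed_z(int(x), n, q)
                enr = (x / n) / q
                if best is None or abs(z) > abs(best["z"]) or (
                    abs(z) == abs(best["z"]) and p < best["p"]
                ):
                    best = {
                        "start": positions[start],
                        "kmer": sub,
                        "z": z,
                        "p": p,
                        "fold": enr,
                        "count": int(x),
                    }
        if best is not None:
            rows.append(best)
    kmer_best = pd.DataFrame(rows).set_index("start")
    return base_z, kmer_best
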