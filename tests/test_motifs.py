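"""Positional composition, KL logos, signature background sets and the
binomial positional enrichment test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import locmut as lm
from locmut.motifs import Z_CAP, background_positional_composition
from locmut.signatures import MUTATION_TYPES_96, SignatureProfile, trinuc_of_type
from locmut.simulate import flat_signature, focused_signature

from conftest import random_genome


class TestPositionalComposition:
    def test_single_kmer_is_one_hot(self):
        comp = lm.positional_composition(["ACGTACGTACG"])
        for pos, base in zip(comp.index, "ACGTACGTACG"):
            assert comp.loc[pos, base] == 1.0

    def test_equal_weights_split_at_divergent_position(self):
        comp = lm.positional_composition(["AACACACACAC", "TACACACACAC"])
        assert comp.loc[-5, "A"] == 0.5 and comp.loc[-5, "T"] == 0.5
        assert comp.loc[-4, "A"] == 1.0

    def test_matches_weighted_tally_oracle(self):
        rng = np.random.default_rng(6)
        kmers = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(30)]
        weights = rng.integers(1, 10, size=30).astype(float)
        comp = lm.positional_composition(kmers, weights)
        for i, pos in enumerate(range(-2, 3)):
            for base in "ACGT":
                expected = sum(w for m, w in zip(kmers, weights) if m[i] == base) / weights.sum()
                assert comp.loc[pos, base] == pytest.approx(expected)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_rejects_empty_and_zero_weights(self):
        with pytest.raises(ValueError):
            lm.positional_composition([])
        with pytest.raises(ValueError):
            lm.positional_composition(["ACA"], [0.0])


class TestKlLogo:
    def test_zero_bits_when_observed_equals_background(self):
        q = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
        p = pd.DataFrame([pd.Series(q)] * 3, index=[-1, 0, 1])
        logo = lm.kl_logo(p, q)
        assert np.allclose(logo.bits.to_numpy(), 0.0)

    def test_one_hot_against_genome_background(self):
        p = pd.DataFrame(
            [{"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}], index=[0]
        )
        logo = lm.kl_logo(p, lm.GENOME_BASE_FREQS)
        expected = math.log2(1 / 0.295)
        assert logo.bits.loc[0] == pytest.approx(expected, abs=1e-3)
        assert logo.bits.loc[0] == pytest.approx(1.761, abs=1e-3)
        assert logo.heights.loc[0, "A"] == pytest.approx(expected, abs=1e-3)

    def test_heights_sum_to_divergence(self):
        rng = np.random.default_rng(12)
        raw = rng.dirichlet([1, 1, 1, 1], size=7)
        p = pd.DataFrame(raw, index=range(-3, 4), columns=list("ACGT"))
        logo = lm.kl_logo(p, lm.GENOME_BASE_FREQS)
        assert np.allclose(logo.heights.sum(axis=1), logo.bits)

    def test_infinite_divergence_rejected(self):
        p = pd.DataFrame([{"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}], index=[0])
        with pytest.raises(ValueError):
            lm.kl_logo(p, {"A": 0.0, "C": 0.5, "G": 0.25, "T": 0.25})


def background_oracle(signature: SignatureProfile, table: lm.KmerFamilyTable) -> dict[str, float]:
    """Exhaustive re-derivation of P(m|s) with plain dictionaries."""
    total = table.total_span
    p_m = {m: n / total for m, n in table.families.items()}
    c = table.k // 2
    p_tri: dict[str, float] = {}
    for m, p in p_m.items():
        tri = m[c - 1 : c + 2]
        p_tri[tri] = p_tri.get(tri, 0.0) + p
    out = {}
    for m, p in p_m.items():
        tri = m[c - 1 : c + 2]
        mass = sum(
            float(signature.probs[u]) for u in MUTATION_TYPES_96 if trinuc_of_type(u) == tri
        )
        out[m] = p / p_tri[tri] * mass
    z = sum(out.values())
    return {m: v / z for m, v in out.items()}


class TestSignatureBackground:
    def test_single_type_signature_supports_one_trinucleotide(self):
        genome = random_genome(500, seed=21)
        table = lm.count_kmer_families(genome, 11)
        sig = focused_signature("s", {"A[C>T]A": 1.0})
        bset = lm.signature_background_set(sig, table)
        support = bset[bset > 0]
        assert all(m[4:7] == "ACA" for m in support.index)
        # P(m|s) proportional to genomic frequency within the support
        counts = np.array([table.count(m) for m in support.index], dtype=float)
        assert np.allclose(support.to_numpy(), counts / counts.sum())

    def test_matches_exhaustive_oracle_on_toy_genome(self):
        genome = lm.GenomeSequence({"c": "ACGTTGCAAACGTGCATTACGGCTAAGCCA"})
        table = lm.count_kmer_families(genome, 3)
        sig = focused_signature("s", {"A[C>T]G": 0.4, "T[T>G]A": 0.35, "G[C>A]C": 0.25})
        bset = lm.signature_background_set(sig, table)
        oracle = background_oracle(sig, table)
        for m, v in oracle.items():
            assert bset[m] == pytest.approx(v)
        assert bset.sum() == pytest.approx(1.0)

    def test_normalization_for_random_profile_battery(self):
        genome = random_genome(2000, seed=22)
        table = lm.count_kmer_families(genome, 5)
        rng = np.random.default_rng(23)
        for i in range(5):
            probs = pd.Series(rng.dirichlet(np.ones(96)), index=list(MUTATION_TYPES_96))
            bset = lm.signature_background_set(SignatureProfile(f"r{i}", probs), table)
            assert bset.sum() == pytest.approx(1.0)

    def test_center_composition_identity(self):
        """The background set's composition at positions -1..+1 equals the
        signature's trinucleotide distribution reweighted by availability."""
        genome = random_genome(3000, seed=24)
        table = lm.count_kmer_families(genome, 5)
        sig = focused_signature("s", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
        bset = lm.signature_background_set(sig, table)
        comp = background_positional_composition(bset)
        tri_probs = bset.groupby(bset.index.str.slice(1, 4)).sum()
        for offset, col in zip(range(3), (-1, 0, 1)):
            for base in "ACGT":
                expected = sum(p for tri, p in tri_probs.items() if tri[offset] == base)
                assert comp.loc[col, base] == pytest.approx(expected)


class TestPositionalEnrichment:
    def test_small_cases_match_exact_binomial(self):
        rng = np.random.default_rng(31)
        bg_kmers = ["AAACA", "AATCA", "GGGCA", "AAATA"]
        bg = pd.Series([0.4, 0.3, 0.2, 0.1], index=bg_kmers)
        observed = pd.Series(rng.integers(1, 15, size=4), index=bg_kmers)
        base_z, _ = lm.positional_enrichment(observed, bg, max_k=1)
        n = int(observed.sum())
        comp_bg = background_positional_composition(bg)
        for pos in base_z.index:
            for base in "ACGT":
                x = sum(int(c) for m, c in observed.items() if m[pos + 2] == base)
                q = float(np.clip(comp_bg.loc[pos, base], 1e-12, 1 - 1e-12))
                p_enr = stats.binom.sf(x - 1, n, q) if x else 1.0
                p_dep = stats.binom.cdf(x, n, q)
                p_min = min(p_enr, p_dep)
                z = base_z.loc[pos, base]
                if p_min <= 0.5:
                    assert stats.norm.sf(abs(z)) == pytest.approx(p_min, rel=1e-6)
                else:
                    assert z == 0.0

    def test_extreme_enrichment_hits_z_cap(self):
        obs = pd.Series({"AAAACAAAAAA": 200})
        bg_kmers = ["AAAACAAAAAA"] + ["GGGGCGGGGGG"] * 0
        bg = pd.Series({"AAAACAAAAAA": 1e-3, "GGGGCGGGGGG": 1 - 1e-3})
        base_z, kmer_best = lm.positional_enrichment(obs, bg, max_k=4)
        assert kmer_best.loc[-5, "z"] == Z_CAP
        assert (base_z.abs() <= Z_CAP).all().all()

    def test_null_calibration_from_background_draw(self):
        rng = np.random.default_rng(32)
        genome = random_genome(4000, seed=33)
        table = lm.count_kmer_families(genome, 5)
        kmers = sorted(table.families)
        probs = np.array([table.families[m] for m in kmers], dtype=float)
        probs /= probs.sum()
        draw = rng.multinomial(10_000, probs)
        observed = pd.Series(draw, index=kmers)
        bg = pd.Series(probs, index=kmers)
        base_z, _ = lm.positional_enrichment(observed, bg, max_k=1)
        assert base_z.abs().max().max() < 4.0

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            lm.positional_enrichment(pd.Series(dtype=float), pd.Series({"ACA": 1.0}))
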