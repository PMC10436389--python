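"""Shared fixtures: small random genomes and the reference planted scenario.

The planted scenario (1 Mb genome, 200 patients, AAACTT motif at 8-fold) is
expensive enough to share session-wide; everything derived from it is
deterministic under its fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import locmut as lm


def random_genome(length: int, seed: int, n_frac: float = 0.0, name: str = "chr1") -> lm.GenomeSequence:
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length, p=[0.295, 0.205, 0.205, 0.295])
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        bases[mask] = "N"
    return lm.GenomeSequence({name: "".join(bases)})


@pytest.fixture(scope="session")
def tiny_genome() -> lm.GenomeSequence:
    return random_genome(2000, seed=7, n_frac=0.01)


@pytest.fixture(scope="session")
def two_signatures() -> pd.DataFrame:
    """Flat background + localized signature as a 96 x 2 matrix."""
    from locmut.simulate import flat_signature, focused_signature

    bg = flat_signature("sig_background")
    loc = focused_signature("sig_localized", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
    return pd.DataFrame({bg.id: bg.probs, loc.id: loc.probs})


@pytest.fixture(scope="session")
def planted():
    """Reference planted scenario plus the full derived analysis chain."""
    cfg = lm.default_scenario(seed=1)
    res = lm.simulate(cfg)
    table = lm.count_kmer_families(res.genome, 11)
    snvs = lm.annotate_snvs(res.genome, res.snvs, 11)
    sig_df = pd.DataFrame({s.id: s.probs for s in cfg.signatures})
    usable = snvs.dropna(subset=["mtype", "kmer"]).reset_index(drop=True)
    posteriors = lm.snv_posteriors(
        usable["mtype"], usable["patient"], res.exposures, sig_df
    )
    assignment = lm.assign_kmers_to_signatures(usable, posteriors)
    recurrence = lm.compute_recurrence(usable)
    stratified = lm.stratify_by_recurrence(recurrence, usable, table, (1, 2, 5))
    return {
        "config": cfg,
        "result": res,
        "table": table,
        "snvs": usable,
        "signatures": sig_df,
        "posteriors": posteriors,
        "assignment": assignment,
        "recurrence": recurrence,
        "stratified": stratified,
    }
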