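"""Region annotation, per-label rate tables, and the nested decomposition."""

import numpy as np
import pandas as pd
import pytest

import locmut as lm
from locmut.genome import KmerInstance
from locmut.regions import UNANNOTATED, RegionAnnotationSet, annotate_instances

from conftest import random_genome


class TestAnnotation:
    def test_whole_contig_region_labels_everything(self):
        regions = RegionAnnotationSet([("c", 0, 100, "all")])
        instances = [KmerInstance("c", s, True) for s in (0, 10, 80)]
        labels = annotate_instances(instances, regions, k=11)
        assert all(lab == {"all"} for lab in labels)

    def test_half_open_end_boundary(self):
        regions = RegionAnnotationSet([("c", 0, 10, "x")])
        inst_inside = KmerInstance("c", 4, True)  # center 9, inside
        inst_at_end = KmerInstance("c", 5, True)  # center 10 == end, outside
        labels = annotate_instances([inst_inside, inst_at_end], regions, k=11)
        assert labels[0] == {"x"}
        assert labels[1] == {UNANNOTATED}

    def test_matches_interval_scan_oracle(self):
        rng = np.random.default_rng(41)
        intervals = [
            ("c", int(a), int(a) + int(b), lab)
            for a, b, lab in zip(
                rng.integers(0, 900, 20), rng.integers(1, 120, 20),
                rng.choice(["r1", "r2", "r3"], 20),
            )
        ]
        regions = RegionAnnotationSet(intervals)
        instances = [KmerInstance("c", int(s), True) for s in rng.integers(0, 980, 50)]
        labels = annotate_instances(instances, regions, k=11)
        for inst, got in zip(instances, labels):
            center = inst.start + 5
            expected = {
                lab for c, s, e, lab in intervals if c == "c" and s <= center < e
            }
            assert got == (expected if expected else {UNANNOTATED})

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            RegionAnnotationSet([("c", 10, 10, "x")])
        with pytest.raises(ValueError):
            RegionAnnotationSet([("c", 0, 10, "")])

    def test_bed_round_trip(self, tmp_path):
        regions = RegionAnnotationSet([("c", 0, 10, "a"), ("c", 5, 20, "b")])
        path = tmp_path / "regions.bed"
        regions.to_bed(path)
        loaded = RegionAnnotationSet.from_bed(path)
        assert loaded.intervals == regions.intervals
        assert loaded.labels == ["a", "b"]


class TestRegionRateTable:
    def test_single_covering_region_has_fold_one_vs_itself(self):
        genome = random_genome(3000, seed=42)
        table = lm.count_kmer_families(genome, 11)
        regions = RegionAnnotationSet([("chr1", 0, 3000, "all")])
        fams = set(list(table.families)[:50])
        snvs = pd.DataFrame(
            {
                "patient": ["p1"] * 3,
                "chrom": ["chr1"] * 3,
                "pos": [100, 200, 300],
                "kmer": [None] * 3,
            }
        )
        snvs["kmer"] = [
            lm.canonical_context(genome, "chr1", p, 11)[0] for p in snvs["pos"]
        ]
        fams |= set(snvs["kmer"])
        span = sum(table.count(m) for m in fams)
        ref = lm.mutation_rate(3, 1, span)
        out = lm.region_rate_table(genome, 11, fams, snvs, regions, ref, 1)
        assert out.loc["all", "fold"] == pytest.approx(1.0)
        assert out.loc["all", "span_bp"] == span

    def test_region_restricted_planting_recovers_label_fold(self):
        """A process planted at fold 10 only inside one region label shows a
        strong rate elevation in that label and none elsewhere."""
        from locmut.simulate import (
            PlantedProcess, SimulationConfig, flat_signature, focused_signature,
        )

        sig_loc = focused_signature("sig_localized", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
        cfg = SimulationConfig(
            genome_length=300_000,
            region_labels=(("target", 0.3), ("other", 0.7)),
            n_patients=150,
            per_patient_burden=40.0,
            signatures=(flat_signature("sig_background"), sig_loc),
            exposure_model=("fixed", (0.5, 0.5)),
            planted_processes=(PlantedProcess("sig_localized", "AAACTT", 10.0, region="target"),),
            seed=7,
        )
        res = lm.simulate(cfg)
        table = lm.count_kmer_families(res.genome, 11)
        snvs = lm.annotate_snvs(res.genome, res.snvs, 11)
        usable = snvs.dropna(subset=["kmer"])
        # the genome-wide motif 11-mer set (mutated or not), split by label
        from locmut.simulate import motif_matches

        motif_fams = {m for m in table.families if motif_matches(m, "AAACTT")}
        span = sum(table.count(m) for m in motif_fams)
        n_in = int(usable["kmer"].isin(motif_fams).sum())
        ref = lm.mutation_rate(n_in, cfg.n_patients, span)
        out = lm.region_rate_table(
            res.genome, 11, motif_fams, usable, res.regions, ref, cfg.n_patients
        )
        assert out.loc["target", "rate"] > 3 * out.loc["other", "rate"]
        assert out.loc["target", "p"] < 1e-6


class TestNestedDecomposition:
    def test_degenerate_chain_keeps_everything(self):
        """Every stage keeps the whole catalog: all stepwise folds are 1 and,
        since no region is elevated, the chain truncates at three stages."""
        genome = random_genome(300, seed=43, n_frac=0.0)
        table = lm.count_kmer_families(genome, 11)
        length = len(genome.contigs["chr1"])
        rows = []
        for pos1 in range(6, length - 4):  # center of every valid window
            ctx = lm.canonical_context(genome, "chr1", pos1, 11)
            for pat in ("p1", "p2"):  # 2 of 4 patients mutate every position
                rows.append((pat, "chr1", pos1, ctx[0]))
        snvs = pd.DataFrame(rows, columns=["patient", "chrom", "pos", "kmer"])
        rec = lm.compute_recurrence(snvs)
        strat = lm.stratify_by_recurrence(rec, snvs, table, (1, 2))
        assigned = set(snvs["kmer"])  # every family assigned
        regions = RegionAnnotationSet([("chr1", 0, length, "all")])
        entry = lm.nested_decomposition(
            genome, snvs, table, assigned, strat, regions,
            n_patients=4, cohort="test", hotspot_level=2, n_tests=1,
        )
        assert entry.truncated and len(entry.stages) == 3
        for stage in entry.stages:
            assert stage.fold_step == pytest.approx(1.0)
            assert stage.span_bp == table.total_span

    def test_span_monotonic_and_fold_product(self, planted):
        assignment = planted["assignment"]
        assigned = set(assignment.index[assignment["assigned"] == "sig_localized"])
        entry = lm.nested_decomposition(
            planted["result"].genome,
            planted["snvs"],
            planted["table"],
            assigned,
            planted["stratified"],
            planted["result"].regions,
            n_patients=planted["config"].n_patients,
            cohort="sig_localized",
            hotspot_level=2,
            n_tests=817,
        )
        spans = [s.span_bp for s in entry.stages]
        assert spans == sorted(spans, reverse=True)
        product = 1.0
        for s in entry.stages:
            product *= s.fold_step
        assert entry.stages[-1].fold_total == pytest.approx(product, rel=1e-9)
        assert entry.stages[-1].logo is not None

    def test_repeat_restricted_process_completes_chain(self):
        from locmut.simulate import (
            PlantedProcess, PlantedRepeat, SimulationConfig,
            flat_signature, focused_signature,
        )

        sig_loc = focused_signature("sig_localized", {"A[C>T]T": 0.5, "C[T>G]T": 0.5})
        cfg = SimulationConfig(
            genome_length=300_000,
            planted_repeats=(PlantedRepeat("GAAACTTCTTT", 150, region="repeat"),),
            region_labels=(("repeat", 0.01), ("other", 0.99)),
            n_patients=150,
            per_patient_burden=40.0,
            signatures=(flat_signature("sig_background"), sig_loc),
            exposure_model=("fixed", (0.5, 0.5)),
            planted_processes=(PlantedProcess("sig_localized", "AAACTT", 8.0, region="repeat"),),
            seed=11,
        )
        res = lm.simulate(cfg)
        table = lm.count_kmer_families(res.genome, 11)
        snvs = lm.annotate_snvs(res.genome, res.snvs, 11).dropna(subset=["mtype", "kmer"])
        sig_df = pd.DataFrame({s.id: s.probs for s in cfg.signatures})
        post = lm.snv_posteriors(snvs["mtype"], snvs["patient"], res.exposures, sig_df)
        assignment = lm.assign_kmers_to_signatures(snvs.reset_index(drop=True), post.reset_index(drop=True))
        assigned = set(assignment.index[assignment["assigned"] == "sig_localized"])
        rec = lm.compute_recurrence(snvs)
        strat = lm.stratify_by_recurrence(rec, snvs, table, (1, 2))
        entry = lm.nested_decomposition(
            res.genome, snvs, table, assigned, strat, res.regions,
            n_patients=cfg.n_patients, cohort="sig_localized",
            hotspot_level=2, n_tests=817,
        )
        assert not entry.truncated and len(entry.stages) == 4
        assert entry.stages[-1].p_adjusted <= 0.01
        # the planted repeat region is strongly elevated over the cohort baseline
        hot = set(strat[2].kmers) & assigned
        baseline = lm.mutation_rate(len(snvs), cfg.n_patients, table.total_span)
        region_table = lm.region_rate_table(
            res.genome, 11, hot, snvs, res.regions, baseline, cfg.n_patients, n_tests=817
        )
        assert region_table.loc["repeat", "fold"] > 5.0
        assert region_table.loc["repeat", "p_adj"] <= 0.01
        # and the final-stage logo peaks inside the planted motif span
        final_logo = entry.stages[-1].logo
        top3 = set(final_logo.bits.sort_values(ascending=False).index[:3])
        assert top3 <= set(range(-4, 3))
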