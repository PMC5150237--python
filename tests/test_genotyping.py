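"""Amplicon workflow: demultiplexing, chimera and homology filters,
oligotype allele calling, trio checks and repeatability."""

import numpy as np
import pytest

from mhcmate.genotyping import (
    UnresolvableGeneError,
    call_alleles,
    column_entropy,
    demultiplex_and_trim,
    filter_chimeras,
    homology_filter,
    mendelian_check,
    recoverable_genotypes,
    repeatability,
)
from mhcmate.simulate import compose_raw_reads, simulate_reads
from mhcmate.types import GenotypeTable


class TestDemultiplex:
    @pytest.fixture()
    def readset(self, population, catalogs):
        inds = dict(list(population.individuals.items())[:6])
        return simulate_reads(inds, catalogs, "MHC1", depth=40, error_rate=0.0,
                              chimera_rate=0.0, seed=41)

    def test_noiseless_reads_fully_assigned(self, readset):
        raw = compose_raw_reads(readset)
        per, log = demultiplex_and_trim(
            raw, readset.barcode_map, {"MHC1": readset.primer_pair}
        )
        assert log["assigned"] == log["input"] == len(readset.reads)
        for (ind, gene), reads in per.items():
            assert gene == "MHC1"
            truth = [r.sequence for r in readset.reads if r.individual_id == ind]
            assert sorted(reads) == sorted(truth)

    def test_single_barcode_mismatch_discards_read(self, readset):
        raw = compose_raw_reads(readset)
        bad = ("T" if raw[0][0] != "T" else "G") + raw[0][1:]
        per, log = demultiplex_and_trim(
            [bad], readset.barcode_map, {"MHC1": readset.primer_pair}
        )
        assert log["bad_barcode"] == 1 and log["assigned"] == 0

    def test_flank_error_assignment_rate(self, readset):
        """With error rate e over barcode+primers of total length F, the
        assigned fraction is (1-e)^F within binomial noise."""
        e = 0.02
        raw = compose_raw_reads(readset, flank_error_rate=e, seed=42)
        per, log = demultiplex_and_trim(
            raw, readset.barcode_map, {"MHC1": readset.primer_pair}
        )
        flanks = 8 + 2 * 20  # barcode + both primers
        expect = (1 - e) ** flanks
        se = np.sqrt(expect * (1 - expect) / len(raw))
        assert abs(log["assigned"] / len(raw) - expect) < 3 * se

    def test_empty_maps_rejected(self):
        with pytest.raises(ValueError):
            demultiplex_and_trim(["ACGT"], {}, {"G": ("A", "C")})


class TestChimeraFilter:
    def test_most_abundant_never_flagged(self):
        reads = ["AAAA"] * 10 + ["CCCC"] * 5 + ["AACC"] * 1
        retained, flagged = filter_chimeras(reads)
        assert "AAAA" in retained and reads.count("AAAA") == retained.count("AAAA")

    def test_constructed_chimera_flagged(self):
        a = "AAAAAAAAAA"
        b = "CCCCCCCCCC"
        chimera = a[:5] + b[5:]
        reads = [a] * 20 + [b] * 15 + [chimera] * 2
        retained, flagged = filter_chimeras(reads)
        assert flagged == [chimera, chimera]
        assert len(retained) == 35

    def test_noiseless_nonchimeric_reads_unflagged(self, population, catalogs):
        inds = dict(list(population.individuals.items())[:8])
        rs = simulate_reads(inds, catalogs, "MHC1", depth=60, error_rate=0.0,
                            chimera_rate=0.0, seed=43)
        for ind in inds:
            reads = [r.sequence for r in rs.reads if r.individual_id == ind]
            retained, flagged = filter_chimeras(reads)
            assert flagged == []

    def test_point_mutant_not_flagged(self):
        # a read one substitution away from an abundant sequence is an
        # error read, not an exact splice of two parents
        a = "AAAAAAAAAA"
        b = "CCCCCCCCCC"
        mutant = "AAAAATAAAA"
        retained, flagged = filter_chimeras([a] * 20 + [b] * 10 + [mutant])
        assert flagged == []

    def test_partition_and_empty_input(self):
        assert filter_chimeras([]) == ([], [])
        reads = ["AAAA"] * 3 + ["AACC"] * 1 + ["CCCC"] * 2
        retained, flagged = filter_chimeras(reads)
        assert sorted(retained + flagged) == sorted(reads)


class TestHomologyFilter:
    REF = ["MKLV"]

    def test_internal_stop_removed(self):
        # ATG AAA TAA GTG -> M K * V
        retained, log = homology_filter(["ATGAAATAAGTG"], self.REF, 0.5)
        assert retained == [] and log["stop_codon"] == 1

    def test_identical_retained_at_full_identity(self):
        # ATG AAG CTT GTT -> MKLV
        retained, _ = homology_filter(["ATGAAGCTTGTT"], self.REF, 1.0)
        assert retained == ["ATGAAGCTTGTT"]

    def test_boundary_identity_inclusive(self):
        # MKLW: 3/4 identical to MKLV -> retained at exactly 0.75
        read = "ATGAAGCTTTGG"
        assert homology_filter([read], self.REF, 0.75)[0] == [read]
        assert homology_filter([read], self.REF, 0.7501)[0] == []

    def test_bad_frame_logged(self):
        retained, log = homology_filter(["ATGAA"], self.REF, 0.5)
        assert retained == [] and log["bad_frame"] == 1


class TestCallAlleles:
    def test_identical_reads_single_allele(self):
        reads = {f"I{i}": ["ACGTACGT"] * 20 for i in range(4)}
        table, calls, log = call_alleles(reads, "G", min_reads_per_allele=5)
        assert len(calls) == 1
        for i in range(4):
            assert table.get(f"I{i}", "G") == frozenset({calls[0].allele_id})
        assert calls[0].representative_sequence == "ACGTACGT"

    def test_zero_entropy_with_distinct_reads_unresolvable(self):
        # two sequences at 50/50 in every individual: every column entropy
        # ln 2 > threshold normally; force threshold above ln 2
        reads = {f"I{i}": ["AAAA"] * 10 + ["CCCC"] * 10 for i in range(3)}
        with pytest.raises(UnresolvableGeneError):
            call_alleles(reads, "G", entropy_threshold=1.0)

    def test_noiseless_recovery_matches_truth(self, population, catalogs):
        inds = dict(list(population.individuals.items())[:20])
        rs = simulate_reads(inds, catalogs, "MHC1", depth=120, error_rate=0.0,
                            chimera_rate=0.0, seed=44)
        by_ind = {}
        for r in rs.reads:
            by_ind.setdefault(r.individual_id, []).append(r.sequence)
        table, calls, _ = call_alleles(by_ind, "MHC1", entropy_threshold=0.045,
                                       min_reads_per_allele=3,
                                       min_fraction_per_allele=0.03)
        truth = GenotypeTable()
        for ind in inds.values():
            truth.set(ind.id, "MHC1", ind.genotypes["MHC1"])
        target = recoverable_genotypes(truth, "MHC1")
        seq2true = {a.dna: a.allele_id for a in catalogs["MHC1"]}
        name_map = {c.allele_id: seq2true.get(c.representative_sequence) for c in calls}
        for ind in target.individuals("MHC1"):
            called = table.get(ind, "MHC1")
            assert called is not None
            assert {name_map[a] for a in called} == set(target.get(ind, "MHC1"))

    def test_single_individual_allele_removed(self):
        shared = "AAAACCCC"
        private = "TTTTCCCC"
        reads = {"I0": [shared] * 30 + [private] * 30,
                 "I1": [shared] * 30, "I2": [shared] * 30}
        table, calls, log = call_alleles(reads, "G", entropy_threshold=0.05,
                                         min_reads_per_allele=5)
        assert len(calls) == 1
        assert log["oligotypes_single_individual_removed"] == 1
        assert table.get("I0", "G") == frozenset({calls[0].allele_id})

    def test_min_reads_monotonicity(self, population, catalogs):
        """Raising min_reads_per_allele never adds an allele."""
        inds = dict(list(population.individuals.items())[:10])
        rs = simulate_reads(inds, catalogs, "MHC1", depth=60, error_rate=0.002,
                            chimera_rate=0.0, seed=45)
        by_ind = {}
        for r in rs.reads:
            by_ind.setdefault(r.individual_id, []).append(r.sequence)
        lo, _, _ = call_alleles(by_ind, "MHC1", entropy_threshold=0.045,
                                min_reads_per_allele=3, min_fraction_per_allele=0.02)
        hi, _, _ = call_alleles(by_ind, "MHC1", entropy_threshold=0.045,
                                min_reads_per_allele=12, min_fraction_per_allele=0.02)
        for ind in hi.individuals("MHC1"):
            assert hi.get(ind, "MHC1") <= lo.get(ind, "MHC1")

    def test_read_order_invariance(self, population, catalogs, rng):
        inds = dict(list(population.individuals.items())[:8])
        rs = simulate_reads(inds, catalogs, "MHC1", depth=50, error_rate=0.005,
                            chimera_rate=0.02, seed=46)
        by_ind = {}
        for r in rs.reads:
            by_ind.setdefault(r.individual_id, []).append(r.sequence)
        shuffled = {}
        for ind, reads in by_ind.items():
            perm = list(reads)
            rng.shuffle(perm)
            shuffled[ind] = perm
        t1, c1, _ = call_alleles(by_ind, "MHC1", entropy_threshold=0.045)
        t2, c2, _ = call_alleles(shuffled, "MHC1", entropy_threshold=0.045)
        assert {k: v for k, v in t1.items()} == {k: v for k, v in t2.items()}
        assert c1 == c2


class TestMendelian:
    def test_consistent_trio_passes(self):
        gt = GenotypeTable({("o", "G"): {"a", "b"}, ("m", "G"): {"a", "c"},
                            ("f", "G"): {"b", "d"}})
        violations, _, _ = mendelian_check(gt, [("o", "m", "f")])
        assert violations == []

    def test_violation_detected_and_corrected(self):
        gt = GenotypeTable({("o", "G"): {"a", "b", "x"}, ("m", "G"): {"a", "c"},
                            ("f", "G"): {"b", "d"}})
        violations, corrected, _ = mendelian_check(gt, [("o", "m", "f")], correct=True)
        assert len(violations) == 1
        assert violations[0].offending_allele_ids == frozenset({"x"})
        assert corrected.get("o", "G") == frozenset({"a", "b"})

    def test_correction_never_empties_genotype(self):
        gt = GenotypeTable({("o", "G"): {"x"}, ("m", "G"): {"a"}, ("f", "G"): {"b"}})
        violations, corrected, _ = mendelian_check(gt, [("o", "m", "f")], correct=True)
        assert len(violations) == 1
        assert len(corrected.get("o", "G")) == 1

    def test_ungenotyped_member_skipped(self):
        gt = GenotypeTable({("o", "G"): {"a"}, ("m", "G"): {"a"}})
        violations, _, log = mendelian_check(gt, [("o", "m", "f")])
        assert violations == [] and log["skipped"] == 1


class TestRepeatability:
    GT = GenotypeTable({
        ("r1a", "G"): {"a", "b", "c"}, ("r1b", "G"): {"a", "b"},
        ("r2a", "G"): {"a", "b"}, ("r2b", "G"): {"a", "b"},
        ("r3a", "G"): {"a"}, ("r3b", "G"): {"b"},
    })

    def test_jaccard_values(self):
        res = repeatability(self.GT, [("r1a", "r1b")])
        assert res.overall == pytest.approx(2 / 3)
        assert repeatability(self.GT, [("r2a", "r2b")]).overall == 1.0
        assert repeatability(self.GT, [("r3a", "r3b")]).overall == 0.0

    def test_exact_match_method(self):
        res = repeatability(
            self.GT, [("r1a", "r1b"), ("r2a", "r2b")], method="exact"
        )
        assert res.overall == pytest.approx(0.5)

    def test_missing_pair_excluded(self):
        res = repeatability(self.GT, [("r1a", "r1b"), ("r1a", "nope")])
        assert res.n_pairs == 1

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            repeatability(self.GT, [])


def test_column_entropy_basics():
    ent = column_entropy(["AAAA", "AAAC", "AAAG", "AAAT"])
    assert ent[0] == 0.0
    assert ent[3] == pytest.approx(np.log(4))
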