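"""Adapter/UMI parsing, deduplication, classification and spike calibration."""

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pirnaphase.preprocess import (ADAPTER3, SPIKE_SEQUENCES, CalibrationError,
                                   ParsedInsert, ReadRejected, SpeciesCount,
                                   SpikeCalibration, absolute_abundance,
                                   classify_reads, deduplicate,
                                   parse_small_rna_read, parse_reads)
from pirnaphase.simulate import RRNA_2S

INSERT = "TGCTTGGACTACATATGGTTG"
BLOCK5_A = "AAACGAAAATCAAAA"      # umi5 = 9xA, variant A spacers CGA/TCA
BLOCK3 = "CCCGTCCCCTAGCCC"        # umi3 = 9xC, spacers GTC/TAG
GOOD_READ = BLOCK5_A + INSERT + BLOCK3 + ADAPTER3


class TestParse:
    def test_grammar_example(self):
        p = parse_small_rna_read(GOOD_READ)
        assert p == ParsedInsert(INSERT, "A" * 9, "C" * 9, "A")

    def test_variant_b(self):
        read = "GGGATCGGGAGTGGG" + INSERT + BLOCK3 + ADAPTER3
        p = parse_small_rna_read(read)
        assert p.adapter_variant == "B"
        assert p.umi5 == "G" * 9

    def test_missing_adapter_rejected(self):
        with pytest.raises(ReadRejected, match="no_adapter"):
            parse_small_rna_read(BLOCK5_A + INSERT + BLOCK3 + "ACGTACGTACGTACGT")

    def test_empty_insert_rejected(self):
        with pytest.raises(ReadRejected, match="empty_insert"):
            parse_small_rna_read(BLOCK5_A + BLOCK3 + ADAPTER3)

    def test_one_spacer_mismatch_tolerated(self):
        read = BLOCK5_A.replace("CGA", "CGT", 1) + INSERT + BLOCK3 + ADAPTER3
        assert parse_small_rna_read(read).insert == INSERT

    def test_two_spacer_mismatches_rejected(self):
        bad5 = "AAACTTAAATCAAAA"  # CGA -> CTT: two mismatches
        with pytest.raises(ReadRejected, match="bad_umi_structure"):
            parse_small_rna_read(bad5 + INSERT + BLOCK3 + ADAPTER3)

    def test_truncated_adapter_still_found(self):
        read = BLOCK5_A + INSERT + BLOCK3 + ADAPTER3[:12]
        assert parse_small_rna_read(read).insert == INSERT

    def test_simulator_roundtrip_is_exact(self, readset, truth):
        """With no sequencing errors every emitted read parses and the
        inserts match the truth table exactly."""
        parsed, rejections = parse_reads(readset.small_reads)
        assert not rejections
        assert len(parsed) == len(readset.small_reads)
        truth_seq = {sp.species_id: sp.sequence for sp in truth.species}
        by_id = {r.id: p.insert for r, p in zip(readset.small_reads, parsed)}
        small_truth = readset.read_truth[readset.read_truth.read_id.isin(by_id)]
        for row in small_truth.itertuples():
            assert by_id[row.read_id] == truth_seq[row.species_id]


class TestDeduplicate:
    def test_same_umi_pair_collapses(self):
        recs = [ParsedInsert("ACGT", "A" * 9, "C" * 9, "A")] * 2
        assert deduplicate(recs) == [SpeciesCount("ACGT", 1)]

    def test_distinct_umi3_counts_two(self):
        recs = [ParsedInsert("ACGT", "A" * 9, "C" * 9, "A"),
                ParsedInsert("ACGT", "A" * 9, "G" * 9, "A")]
        assert deduplicate(recs) == [SpeciesCount("ACGT", 2)]

    @given(st.permutations(list(range(8))))
    def test_order_independent(self, order):
        recs = [ParsedInsert(f"ACGT{i % 3}", f"{i:09d}"[:9], "C" * 9, "A")
                for i in range(8)]
        assert deduplicate([recs[i] for i in order]) == deduplicate(recs)

    def test_idempotent_under_duplication(self):
        recs = [ParsedInsert("ACGT", f"{i:09d}"[:9], "C" * 9, "A") for i in range(5)]
        assert deduplicate(recs * 3) == deduplicate(recs)

    def test_recovers_truth_counts_without_errors(self, readset, truth):
        """PCR duplicates (same UMI pair) collapse; deduplicated counts equal
        the per-species multinomial read draws recorded in the truth table."""
        parsed, _ = parse_reads(readset.small_reads)
        species = {s.sequence: s.count for s in deduplicate(parsed)}
        truth_sp = {sp.species_id: sp for sp in truth.species}
        expected = defaultdict(int)
        for sid, n in readset.small_species_reads.items():
            expected[truth_sp[sid].sequence] += n
        assert species == dict(expected)


class TestClassify:
    def test_partition(self):
        rrna = {"2S": RRNA_2S}
        spike1 = SPIKE_SEQUENCES["spike1"]
        near_2s = "A" + RRNA_2S[1:25]  # 1 mismatch vs the reference prefix
        random_sp = "CATCATGAGGACCTCTCAGATTACG"
        species = [SpeciesCount(spike1, 9), SpeciesCount(RRNA_2S[:25], 4),
                   SpeciesCount(near_2s, 2), SpeciesCount(random_sp, 1)]
        res = classify_reads(species, rrna, SPIKE_SEQUENCES)
        assert res.spikein["spike1"] == 9
        assert {s.sequence for s in res.rrna} == {RRNA_2S[:25], near_2s}
        assert [s.sequence for s in res.retained] == [random_sp]

    def test_spike_precedence_over_rrna(self):
        seq = SPIKE_SEQUENCES["spike2"]
        res = classify_reads([SpeciesCount(seq, 3)], {"ref": seq}, SPIKE_SEQUENCES)
        assert res.spikein["spike2"] == 3 and not res.rrna

    def test_empty_rrna_refs_rejected(self):
        with pytest.raises(ValueError):
            classify_reads([SpeciesCount("ACGT" * 6, 1)], {})


class TestAbsoluteAbundance:
    CAL = SpikeCalibration((10,) * 6, molecules_per_species=1e6, total_rna_pg=100.0)

    def test_forced_arithmetic(self):
        assert absolute_abundance(5, self.CAL) == pytest.approx(5e4)

    def test_zero_reads_zero_molecules(self):
        assert absolute_abundance(0, self.CAL) == 0.0

    def test_all_zero_counts_uncalibrated(self):
        with pytest.raises(CalibrationError, match="uncalibrated"):
            SpikeCalibration((0,) * 6, 1e6, 100.0)

    @given(st.integers(1, 10_000), st.integers(1, 50))
    def test_linear_and_scale_invariant(self, reads, k):
        base = absolute_abundance(reads, self.CAL)
        assert absolute_abundance(2 * reads, self.CAL) == pytest.approx(2 * base)
        scaled = SpikeCalibration(tuple(10 * k for _ in range(6)), 1e6, 100.0)
        assert absolute_abundance(reads * k, scaled) == pytest.approx(base)

    def test_median_robust_to_one_failed_spike(self):
        cal = SpikeCalibration((10, 10, 10, 10, 10, 0), 1e6, 100.0)
        assert cal.reads_per_molecule == pytest.approx(10 / 1e6)

    def test_simulator_recovery_within_poisson_noise(self, readset, truth, clean_cfg):
        parsed, _ = parse_reads(readset.small_reads)
        species = deduplicate(parsed)
        phased_seqs = {sp.sequence for sp in truth.by_class("phased")}
        target = sum(s.count for s in species if s.sequence in phased_seqs)
        res = classify_reads(species, {"2S": RRNA_2S}, SPIKE_SEQUENCES)
        cal = SpikeCalibration(tuple(res.spikein.values()),
                               clean_cfg.spike_molecules_per_species,
                               clean_cfg.total_rna_pg)
        est = target / cal.reads_per_molecule
        true_m = sum(sp.molecules for sp in truth.by_class("phased"))
        assert abs(est - true_m) <= 3 * np.sqrt(target) / cal.reads_per_molecule
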