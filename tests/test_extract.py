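"""Read QC, split-half extraction, and mismatch-tolerant mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace import (
    HalfMatch,
    ReadRecord,
    assign_barcode,
    assign_reads,
    build_count_table,
    map_half,
    mean_phred,
    qc_filter,
    split_read,
)


def _mutate(seq: str, positions, rng=None):
    """Substitute at given positions, never reproducing the original base."""
    order = "ACGT"
    out = list(seq)
    for k, pos in enumerate(positions):
        out[pos] = order[(order.index(out[pos]) + 1 + k % 3) % 4]
    return "".join(out)


class TestMeanPhred:
    def test_constant_qualities(self):
        assert mean_phred("IIII") == 40.0

    def test_hand_computed_mixture(self):
        # 'I' is Phred 40, '#' is Phred 2 -> mean 21
        assert mean_phred("I#") == 21.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_phred("")

    def test_character_below_offset_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            mean_phred("I I")


class TestQcFilter:
    def test_good_read_passes(self):
        read = ReadRecord("r1", "A" * 40, "I" * 40)
        assert qc_filter(read) == (True, None)

    def test_mean_just_below_threshold_fails(self):
        # 39 bases at Phred 30 ('?') and one at 26 (';') -> mean 29.9
        read = ReadRecord("r1", "A" * 40, "?" * 39 + ";")
        ok, reason = qc_filter(read)
        assert not ok and reason == "low_quality"
        assert mean_phred(read.qualities) == pytest.approx(29.9)

    def test_wrong_length_fails_even_at_high_quality(self):
        read = ReadRecord("r1", "A" * 39, "I" * 39)
        assert qc_filter(read) == (False, "wrong_length")

    def test_low_quality_reported_before_length(self):
        read = ReadRecord("r1", "A" * 39, "#" * 39)
        assert qc_filter(read) == (False, "low_quality")


class TestSplitRead:
    def test_block_sequence(self):
        left, right, linker = split_read("A" * 18 + "CCCC" + "G" * 18)
        assert (left, right, linker) == ("A" * 18, "G" * 18, "CCCC")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=40, max_size=40))
    def test_partition_identity(self, seq):
        left, right, linker = split_read(seq)
        assert left + linker + right == seq

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="40"):
            split_read("A" * 41)


class TestMapHalf:
    def test_exact_hit(self, small_library):
        hit = map_half(small_library.left_modules[4], "L", small_library)
        assert (hit.module_index, hit.mismatches, hit.ambiguous) == (5, 0, False)

    def test_two_mismatches_recovered(self, small_library):
        query = _mutate(small_library.left_modules[4], [0, 9])
        hit = map_half(query, "L", small_library)
        assert (hit.module_index, hit.mismatches) == (5, 2)

    def test_three_mismatches_unmapped(self, small_library):
        # library distance >= 5 guarantees no other module within 2 of this query
        query = _mutate(small_library.right_modules[0], [2, 7, 12])
        hit = map_half(query, "R", small_library)
        assert not hit.mapped and not hit.ambiguous

    def test_tie_is_ambiguous(self):
        from clonetrace.simdata import BarcodeLibrary

        m1 = "ACGTACGTACGTACGTAC"
        m2 = _mutate(m1, [0, 17])  # distance 2 from m1
        lib = BarcodeLibrary((m1, m2), ("T" * 18,))
        # midpoint: mutating position 0 as in m2 leaves 1 mismatch to each module
        mid = _mutate(m1, [0])
        for ref in (m1, m2):
            assert ((np.frombuffer(mid.encode(), np.uint8)
                     != np.frombuffer(ref.encode(), np.uint8)).sum() == 1)
        hit = map_half(mid, "L", lib)
        assert hit.ambiguous and not hit.mapped

    def test_non_acgt_counts_as_mismatch(self, small_library):
        query = "N" + small_library.left_modules[0][1:]
        hit = map_half(query, "L", small_library)
        assert (hit.module_index, hit.mismatches) == (1, 1)

    def test_matches_exhaustive_scan(self, small_library, rng):
        mat = np.frombuffer("".join(small_library.left_modules).encode(),
                            np.uint8).reshape(20, 18)
        for _ in range(300):
            base = small_library.left_modules[rng.integers(0, 20)]
            k = int(rng.integers(0, 4))
            pos = rng.choice(18, size=k, replace=False)
            query = _mutate(base, pos.tolist())
            hit = map_half(query, "L", small_library)
            dists = (mat != np.frombuffer(query.encode(), np.uint8)).sum(axis=1)
            best = dists.min()
            winners = np.flatnonzero(dists == best)
            if best > 2:
                assert not hit.mapped
            elif len(winners) > 1:
                assert hit.ambiguous
            else:
                assert hit.module_index == winners[0] + 1 and hit.mismatches == best


class TestAssignBarcode:
    L5 = HalfMatch("L", 5, 0)
    R9 = HalfMatch("R", 9, 1)
    L_MISS = HalfMatch("L", None, None)
    R_MISS = HalfMatch("R", None, None)
    L_AMB = HalfMatch("L", None, None, ambiguous=True)

    def test_concordant_pair(self):
        assert assign_barcode(self.L5, self.R9) == ("5:9", None)

    def test_one_side_unmapped(self):
        assert assign_barcode(self.L5, self.R_MISS) == (None, "right_unmapped")
        assert assign_barcode(self.L_MISS, self.R9) == (None, "left_unmapped")

    def test_both_unmapped(self):
        assert assign_barcode(self.L_MISS, self.R_MISS) == (None, "both_unmapped")

    def test_ambiguous_dominates_single_miss(self):
        assert assign_barcode(self.L_AMB, self.R9) == (None, "ambiguous")

    def test_sides_enforced(self):
        with pytest.raises(ValueError):
            assign_barcode(self.R9, self.L5)


class TestBuildCountTable:
    def test_single_clone_all_reads(self, small_library, tmp_path):
        seq = small_library.barcode_sequence("5:9")
        path = tmp_path / "s.fastq"
        with open(path, "wt") as fh:
            for i in range(100):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * 40}\n")
        table = build_count_table({"s1": path}, small_library)
        assert table.barcodes == ["5:9"]
        assert table.df.loc["5:9", "s1"] == 100

    def test_empty_fastq(self, small_library, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = build_count_table({"s1": path}, small_library)
        assert len(table.df) == 0
        assert table.qc["s1"] == {
            "total": 0, "assigned": 0,
            "discarded": {r: 0 for r in
                          ("low_quality", "wrong_length", "left_unmapped",
                           "right_unmapped", "both_unmapped", "ambiguous")},
        }

    def test_duplicate_sample_id_rejected(self, small_library, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text("")
        with pytest.raises(ValueError, match="duplicate"):
            build_count_table([("a", str(path)), ("a", str(path))], small_library)

    def test_accounting_invariant(self, small_library, selected_population, fastq_factory):
        path, _ = fastq_factory(selected_population, n_reads=3000,
                                substitution_rate=0.05, fraction_low_quality=0.1,
                                seed=7, name="noisy.fastq")
        table = build_count_table({"s": path}, small_library)
        rec = table.qc["s"]
        assert rec["assigned"] + sum(rec["discarded"].values()) == rec["total"] == 3000

    def test_sample_relabeling_permutes_columns_only(self, small_library,
                                                     selected_population, fastq_factory):
        p1, _ = fastq_factory(selected_population, n_reads=1000, seed=1, name="a.fastq")
        p2, _ = fastq_factory(selected_population, n_reads=1000, seed=2, name="b.fastq")
        t1 = build_count_table([("x", p1), ("y", p2)], small_library)
        t2 = build_count_table([("y", p2), ("x", p1)], small_library)
        assert t1.samples == ["x", "y"] and t2.samples == ["y", "x"]
        assert t1.df.equals(t2.df[["x", "y"]])

    def test_more_mismatches_never_decreases_assignment(self, small_library,
                                                        selected_population,
                                                        fastq_factory):
        path, _ = fastq_factory(selected_population, n_reads=3000,
                                substitution_rate=0.04, seed=8, name="err.fastq")
        assigned = [
            build_count_table({"s": path}, small_library, max_mismatches=m).qc["s"]["assigned"]
            for m in (0, 1, 2)
        ]
        assert assigned[0] <= assigned[1] <= assigned[2]

    def test_truth_recovery_with_errors(self, small_library, selected_population,
                                        fastq_factory):
        path, truth = fastq_factory(selected_population, n_reads=5000,
                                    substitution_rate=0.005, seed=9, name="t.fastq")
        detail = assign_reads(path, small_library)
        merged = detail.merge(truth, on="read_id", suffixes=("_called", "_true"))
        qc_pass = merged[~merged["reason"].isin(["low_quality", "wrong_length"])]
        correct = (qc_pass["barcode_id_called"] == qc_pass["barcode_id_true"]).mean()
        assert correct >= 0.99


def test_min_count_filter(small_library, selected_population, fastq_factory):
    path, _ = fastq_factory(selected_population, n_reads=2000, seed=10, name="mc.fastq")
    loose = build_count_table({"s": path}, small_library, min_count=1)
    strict = build_count_table({"s": path}, small_library, min_count=5)
    assert set(strict.df.index) <= set(loose.df.index)
    assert (strict.df.max(axis=1) >= 5).all()
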