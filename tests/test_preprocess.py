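"""Read cleaning, tag collapsing and library comparison."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saltmir as sm
from saltmir.preprocess import DEFAULT_ADAPTER3, FastqParseError, read_collapsed_fasta, write_collapsed_fasta

AD3 = DEFAULT_ADAPTER3
Q40 = "I"


def _rec(seq, qual=None, title="r"):
    return (title, seq, qual if qual is not None else Q40 * len(seq))


class TestCleanReads:
    def test_adapter_only_read_is_insert_null(self):
        inserts, rep = sm.clean_reads([_rec(AD3 + AD3)])
        assert rep.insert_null == 1 and inserts == []

    def test_good_insert_is_emitted_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
        inserts, rep = sm.clean_reads([_rec(insert + AD3)])
        assert inserts == [insert]
        assert rep.clean_reads == 1

    def test_polya_insert_counted(self):
        inserts, rep = sm.clean_reads([_rec("A" * 20 + AD3)])
        assert rep.polyA == 1 and inserts == []

    def test_low_quality_not_high_quality(self):
        seq = "ACGTACGTACGTACGTACGTA" + AD3
        inserts, rep = sm.clean_reads([_rec(seq, qual=")" * len(seq))])
        assert rep.total_reads == 1 and rep.high_quality == 0

    def test_missing_adapter_counted(self):
        inserts, rep = sm.clean_reads([_rec("ACGT" * 12)])
        assert rep.adapter3_null == 1

    def test_five_prime_contaminant(self):
        from saltmir.preprocess import DEFAULT_ADAPTER5

        insert = DEFAULT_ADAPTER5[-8:] + "ACGTACGTACGTA"
        _, rep = sm.clean_reads([_rec(insert + AD3)])
        assert rep.adapter5_contaminant == 1

    def test_length_window(self):
        _, rep = sm.clean_reads([_rec("ACGTACGTACGTACGTC" + AD3)])  # 17 nt
        assert rep.too_short == 1
        long_insert = "ACGTC" * 7  # 35 nt
        _, rep = sm.clean_reads([_rec(long_insert + AD3)])
        assert rep.too_long == 1

    def test_window_override_to_15(self):
        insert = "ACGTACGTACGTACG"  # 15 nt
        inserts, _ = sm.clean_reads([_rec(insert + AD3)], min_len=15)
        assert inserts == [insert]

    def test_cleaning_is_idempotent(self):
        reads = [
            _rec("ACGTACGTACGTACGTACGTA" + AD3),
            _rec("TTGGCATGCATGCATGCAAT" + AD3),
        ]
        first, _ = sm.clean_reads(reads)
        second, rep = sm.clean_reads([_rec(s + AD3) for s in first])
        assert second == first
        assert rep.clean_reads == rep.high_quality

    def test_malformed_fastq_names_record(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(FastqParseError) as err:
            sm.clean_reads(str(bad))
        assert err.value.record_index == 0

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            sm.clean_reads([], adapter3="")


class TestCollapse:
    def test_counts_per_library(self):
        tags = sm.collapse(["ACGT"] * 3, ["ACGT"] * 2)
        t = tags["ACGT"]
        assert (t.count_ck, t.count_na) == (3, 2)

    def test_empty_input(self):
        assert sm.collapse([], []) == {}

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        ck=st.lists(st.sampled_from(["ACGT", "GGGA", "TTAC", "CCAT"]), max_size=50),
        na=st.lists(st.sampled_from(["ACGT", "GGGA", "TTAC"]), max_size=50),
    )
    def test_count_conservation(self, ck, na):
        """Collapsing never loses or invents reads."""
        tags = sm.collapse(ck, na)
        assert sum(t.count_ck for t in tags.values()) == len(ck)
        assert sum(t.count_na for t in tags.values()) == len(na)
        assert all(t.total >= 1 for t in tags.values())

    def test_collapsed_fasta_roundtrip(self, tmp_path):
        tags = sm.collapse(["ACGTACGTACGTACGTACGTA"] * 3, ["TTGGCATGCATGCATGCAAT"])
        path = tmp_path / "tags.fa"
        write_collapsed_fasta(tags, path)
        back = read_collapsed_fasta(path)
        assert {s: (t.count_ck, t.count_na) for s, t in back.items()} == {
            s: (t.count_ck, t.count_na) for s, t in tags.items()
        }


class TestLengthDistribution:
    def test_single_tag(self):
        tags = sm.collapse(["A" * 21], [])
        # poly-A would never survive cleaning, but the op is count-agnostic
        dist = sm.length_distribution(tags.values())
        assert dist["ck"] == {21: 100.0}

    def test_equal_split(self):
        tags = sm.collapse(["ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGTAC"], [])
        dist = sm.length_distribution(tags.values())
        assert dist["ck"][20] == 50.0 and dist["ck"][22] == 50.0

    def test_percentages_sum_to_100(self, small_study):
        dist = sm.length_distribution(small_study["result"].tags.values())
        for lib in ("ck", "na"):
            assert abs(sum(dist[lib].values()) - 100.0) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.length_distribution([])


class TestCompareLibraries:
    def test_identical_libraries_have_no_specific_tags(self):
        tags = sm.collapse(["ACGT", "GGTA"], ["ACGT", "GGTA"])
        cmp_ = sm.compare_libraries(tags.values())
        assert cmp_.unique_ck_only == 0 and cmp_.unique_na_only == 0
        assert cmp_.pct["unique_common"] == 100.0

    def test_disjoint_libraries(self):
        tags = sm.collapse(["ACGT"], ["GGTA"])
        cmp_ = sm.compare_libraries(tags.values())
        assert cmp_.unique_common == 0
        assert cmp_.pct["unique_ck_only"] + cmp_.pct["unique_na_only"] == 100.0

    def test_common_tags_contribute_both_libraries_to_totals(self):
        tags = sm.collapse(["ACGT"] * 3, ["ACGT"] * 5)
        cmp_ = sm.compare_libraries(tags.values())
        assert cmp_.total_common == 8

    def test_partition_sums(self, small_study):
        tags = small_study["result"].tags
        cmp_ = sm.compare_libraries(tags.values())
        assert cmp_.unique_common + cmp_.unique_ck_only + cmp_.unique_na_only == len(tags)
        pct = cmp_.pct
        assert abs(pct["unique_common"] + pct["unique_ck_only"] + pct["unique_na_only"] - 100) <= 0.02
        assert abs(pct["total_common"] + pct["total_ck_only"] + pct["total_na_only"] - 100) <= 0.02


class TestReportArithmetic:
    def test_percentages_recompute_from_counts(self):
        rep = sm.CleaningReport.from_counts(
            total_reads=1000, high_quality=990, adapter3_null=5, insert_null=3,
            adapter5_contaminant=2, too_short=10, polyA=1,
        )
        assert rep.clean_reads == 969
        pct = rep.percentages
        assert pct["high_quality"] == 100.0
        assert abs(sum(pct[k] for k in pct if k != "high_quality" and k != "clean_reads")
                   + pct["clean_reads"] - 100.0) <= 0.05

    def test_partition_validation(self):
        rep = sm.CleaningReport(total_reads=10, high_quality=10, clean_reads=9)
        with pytest.raises(ValueError):
            rep.validate()
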