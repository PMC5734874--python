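import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quiemut.spectrum import (
    DEFAULT_INDEL_BINS,
    PAIR_CLASSES,
    MutationRecord,
    bin_indel_sizes,
    classify_snv,
    deduplicate,
    summarize_spectrum,
)
from quiemut.synthetic_data import records_from_class_counts, records_from_indel_totals

from conftest import make_record

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestClassifySNV:
    def test_transition_ct(self):
        cls = classify_snv("C", "T")
        assert cls.is_transition
        assert cls.pair_class == "GC>AT"

    def test_transversion_gt(self):
        cls = classify_snv("G", "T")
        assert not cls.is_transition
        assert cls.pair_class == "GC>TA"

    def test_at_ta_excluded_from_bias(self):
        cls = classify_snv("A", "T")
        assert not cls.is_transition
        assert cls.pair_class == "AT>TA"
        assert not cls.to_at and not cls.to_gc

    @pytest.mark.parametrize("ref,alt", [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    def test_all_transitions(self, ref, alt):
        assert classify_snv(ref, alt).is_transition

    def test_twelve_substitutions_partition_into_six_classes(self):
        seen = {}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                seen.setdefault(classify_snv(ref, alt).pair_class, []).append((ref, alt))
        assert set(seen) == set(PAIR_CLASSES)
        assert all(len(v) == 2 for v in seen.values())

    @pytest.mark.parametrize("ref", "ACGT")
    @pytest.mark.parametrize("alt", "ACGT")
    def test_strand_symmetry(self, ref, alt):
        if ref == alt:
            return
        fwd = classify_snv(ref, alt)
        rev = classify_snv(COMPLEMENT[ref], COMPLEMENT[alt])
        assert fwd == rev

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_snv("A", "A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_snv("N", "A")

    def test_case_and_u_normalization(self):
        assert classify_snv("c", "u") == classify_snv("C", "T")


class TestDeduplicate:
    def test_collapses_within_population(self):
        same = [make_record(sample=f"s{i}", day=d) for i, d in enumerate([8, 1, 15])]
        other = make_record(sample="x", position=5, ref="A", alt="", day=8)
        out = deduplicate(same + [other])
        assert len(out) == 2
        kept = [r for r in out if r.position == 1][0]
        assert kept.day == 1  # earliest day wins

    def test_distinct_populations_kept(self):
        recs = [make_record(population="p1"), make_record(population="p2")]
        assert len(deduplicate(recs)) == 2

    def test_empty(self):
        assert deduplicate([]) == []

    def test_tie_broken_by_input_order(self):
        recs = [make_record(sample="first"), make_record(sample="second")]
        out = deduplicate(recs)
        assert len(out) == 1 and out[0].sample_id == "first"

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2"]),
                st.integers(min_value=1, max_value=4),
                st.sampled_from([("C", "T"), ("A", "G"), ("A", "")]),
                st.integers(min_value=0, max_value=15),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_grouping(self, raw):
        records = [
            make_record(sample=f"s{i}", population=p, day=d, position=pos,
                        ref=ra[0], alt=ra[1])
            for i, (p, pos, ra, d) in enumerate(raw)
        ]
        out = deduplicate(records)
        # Oracle: group by identity key, keep min (day, input index).
        groups = {}
        for i, r in enumerate(records):
            groups.setdefault(r.key, []).append((r.day, i, r))
        expected = {key: min(v)[2] for key, v in groups.items()}
        assert {r.key for r in out} == set(expected)
        for r in out:
            assert r is expected[r.key]


class TestSummarizeSpectrum:
    def test_day1_table_counts(self):
        # Marginals: 33 Ts, 72 Tv, 63 to-AT, 17 to-GC, 105 SNVs total.
        records = records_from_class_counts(
            {"GC>AT": 30, "AT>GC": 3, "GC>TA": 33, "AT>CG": 14,
             "AT>TA": 13, "GC>CG": 12}
        )
        s = summarize_spectrum(records)
        assert s.n_snv == 105
        assert s.n_ts == 33 and s.n_tv == 72
        assert round(s.ts_tv_ratio, 2) == 2.18
        assert s.n_to_AT == 63 and s.n_to_GC == 17
        assert round(s.at_bias, 2) == 3.71

    def test_day8_15_indel_totals(self):
        records = records_from_indel_totals(170, 1771, 50, 500)
        s = summarize_spectrum(records)
        assert s.n_indel == 220
        assert s.n_del == 170 and s.n_ins == 50
        assert round(s.del_ins_ratio, 1) == 3.4
        assert s.net_loss == 1271
        assert s.bases_lost == 1771 and s.bases_gained == 500

    def test_day1_average_loss(self):
        s = summarize_spectrum(records_from_indel_totals(16, 334, 24, 269))
        assert round(s.avg_loss_per_event) == 21  # 334 / 16
        assert round(s.avg_gain_per_event) == 11  # 269 / 24
        assert s.net_loss == 65

    def test_empty_input(self):
        s = summarize_spectrum([])
        assert s.n_snv == 0 and s.n_indel == 0
        assert math.isnan(s.ts_tv_ratio)
        assert math.isnan(s.at_bias)
        assert math.isnan(s.del_ins_ratio)

    def test_permutation_invariance(self, rng):
        records = records_from_class_counts(
            {"GC>AT": 5, "AT>TA": 2}
        ) + records_from_indel_totals(3, 10, 2, 4, start_position=100)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert summarize_spectrum(records) == summarize_spectrum(shuffled)

    def test_partition_invariant(self):
        records = records_from_class_counts({c: 3 for c in PAIR_CLASSES})
        s = summarize_spectrum(records)
        assert s.n_ts + s.n_tv == s.n_snv
        assert sum(s.class_counts.values()) == s.n_snv

    def test_complex_mutations_counted_separately(self):
        records = [
            make_record(),
            make_record(position=10, ref="AC", alt="GT"),
            make_record(position=20, ref="A", alt=""),
        ]
        s = summarize_spectrum(records)
        assert s.n_snv == 1 and s.n_indel == 1 and s.n_complex == 1

    def test_signed_histogram(self):
        records = [
            make_record(position=1, ref="AAA", alt=""),
            make_record(position=2, ref="", alt="AT"),
            make_record(position=3, ref="A", alt=""),
        ]
        s = summarize_spectrum(records)
        assert s.indel_size_histogram == {-3: 1, -1: 1, 2: 1}

    def test_dedupe_flag(self):
        records = [make_record(sample="a"), make_record(sample="b")]
        assert summarize_spectrum(records, dedupe=True).n_snv == 1

    def test_malformed_record_reports_index(self):
        good = make_record()
        bad = make_record(position=2)
        object.__setattr__(bad, "ref", "")
        object.__setattr__(bad, "alt", "")
        with pytest.raises(ValueError, match="record 1"):
            summarize_spectrum([good, bad])


class TestRecordModel:
    def test_both_sides_empty_rejected(self):
        with pytest.raises(ValueError):
            make_record(ref="", alt="")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            make_record(ref="X", alt="T")

    def test_dash_normalized_on_parse(self):
        rec = make_record(ref="-", alt="AT")
        assert rec.ref == "" and rec.kind == "indel" and rec.net_size == 2

    def test_kinds(self):
        assert make_record(ref="A", alt="G").kind == "snv"
        assert make_record(ref="AG", alt="CT").kind == "complex"
        assert make_record(ref="AG", alt="C").kind == "indel"
        assert make_record(ref="AG", alt="C").net_size == -1


def test_bin_indel_sizes_default_bins():
    hist = {-12: 1, -5: 2, -2: 1, -1: 4, 1: 3, 3: 1, 11: 2}
    out = bin_indel_sizes(hist, DEFAULT_INDEL_BINS)
    assert out["-1"] == 4 and out["+1"] == 3
    assert out["-2-3"] == 1 and out["+2-3"] == 1
    assert out["-4-10"] == 2 and out["+4-10"] == 0
    assert out["->10"] == 1 and out["+>10"] == 2
    assert sum(out.values()) == sum(hist.values())
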