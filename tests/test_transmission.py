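"""Proband/maternal pairing, heteroplasmic-shift classes, and summaries."""

import copy

import pytest

from mttriage import MtError, MtVariant, SampleCallSet
from mttriage.transmission import (
    FamilyPair,
    TransmissionRecord,
    classify_shift,
    pair_variants,
    transmission_summary,
)


def _cs(sample_id, entries, data_type="GS"):
    variants = [
        MtVariant(position=p, ref_allele="A", alt_allele="G", alt_depth=1000, ref_depth=10, hl=hl)
        for p, hl in entries
    ]
    return SampleCallSet(sample_id=sample_id, data_type=data_type, variants=variants)


class TestClassifyShift:
    @pytest.mark.parametrize(
        "maternal,proband,expected",
        [
            (0.36, 0.72, "positive"),   # crosses 60% upward between generations
            (0.90, 0.90, "none"),
            (0.70, 0.50, "negative"),
            (0.60, 0.90, "none"),       # boundary HL on either side is not a crossing
            (0.30, 0.60, "none"),
            (0.59, 0.61, "positive"),
        ],
    )
    def test_shift_classes(self, maternal, proband, expected):
        assert classify_shift(maternal, proband) == expected

    def test_antisymmetric(self):
        for m, p in [(0.1, 0.9), (0.9, 0.1), (0.5, 0.5), (0.59, 0.61)]:
            forward = classify_shift(m, p)
            backward = classify_shift(p, m)
            flip = {"positive": "negative", "negative": "positive", "none": "none"}
            assert backward == flip[forward]

    def test_out_of_range(self):
        with pytest.raises(MtError):
            classify_shift(1.2, 0.5)


class TestPairVariants:
    def test_identical_callsets_all_shared(self):
        entries = [(100, 0.5), (200, 0.9)]
        pair = FamilyPair("f", _cs("p", entries), _cs("m", entries))
        records = pair_variants(pair)
        assert all(r.status == "shared" for r in records)

    def test_empty_maternal_all_proband_only(self):
        pair = FamilyPair("f", _cs("p", [(100, 0.5)]), _cs("m", []))
        records = pair_variants(pair)
        assert [r.status for r in records] == ["proband_only"]
        assert records[0].note  # no de novo claim, but the caveat is recorded

    def test_planted_shared_and_only_counts(self):
        shared = [(100 + i, 0.5) for i in range(10)]
        only = [(300 + i, 0.5) for i in range(3)]
        pair = FamilyPair("f", _cs("p", shared + only), _cs("m", shared))
        records = pair_variants(pair)
        statuses = [r.status for r in records]
        assert statuses.count("shared") == 10
        assert statuses.count("proband_only") == 3

    def test_below_floor_proband_variants_skipped(self):
        pair = FamilyPair("f", _cs("p", [(100, 0.005)]), _cs("m", []))
        assert pair_variants(pair) == []

    def test_below_floor_maternal_counts_as_absent(self):
        pair = FamilyPair("f", _cs("p", [(100, 0.5)]), _cs("m", [(100, 0.005)]))
        assert pair_variants(pair)[0].status == "proband_only"

    def test_data_type_mismatch(self):
        with pytest.raises(MtError):
            FamilyPair("f", _cs("p", [], data_type="GS"), _cs("m", [], data_type="RNA"))

    def test_conservation(self, cohort):
        """shared + proband_only equals the probands' above-floor variants."""
        for row in cohort.pedigree.itertuples(index=False):
            if not row.maternal_sample:
                continue
            pair = FamilyPair(
                row.family_id,
                cohort.callsets[row.proband_sample],
                cohort.callsets[row.maternal_sample],
            )
            records = pair_variants(pair)
            above_floor = sum(
                1 for v in cohort.callsets[row.proband_sample].variants if v.hl >= 0.01
            )
            assert len(records) == above_floor


def _fixture_records(n_shared, n_positive, n_negative, n_only, n_only_high):
    records = []
    for i in range(n_shared):
        if i < n_positive:
            m_hl, p_hl = 0.30, 0.72
        elif i < n_positive + n_negative:
            m_hl, p_hl = 0.72, 0.30
        else:
            m_hl, p_hl = 0.50, 0.50
        records.append(
            TransmissionRecord("f", (100, "A", "G"), p_hl, m_hl, "shared",
                               classify_shift(m_hl, p_hl))
        )
    for i in range(n_only):
        p_hl = 0.80 if i < n_only_high else 0.10
        records.append(TransmissionRecord("f", (200, "A", "G"), p_hl, None, "proband_only", "n/a"))
    return records


class TestSummary:
    def test_published_shift_percentages(self):
        """147 positive / 85 negative among 80,753 shared -> 0.18% / 0.11%."""
        records = _fixture_records(80753, 147, 85, 1019, 388)
        summary = transmission_summary(records)
        assert summary.positive_shift_pct == 0.18
        assert summary.negative_shift_pct == 0.11
        assert summary.proband_only_high_hl_pct == 38.08
        assert summary.maternal_detection_pct == round(100 * 80753 / 81772, 2)

    def test_zero_denominator_marked(self):
        summary = transmission_summary([])
        assert summary.maternal_detection_pct is None
        assert summary.positive_shift_pct is None

    def test_scale_free_under_duplication(self):
        records = _fixture_records(200, 3, 2, 10, 4)
        once = transmission_summary(records)
        twice = transmission_summary(records + copy.deepcopy(records))
        assert once.positive_shift_pct == twice.positive_shift_pct
        assert once.maternal_detection_pct == twice.maternal_detection_pct
        assert once.proband_only_high_hl_pct == twice.proband_only_high_hl_pct

    def test_shift_classes_partition_shared(self):
        records = _fixture_records(500, 5, 7, 20, 3)
        summary = transmission_summary(records)
        none_count = sum(1 for r in records if r.status == "shared" and r.shift == "none")
        assert summary.positive_shift + summary.negative_shift + none_count == summary.shared
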