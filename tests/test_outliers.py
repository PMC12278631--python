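"""Heteroplasmic burden counting and mutator-outlier flagging."""

import numpy as np
import pytest

from mttriage import MtVariant, SampleCallSet
from mttriage.outliers import HetBurden, burden, flag_outliers, heteroplasmic_count
from mttriage.simulate import plant_mutator


def _cs(hls, sample_id="s", data_type="ES_twist", indel_positions=()):
    variants = []
    for i, hl in enumerate(hls):
        alt = "AG" if i in indel_positions else "G"
        variants.append(
            MtVariant(position=100 + i, ref_allele="A", alt_allele=alt,
                      alt_depth=100, ref_depth=100, hl=hl)
        )
    return SampleCallSet(sample_id=sample_id, data_type=data_type, variants=variants)


class TestHeteroplasmicCount:
    def test_window_split_by_class(self):
        cs = _cs([0.10, 0.20, 0.50], indel_positions=(2,))
        assert heteroplasmic_count(cs) == (2, 1)

    def test_empty(self):
        assert heteroplasmic_count(_cs([])) == (0, 0)

    def test_ceiling_excludes_near_homoplasmy(self):
        assert heteroplasmic_count(_cs([0.95])) == (0, 0)
        assert heteroplasmic_count(_cs([0.9499])) == (1, 0)

    def test_floor_inclusive(self):
        assert heteroplasmic_count(_cs([0.01])) == (1, 0)
        assert heteroplasmic_count(_cs([0.009])) == (0, 0)

    def test_widening_window_monotone(self):
        cs = _cs([0.005, 0.02, 0.5, 0.96])
        narrow = sum(heteroplasmic_count(cs, floor=0.05, ceiling=0.9))
        default = sum(heteroplasmic_count(cs))
        wide = sum(heteroplasmic_count(cs, floor=0.001, ceiling=1.01))
        assert narrow <= default <= wide

    def test_planted_mutator_burden(self):
        cs = SampleCallSet(sample_id="m", data_type="ES_twist")
        plant_mutator(cs, 910, 31, seed=3)
        snv, indel = heteroplasmic_count(cs)
        assert (snv, indel) == (910, 31)

    def test_planting_nothing_is_identity(self):
        cs = _cs([0.5])
        plant_mutator(cs, 0, 0, seed=0)
        assert len(cs.variants) == 1


def _stratum(totals, data_type="ES_twist"):
    return [
        HetBurden(sample_id=f"s{i}", data_type=data_type, snv_count=int(t), indel_count=0)
        for i, t in enumerate(totals)
    ]


class TestFlagOutliers:
    def test_941_against_poisson_background(self):
        rng = np.random.default_rng(0)
        burdens = _stratum(list(rng.poisson(10, size=99)) + [941])
        flag_outliers(burdens)
        flagged = [b.sample_id for b in burdens if b.outlier]
        assert flagged == ["s99"]

    def test_identical_totals_never_flagged(self):
        burdens = _stratum([150] * 20)
        flag_outliers(burdens)
        assert not any(b.outlier for b in burdens)

    def test_small_stratum_warns_and_skips(self):
        burdens = _stratum([10, 941])
        with pytest.warns(UserWarning):
            flag_outliers(burdens)
        assert not any(b.outlier for b in burdens)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        totals = list(rng.poisson(10, size=50)) + [700]
        base = _stratum(totals)
        shifted = _stratum([t + 5 for t in totals])
        flag_outliers(base)
        flag_outliers(shifted)
        for a, b in zip(base, shifted):
            assert a.outlier == b.outlier
            assert a.robust_z == pytest.approx(b.robust_z)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        totals = list(rng.poisson(10, size=50)) + [600]
        forward = _stratum(totals)
        backward = _stratum(totals[::-1])
        flag_outliers(forward)
        flag_outliers(backward)
        assert sorted(b.total for b in forward if b.outlier) == sorted(
            b.total for b in backward if b.outlier
        )

    def test_moderate_excess_below_count_floor_not_flagged(self):
        rng = np.random.default_rng(3)
        burdens = _stratum(list(rng.poisson(10, size=99)) + [60])
        flag_outliers(burdens)
        assert not any(b.outlier for b in burdens)

    def test_strata_are_independent(self):
        rng = np.random.default_rng(4)
        a = _stratum(list(rng.poisson(10, size=50)) + [941], data_type="ES_twist")
        b = _stratum(list(rng.poisson(1000, size=50)), data_type="GS")
        flag_outliers(a + b)
        assert sum(x.outlier for x in a) == 1
        assert sum(x.outlier for x in b) == 0


def test_mutator_sample_isolated_in_cohort(cohort):
    """The planted mutator proband is the only flagged sample cohort-wide."""
    truth = cohort.truth_samples
    mutator_id = truth.loc[truth["mutator"], "sample_id"].iloc[0]
    burdens = [burden(cohort.callsets[s]) for s in cohort.pedigree["proband_sample"]]
    flag_outliers(burdens)
    flagged = [b.sample_id for b in burdens if b.outlier]
    assert flagged == [mutator_id]


def test_mutator_maternal_overlap(cohort):
    """12 of the planted somatic variants are shared with the mother."""
    from mttriage.transmission import FamilyPair, pair_variants

    truth = cohort.truth_samples
    mutator_id = truth.loc[truth["mutator"], "sample_id"].iloc[0]
    family = truth.loc[truth["mutator"], "family_id"].iloc[0]
    row = cohort.pedigree.set_index("family_id").loc[family]
    pair = FamilyPair(family, cohort.callsets[mutator_id], cohort.callsets[row.maternal_sample])
    records = pair_variants(pair)
    planted_positions = {
        v.position for v in cohort.callsets[mutator_id].variants
    } - {
        int(p) for p in cohort.truth_variants.loc[
            cohort.truth_variants["sample_id"] == mutator_id, "position"
        ]
    }
    shared_planted = [
        r for r in records if r.key[0] in planted_positions and r.status == "shared"
    ]
    assert len(shared_planted) == 12
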