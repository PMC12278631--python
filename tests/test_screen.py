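"""Reported-pathogenic catalog construction, screening, and triage tiers."""

import pytest

from mttriage import MtError, MtVariant, SampleCallSet
from mttriage.screen import (
    TIER_HIGH_INCOMPLETE,
    TIER_HIGH_PENETRANT,
    TIER_LOW,
    build_plp_catalog,
    screen_callset,
    triage_hit,
)


def _mitomap(*keys, status="cfrm"):
    return [{"position": p, "ref": r, "alt": a, "status": status} for p, r, a in keys]


def _clinvar(*keys, stars=2, classification="P/LP"):
    return [
        {"position": p, "ref": r, "alt": a, "classification": classification, "stars": stars}
        for p, r, a in keys
    ]


class TestCatalog:
    def test_union_counts_with_overlap(self, cohort):
        """127 confirmed + 111 two-star entries sharing 86 keys -> 152 unique."""
        catalog = build_plp_catalog(cohort.mitomap_records, cohort.clinvar_records)
        assert len(catalog) == 152
        both = sum(1 for e in catalog.entries.values() if len(e.source_flags) == 2)
        assert both == 86

    def test_empty_inputs(self):
        assert len(build_plp_catalog([], [], incomplete_penetrance_keys=set())) == 0

    def test_one_star_excluded(self):
        catalog = build_plp_catalog(
            [], _clinvar((100, "A", "G"), stars=1), incomplete_penetrance_keys=set()
        )
        assert len(catalog) == 0

    def test_non_confirmed_mitomap_excluded(self):
        catalog = build_plp_catalog(
            _mitomap((100, "A", "G"), status="rptd"), [], incomplete_penetrance_keys=set()
        )
        assert len(catalog) == 0

    def test_conflicting_alts_within_source(self):
        records = _clinvar((100, "A", "G"), (100, "A", "T"))
        with pytest.raises(MtError):
            build_plp_catalog([], records, incomplete_penetrance_keys=set())

    def test_penetrance_flag_joined(self):
        catalog = build_plp_catalog(
            _mitomap((11778, "G", "A")), [], incomplete_penetrance_keys={(11778, "G", "A")}
        )
        assert catalog.get((11778, "G", "A")).incomplete_penetrance


class TestTriage:
    @pytest.mark.parametrize(
        "hl,flagged,tier",
        [
            (0.99, True, TIER_HIGH_INCOMPLETE),   # LHON-like at near homoplasmy
            (0.99, False, TIER_HIGH_PENETRANT),   # m.8993T>C-like
            (0.08, False, TIER_LOW),              # m.3243A>G at low blood HL
            (0.60, False, TIER_HIGH_PENETRANT),   # threshold inclusive
            (0.59, True, TIER_LOW),
        ],
    )
    def test_tier_stratification(self, hl, flagged, tier):
        assert triage_hit(hl, flagged) == tier


class TestScreen:
    def _callset(self, entries):
        variants = [
            MtVariant(position=p, ref_allele=r, alt_allele=a, alt_depth=1000, ref_depth=10, hl=hl)
            for (p, r, a), hl in entries
        ]
        return SampleCallSet(sample_id="s", data_type="GS", variants=variants)

    def test_catalog_hit_above_floor(self):
        catalog = build_plp_catalog(_mitomap((5591, "G", "A")), [], incomplete_penetrance_keys=set())
        hits, _ = screen_callset(self._callset([((5591, "G", "A"), 0.86)]), catalog)
        assert len(hits) == 1 and hits[0].tier == TIER_HIGH_PENETRANT

    def test_below_floor_excluded(self):
        catalog = build_plp_catalog(_mitomap((5591, "G", "A")), [], incomplete_penetrance_keys=set())
        hits, _ = screen_callset(self._callset([((5591, "G", "A"), 0.04)]), catalog)
        assert hits == []

    def test_non_catalog_variant_never_hits(self):
        catalog = build_plp_catalog(_mitomap((5591, "G", "A")), [], incomplete_penetrance_keys=set())
        hits, _ = screen_callset(self._callset([((600, "C", "T"), 0.99)]), catalog)
        assert hits == []

    def test_raising_floor_never_adds_hits(self):
        catalog = build_plp_catalog(
            _mitomap((100, "A", "G"), (200, "C", "T"), (300, "G", "A")),
            [],
            incomplete_penetrance_keys=set(),
        )
        cs = self._callset(
            [((100, "A", "G"), 0.06), ((200, "C", "T"), 0.50), ((300, "G", "A"), 0.95)]
        )
        previous = None
        for floor in (0.05, 0.10, 0.60, 0.96):
            hits, _ = screen_callset(cs, catalog, min_hl=floor)
            keys = {h.key for h in hits}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_planted_catalog_variants_recovered(self, cohort):
        """Screen recovers every planted reported-pathogenic variant at >= 5% HL
        and never reports the below-floor planting."""
        catalog = build_plp_catalog(cohort.mitomap_records, cohort.clinvar_records)
        truth = cohort.truth_variants
        planted = truth[truth["kind"] == "plp"]
        hits_by_sample = {}
        for sample_id in cohort.pedigree["proband_sample"]:
            hits, _ = screen_callset(cohort.callsets[sample_id], catalog)
            hits_by_sample[sample_id] = {h.key for h in hits}
        for row in planted.itertuples(index=False):
            key = (row.position, row.ref, row.alt)
            if row.true_hl >= 0.05:
                assert key in hits_by_sample[row.sample_id]
            else:
                assert key not in hits_by_sample[row.sample_id]

    def test_deletions_reported_at_any_hl(self):
        from mttriage import MtDeletion

        cs = SampleCallSet(
            sample_id="s", data_type="ES_twist",
            deletions=[MtDeletion(start=8470, end=13446, hl=0.02)],
        )
        catalog = build_plp_catalog([], [], incomplete_penetrance_keys=set())
        _, deletion_hits = screen_callset(cs, catalog)
        assert len(deletion_hits) == 1
        assert deletion_hits[0].deletion.label == "m.8470_13446del4977"
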