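"""Rare deleterious-variant prioritization cascade vs a brute-force oracle."""

import numpy as np
import pytest

from mttriage import MtVariant
from mttriage.annotate import AnnotatedVariant, InSilicoScores, PopulationFrequency
from mttriage.prioritize import (
    PrioritizerConfig,
    decide,
    deleterious_criteria,
    prioritize_callset,
    rarity_filter,
    review_all_rare,
)

CONSEQUENCES = ["synonymous", "missense", "stop_gained", "frameshift", "stop_loss",
                "tRNA", "rRNA", "noncoding"]


def make_av(
    consequence="missense",
    apogee2=None,
    hmtvar=None,
    mitotip=None,
    pon=None,
    mlc=None,
    regional=False,
    gnomad_hom=0.0,
    helix_hom=0.0,
    internal_ac=1,
    haplogroup_defining=False,
    position=1000,
):
    v = MtVariant(position=position, ref_allele="A", alt_allele="G",
                  alt_depth=100, ref_depth=100, consequence=consequence)
    return AnnotatedVariant(
        variant=v,
        freq_gnomad=PopulationFrequency("gnomad_style", hom_af=gnomad_hom),
        freq_helix=PopulationFrequency("helix_style", hom_af=helix_hom),
        scores=InSilicoScores(apogee2=apogee2, hmtvar=hmtvar, mitotip=mitotip,
                              pon_mt_trna=pon, mlc=mlc, in_regional_constraint=regional),
        is_haplogroup_defining=haplogroup_defining,
        internal_ac=internal_ac,
    )


class TestRarity:
    def test_absent_everywhere_single_carrier(self):
        assert rarity_filter(make_av())

    def test_too_common_in_one_source(self):
        assert not rarity_filter(make_av(gnomad_hom=1 / 40000))

    def test_internal_ac_boundary(self):
        assert rarity_filter(make_av(internal_ac=10))
        assert not rarity_filter(make_av(internal_ac=11))

    def test_threshold_is_strict(self):
        assert not rarity_filter(make_av(helix_hom=1 / 50000))
        assert rarity_filter(make_av(helix_hom=1 / 50001))


class TestDeleteriousCriteria:
    def test_missense_with_constraint(self):
        """m.15347C>T-like: APOGEE2 0.64, HmtVar 0.84, regional missense constraint."""
        av = make_av(consequence="missense", apogee2=0.64, hmtvar=0.84, mlc=0.53, regional=True)
        assert deleterious_criteria(av) == {"missense_score", "constraint"}

    def test_trna_with_subthreshold_mlc(self):
        """m.16023G>A-like: MitoTIP 17.6, PON 0.8; MLC 0.73 fails the 0.75 cut."""
        av = make_av(consequence="tRNA", mitotip=17.6, hmtvar=0.65, pon=0.8, mlc=0.73)
        assert deleterious_criteria(av) == {"trna_score"}

    def test_missing_scores_never_satisfy(self):
        assert deleterious_criteria(make_av(consequence="missense")) == set()

    def test_lof_consequences(self):
        assert "lof" in deleterious_criteria(make_av(consequence="frameshift"))
        assert "lof" in deleterious_criteria(make_av(consequence="stop_gained"))
        assert "lof" in deleterious_criteria(make_av(consequence="stop_loss"))
        cfg = PrioritizerConfig(include_stop_loss_as_lof=False)
        assert "lof" not in deleterious_criteria(make_av(consequence="stop_loss"), cfg)

    def test_rrna_only_via_constraint(self):
        av = make_av(consequence="rRNA", apogee2=0.99, hmtvar=0.99, mitotip=99.0, pon=0.99, mlc=0.5)
        assert deleterious_criteria(av) == set()
        assert deleterious_criteria(make_av(consequence="rRNA", mlc=0.75)) == {"constraint"}

    def test_printed_inequality_directions(self):
        assert deleterious_criteria(make_av(consequence="missense", apogee2=0.5)) == set()
        assert deleterious_criteria(make_av(consequence="missense", hmtvar=0.35)) == {"missense_score"}
        assert deleterious_criteria(make_av(consequence="tRNA", mitotip=12.66)) == set()
        assert deleterious_criteria(make_av(consequence="tRNA", pon=0.5)) == {"trna_score"}
        assert deleterious_criteria(make_av(mlc=0.75)) == {"constraint"}
        assert deleterious_criteria(make_av(mlc=0.7499)) == set()


class TestCascade:
    def test_haplogroup_defining_short_circuits(self):
        av = make_av(apogee2=0.9, haplogroup_defining=True)
        assert not decide(av).prioritized

    def test_synonymous_short_circuits(self):
        av = make_av(consequence="synonymous", mlc=0.9)
        assert not decide(av).prioritized

    def test_stage_flags_always_recorded(self):
        decision = decide(make_av(consequence="synonymous", haplogroup_defining=True))
        assert set(decision.stage_results) == {"non_haplogroup", "non_synonymous", "rare", "deleterious"}

    def test_tightening_thresholds_never_enlarges(self):
        rng = np.random.default_rng(42)
        avs = [_random_av(rng) for _ in range(300)]
        loose = {i for i, av in enumerate(avs) if decide(av, PrioritizerConfig()).prioritized}
        tight_cfg = PrioritizerConfig(mlc_ge=0.9, max_internal_ac=5, apogee2_gt=0.7)
        tight = {i for i, av in enumerate(avs) if decide(av, tight_cfg).prioritized}
        assert tight <= loose


class TestRelaxedReview:
    def test_definite_category_drops_stage_four(self):
        av = make_av(consequence="missense")  # no scores at all
        assert review_all_rare([av], "definite") == [av]
        assert review_all_rare([av], "probable") == [av]

    def test_unlikely_category_returns_nothing(self):
        assert review_all_rare([make_av(consequence="missense")], "unlikely") == []

    def test_synonymous_still_excluded(self):
        assert review_all_rare([make_av(consequence="synonymous")], "definite") == []

    def test_superset_of_prioritized(self):
        rng = np.random.default_rng(7)
        avs = [_random_av(rng) for _ in range(300)]
        prioritized = {id(d.annotated_variant) for d in prioritize_callset(avs) if d.prioritized}
        relaxed = {id(av) for av in review_all_rare(avs, "definite")}
        assert prioritized <= relaxed


def _random_av(rng: np.random.Generator) -> AnnotatedVariant:
    def maybe(value):
        return value if rng.random() < 0.5 else None

    return make_av(
        consequence=str(rng.choice(CONSEQUENCES)),
        apogee2=maybe(float(rng.uniform(0, 1))),
        hmtvar=maybe(float(rng.uniform(0, 1))),
        mitotip=maybe(float(rng.uniform(0, 25))),
        pon=maybe(float(rng.uniform(0, 1))),
        mlc=maybe(float(rng.uniform(0, 1))),
        regional=bool(rng.random() < 0.1),
        gnomad_hom=float(rng.choice([0.0, 1e-6, 1e-5, 1 / 50000, 1e-4, 1e-2])),
        helix_hom=float(rng.choice([0.0, 1e-6, 1e-5, 1 / 50000, 1e-4, 1e-2])),
        internal_ac=int(rng.integers(1, 15)),
        haplogroup_defining=bool(rng.random() < 0.3),
        position=int(rng.integers(1, 16570)),
    )


def brute_force_prioritized(avs, cfg: PrioritizerConfig) -> set[int]:
    """Independent straight-line restatement of the published filter."""
    out = set()
    for i, av in enumerate(avs):
        if av.is_haplogroup_defining:
            continue
        if av.variant.consequence == "synonymous":
            continue
        if not (av.freq_gnomad.hom_af < 1 / 50000 and av.freq_helix.hom_af < 1 / 50000):
            continue
        if av.internal_ac > 10:
            continue
        s = av.scores
        c = av.variant.consequence
        lof = c in ("frameshift", "stop_gained") or (cfg.include_stop_loss_as_lof and c == "stop_loss")
        missense = c == "missense" and (
            (s.apogee2 is not None and s.apogee2 > 0.5) or (s.hmtvar is not None and s.hmtvar >= 0.35)
        )
        trna = c == "tRNA" and (
            (s.mitotip is not None and s.mitotip > 12.66)
            or (s.pon_mt_trna is not None and s.pon_mt_trna >= 0.5)
            or (s.hmtvar is not None and s.hmtvar >= 0.35)
        )
        constraint = s.in_regional_constraint or (s.mlc is not None and s.mlc >= 0.75)
        if lof or missense or trna or constraint:
            out.add(i)
    return out


@pytest.mark.parametrize("seed", range(20))
def test_cascade_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    avs = [_random_av(rng) for _ in range(int(rng.integers(50, 500)))]
    cfg = PrioritizerConfig()
    decisions = prioritize_callset(avs, cfg)
    mine = {i for i, d in enumerate(decisions) if d.prioritized}
    assert mine == brute_force_prioritized(avs, cfg)


def test_monotone_funnel(cohort):
    """Stage passers nest: prioritized <= rare <= non-synonymous <= all."""
    from mttriage.annotate import annotate_callset, build_internal_ac_index

    callsets = [cohort.callsets[s] for s in sorted(cohort.callsets)]
    index = build_internal_ac_index(callsets)
    pid = cohort.pedigree["proband_sample"].iloc[0]
    avs = annotate_callset(cohort.callsets[pid], cohort.resources, internal_ac_index=index)
    decisions = prioritize_callset(avs)
    n_all = len(decisions)
    n1 = sum(1 for d in decisions if d.stage_results["non_haplogroup"])
    n2 = sum(1 for d in decisions if d.stage_results["non_haplogroup"] and d.stage_results["non_synonymous"])
    n3 = sum(
        1 for d in decisions
        if d.stage_results["non_haplogroup"] and d.stage_results["non_synonymous"] and d.stage_results["rare"]
    )
    n4 = sum(1 for d in decisions if d.prioritized)
    assert n4 <= n3 <= n2 <= n1 <= n_all
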