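"""Four-stage prioritization cascade for rare, potentially deleterious
mtDNA variants.

A variant is prioritized when it passes all four stages:

1. **non-haplogroup-defining** for the carrier's own haplogroup;
2. **non-synonymous** (any consequence other than synonymous);
3. **rare** — homoplasmic allele frequency < 1:50,000 in *both*
   reference sources (gnomAD-style and HelixMTdb-style; absence counts
   as rare) *and* carried by <= 10 samples in the analyzed call-set
   collection;
4. **predicted deleterious** by at least one of four criteria:
   loss-of-function consequence, missense score (APOGEE2 > 0.5 or
   HmtVar >= 0.35), tRNA score (MitoTIP > 12.66, PON-mt-tRNA >= 0.5,
   or HmtVar >= 0.35), or mitochondrial constraint (inside a
   regionally constrained interval, or positional MLC >= 0.75).

Missing scores never satisfy their clause; rRNA and non-coding variants
can therefore only be prioritized via the constraint criterion.  For
probands whose phenotype already indicates a probable or definite
mitochondrial disease, a relaxed review drops stage 4 entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import AnnotatedVariant

CRITERION_LOF = "lof"
CRITERION_MISSENSE = "missense_score"
CRITERION_TRNA = "trna_score"
CRITERION_CONSTRAINT = "constraint"


@dataclass
class PrioritizerConfig:
    """All cascade thresholds; defaults follow the published pipeline."""

    hom_af_threshold: float = 1.0 / 50000.0  # strictly below, both sources
    max_internal_ac: int = 10
    apogee2_gt: float = 0.5
    hmtvar_ge: float = 0.35
    mitotip_gt: float = 12.66
    pon_ge: float = 0.5
    mlc_ge: float = 0.75
    # Table-2 practice labels a stop-loss call "LoF"; toggleable because the
    # stated LoF criterion lists only frameshift and stop-gained.
    include_stop_loss_as_lof: bool = True

    @property
    def lof_consequences(self) -> frozenset[str]:
        base = {"frameshift", "stop_gained"}
        if self.include_stop_loss_as_lof:
            base.add("stop_loss")
        return frozenset(base)


@dataclass
class PrioritizationDecision:
    annotated_variant: AnnotatedVariant
    stage_results: dict[str, bool] = field(default_factory=dict)
    criteria_met: set[str] = field(default_factory=set)

    @property
    def prioritized(self) -> bool:
        return all(
            self.stage_results.get(stage, False)
            for stage in ("non_haplogroup", "non_synonymous", "rare", "deleterious")
        )


def rarity_filter(
    av: AnnotatedVariant,
    threshold: float = PrioritizerConfig.hom_af_threshold,
    max_internal_ac: int = PrioritizerConfig.max_internal_ac,
) -> bool:
    """Rare at homoplasmy in both reference sources and internally."""
    return (
        av.freq_gnomad.hom_af < threshold
        and av.freq_helix.hom_af < threshold
        and av.internal_ac <= max_internal_ac
    )


def deleterious_criteria(
    av: AnnotatedVariant, config: PrioritizerConfig | None = None
) -> set[str]:
    """Which of the four deleteriousness criteria the variant meets."""
    cfg = config or PrioritizerConfig()
    s = av.scores
    met: set[str] = set()
    consequence = av.variant.consequence
    if consequence in cfg.lof_consequences:
        met.add(CRITERION_LOF)
    if consequence == "missense" and (
        (s.apogee2 is not None and s.apogee2 > cfg.apogee2_gt)
        or (s.hmtvar is not None and s.hmtvar >= cfg.hmtvar_ge)
    ):
        met.add(CRITERION_MISSENSE)
    if consequence == "tRNA" and (
        (s.mitotip is not None and s.mitotip > cfg.mitotip_gt)
        or (s.pon_mt_trna is not None and s.pon_mt_trna >= cfg.pon_ge)
        or (s.hmtvar is not None and s.hmtvar >= cfg.hmtvar_ge)
    ):
        met.add(CRITERION_TRNA)
    if s.in_regional_constraint or (s.mlc is not None and s.mlc >= cfg.mlc_ge):
        met.add(CRITERION_CONSTRAINT)
    return met


def decide(av: AnnotatedVariant, config: PrioritizerConfig | None = None) -> PrioritizationDecision:
    """Run the full cascade on one annotated variant, recording stage flags."""
    cfg = config or PrioritizerConfig()
    criteria = deleterious_criteria(av, cfg)
    stages = {
        "non_haplogroup": not av.is_haplogroup_defining,
        "non_synonymous": av.variant.consequence != "synonymous",
        "rare": rarity_filter(av, cfg.hom_af_threshold, cfg.max_internal_ac),
        "deleterious": bool(criteria),
    }
    return PrioritizationDecision(annotated_variant=av, stage_results=stages, criteria_met=criteria)


def prioritize_callset(
    annotated: list[AnnotatedVariant], config: PrioritizerConfig | None = None
) -> list[PrioritizationDecision]:
    """Decisions for every variant of one annotated call set."""
    cfg = config or PrioritizerConfig()
    return [decide(av, cfg) for av in annotated]


def review_all_rare(
    annotated: list[AnnotatedVariant],
    mdc_category: str,
    config: PrioritizerConfig | None = None,
) -> list[AnnotatedVariant]:
    """Relaxed review for probable/definite-MDC probands.

    Returns all rare, non-synonymous, non-haplogroup-defining variants
    regardless of predicted deleteriousness; empty for other categories.
    """
    if mdc_category not in {"probable", "definite"}:
        return []
    cfg = config or PrioritizerConfig()
    return [
        av
        for av in annotated
        if not av.is_haplogroup_defining
        and av.variant.consequence != "synonymous"
        and rarity_filter(av, cfg.hom_af_threshold, cfg.max_internal_ac)
    ]
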