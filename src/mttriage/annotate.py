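"""Joining call sets to population frequencies, in-silico scores,
constraint metrics, haplogroup-defining lists, and P/LP catalogs.

Lookups are exact on the (position, ref, alt) key.  A variant absent
from a frequency database is represented by the all-zero "absent"
record, so the downstream rarity filter treats absence as evidence of
rarity.  Missing in-silico scores are retained as ``None`` and can
never satisfy a threshold criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MT_GENOME_LENGTH, MtError, MtVariant, SampleCallSet

Key = tuple[int, str, str]

DETECTION_FLOOR = 0.01  # minimum HL for a variant to count as detected


@dataclass(frozen=True)
class PopulationFrequency:
    """Homoplasmic and heteroplasmic frequency evidence from one database."""

    source: str  # "gnomad_style" or "helix_style"
    hom_af: float = 0.0
    het_af: float = 0.0
    het_ac: int = 0
    max_observed_hl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("hom_af", "het_af", "max_observed_hl"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise MtError(f"{name} out of [0, 1]: {value}")
        if self.het_ac < 0:
            raise MtError(f"het_ac must be >= 0, got {self.het_ac}")

    @property
    def absent(self) -> bool:
        return self.hom_af == 0 and self.het_af == 0 and self.het_ac == 0 and self.max_observed_hl == 0


@dataclass(frozen=True)
class InSilicoScores:
    """Pathogenicity predictions and constraint for one variant.

    APOGEE2 and HmtVar score missense variants, MitoTIP and PON-mt-tRNA
    score tRNA variants; MLC is the per-nucleotide mitochondrial local
    constraint in [0, 1] and ``in_regional_constraint`` marks membership
    in an intolerant interval.  ``None`` means no prediction available.
    """

    apogee2: float | None = None
    hmtvar: float | None = None
    mitotip: float | None = None
    pon_mt_trna: float | None = None
    mlc: float | None = None
    in_regional_constraint: bool = False

    def __post_init__(self) -> None:
        for name in ("apogee2", "hmtvar", "pon_mt_trna", "mlc"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise MtError(f"{name} out of [0, 1]: {value}")


@dataclass
class AnnotatedVariant:
    """An :class:`~mttriage.core.MtVariant` joined to all its evidence."""

    variant: MtVariant
    sample_id: str = ""
    freq_gnomad: PopulationFrequency = field(
        default_factory=lambda: PopulationFrequency("gnomad_style")
    )
    freq_helix: PopulationFrequency = field(
        default_factory=lambda: PopulationFrequency("helix_style")
    )
    scores: InSilicoScores = field(default_factory=InSilicoScores)
    is_haplogroup_defining: bool = False
    internal_ac: int = 0
    plp_status: str = "none"  # "none" | "reported_plp"
    incomplete_penetrance_flag: bool = False

    @property
    def key(self) -> Key:
        return self.variant.key


@dataclass
class AnnotationResources:
    """Bundle of loaded annotation tables consumed by :func:`annotate_callset`."""

    gnomad: dict[Key, PopulationFrequency] = field(default_factory=dict)
    helix: dict[Key, PopulationFrequency] = field(default_factory=dict)
    scores: dict[Key, InSilicoScores] = field(default_factory=dict)
    regional_constraint: np.ndarray = field(
        default_factory=lambda: np.zeros(MT_GENOME_LENGTH + 1, dtype=bool)
    )
    haplogroups: dict[str, set[Key]] = field(default_factory=dict)


# -- table loaders -----------------------------------------------------------


def load_frequency_table(path: str | Path, source: str) -> dict[Key, PopulationFrequency]:
    """TSV with columns position, ref, alt, hom_af, het_af, het_ac, max_observed_hl."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"position", "ref", "alt", "hom_af", "het_af", "het_ac", "max_observed_hl"}
    if not required <= set(df.columns):
        raise MtError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    table: dict[Key, PopulationFrequency] = {}
    for row in df.itertuples(index=False):
        key = (int(row.position), str(row.ref), str(row.alt))
        try:
            table[key] = PopulationFrequency(
                source=source,
                hom_af=float(row.hom_af),
                het_af=float(row.het_af),
                het_ac=int(row.het_ac),
                max_observed_hl=float(row.max_observed_hl),
            )
        except (MtError, ValueError) as exc:
            raise MtError(f"{path}: malformed row {key}: {exc}") from exc
    return table


def load_score_table(path: str | Path) -> dict[Key, InSilicoScores]:
    """TSV with columns position, ref, alt, apogee2, hmtvar, mitotip, pon_mt_trna, mlc.

    Empty cells denote missing scores.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    table: dict[Key, InSilicoScores] = {}

    def opt(value: object) -> float | None:
        return None if pd.isna(value) else float(value)

    for row in df.itertuples(index=False):
        key = (int(row.position), str(row.ref), str(row.alt))
        try:
            table[key] = InSilicoScores(
                apogee2=opt(row.apogee2),
                hmtvar=opt(row.hmtvar),
                mitotip=opt(row.mitotip),
                pon_mt_trna=opt(row.pon_mt_trna),
                mlc=opt(row.mlc),
            )
        except (MtError, ValueError) as exc:
            raise MtError(f"{path}: malformed row {key}: {exc}") from exc
    return table


def load_regional_constraint_bed(path: str | Path) -> np.ndarray:
    """BED intervals (0-based half-open) -> boolean mask over 1-based positions."""
    mask = np.zeros(MT_GENOME_LENGTH + 1, dtype=bool)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MtError(f"{path}:{lineno}: BED line needs >= 3 fields")
            start0, end0 = int(fields[1]), int(fields[2])
            if not 0 <= start0 < end0 <= MT_GENOME_LENGTH:
                raise MtError(f"{path}:{lineno}: interval [{start0}, {end0}) outside the mtDNA")
            mask[start0 + 1 : end0 + 1] = True  # 1-based inclusive
    return mask


def load_haplogroup_table(path: str | Path) -> dict[str, set[Key]]:
    """TSV with columns haplogroup, position, ref, alt."""
    df = pd.read_csv(path, sep="\t")
    table: dict[str, set[Key]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.haplogroup), set()).add(
            (int(row.position), str(row.ref), str(row.alt))
        )
    return table


# -- lookups -----------------------------------------------------------------


def annotate_frequencies(
    variant: MtVariant,
    gnomad_table: dict[Key, PopulationFrequency],
    helix_table: dict[Key, PopulationFrequency],
) -> tuple[PopulationFrequency, PopulationFrequency]:
    """Exact-key lookup in both frequency sources; absent -> all-zero record."""
    gnomad = gnomad_table.get(variant.key, PopulationFrequency("gnomad_style"))
    helix = helix_table.get(variant.key, PopulationFrequency("helix_style"))
    return gnomad, helix


def flag_haplogroup_defining(
    variant: MtVariant, haplogroup: str, hg_table: dict[str, set[Key]]
) -> bool:
    """True iff the variant defines the sample's own haplogroup."""
    if haplogroup not in hg_table:
        raise MtError(f"unknown haplogroup {haplogroup!r}")
    return variant.key in hg_table[haplogroup]


def internal_allele_count(
    variant: MtVariant,
    cohort_callsets: list[SampleCallSet],
    detection_floor: float = DETECTION_FLOOR,
) -> int:
    """Number of cohort samples carrying the variant at HL >= the detection floor."""
    count = 0
    for cs in cohort_callsets:
        hit = cs.get(variant.key)
        if hit is not None and hit.hl >= detection_floor:
            count += 1
    return count


def annotate_callset(
    callset: SampleCallSet,
    resources: AnnotationResources,
    cohort_callsets: list[SampleCallSet] | None = None,
    internal_ac_index: dict[Key, int] | None = None,
) -> list[AnnotatedVariant]:
    """Annotate every variant of one call set.

    ``internal_ac_index`` (from :func:`build_internal_ac_index`) avoids
    rescanning the cohort per variant; when neither it nor
    ``cohort_callsets`` is given the internal AC defaults to 1 (the
    carrier itself).
    """
    annotated: list[AnnotatedVariant] = []
    for v in callset.variants:
        gnomad, helix = annotate_frequencies(v, resources.gnomad, resources.helix)
        scores = resources.scores.get(v.key, InSilicoScores())
        scores = InSilicoScores(
            apogee2=scores.apogee2,
            hmtvar=scores.hmtvar,
            mitotip=scores.mitotip,
            pon_mt_trna=scores.pon_mt_trna,
            mlc=scores.mlc,
            in_regional_constraint=bool(resources.regional_constraint[v.position]),
        )
        if internal_ac_index is not None:
            ac = internal_ac_index.get(v.key, 0)
        elif cohort_callsets is not None:
            ac = internal_allele_count(v, cohort_callsets)
        else:
            ac = 1
        annotated.append(
            AnnotatedVariant(
                variant=v,
                sample_id=callset.sample_id,
                freq_gnomad=gnomad,
                freq_helix=helix,
                scores=scores,
                is_haplogroup_defining=(
                    flag_haplogroup_defining(v, callset.haplogroup, resources.haplogroups)
                    if callset.haplogroup in resources.haplogroups
                    else False
                ),
                internal_ac=ac,
            )
        )
    return annotated


def build_internal_ac_index(
    cohort_callsets: list[SampleCallSet], detection_floor: float = DETECTION_FLOOR
) -> dict[Key, int]:
    """Carrier count per variant key across the whole cohort, in one pass."""
    index: dict[Key, int] = {}
    for cs in cohort_callsets:
        for v in cs.variants:
            if v.hl >= detection_floor:
                index[v.key] = index.get(v.key, 0) + 1
    return index
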