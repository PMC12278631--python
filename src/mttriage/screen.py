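"""Reported pathogenic-variant screening.

The catalog of reported P/LP variants is the union of MITOMAP-style
"confirmed" entries and ClinVar-style P/LP entries with >= 2-star
review status.  Call sets are screened at >= 5% HL; hits are stratified
into triage tiers by HL against the typical disease-causing threshold
(60%) and by whether the variant is curated as incompletely penetrant
at near homoplasmy (e.g., the common LHON alleles).  Large deletions
are reported separately at any HL.

The final clinical labels (diagnostic / candidate / undetermined)
require expert review; hits carry an empty ``clinical_label`` slot that
is never auto-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import pandas as pd
import yaml

from .annotate import Key
from .core import MtDeletion, MtError, SampleCallSet

MIN_SCREEN_HL = 0.05
HIGH_HL_THRESHOLD = 0.60

TIER_HIGH_PENETRANT = "high_hl_penetrant"
TIER_HIGH_INCOMPLETE = "high_hl_incomplete_penetrance"
TIER_LOW = "low_hl"


@dataclass
class PlpEntry:
    source_flags: set[str]  # subset of {"mitomap_cfrm", "clinvar_plp_2star"}
    associated_phenotype: str = ""
    incomplete_penetrance: bool = False


@dataclass
class PlpCatalog:
    entries: dict[Key, PlpEntry] = field(default_factory=dict)

    def __contains__(self, key: Key) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: Key) -> PlpEntry | None:
        return self.entries.get(key)


@dataclass
class ScreenHit:
    sample_id: str
    key: Key
    gene: str
    hl: float
    alt_depth: int
    ref_depth: int
    tier: str
    incomplete_penetrance: bool
    associated_phenotype: str = ""
    clinical_label: str = ""  # reserved for human review


@dataclass
class DeletionHit:
    sample_id: str
    deletion: MtDeletion
    clinical_label: str = ""


def default_incomplete_penetrance_keys() -> set[Key]:
    """Curated variants reported as incompletely penetrant at near homoplasmy.

    Shipped as an editable YAML list; seeded with the classic LHON
    alleles, the aminoglycoside-ototoxicity rRNA variant, and
    m.3243A>G, for which asymptomatic high-HL carriers are reported.
    """
    text = (
        importlib_resources.files("mttriage").joinpath("data/incomplete_penetrance.yaml").read_text()
    )
    return _parse_penetrance_yaml(text)


def load_incomplete_penetrance(path: str | Path) -> set[Key]:
    return _parse_penetrance_yaml(Path(path).read_text(encoding="utf-8"))


def _parse_penetrance_yaml(text: str) -> set[Key]:
    data = yaml.safe_load(text)
    keys: set[Key] = set()
    for entry in data.get("incomplete_penetrance", []):
        keys.add((int(entry["position"]), str(entry["ref"]), str(entry["alt"])))
    return keys


def build_plp_catalog(
    mitomap_records,
    clinvar_records,
    incomplete_penetrance_keys: set[Key] | None = None,
) -> PlpCatalog:
    """Merge MITOMAP-confirmed and ClinVar >= 2-star P/LP records.

    ``mitomap_records``: iterable of dicts with position, ref, alt,
    status (only "cfrm" entries enter the catalog), phenotype.
    ``clinvar_records``: dicts with position, ref, alt, classification
    ("P", "LP" or "P/LP"), stars (int), phenotype.
    """
    if incomplete_penetrance_keys is None:
        incomplete_penetrance_keys = default_incomplete_penetrance_keys()
    entries: dict[Key, PlpEntry] = {}

    def add(key: Key, flag: str, phenotype: str) -> None:
        entry = entries.get(key)
        if entry is None:
            entries[key] = PlpEntry(
                source_flags={flag},
                associated_phenotype=phenotype,
                incomplete_penetrance=key in incomplete_penetrance_keys,
            )
        else:
            entry.source_flags.add(flag)
            if not entry.associated_phenotype:
                entry.associated_phenotype = phenotype

    for rec in mitomap_records:
        if str(rec.get("status", "")) != "cfrm":
            continue
        key = (int(rec["position"]), str(rec["ref"]), str(rec["alt"]))
        _check_conflict(entries, key, "mitomap_cfrm")
        add(key, "mitomap_cfrm", str(rec.get("phenotype", "")))
    clinvar_seen: dict[tuple[int, str], str] = {}
    for rec in clinvar_records:
        if str(rec.get("classification", "")) not in {"P", "LP", "P/LP"}:
            continue
        if int(rec.get("stars", 0)) < 2:
            continue
        key = (int(rec["position"]), str(rec["ref"]), str(rec["alt"]))
        prior = clinvar_seen.get((key[0], key[1]))
        if prior is not None and prior != key[2]:
            raise MtError(
                f"conflicting ClinVar alt alleles at m.{key[0]}{key[1]}: {prior} vs {key[2]}"
            )
        clinvar_seen[(key[0], key[1])] = key[2]
        add(key, "clinvar_plp_2star", str(rec.get("phenotype", "")))
    return PlpCatalog(entries=entries)


def _check_conflict(entries: dict[Key, PlpEntry], key: Key, flag: str) -> None:
    # duplicate identical keys within one source are tolerated (dedup);
    # conflicting alts at one (position, ref) within one source are not.
    for existing in entries:
        if existing[0] == key[0] and existing[1] == key[1] and existing[2] != key[2]:
            if flag in entries[existing].source_flags:
                raise MtError(
                    f"conflicting {flag} alt alleles at m.{key[0]}{key[1]}: "
                    f"{existing[2]} vs {key[2]}"
                )


def load_catalog_tsv(path: str | Path, source: str) -> list[dict]:
    """Load a MITOMAP-style ('mitomap') or ClinVar-style ('clinvar') TSV export."""
    df = pd.read_csv(path, sep="\t")
    records = df.to_dict("records")
    expected = {"mitomap": {"position", "ref", "alt", "status"},
                "clinvar": {"position", "ref", "alt", "classification", "stars"}}[source]
    if records and not expected <= set(records[0]):
        raise MtError(f"{path}: missing columns {sorted(expected - set(records[0]))}")
    return records


def triage_hit(
    hl: float,
    incomplete_penetrance: bool,
    high_hl_threshold: float = HIGH_HL_THRESHOLD,
) -> str:
    """Stratify a catalog hit by HL and curated penetrance."""
    if hl >= high_hl_threshold:
        return TIER_HIGH_INCOMPLETE if incomplete_penetrance else TIER_HIGH_PENETRANT
    return TIER_LOW


def screen_callset(
    callset: SampleCallSet,
    catalog: PlpCatalog,
    min_hl: float = MIN_SCREEN_HL,
    high_hl_threshold: float = HIGH_HL_THRESHOLD,
) -> tuple[list[ScreenHit], list[DeletionHit]]:
    """One hit per catalog variant at HL >= ``min_hl``; deletions at any HL."""
    hits: list[ScreenHit] = []
    for v in callset.variants:
        entry = catalog.get(v.key)
        if entry is None or v.hl < min_hl:
            continue
        hits.append(
            ScreenHit(
                sample_id=callset.sample_id,
                key=v.key,
                gene=v.gene,
                hl=v.hl,
                alt_depth=v.alt_depth,
                ref_depth=v.ref_depth,
                tier=triage_hit(v.hl, entry.incomplete_penetrance, high_hl_threshold),
                incomplete_penetrance=entry.incomplete_penetrance,
                associated_phenotype=entry.associated_phenotype,
            )
        )
    deletion_hits = [DeletionHit(sample_id=callset.sample_id, deletion=d) for d in callset.deletions]
    return hits, deletion_hits
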