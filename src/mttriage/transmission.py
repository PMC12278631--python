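"""Maternal transmission analysis.

Proband and maternal call sets of the same data type are paired;
proband variants at or above the detection floor are partitioned into
*shared* (same key detected in the mother) and *proband-only* (de novo,
somatic, or below detection in the sampled maternal tissue — the
records carry a note slot, no de novo claim is made).  Shared variants
are classified for heteroplasmic shift around the typical
disease-causing threshold of 60% HL: a *positive* shift crosses from
strictly below to strictly above the threshold between generations, a
*negative* shift the reverse; an HL exactly at the threshold on either
side yields "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import Key
from .core import MtError, SampleCallSet

DETECTION_FLOOR = 0.01
SHIFT_THRESHOLD = 0.60

SHIFT_POSITIVE = "positive"
SHIFT_NEGATIVE = "negative"
SHIFT_NONE = "none"
SHIFT_NA = "n/a"

STATUS_SHARED = "shared"
STATUS_PROBAND_ONLY = "proband_only"


@dataclass
class FamilyPair:
    family_id: str
    proband_callset: SampleCallSet
    maternal_callset: SampleCallSet

    def __post_init__(self) -> None:
        if self.proband_callset.data_type != self.maternal_callset.data_type:
            raise MtError(
                f"family {self.family_id}: proband data type "
                f"{self.proband_callset.data_type} != maternal "
                f"{self.maternal_callset.data_type}"
            )
        if self.proband_callset.sample_id == self.maternal_callset.sample_id:
            raise MtError(f"family {self.family_id}: proband and maternal sample ids coincide")

    @property
    def data_type(self) -> str:
        return self.proband_callset.data_type


@dataclass
class TransmissionRecord:
    family_id: str
    key: Key
    proband_hl: float
    maternal_hl: float | None
    status: str
    shift: str
    note: str = ""


def classify_shift(
    maternal_hl: float, proband_hl: float, threshold: float = SHIFT_THRESHOLD
) -> str:
    """Shift class of a shared variant across one transmission."""
    if not (0.0 <= maternal_hl <= 1.0 and 0.0 <= proband_hl <= 1.0):
        raise MtError("HLs must be in [0, 1]")
    if maternal_hl < threshold and proband_hl > threshold:
        return SHIFT_POSITIVE
    if maternal_hl > threshold and proband_hl < threshold:
        return SHIFT_NEGATIVE
    return SHIFT_NONE


def pair_variants(
    pair: FamilyPair,
    detection_floor: float = DETECTION_FLOOR,
    threshold: float = SHIFT_THRESHOLD,
) -> list[TransmissionRecord]:
    """One record per proband variant at HL >= the detection floor."""
    maternal = {
        v.key: v.hl for v in pair.maternal_callset.variants if v.hl >= detection_floor
    }
    records: list[TransmissionRecord] = []
    for v in pair.proband_callset.variants:
        if v.hl < detection_floor:
            continue
        m_hl = maternal.get(v.key)
        if m_hl is not None:
            records.append(
                TransmissionRecord(
                    family_id=pair.family_id,
                    key=v.key,
                    proband_hl=v.hl,
                    maternal_hl=m_hl,
                    status=STATUS_SHARED,
                    shift=classify_shift(m_hl, v.hl, threshold),
                )
            )
        else:
            records.append(
                TransmissionRecord(
                    family_id=pair.family_id,
                    key=v.key,
                    proband_hl=v.hl,
                    maternal_hl=None,
                    status=STATUS_PROBAND_ONLY,
                    shift=SHIFT_NA,
                    note="de novo, somatic, or present at undetectable levels",
                )
            )
    return records


@dataclass
class TransmissionSummary:
    total: int
    shared: int
    proband_only: int
    positive_shift: int
    negative_shift: int
    proband_only_high_hl: int
    high_hl_threshold: float = SHIFT_THRESHOLD
    # percentages (2 decimals); None marks a zero denominator
    maternal_detection_pct: float | None = None
    positive_shift_pct: float | None = None
    negative_shift_pct: float | None = None
    proband_only_high_hl_pct: float | None = None


def _pct(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 2)


def transmission_summary(
    records: list[TransmissionRecord], high_hl_threshold: float = SHIFT_THRESHOLD
) -> TransmissionSummary:
    """Cohort-wide counts and percentages over per-family records."""
    shared = [r for r in records if r.status == STATUS_SHARED]
    proband_only = [r for r in records if r.status == STATUS_PROBAND_ONLY]
    positive = sum(1 for r in shared if r.shift == SHIFT_POSITIVE)
    negative = sum(1 for r in shared if r.shift == SHIFT_NEGATIVE)
    po_high = sum(1 for r in proband_only if r.proband_hl >= high_hl_threshold)
    return TransmissionSummary(
        total=len(records),
        shared=len(shared),
        proband_only=len(proband_only),
        positive_shift=positive,
        negative_shift=negative,
        proband_only_high_hl=po_high,
        high_hl_threshold=high_hl_threshold,
        maternal_detection_pct=_pct(len(shared), len(records)),
        positive_shift_pct=_pct(positive, len(shared)),
        negative_shift_pct=_pct(negative, len(shared)),
        proband_only_high_hl_pct=_pct(po_high, len(proband_only)),
    )
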