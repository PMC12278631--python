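"""Core mtDNA variant data model and heteroplasmy arithmetic.

Coordinates are 1-based, inclusive, on the revised Cambridge Reference
Sequence (rCRS, NC_012920.1), a circular molecule of 16,569 bp.  The
heteroplasmy level (HL) of a variant is the fraction of mtDNA molecules
carrying the alternate allele, estimated here as alt / (alt + ref) over
the two reported allele depths; reads supporting other alleles at the
site are ignored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

MT_GENOME_LENGTH = 16569

CONSEQUENCES = frozenset(
    {
        "synonymous",
        "missense",
        "stop_gained",
        "frameshift",
        "stop_loss",
        "tRNA",
        "rRNA",
        "noncoding",
    }
)

DATA_TYPES = frozenset({"GS", "ES_twist", "ES_nextera", "RNA"})

_DEL_LABEL_RE = re.compile(r"^m\.(\d+)_(\d+)del(\d+)$")


class MtError(ValueError):
    """Raised on contract violations in the mtDNA data model."""


def compute_hl(alt_depth: int, ref_depth: int) -> float:
    """Heteroplasmy level from an (alt, ref) allele-depth pair.

    Parameters
    ----------
    alt_depth, ref_depth : int
        Non-negative read counts supporting the alternate and reference
        allele.  Their sum must be positive: a site with no informative
        reads is uncallable.

    Returns
    -------
    float
        alt_depth / (alt_depth + ref_depth), in [0, 1].
    """
    if alt_depth < 0 or ref_depth < 0:
        raise MtError(f"negative allele depth: alt={alt_depth}, ref={ref_depth}")
    total = alt_depth + ref_depth
    if total == 0:
        raise MtError("uncallable site: alt_depth + ref_depth == 0")
    return alt_depth / total


def hl_percent(hl: float) -> int:
    """Display an HL fraction as an integer percent.

    Rounds half away from zero, the convention that maps 0.1892 -> 19
    and 0.7011 -> 70.
    """
    if not 0.0 <= hl <= 1.0:
        raise MtError(f"HL out of range [0, 1]: {hl}")
    return int(math.floor(hl * 100.0 + 0.5))


def deletion_label(start: int, end: int) -> str:
    """HGVS-style label for a large mtDNA deletion, e.g. ``m.8470_13446del4977``.

    ``start`` and ``end`` are the first and last deleted bases (1-based,
    inclusive); the size suffix is ``end - start + 1``.  Origin-spanning
    deletions (start >= end) are rejected.
    """
    if not (1 <= start <= MT_GENOME_LENGTH and 1 <= end <= MT_GENOME_LENGTH):
        raise MtError(f"deletion breakpoints outside 1..{MT_GENOME_LENGTH}: {start}, {end}")
    if start >= end:
        raise MtError(
            f"start ({start}) must be < end ({end}); origin-spanning deletions unsupported"
        )
    return f"m.{start}_{end}del{end - start + 1}"


def parse_deletion_label(label: str) -> tuple[int, int, int]:
    """Invert :func:`deletion_label`; returns (start, end, size)."""
    m = _DEL_LABEL_RE.match(label)
    if m is None:
        raise MtError(f"not a deletion label: {label!r}")
    start, end, size = (int(g) for g in m.groups())
    if size != end - start + 1:
        raise MtError(f"inconsistent deletion label {label!r}: size != end - start + 1")
    return start, end, size


@dataclass
class MtVariant:
    """One called mtDNA SNV or small indel with its allele depths and HL."""

    position: int
    ref_allele: str
    alt_allele: str
    alt_depth: int
    ref_depth: int
    hl: float | None = None
    consequence: str = "noncoding"
    gene: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise MtError(f"position {self.position} outside 1..{MT_GENOME_LENGTH}")
        if not self.ref_allele or not self.alt_allele:
            raise MtError("ref_allele and alt_allele must be non-empty")
        if self.consequence not in CONSEQUENCES:
            raise MtError(f"unknown consequence {self.consequence!r}")
        if self.hl is None:
            self.hl = compute_hl(self.alt_depth, self.ref_depth)
        if not 0.0 <= self.hl <= 1.0:
            raise MtError(f"HL out of range: {self.hl}")
        if self.alt_depth < 0 or self.ref_depth < 0:
            raise MtError("allele depths must be non-negative")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def variant_class(self) -> str:
        """``indel`` iff ref and alt lengths differ, else ``SNV``."""
        return "indel" if len(self.ref_allele) != len(self.alt_allele) else "SNV"

    @property
    def label(self) -> str:
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"


@dataclass
class MtDeletion:
    """A large mtDNA deletion with breakpoints and heteroplasmy level."""

    start: int
    end: int
    hl: float

    def __post_init__(self) -> None:
        # deletion_label re-validates breakpoints and ordering
        deletion_label(self.start, self.end)
        if not 0.0 <= self.hl <= 1.0:
            raise MtError(f"deletion HL out of range: {self.hl}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return deletion_label(self.start, self.end)


@dataclass
class SampleCallSet:
    """All variant calls of one sample plus its QC-relevant metadata."""

    sample_id: str
    data_type: str
    haplogroup: str = ""
    variants: list[MtVariant] = field(default_factory=list)
    deletions: list[MtDeletion] = field(default_factory=list)
    mean_coverage: float = 0.0
    contamination_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise MtError(f"unknown data type {self.data_type!r}; expected one of {sorted(DATA_TYPES)}")
        if self.mean_coverage < 0:
            raise MtError("mean_coverage must be >= 0")
        seen: set[tuple[int, str, str]] = set()
        for v in self.variants:
            if v.key in seen:
                raise MtError(f"duplicate variant {v.label} in sample {self.sample_id}")
            seen.add(v.key)

    def get(self, key: tuple[int, str, str]) -> MtVariant | None:
        for v in self.variants:
            if v.key == key:
                return v
        return None

    def __len__(self) -> int:
        return len(self.variants)
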