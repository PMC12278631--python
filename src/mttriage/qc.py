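"""Sample-level quality control.

Two exclusion rules apply before any variant analysis:

* **contamination** — a sample is contaminated when >= 2% of its
  observed haplogroup-defining variants sit at an intermediate HL of
  85%-99.8%.  True homoplasmies of the carrier's own haplogroup should
  be at (near-)homoplasmy; a second mtDNA population drags them into
  that window.
* **low coverage** — mean per-base mtDNA coverage < 20x.

The denominator of the contamination fraction is the set of
haplogroup-defining variants of the sample's own haplogroup observed in
the sample at any HL (the full phylotree expectation is not an input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Key, flag_haplogroup_defining
from .core import MT_GENOME_LENGTH, MtError, SampleCallSet

CONTAMINATION_HL_LOW = 0.85
CONTAMINATION_HL_HIGH = 0.998
MAX_CONTAMINATION = 0.02
MIN_MEAN_COVERAGE = 20.0


@dataclass
class QcResult:
    sample_id: str
    mean_coverage: float
    contamination_fraction: float
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def contamination_fraction(callset: SampleCallSet, hg_table: dict[str, set[Key]]) -> float:
    """Fraction of observed haplogroup-defining variants at 85%-99.8% HL.

    Returns 0.0 when no haplogroup-defining variant is observed.
    Raises on an unknown haplogroup label.
    """
    if callset.haplogroup not in hg_table:
        raise MtError(f"unknown haplogroup {callset.haplogroup!r} for sample {callset.sample_id}")
    observed = [
        v for v in callset.variants if flag_haplogroup_defining(v, callset.haplogroup, hg_table)
    ]
    if not observed:
        return 0.0
    in_window = sum(1 for v in observed if CONTAMINATION_HL_LOW <= v.hl <= CONTAMINATION_HL_HIGH)
    return in_window / len(observed)


def mean_coverage(depths) -> float:
    """Arithmetic mean of a full-length per-base depth vector (16,569 entries)."""
    depths = np.asarray(depths, dtype=float)
    if depths.shape != (MT_GENOME_LENGTH,):
        raise MtError(f"expected {MT_GENOME_LENGTH} per-base depths, got {depths.shape}")
    if (depths < 0).any():
        raise MtError("negative depth encountered")
    return float(depths.mean())


def load_depth_table(path: str | Path) -> np.ndarray:
    """Per-base depths from TSV: 2 columns (position, depth) or samtools-depth
    style 3 columns (chrom, position, depth).  Positions are 1-based; missing
    positions get depth 0."""
    depths = np.zeros(MT_GENOME_LENGTH, dtype=float)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                pos, depth = int(fields[0]), float(fields[1])
            elif len(fields) >= 3:
                pos, depth = int(fields[1]), float(fields[2])
            else:
                raise MtError(f"{path}:{lineno}: expected 2 or 3 columns")
            if not 1 <= pos <= MT_GENOME_LENGTH:
                raise MtError(f"{path}:{lineno}: position {pos} outside the mtDNA")
            depths[pos - 1] = depth
    return depths


def qc_pass(
    sample_id: str,
    mean_cov: float,
    contamination: float,
    min_coverage: float = MIN_MEAN_COVERAGE,
    max_contamination: float = MAX_CONTAMINATION,
) -> QcResult:
    """Apply both exclusion rules; < 20x fails, >= 2% contamination fails."""
    reasons: list[str] = []
    if mean_cov < min_coverage:
        reasons.append("low_coverage")
    if contamination >= max_contamination:
        reasons.append("contamination")
    return QcResult(
        sample_id=sample_id,
        mean_coverage=mean_cov,
        contamination_fraction=contamination,
        fail_reasons=reasons,
    )
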