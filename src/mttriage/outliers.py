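"""Excess-heteroplasmy (mutator-phenotype) outlier detection.

Defective proofreading of the mtDNA polymerase (POLG exonuclease
domain) produces genome-wide accumulation of somatic point mutations:
hundreds of low-HL variants in a sample whose peers carry ~10.  Each
sample's heteroplasmic burden is counted in the HL window
[floor, ceiling) — default [1%, 95%), excluding near-homoplasmies —
and flagged within its data-type stratum by a robust z-score,
(total - median) / (1.4826 * MAD), with an absolute count floor so that
ordinary variability is never flagged.  A degenerate stratum (MAD = 0)
falls back to the count floor alone, except that samples at the stratum
median are never flagged (their robust z is undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SampleCallSet

HET_FLOOR = 0.01
HET_CEILING = 0.95
Z_CUT = 5.0
MIN_OUTLIER_COUNT = 100
MAD_SCALE = 1.4826  # consistency constant for a normal distribution


@dataclass
class HetBurden:
    sample_id: str
    data_type: str
    snv_count: int
    indel_count: int
    robust_z: float = float("nan")
    outlier: bool = False

    @property
    def total(self) -> int:
        return self.snv_count + self.indel_count


def heteroplasmic_count(
    callset: SampleCallSet, floor: float = HET_FLOOR, ceiling: float = HET_CEILING
) -> tuple[int, int]:
    """(snv_count, indel_count) of variants with floor <= HL < ceiling."""
    snv = indel = 0
    for v in callset.variants:
        if floor <= v.hl < ceiling:
            if v.variant_class == "SNV":
                snv += 1
            else:
                indel += 1
    return snv, indel


def burden(callset: SampleCallSet, floor: float = HET_FLOOR, ceiling: float = HET_CEILING) -> HetBurden:
    snv, indel = heteroplasmic_count(callset, floor, ceiling)
    return HetBurden(
        sample_id=callset.sample_id,
        data_type=callset.data_type,
        snv_count=snv,
        indel_count=indel,
    )


def flag_outliers(
    burdens: list[HetBurden],
    z_cut: float = Z_CUT,
    min_count: int = MIN_OUTLIER_COUNT,
) -> list[HetBurden]:
    """Flag excess-burden samples within each data-type stratum.

    Returns the same burden objects with ``robust_z`` and ``outlier``
    filled in.  Strata with fewer than 3 samples get a warning and no
    flags.
    """
    by_type: dict[str, list[HetBurden]] = {}
    for b in burdens:
        by_type.setdefault(b.data_type, []).append(b)
    for data_type, stratum in by_type.items():
        if len(stratum) < 3:
            warnings.warn(
                f"stratum {data_type!r} has {len(stratum)} samples (< 3); no outlier flags",
                stacklevel=2,
            )
            for b in stratum:
                b.robust_z = float("nan")
                b.outlier = False
            continue
        totals = np.array([b.total for b in stratum], dtype=float)
        median = float(np.median(totals))
        mad = float(np.median(np.abs(totals - median)))
        for b in stratum:
            if mad > 0:
                b.robust_z = (b.total - median) / (MAD_SCALE * mad)
                b.outlier = b.robust_z > z_cut and b.total >= min_count
            else:
                # robust z undefined; fall back to the absolute count floor,
                # never flagging samples sitting at the stratum median
                b.robust_z = float("inf") if b.total > median else float("nan")
                b.outlier = b.total > median and b.total >= min_count
    return burdens
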