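"""Reading and writing of per-sample mtDNA call sets.

Two on-disk dialects are supported:

* **VCF** — single-sample, contig ``chrM`` (``MT`` and ``NC_012920.1``
  accepted on input and remapped), ``FORMAT/AD`` depth pair (ref, alt),
  ``FORMAT/HL`` fractional heteroplasmy, custom ``INFO/GENE`` and
  ``INFO/CONSEQ`` annotations.  Large deletions are symbolic ``<DEL>``
  records with ``INFO/END``; POS holds the first deleted base.
* **TSV** — tab-separated with header ``sample_id, position, ref, alt,
  alt_depth, ref_depth, consequence, gene, hl``; sample metadata in
  leading ``#key=value`` comment lines.  Deletion rows use ``ref=DEL``
  and the ``m.{start}_{end}del{size}`` label in the ``alt`` column.

Both writers emit records sorted by position; HL is stored as a fraction
and recomputed from the depth pair when absent on input.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pysam

from .core import (
    MT_GENOME_LENGTH,
    MtDeletion,
    MtError,
    MtVariant,
    SampleCallSet,
    compute_hl,
    parse_deletion_label,
)

MT_CONTIGS = {"chrM", "MT", "NC_012920.1"}

_TSV_COLUMNS = [
    "sample_id",
    "position",
    "ref",
    "alt",
    "alt_depth",
    "ref_depth",
    "consequence",
    "gene",
    "hl",
]


def read_callset(path: str | Path, format: str | None = None) -> SampleCallSet:
    """Load a :class:`SampleCallSet` from a VCF or TSV file.

    ``format`` is inferred from the file suffix when omitted.  Malformed
    records raise :class:`MtError` naming the offending record.
    """
    path = Path(path)
    fmt = format or ("vcf" if path.suffix == ".vcf" else "tsv")
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise MtError(f"unknown call-set format {fmt!r}")


def write_callset(callset: SampleCallSet, path: str | Path, format: str | None = None) -> None:
    """Write a call set; inverse of :func:`read_callset`."""
    path = Path(path)
    fmt = format or ("vcf" if path.suffix == ".vcf" else "tsv")
    if fmt == "vcf":
        _write_vcf(callset, path)
    elif fmt == "tsv":
        _write_tsv(callset, path)
    else:
        raise MtError(f"unknown call-set format {fmt!r}")


# -- VCF dialect -------------------------------------------------------------


def _vcf_header(callset: SampleCallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add("chrM", length=MT_GENOME_LENGTH)
    header.add_line('##ALT=<ID=DEL,Description="Large mtDNA deletion">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Last deleted base (1-based)">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="mtDNA gene symbol">')
    header.add_line('##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Functional consequence">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref, alt)">')
    header.add_line('##FORMAT=<ID=HL,Number=1,Type=Float,Description="Heteroplasmy level (fraction)">')
    header.add_line(f"##mt_data_type={callset.data_type}")
    header.add_line(f"##mt_haplogroup={callset.haplogroup}")
    header.add_line(f"##mt_mean_coverage={callset.mean_coverage!r}")
    header.add_sample(callset.sample_id)
    return header


def _write_vcf(callset: SampleCallSet, path: Path) -> None:
    header = _vcf_header(callset)
    sid = callset.sample_id
    with pysam.VariantFile(str(path), "w", header=header) as out:
        records = []
        for v in sorted(callset.variants, key=lambda v: v.position):
            rec = out.new_record(
                contig="chrM",
                start=v.position - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["CONSEQ"] = v.consequence
            rec.samples[sid]["AD"] = (v.ref_depth, v.alt_depth)
            rec.samples[sid]["HL"] = float(v.hl)
            records.append(rec)
        for d in sorted(callset.deletions, key=lambda d: d.start):
            rec = out.new_record(
                contig="chrM",
                start=d.start - 1,
                alleles=("N", "<DEL>"),
                stop=d.end,
            )
            rec.info["SVTYPE"] = "DEL"
            rec.samples[sid]["HL"] = float(d.hl)
            records.append(rec)
        for rec in sorted(records, key=lambda r: r.pos):
            out.write(rec)


def _read_vcf(path: Path) -> SampleCallSet:
    variants: list[MtVariant] = []
    deletions: list[MtDeletion] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise MtError(f"{path}: expected a single-sample VCF, found {len(samples)} samples")
        sid = samples[0]
        meta = {"mt_data_type": "GS", "mt_haplogroup": "", "mt_mean_coverage": "0.0"}
        for line in str(vcf.header).splitlines():
            for key in meta:
                if line.startswith(f"##{key}="):
                    meta[key] = line.split("=", 1)[1]
        has_hl = "HL" in vcf.header.formats
        has_gene = "GENE" in vcf.header.info
        has_conseq = "CONSEQ" in vcf.header.info
        for rec in vcf:
            position = rec.pos  # pysam's pos is already 1-based
            if rec.contig not in MT_CONTIGS:
                raise MtError(f"{path}: unknown contig {rec.contig!r} at record {position}")
            if rec.alts is None or len(rec.alts) != 1:
                raise MtError(f"{path}: record at {position} must have exactly one ALT")
            alt = rec.alts[0]
            fmt = rec.samples[sid]
            hl = fmt.get("HL") if has_hl else None
            if alt == "<DEL>":
                if hl is None:
                    raise MtError(f"{path}: <DEL> record at {position} lacks FORMAT/HL")
                deletions.append(MtDeletion(start=position, end=rec.stop, hl=float(hl)))
                continue
            ad = fmt.get("AD")
            if ad is None or len(ad) != 2 or any(x is None for x in ad):
                raise MtError(f"{path}: record at {position} lacks a FORMAT/AD (ref, alt) pair")
            ref_depth, alt_depth = int(ad[0]), int(ad[1])
            if not 1 <= position <= MT_GENOME_LENGTH:
                raise MtError(f"{path}: position {position} outside 1..{MT_GENOME_LENGTH}")
            gene = rec.info.get("GENE", ".") if has_gene else "."
            try:
                variants.append(
                    MtVariant(
                        position=position,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        alt_depth=alt_depth,
                        ref_depth=ref_depth,
                        hl=float(hl) if hl is not None else None,
                        consequence=rec.info.get("CONSEQ", "noncoding") if has_conseq else "noncoding",
                        gene="" if gene == "." else gene,
                    )
                )
            except MtError as exc:
                raise MtError(f"{path}: malformed record at position {position}: {exc}") from exc
    return SampleCallSet(
        sample_id=sid,
        data_type=meta["mt_data_type"],
        haplogroup=meta["mt_haplogroup"],
        variants=variants,
        deletions=deletions,
        mean_coverage=float(meta["mt_mean_coverage"]),
    )


# -- TSV dialect -------------------------------------------------------------


def _write_tsv(callset: SampleCallSet, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"#sample_id={callset.sample_id}\n")
        fh.write(f"#data_type={callset.data_type}\n")
        fh.write(f"#haplogroup={callset.haplogroup}\n")
        fh.write(f"#mean_coverage={callset.mean_coverage!r}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        rows = []
        for v in callset.variants:
            rows.append(
                (
                    v.position,
                    [
                        callset.sample_id,
                        v.position,
                        v.ref_allele,
                        v.alt_allele,
                        v.alt_depth,
                        v.ref_depth,
                        v.consequence,
                        v.gene,
                        repr(float(v.hl)),
                    ],
                )
            )
        for d in callset.deletions:
            rows.append(
                (
                    d.start,
                    [callset.sample_id, d.start, "DEL", d.label, 0, 0, "large_deletion", "", repr(float(d.hl))],
                )
            )
        for _, row in sorted(rows, key=lambda r: r[0]):
            writer.writerow(row)


def _read_tsv(path: Path) -> SampleCallSet:
    meta = {"sample_id": "", "data_type": "GS", "haplogroup": "", "mean_coverage": "0.0"}
    variants: list[MtVariant] = []
    deletions: list[MtDeletion] = []
    with open(path, newline="", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key in meta:
                meta[key] = value
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise MtError(f"{path}: missing header row")
    header = lines[body_start].split("\t")
    required = _TSV_COLUMNS[:-1]  # hl column optional
    if header[: len(required)] != required:
        raise MtError(f"{path}: unexpected TSV header {header!r}")
    has_hl = "hl" in header
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise MtError(f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}")
        row = dict(zip(header, fields))
        if not meta["sample_id"]:
            meta["sample_id"] = row["sample_id"]
        try:
            position = int(row["position"])
            hl = float(row["hl"]) if has_hl and row["hl"] != "" else None
            if row["ref"] == "DEL":
                start, end, _ = parse_deletion_label(row["alt"])
                if start != position:
                    raise MtError(f"deletion label {row['alt']} does not start at {position}")
                deletions.append(MtDeletion(start=start, end=end, hl=hl if hl is not None else 0.0))
            else:
                variants.append(
                    MtVariant(
                        position=position,
                        ref_allele=row["ref"],
                        alt_allele=row["alt"],
                        alt_depth=int(row["alt_depth"]),
                        ref_depth=int(row["ref_depth"]),
                        hl=hl,
                        consequence=row["consequence"],
                        gene=row["gene"],
                    )
                )
        except (MtError, ValueError) as exc:
            raise MtError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return SampleCallSet(
        sample_id=meta["sample_id"],
        data_type=meta["data_type"],
        haplogroup=meta["haplogroup"],
        variants=variants,
        deletions=deletions,
        mean_coverage=float(meta["mean_coverage"]),
    )
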