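"""End-to-end cohort triage pipeline and report rendering.

Stage order: sample QC -> annotation -> reported-pathogenic screen ->
rare-variant prioritization -> maternal transmission -> mutator-outlier
detection -> MDC phenotype scoring -> report.  Every excluded sample
and every filtered variant records its first failing rule, so the
prioritization funnel is auditable.  Machine triage tiers are emitted;
the clinical labels (diagnostic / candidate / undetermined) are left to
human review and never auto-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as _annotate
from . import outliers as _outliers
from . import phenotype as _phenotype
from . import prioritize as _prioritize
from . import qc as _qc
from . import screen as _screen
from . import transmission as _transmission
from .core import MtError, SampleCallSet, hl_percent
from .io import read_callset

logger = logging.getLogger("mttriage")


@dataclass
class PipelineConfig:
    """Paths to every input consumed by :func:`run_pipeline`.

    Relative paths are resolved against ``base_dir``.
    """

    callset_dir: str = "callsets"
    pedigree: str = "pedigree.tsv"
    gnomad: str = "tables/gnomad.tsv"
    helix: str = "tables/helix.tsv"
    scores: str = "tables/scores.tsv"
    regional_constraint: str = "tables/regional_constraint.bed"
    haplogroups: str = "tables/haplogroups.tsv"
    mitomap: str = "tables/mitomap.tsv"
    clinvar: str = "tables/clinvar.tsv"
    hpo: str = "hpo.tsv"
    ontology: str = "ontology.obo"
    penetrance: str | None = None  # None -> packaged default list
    mdc_config: str | None = None  # None -> packaged default config
    base_dir: Path = field(default_factory=Path)

    def path(self, name: str) -> Path:
        return self.base_dir / getattr(self, name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "base_dir"}
        kwargs = {k: v for k, v in data.items() if k in known and v is not None}
        return cls(base_dir=path.parent, **kwargs)


@dataclass
class TriageReport:
    qc: pd.DataFrame
    screen_hits: pd.DataFrame
    deletion_hits: pd.DataFrame
    prioritized: pd.DataFrame
    transmission: pd.DataFrame
    burdens: pd.DataFrame
    mdc: pd.DataFrame
    summary: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("qc", "screen_hits", "deletion_hits", "prioritized", "transmission", "burdens", "mdc"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True), encoding="utf-8"
        )


def _missing(stage: str, path: Path) -> MtError:
    return MtError(f"stage {stage!r}: missing input file {path}")


def load_callsets(directory: Path) -> dict[str, SampleCallSet]:
    callsets: dict[str, SampleCallSet] = {}
    for path in sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.vcf")):
        cs = read_callset(path)
        callsets[cs.sample_id] = cs
    return callsets


def run_pipeline(config: PipelineConfig) -> TriageReport:
    """Execute all triage stages over a cohort directory."""
    for stage, name in (
        ("load", "pedigree"), ("annotate", "gnomad"), ("annotate", "helix"),
        ("annotate", "scores"), ("annotate", "haplogroups"),
        ("screen", "mitomap"), ("screen", "clinvar"),
        ("mdc", "hpo"), ("mdc", "ontology"),
    ):
        if not config.path(name).exists():
            raise _missing(stage, config.path(name))
    callset_dir = config.path("callset_dir")
    if not callset_dir.is_dir():
        raise _missing("load", callset_dir)

    callsets = load_callsets(callset_dir)
    logger.info("loaded %d call sets", len(callsets))
    pedigree = pd.read_csv(config.path("pedigree"), sep="\t", keep_default_na=False)

    resources = _annotate.AnnotationResources(
        gnomad=_annotate.load_frequency_table(config.path("gnomad"), "gnomad_style"),
        helix=_annotate.load_frequency_table(config.path("helix"), "helix_style"),
        scores=_annotate.load_score_table(config.path("scores")),
        regional_constraint=_annotate.load_regional_constraint_bed(config.path("regional_constraint")),
        haplogroups=_annotate.load_haplogroup_table(config.path("haplogroups")),
    )

    # -- QC ------------------------------------------------------------------
    qc_rows = []
    passing: dict[str, SampleCallSet] = {}
    for sample_id in sorted(callsets):
        cs = callsets[sample_id]
        contamination = (
            _qc.contamination_fraction(cs, resources.haplogroups)
            if cs.haplogroup in resources.haplogroups
            else 0.0
        )
        result = _qc.qc_pass(sample_id, cs.mean_coverage, contamination)
        if result.passed:
            passing[sample_id] = cs
        else:
            logger.info("excluding %s: %s", sample_id, ",".join(result.fail_reasons))
        qc_rows.append(
            {
                "sample_id": sample_id,
                "mean_coverage": result.mean_coverage,
                "contamination_fraction": result.contamination_fraction,
                "pass": result.passed,
                "fail_reasons": ",".join(result.fail_reasons),
            }
        )
    qc_df = pd.DataFrame(qc_rows)

    # -- annotation ----------------------------------------------------------
    cohort_list = [passing[s] for s in sorted(passing)]
    ac_index = _annotate.build_internal_ac_index(cohort_list)
    proband_ids = [p for p in pedigree["proband_sample"] if p in passing]
    annotated: dict[str, list[_annotate.AnnotatedVariant]] = {
        pid: _annotate.annotate_callset(passing[pid], resources, internal_ac_index=ac_index)
        for pid in proband_ids
    }

    # -- reported-pathogenic screen ------------------------------------------
    penetrance = (
        _screen.load_incomplete_penetrance(config.path("penetrance"))
        if config.penetrance
        else _screen.default_incomplete_penetrance_keys()
    )
    catalog = _screen.build_plp_catalog(
        _screen.load_catalog_tsv(config.path("mitomap"), "mitomap"),
        _screen.load_catalog_tsv(config.path("clinvar"), "clinvar"),
        incomplete_penetrance_keys=penetrance,
    )
    hit_rows, deletion_rows = [], []
    for pid in proband_ids:
        hits, deletion_hits = _screen.screen_callset(passing[pid], catalog)
        for h in hits:
            hit_rows.append(
                {
                    "sample_id": h.sample_id,
                    "gene": h.gene,
                    "variant": f"m.{h.key[0]}{h.key[1]}>{h.key[2]}",
                    "hl_percent": hl_percent(h.hl),
                    "alt_depth": h.alt_depth,
                    "ref_depth": h.ref_depth,
                    "tier": h.tier,
                    "clinical_label": h.clinical_label,
                }
            )
        for d in deletion_hits:
            deletion_rows.append(
                {
                    "sample_id": d.sample_id,
                    "label": d.deletion.label,
                    "hl_percent": hl_percent(d.deletion.hl),
                    "clinical_label": d.clinical_label,
                }
            )
    screen_df = pd.DataFrame(
        hit_rows,
        columns=["sample_id", "gene", "variant", "hl_percent", "alt_depth", "ref_depth", "tier", "clinical_label"],
    )
    deletion_df = pd.DataFrame(deletion_rows, columns=["sample_id", "label", "hl_percent", "clinical_label"])

    # -- rare-variant prioritization -----------------------------------------
    prio_cfg = _prioritize.PrioritizerConfig()
    prio_rows = []
    for pid in proband_ids:
        for decision in _prioritize.prioritize_callset(annotated[pid], prio_cfg):
            av = decision.annotated_variant
            first_fail = next(
                (
                    stage
                    for stage in ("non_haplogroup", "non_synonymous", "rare", "deleterious")
                    if not decision.stage_results[stage]
                ),
                "",
            )
            if not decision.prioritized and first_fail in ("non_haplogroup", "non_synonymous"):
                continue  # keep the report compact; funnel counts retain these stages
            prio_rows.append(
                {
                    "sample_id": pid,
                    "gene": av.variant.gene,
                    "variant": av.variant.label,
                    "consequence": av.variant.consequence,
                    "hl_percent": hl_percent(av.variant.hl),
                    "alt_depth": av.variant.alt_depth,
                    "ref_depth": av.variant.ref_depth,
                    "gnomad_hom_af": av.freq_gnomad.hom_af,
                    "helix_hom_af": av.freq_helix.hom_af,
                    "internal_ac": av.internal_ac,
                    "criteria": ",".join(sorted(decision.criteria_met)),
                    "first_failing_stage": first_fail,
                    "prioritized": decision.prioritized,
                    "clinical_label": "",
                }
            )
    prio_df = pd.DataFrame(
        prio_rows,
        columns=[
            "sample_id", "gene", "variant", "consequence", "hl_percent", "alt_depth",
            "ref_depth", "gnomad_hom_af", "helix_hom_af", "internal_ac", "criteria",
            "first_failing_stage", "prioritized", "clinical_label",
        ],
    )

    # funnel counts over all proband variants
    funnel = {"all": 0, "non_haplogroup": 0, "non_synonymous": 0, "rare": 0, "deleterious": 0}
    for pid in proband_ids:
        for decision in _prioritize.prioritize_callset(annotated[pid], prio_cfg):
            funnel["all"] += 1
            passed = True
            for stage in ("non_haplogroup", "non_synonymous", "rare", "deleterious"):
                passed = passed and decision.stage_results[stage]
                if passed:
                    funnel[stage] += 1

    # -- maternal transmission -----------------------------------------------
    transmission_records = []
    for row in pedigree.itertuples(index=False):
        if not row.maternal_sample or row.proband_sample not in passing or row.maternal_sample not in passing:
            continue
        pair = _transmission.FamilyPair(
            family_id=row.family_id,
            proband_callset=passing[row.proband_sample],
            maternal_callset=passing[row.maternal_sample],
        )
        transmission_records.extend(_transmission.pair_variants(pair))
    tx_summary = _transmission.transmission_summary(transmission_records)
    tx_df = pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "variant": f"m.{r.key[0]}{r.key[1]}>{r.key[2]}",
                "proband_hl": r.proband_hl,
                "maternal_hl": r.maternal_hl,
                "status": r.status,
                "shift": r.shift,
                "note": r.note,
            }
            for r in transmission_records
        ],
        columns=["family_id", "variant", "proband_hl", "maternal_hl", "status", "shift", "note"],
    )

    # -- mutator outliers ----------------------------------------------------
    burdens = [_outliers.burden(passing[pid]) for pid in proband_ids]
    _outliers.flag_outliers(burdens)
    burden_df = pd.DataFrame(
        [
            {
                "sample_id": b.sample_id,
                "data_type": b.data_type,
                "snv_count": b.snv_count,
                "indel_count": b.indel_count,
                "total": b.total,
                "robust_z": b.robust_z,
                "outlier": b.outlier,
            }
            for b in burdens
        ],
        columns=["sample_id", "data_type", "snv_count", "indel_count", "total", "robust_z", "outlier"],
    )

    # -- MDC phenotype scoring -----------------------------------------------
    ontology = _phenotype.load_ontology(config.path("ontology"))
    mdc_cfg = (
        _phenotype.load_mdc_config(config.path("mdc_config"))
        if config.mdc_config
        else _phenotype.default_mdc_config()
    )
    hpo_df = pd.read_csv(config.path("hpo"), sep="\t", keep_default_na=False)
    mdc_rows = []
    mdc_by_proband: dict[str, str] = {}
    for row in hpo_df.itertuples(index=False):
        if row.proband_id not in passing:
            continue
        terms = [t for t in str(row.hpo_terms).split(",") if t]
        profile = _phenotype.build_profile(row.proband_id, terms, ontology)
        result = _phenotype.mdc_score(profile, mdc_cfg)
        mdc_by_proband[row.proband_id] = result.category
        mdc_rows.append(
            {
                "proband_id": row.proband_id,
                "n_reported_terms": len(profile.reported_terms),
                "n_expanded_terms": len(profile.expanded_terms),
                "mdc_score": result.score,
                "mdc_category": result.category,
            }
        )
    mdc_df = pd.DataFrame(
        mdc_rows,
        columns=["proband_id", "n_reported_terms", "n_expanded_terms", "mdc_score", "mdc_category"],
    )

    # relaxed review for probable/definite-MDC probands
    relaxed_rows = 0
    for pid in proband_ids:
        category = mdc_by_proband.get(pid, "unlikely")
        relaxed_rows += len(_prioritize.review_all_rare(annotated[pid], category, prio_cfg))

    report = TriageReport(
        qc=qc_df,
        screen_hits=screen_df,
        deletion_hits=deletion_df,
        prioritized=prio_df,
        transmission=tx_df,
        burdens=burden_df,
        mdc=mdc_df,
        summary={},
    )
    report.summary = summarize_counts(report, n_probands=len(proband_ids), extras={
        "funnel": funnel,
        "relaxed_review_variants": relaxed_rows,
        "transmission": {
            "total": tx_summary.total,
            "shared": tx_summary.shared,
            "proband_only": tx_summary.proband_only,
            "positive_shift": tx_summary.positive_shift,
            "negative_shift": tx_summary.negative_shift,
            "maternal_detection_pct": tx_summary.maternal_detection_pct,
            "positive_shift_pct": tx_summary.positive_shift_pct,
            "negative_shift_pct": tx_summary.negative_shift_pct,
            "proband_only_high_hl_pct": tx_summary.proband_only_high_hl_pct,
        },
    })
    return report


def summarize_counts(report: TriageReport, n_probands: int, extras: dict | None = None) -> dict:
    """Cohort summary; every ratio carries its numerator and denominator."""
    prioritized = (
        int(report.prioritized["prioritized"].sum()) if len(report.prioritized) else 0
    )
    summary = {
        "n_probands_analyzed": n_probands,
        "empty_cohort": n_probands == 0,
        "qc": {
            "n_samples": int(len(report.qc)),
            "n_excluded": int((~report.qc["pass"]).sum()) if len(report.qc) else 0,
        },
        "screen": {
            "n_hits": int(len(report.screen_hits)),
            "n_probands_with_hit": int(report.screen_hits["sample_id"].nunique()) if len(report.screen_hits) else 0,
            "n_deletions": int(len(report.deletion_hits)),
            "tiers": report.screen_hits["tier"].value_counts().to_dict() if len(report.screen_hits) else {},
        },
        "prioritization": {
            "n_prioritized": prioritized,
            "per_proband_mean": round(prioritized / n_probands, 2) if n_probands else None,
        },
        "outliers": {
            "n_flagged": int(report.burdens["outlier"].sum()) if len(report.burdens) else 0,
            "flagged_samples": (
                sorted(report.burdens.loc[report.burdens["outlier"], "sample_id"].tolist())
                if len(report.burdens)
                else []
            ),
        },
        "mdc": {
            "categories": report.mdc["mdc_category"].value_counts().to_dict() if len(report.mdc) else {},
        },
    }
    if extras:
        summary.update(extras)
    return summary
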