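"""Synthetic mtDNA cohort generator.

Produces fully synthetic proband/maternal call sets, annotation tables,
P/LP catalogs, pedigrees, phenotype term lists, a toy HPO ontology, and
a ground-truth table, so that every analysis stage is testable without
external downloads.  The generator's defaults emulate the cohort
structure the analysis assumes: ~23 haplogroup-backbone variants per
sample at near homoplasmy, a Poisson heteroplasmic burden with mean
10.1, maternal transmission through a binomial germline bottleneck,
per-data-type coverage means (GS 4,416x; ES-Twist 6,315x; ES-Nextera
47x; RNA 5,894x), planted reported-pathogenic variants, contaminated
samples, and one mutator sample carrying 910 somatic SNVs + 31 indels
of which 12 are shared with its mother.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import (
    AnnotationResources,
    InSilicoScores,
    Key,
    PopulationFrequency,
)
from .core import MT_GENOME_LENGTH, MtDeletion, MtError, MtVariant, SampleCallSet
from .io import write_callset

COVERAGE_MEANS = {"GS": 4416.0, "ES_twist": 6315.0, "ES_nextera": 47.0, "RNA": 5894.0}

# Approximate rCRS gene map (start, end, gene, class); first match wins.
_GENE_MAP = [
    (577, 647, "MT-TF", "tRNA"),
    (648, 1601, "MT-RNR1", "rRNA"),
    (1602, 1670, "MT-TV", "tRNA"),
    (1671, 3229, "MT-RNR2", "rRNA"),
    (3230, 3304, "MT-TL1", "tRNA"),
    (3307, 4262, "MT-ND1", "protein"),
    (4263, 4331, "MT-TI", "tRNA"),
    (4329, 4400, "MT-TQ", "tRNA"),
    (4402, 4469, "MT-TM", "tRNA"),
    (4470, 5511, "MT-ND2", "protein"),
    (5512, 5579, "MT-TW", "tRNA"),
    (5587, 5655, "MT-TA", "tRNA"),
    (5657, 5729, "MT-TN", "tRNA"),
    (5761, 5826, "MT-TC", "tRNA"),
    (5826, 5891, "MT-TY", "tRNA"),
    (5904, 7445, "MT-CO1", "protein"),
    (7446, 7514, "MT-TS1", "tRNA"),
    (7518, 7585, "MT-TD", "tRNA"),
    (7586, 8269, "MT-CO2", "protein"),
    (8295, 8364, "MT-TK", "tRNA"),
    (8366, 8572, "MT-ATP8", "protein"),
    (8527, 9207, "MT-ATP6", "protein"),
    (9207, 9990, "MT-CO3", "protein"),
    (9991, 10058, "MT-TG", "tRNA"),
    (10059, 10404, "MT-ND3", "protein"),
    (10405, 10469, "MT-TR", "tRNA"),
    (10470, 10766, "MT-ND4L", "protein"),
    (10760, 12137, "MT-ND4", "protein"),
    (12138, 12206, "MT-TH", "tRNA"),
    (12207, 12265, "MT-TS2", "tRNA"),
    (12266, 12336, "MT-TL2", "tRNA"),
    (12337, 14148, "MT-ND5", "protein"),
    (14149, 14673, "MT-ND6", "protein"),
    (14674, 14742, "MT-TE", "tRNA"),
    (14747, 15887, "MT-CYB", "protein"),
    (15888, 15953, "MT-TT", "tRNA"),
    (15956, 16023, "MT-TP", "tRNA"),
]

_BASES = ("A", "C", "G", "T")

HAPLOGROUPS = ("H1", "U5a", "J1c", "T2b", "K1a", "L3e")


def locate(position: int) -> tuple[str, str]:
    """(gene, gene_class) at a position; control region -> ('', 'noncoding')."""
    for start, end, gene, kind in _GENE_MAP:
        if start <= position <= end:
            return gene, kind
    return "", "noncoding"


def _consequence_for(position: int, rng: np.random.Generator) -> tuple[str, str]:
    gene, kind = locate(position)
    if kind == "tRNA":
        return gene, "tRNA"
    if kind == "rRNA":
        return gene, "rRNA"
    if kind == "noncoding":
        return gene, "noncoding"
    consequence = rng.choice(
        ["synonymous", "missense", "stop_gained", "frameshift"], p=[0.42, 0.55, 0.02, 0.01]
    )
    return gene, str(consequence)


@dataclass
class PlpPlant:
    """A reported-pathogenic variant planted into one family's proband."""

    key: Key
    hl: float
    consequence: str
    gene: str
    maternal_hl: float | None = None  # None -> absent from mother
    hpo_terms: list[str] | None = None  # curated phenotype for the family


@dataclass
class RarePlant:
    """A rare potentially deleterious variant with controlled annotations."""

    key: Key
    hl: float
    consequence: str
    gene: str
    scores: InSilicoScores
    in_regional_constraint: bool = False
    helix_het: tuple[float, int, float] | None = None  # (het_af, het_ac, max_hl)
    expect_prioritized: bool = True
    hpo_terms: list[str] | None = None


@dataclass
class MutatorSpec:
    snv_count: int = 910
    indel_count: int = 31
    maternal_overlap: int = 12
    data_type: str = "ES_twist"


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_families: int = 100
    data_type_mix: dict = field(
        default_factory=lambda: {"GS": 0.4, "ES_twist": 0.3, "ES_nextera": 0.2, "RNA": 0.1}
    )
    maternal_fraction: float = 0.5
    backbone_size: int = 23
    het_mean: float = 10.1
    de_novo_mean: float = 0.4
    bottleneck_n: int = 30
    detection_floor: float = 0.01
    contaminated_samples: int = 2
    contamination_level: float = 0.05  # fraction of backbone moved into the QC window
    low_coverage_samples: int = 1
    common_het_fraction: float = 0.8  # inherited heteroplasmies drawn from known polymorphisms
    n_common_pool: int = 300
    mutator: MutatorSpec | None = field(default_factory=MutatorSpec)
    plp_plants: list[PlpPlant] | None = None  # None -> default plantings
    rare_plants: list[RarePlant] | None = None
    deletion_plants: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(8470, 13446, 0.70), (7773, 13094, 0.82)]
    )
    n_mitomap: int = 127
    n_clinvar: int = 111
    n_catalog_overlap: int = 86
    seed: int = 0


def default_plp_plants() -> list[PlpPlant]:
    """Reported-pathogenic plantings spanning the triage tiers."""
    return [
        PlpPlant((3243, "A", "G"), 0.08, "tRNA", "MT-TL1", maternal_hl=0.05),
        PlpPlant((8993, "T", "C"), 0.99, "missense", "MT-ATP6", maternal_hl=0.90),
        PlpPlant((11778, "G", "A"), 0.99, "missense", "MT-ND4", maternal_hl=0.99),
        PlpPlant((1555, "A", "G"), 0.98, "rRNA", "MT-RNR1", maternal_hl=0.97),
        PlpPlant(
            (5591, "G", "A"), 0.86, "tRNA", "MT-TA", maternal_hl=None,
            # mitochondrial-myopathy presentation: definite MDC
            hpo_terms=["HP:0003737", "HP:0003200", "HP:0003688", "HP:0003128"],
        ),
        PlpPlant((591, "C", "T"), 0.72, "tRNA", "MT-TF", maternal_hl=0.36),
        PlpPlant((3946, "G", "A"), 0.70, "missense", "MT-ND1", maternal_hl=None),
        # below the 5% screening floor: must never be reported
        PlpPlant((8344, "A", "G"), 0.04, "tRNA", "MT-TK", maternal_hl=0.03),
    ]


def default_rare_plants() -> list[RarePlant]:
    """Rare deleterious plantings, including sub-threshold decoys."""
    return [
        RarePlant(
            (15347, "C", "T"), 0.19, "missense", "MT-CYB",
            InSilicoScores(apogee2=0.64, hmtvar=0.84, mlc=0.53),
            in_regional_constraint=True,
            hpo_terms=["HP:0001639", "HP:0003128", "HP:0002151", "HP:0001263"],
        ),
        RarePlant(
            (16023, "G", "A"), 0.15, "tRNA", "MT-TP",
            InSilicoScores(mitotip=17.6, hmtvar=0.65, pon_mt_trna=0.8, mlc=0.73),
            helix_het=(1.53e-05, 3, 0.15),
        ),
        RarePlant(
            (6853, "G", "C"), 0.06, "missense", "MT-CO1",
            InSilicoScores(apogee2=0.52, hmtvar=0.8, mlc=0.87),
        ),
        RarePlant(
            (8570, "T", "C"), 0.95, "stop_loss", "MT-ATP8",
            InSilicoScores(mlc=0.03),
        ),
        # decoy: missense with sub-threshold scores, no constraint -> not prioritized
        RarePlant(
            (8611, "C", "A"), 1.0, "missense", "MT-ATP6",
            InSilicoScores(apogee2=0.45, hmtvar=0.30, mlc=0.01),
            expect_prioritized=False,
        ),
    ]


@dataclass
class SyntheticCohort:
    """In-memory cohort plus its ground truth."""

    config: CohortConfig
    callsets: dict[str, SampleCallSet]  # sample_id -> call set
    pedigree: pd.DataFrame  # family_id, proband_sample, maternal_sample, data_type
    resources: AnnotationResources
    mitomap_records: list[dict]
    clinvar_records: list[dict]
    hpo_terms: dict[str, list[str]]  # proband sample_id -> reported HPO ids
    truth_variants: pd.DataFrame
    truth_samples: pd.DataFrame
    ontology_obo: str

    def proband_callsets(self) -> list[SampleCallSet]:
        return [self.callsets[s] for s in self.pedigree["proband_sample"]]

    def write(self, outdir: str | Path, n_depth_files: int = 2) -> None:
        """Emit every consumed file format under ``outdir``."""
        outdir = Path(outdir)
        (outdir / "callsets").mkdir(parents=True, exist_ok=True)
        (outdir / "tables").mkdir(exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        for sample_id in sorted(self.callsets):
            write_callset(self.callsets[sample_id], outdir / "callsets" / f"{sample_id}.tsv")
        self.pedigree.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
        _write_frequency_table(self.resources.gnomad, outdir / "tables" / "gnomad.tsv")
        _write_frequency_table(self.resources.helix, outdir / "tables" / "helix.tsv")
        _write_score_table(self.resources.scores, outdir / "tables" / "scores.tsv")
        _write_constraint_bed(self.resources.regional_constraint, outdir / "tables" / "regional_constraint.bed")
        _write_haplogroup_table(self.resources.haplogroups, outdir / "tables" / "haplogroups.tsv")
        pd.DataFrame(self.mitomap_records).to_csv(outdir / "tables" / "mitomap.tsv", sep="\t", index=False)
        pd.DataFrame(self.clinvar_records).to_csv(outdir / "tables" / "clinvar.tsv", sep="\t", index=False)
        hpo_rows = [
            {"proband_id": pid, "hpo_terms": ",".join(terms)}
            for pid, terms in sorted(self.hpo_terms.items())
        ]
        pd.DataFrame(hpo_rows).to_csv(outdir / "hpo.tsv", sep="\t", index=False)
        (outdir / "ontology.obo").write_text(self.ontology_obo, encoding="utf-8")
        self.truth_variants.to_csv(outdir / "truth" / "variants.tsv", sep="\t", index=False)
        self.truth_samples.to_csv(outdir / "truth" / "samples.tsv", sep="\t", index=False)
        # full per-base depth files for a few samples (samtools-depth style)
        rng = np.random.default_rng(self.config.seed + 7)
        for sample_id in sorted(self.callsets)[:n_depth_files]:
            cs = self.callsets[sample_id]
            depths = rng.poisson(cs.mean_coverage, size=MT_GENOME_LENGTH)
            with open(outdir / "tables" / f"depth_{sample_id}.tsv", "w", encoding="utf-8") as fh:
                for pos, depth in enumerate(depths, start=1):
                    fh.write(f"chrM\t{pos}\t{depth}\n")
        cfg = _plain(asdict(self.config))
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")


def simulate_transmission(
    maternal_hl: float, bottleneck_n: int, seed: int | np.random.Generator = 0
) -> float:
    """Offspring HL after a single-generation binomial germline bottleneck.

    Draws k ~ Binomial(bottleneck_n, maternal_hl) segregating units and
    returns k / bottleneck_n.  HLs of 0 and 1 are absorbing.
    """
    if not 0.0 <= maternal_hl <= 1.0:
        raise MtError(f"maternal HL out of [0, 1]: {maternal_hl}")
    if bottleneck_n < 1:
        raise MtError(f"bottleneck size must be >= 1, got {bottleneck_n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.binomial(bottleneck_n, maternal_hl)) / bottleneck_n


def _draw_depths(hl: float, mean_coverage: float, rng: np.random.Generator) -> tuple[int, int]:
    total = max(int(rng.poisson(mean_coverage)), 2)
    alt = int(rng.binomial(total, hl))
    # keep the planted variant detectable at its nominal HL
    if hl > 0 and alt == 0:
        alt = 1
    if hl < 1 and alt == total:
        alt = total - 1
    return alt, total - alt


def _make_variant(
    position: int,
    ref: str,
    alt: str,
    hl: float,
    mean_coverage: float,
    rng: np.random.Generator,
    consequence: str,
    gene: str,
) -> MtVariant:
    alt_depth, ref_depth = _draw_depths(hl, mean_coverage, rng)
    return MtVariant(
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        alt_depth=alt_depth,
        ref_depth=ref_depth,
        hl=hl,
        consequence=consequence,
        gene=gene,
    )


def _random_key(rng: np.random.Generator, used: set[int], indel: bool = False) -> Key:
    while True:
        position = int(rng.integers(1, MT_GENOME_LENGTH + 1))
        if position in used:
            continue
        used.add(position)
        ref = str(rng.choice(_BASES))
        if indel:
            alt = ref + str(rng.choice(_BASES))
        else:
            alt = str(rng.choice([b for b in _BASES if b != ref]))
        return (position, ref, alt)


def plant_mutator(
    callset: SampleCallSet,
    snv_count: int,
    indel_count: int,
    hl_distribution=None,
    seed: int | np.random.Generator = 0,
    maternal_callset: SampleCallSet | None = None,
    maternal_overlap: int = 0,
) -> SampleCallSet:
    """Add low-HL somatic variants at unused positions (mutator phenotype).

    ``hl_distribution`` is a callable rng -> HL; default Uniform(0.01,
    0.30).  Optionally shares ``maternal_overlap`` of the planted
    variants with the maternal call set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if hl_distribution is None:
        hl_distribution = lambda r: float(r.uniform(0.01, 0.30))
    used = {v.position for v in callset.variants}
    if snv_count + indel_count > MT_GENOME_LENGTH - len(used):
        raise MtError("requested mutator burden exceeds available positions")
    mean_cov = COVERAGE_MEANS.get(callset.data_type, 1000.0)
    planted: list[MtVariant] = []
    for i in range(snv_count + indel_count):
        key = _random_key(rng, used, indel=i >= snv_count)
        gene, consequence = _consequence_for(key[0], rng)
        if consequence == "synonymous":
            consequence = "missense"  # somatic plantings kept non-synonymous-biased
        hl = min(max(hl_distribution(rng), 0.01), 0.94)
        planted.append(_make_variant(key[0], key[1], key[2], hl, mean_cov, rng, consequence, gene))
    callset.variants.extend(planted)
    if maternal_callset is not None and maternal_overlap > 0:
        maternal_used = {v.position for v in maternal_callset.variants}
        for v in planted[:maternal_overlap]:
            if v.position in maternal_used:
                continue
            maternal_callset.variants.append(
                _make_variant(
                    v.position, v.ref_allele, v.alt_allele, v.hl,
                    COVERAGE_MEANS.get(maternal_callset.data_type, 1000.0),
                    rng, v.consequence, v.gene,
                )
            )
    return callset


def _haplogroup_backbones(
    rng: np.random.Generator, backbone_size: int, used: set[int]
) -> dict[str, list[tuple[Key, str, str]]]:
    """Backbone variant list per haplogroup: (key, gene, consequence)."""
    backbones: dict[str, list[tuple[Key, str, str]]] = {}
    for hg in HAPLOGROUPS:
        members = []
        for _ in range(backbone_size):
            key = _random_key(rng, used)
            gene, consequence = _consequence_for(key[0], rng)
            members.append((key, gene, consequence))
        backbones[hg] = members
    return backbones


def _build_catalog_records(
    rng: np.random.Generator,
    plp_plants: list[PlpPlant],
    used: set[int],
    n_mitomap: int,
    n_clinvar: int,
    n_overlap: int,
) -> tuple[list[dict], list[dict]]:
    """MITOMAP-style and ClinVar-style records with a forced overlap.

    Planted keys are placed in both sources; filler keys bring the totals
    to the requested counts (unique total = n_mitomap + n_clinvar - n_overlap).
    """
    if n_overlap > min(n_mitomap, n_clinvar) or n_overlap < len(plp_plants):
        raise MtError("catalog overlap must fit both sources and cover all plantings")
    planted_keys = [p.key for p in plp_plants]
    for key in planted_keys:
        used.add(key[0])
    n_filler_overlap = n_overlap - len(planted_keys)
    overlap_keys = planted_keys + [_random_key(rng, used) for _ in range(n_filler_overlap)]
    mitomap_only = [_random_key(rng, used) for _ in range(n_mitomap - n_overlap)]
    clinvar_only = [_random_key(rng, used) for _ in range(n_clinvar - n_overlap)]
    mitomap = [
        {"position": k[0], "ref": k[1], "alt": k[2], "status": "cfrm", "phenotype": "synthetic MD"}
        for k in overlap_keys + mitomap_only
    ]
    clinvar = [
        {
            "position": k[0], "ref": k[1], "alt": k[2],
            "classification": "P/LP", "stars": 2, "phenotype": "synthetic MD",
        }
        for k in overlap_keys + clinvar_only
    ]
    # a 1-star decoy that must be excluded from the catalog
    decoy = _random_key(rng, used)
    clinvar.append(
        {
            "position": decoy[0], "ref": decoy[1], "alt": decoy[2],
            "classification": "P/LP", "stars": 1, "phenotype": "synthetic, low review",
        }
    )
    return mitomap, clinvar


_TOY_ONTOLOGY_TERMS = [
    # (id, name, parents)
    ("HP:0000001", "All", []),
    ("HP:0000118", "Phenotypic abnormality", ["HP:0000001"]),
    ("HP:0000005", "Mode of inheritance", ["HP:0000001"]),
    ("HP:0000007", "Autosomal recessive inheritance", ["HP:0000005"]),
    ("HP:0033127", "Abnormality of the musculoskeletal system", ["HP:0000118"]),
    ("HP:0003011", "Abnormality of the musculature", ["HP:0033127"]),
    ("HP:0003198", "Myopathy", ["HP:0003011"]),
    ("HP:0003737", "Mitochondrial myopathy", ["HP:0003198"]),
    ("HP:0001252", "Hypotonia", ["HP:0003011"]),
    ("HP:0003324", "Generalized muscle weakness", ["HP:0003011"]),
    ("HP:0003546", "Exercise intolerance", ["HP:0003011"]),
    ("HP:0000707", "Abnormality of the nervous system", ["HP:0000118"]),
    ("HP:0012638", "Abnormal nervous system physiology", ["HP:0000707"]),
    ("HP:0001250", "Seizure", ["HP:0012638"]),
    ("HP:0002069", "Bilateral tonic-clonic seizure", ["HP:0001250"]),
    ("HP:0002376", "Developmental regression", ["HP:0012638"]),
    ("HP:0012758", "Neurodevelopmental delay", ["HP:0012638"]),
    ("HP:0001263", "Global developmental delay", ["HP:0012758"]),
    ("HP:0000505", "Visual impairment", ["HP:0000707"]),
    ("HP:0000556", "Retinal dystrophy", ["HP:0000505"]),
    ("HP:0000365", "Hearing impairment", ["HP:0000118"]),
    ("HP:0000407", "Sensorineural hearing impairment", ["HP:0000365"]),
    ("HP:0001626", "Abnormality of the cardiovascular system", ["HP:0000118"]),
    ("HP:0001638", "Cardiomyopathy", ["HP:0001626"]),
    ("HP:0001639", "Hypertrophic cardiomyopathy", ["HP:0001638"]),
    ("HP:0001507", "Growth abnormality", ["HP:0000118"]),
    ("HP:0001508", "Failure to thrive", ["HP:0001507"]),
    ("HP:0000119", "Abnormality of the genitourinary system", ["HP:0000118"]),
    ("HP:0000124", "Renal tubular dysfunction", ["HP:0000119"]),
    ("HP:0001871", "Abnormality of blood and blood-forming tissues", ["HP:0000118"]),
    ("HP:0001903", "Anemia", ["HP:0001871"]),
    ("HP:0001875", "Neutropenia", ["HP:0001871"]),
    ("HP:0001939", "Abnormality of metabolism/homeostasis", ["HP:0000118"]),
    ("HP:0003128", "Lactic acidosis", ["HP:0001939"]),
    ("HP:0002151", "Increased serum lactate", ["HP:0001939"]),
    ("HP:0001987", "Hyperammonemia", ["HP:0001939"]),
    ("HP:0012443", "Abnormal brain morphology", ["HP:0000707"]),
    ("HP:0002500", "Abnormal cerebral white matter morphology", ["HP:0012443"]),
    ("HP:0001272", "Cerebellar atrophy", ["HP:0012443"]),
    ("HP:0011804", "Abnormal muscle physiology", ["HP:0003011"]),
    ("HP:0003200", "Ragged-red muscle fibers", ["HP:0011804"]),
    ("HP:0003688", "Cytochrome C oxidase-negative muscle fibers", ["HP:0011804"]),
]


def toy_ontology_obo() -> str:
    """A small, valid OBO document with HPO-style ids."""
    lines = ["format-version: 1.2", "ontology: hp-toy", ""]
    for term_id, name, parents in _TOY_ONTOLOGY_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        for parent in parents:
            lines.append(f"is_a: {parent}")
        lines.append("")
    return "\n".join(lines)


_PHENO_POOL = [
    "HP:0002069", "HP:0001263", "HP:0000556", "HP:0000407", "HP:0001639",
    "HP:0001508", "HP:0001903", "HP:0001875", "HP:0002151", "HP:0001272",
    "HP:0003737", "HP:0003200", "HP:0003688", "HP:0003128", "HP:0001252",
]


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Build a deterministic synthetic cohort from the study conditions."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    plp_plants = default_plp_plants() if cfg.plp_plants is None else cfg.plp_plants
    rare_plants = default_rare_plants() if cfg.rare_plants is None else cfg.rare_plants

    plant_positions = [p.key[0] for p in plp_plants] + [p.key[0] for p in rare_plants]
    if len(set(plant_positions)) != len(plant_positions):
        raise MtError("impossible plantings: two planted alleles share one position")
    reserved = set(plant_positions)
    global_used = set(reserved)
    backbones = _haplogroup_backbones(rng, cfg.backbone_size, global_used)
    mitomap_records, clinvar_records = _build_catalog_records(
        rng, plp_plants, global_used, cfg.n_mitomap, cfg.n_clinvar, cfg.n_catalog_overlap,
    )
    # pool of common polymorphisms: known in both reference sources at
    # homoplasmic frequencies above the rarity threshold
    common_pool = [
        (_random_key(rng, global_used), float(rng.uniform(5e-5, 5e-3)))
        for _ in range(cfg.n_common_pool)
    ]

    resources = AnnotationResources()
    resources.haplogroups = {
        hg: {key for (key, _, _) in members} for hg, members in backbones.items()
    }
    # regional-constraint intervals (1-based inclusive): cover the P15-style plant
    constraint_intervals = [(15300, 15400), (3300, 3400), (10050, 10120)]
    for start, end in constraint_intervals:
        resources.regional_constraint[start : end + 1] = True
    for plant in rare_plants:
        if plant.in_regional_constraint and not resources.regional_constraint[plant.key[0]]:
            lo = max(1, plant.key[0] - 5)
            resources.regional_constraint[lo : plant.key[0] + 6] = True

    # backbone variants are common at homoplasmy in both reference sources
    for hg, members in backbones.items():
        for key, _, _ in members:
            af = float(rng.uniform(0.002, 0.4))
            resources.gnomad[key] = PopulationFrequency("gnomad_style", hom_af=af)
            resources.helix[key] = PopulationFrequency("helix_style", hom_af=af)
    # rare plantings: absent at homoplasmy; optional low-count heteroplasmic records
    for plant in rare_plants:
        resources.scores[plant.key] = plant.scores
        if plant.helix_het is not None:
            het_af, het_ac, max_hl = plant.helix_het
            resources.helix[plant.key] = PopulationFrequency(
                "helix_style", het_af=het_af, het_ac=het_ac, max_observed_hl=max_hl
            )
    for key, af in common_pool:
        het_af = float(rng.uniform(1e-5, 1e-3))
        resources.gnomad[key] = PopulationFrequency(
            "gnomad_style", hom_af=af, het_af=het_af,
            het_ac=int(rng.integers(1, 50)), max_observed_hl=float(rng.uniform(0.1, 1.0)),
        )
        resources.helix[key] = PopulationFrequency("helix_style", hom_af=af)
    # common decoy: qualifying scores but too frequent at homoplasmy
    common_decoy = _random_key(rng, global_used)
    resources.gnomad[common_decoy] = PopulationFrequency("gnomad_style", hom_af=1.0 / 40000.0)
    resources.scores[common_decoy] = InSilicoScores(apogee2=0.9, hmtvar=0.9, mlc=0.9)

    data_types = sorted(cfg.data_type_mix)
    probabilities = np.array([cfg.data_type_mix[t] for t in data_types], dtype=float)
    probabilities /= probabilities.sum()

    callsets: dict[str, SampleCallSet] = {}
    pedigree_rows: list[dict] = []
    truth_variant_rows: list[dict] = []
    truth_sample_rows: list[dict] = []
    hpo_terms: dict[str, list[str]] = {}

    n_plp = len(plp_plants)
    n_rare = len(rare_plants)
    mutator_family: int | None = None
    next_free = n_plp + n_rare
    if cfg.mutator is not None:
        mutator_family = next_free  # first family after the planted ones
        next_free += 1
    deletion_families = {next_free + i: d for i, d in enumerate(cfg.deletion_plants)}
    next_free += len(cfg.deletion_plants)
    if next_free >= cfg.n_families:
        raise MtError("n_families too small for the requested plantings")

    contaminated: set[int] = set()
    low_coverage: set[int] = set()
    candidates = [i for i in range(cfg.n_families) if i >= next_free]
    if cfg.contaminated_samples + cfg.low_coverage_samples > len(candidates):
        raise MtError("not enough families for contamination/low-coverage plantings")
    picked = list(rng.choice(candidates, size=cfg.contaminated_samples + cfg.low_coverage_samples, replace=False))
    contaminated = set(int(x) for x in picked[: cfg.contaminated_samples])
    low_coverage = set(int(x) for x in picked[cfg.contaminated_samples :])

    for fam_idx in range(cfg.n_families):
        family_id = f"F{fam_idx:04d}"
        proband_id = f"{family_id}_P"
        maternal_id = f"{family_id}_M"
        data_type = str(rng.choice(data_types, p=probabilities))
        if fam_idx == mutator_family and cfg.mutator is not None:
            data_type = cfg.mutator.data_type
        haplogroup = str(rng.choice(HAPLOGROUPS))
        mean_cov = COVERAGE_MEANS[data_type]
        has_mother = bool(rng.random() < cfg.maternal_fraction)
        if fam_idx == mutator_family or fam_idx < n_plp:
            has_mother = True  # transmission plantings need the pair

        proband_variants: list[MtVariant] = []
        maternal_variants: list[MtVariant] = []
        # keep random heteroplasmies off the reserved planting positions
        used_positions: set[int] = set(reserved)

        # haplogroup backbone at near homoplasmy, shared with the mother
        is_contaminated = fam_idx in contaminated
        backbone = backbones[haplogroup]
        n_window = (
            max(int(np.ceil(cfg.contamination_level * len(backbone))), 1) if is_contaminated else 0
        )
        for j, (key, gene, consequence) in enumerate(backbone):
            used_positions.add(key[0])
            # clean samples carry their backbone above the 99.8% contamination window
            hl = float(rng.uniform(0.9985, 1.0))
            if j < n_window:
                hl = float(rng.uniform(0.86, 0.99))  # contamination window
            proband_variants.append(
                _make_variant(key[0], key[1], key[2], hl, mean_cov, rng, consequence, gene)
            )
            if has_mother:
                maternal_variants.append(
                    _make_variant(
                        key[0], key[1], key[2], float(rng.uniform(0.9985, 1.0)),
                        mean_cov, rng, consequence, gene,
                    )
                )
            truth_variant_rows.append(
                {
                    "sample_id": proband_id, "family_id": family_id,
                    "position": key[0], "ref": key[1], "alt": key[2],
                    "true_hl": hl, "kind": "backbone", "consequence": consequence,
                }
            )

        # maternal heteroplasmies transmitted through the bottleneck;
        # most are known polymorphisms, the rest private
        n_het = int(rng.poisson(cfg.het_mean))
        for _ in range(n_het):
            key = None
            if rng.random() < cfg.common_het_fraction:
                pool_key, _ = common_pool[int(rng.integers(len(common_pool)))]
                if pool_key[0] not in used_positions:
                    key = pool_key
                    used_positions.add(key[0])
            if key is None:
                key = _random_key(rng, used_positions)
            gene, consequence = _consequence_for(key[0], rng)
            maternal_hl = float(rng.uniform(0.01, 0.90))
            proband_hl = simulate_transmission(maternal_hl, cfg.bottleneck_n, rng)
            if has_mother:
                maternal_variants.append(
                    _make_variant(key[0], key[1], key[2], maternal_hl, mean_cov, rng, consequence, gene)
                )
            if proband_hl >= cfg.detection_floor:
                proband_variants.append(
                    _make_variant(key[0], key[1], key[2], proband_hl, mean_cov, rng, consequence, gene)
                )
                truth_variant_rows.append(
                    {
                        "sample_id": proband_id, "family_id": family_id,
                        "position": key[0], "ref": key[1], "alt": key[2],
                        "true_hl": proband_hl, "kind": "heteroplasmy",
                        "consequence": consequence, "maternal_hl": maternal_hl,
                    }
                )

        # proband-only (de novo / somatic) heteroplasmies
        for _ in range(int(rng.poisson(cfg.de_novo_mean))):
            key = _random_key(rng, used_positions)
            gene, consequence = _consequence_for(key[0], rng)
            hl = float(rng.uniform(0.01, 0.95))
            proband_variants.append(
                _make_variant(key[0], key[1], key[2], hl, mean_cov, rng, consequence, gene)
            )
            truth_variant_rows.append(
                {
                    "sample_id": proband_id, "family_id": family_id,
                    "position": key[0], "ref": key[1], "alt": key[2],
                    "true_hl": hl, "kind": "de_novo", "consequence": consequence,
                }
            )

        # planted reported-pathogenic / rare-deleterious variants
        plant_kind = None
        if fam_idx < n_plp:
            plant = plp_plants[fam_idx]
            plant_kind = "plp"
        elif fam_idx < n_plp + n_rare:
            plant = rare_plants[fam_idx - n_plp]
            plant_kind = "rare"
        if plant_kind is not None:
            key = plant.key
            if key[0] in used_positions and key[0] not in reserved:
                raise MtError(f"planting collision at position {key[0]}")
            used_positions.add(key[0])
            proband_variants.append(
                _make_variant(
                    key[0], key[1], key[2], plant.hl, mean_cov, rng, plant.consequence, plant.gene
                )
            )
            maternal_hl = getattr(plant, "maternal_hl", None)
            if has_mother and maternal_hl is not None:
                maternal_variants.append(
                    _make_variant(
                        key[0], key[1], key[2], maternal_hl, mean_cov, rng,
                        plant.consequence, plant.gene,
                    )
                )
            truth_variant_rows.append(
                {
                    "sample_id": proband_id, "family_id": family_id,
                    "position": key[0], "ref": key[1], "alt": key[2],
                    "true_hl": plant.hl, "kind": plant_kind,
                    "consequence": plant.consequence,
                    "maternal_hl": maternal_hl,
                    "expect_prioritized": getattr(plant, "expect_prioritized", None),
                }
            )

        deletions = []
        if fam_idx in deletion_families:
            start, end, del_hl = deletion_families[fam_idx]
            deletions.append(MtDeletion(start=start, end=end, hl=del_hl))
            truth_variant_rows.append(
                {
                    "sample_id": proband_id, "family_id": family_id,
                    "position": start, "ref": "DEL",
                    "alt": f"m.{start}_{end}del{end - start + 1}",
                    "true_hl": del_hl, "kind": "large_deletion", "consequence": "large_deletion",
                }
            )

        sample_mean_cov = 10.0 if fam_idx in low_coverage else mean_cov
        proband = SampleCallSet(
            sample_id=proband_id, data_type=data_type, haplogroup=haplogroup,
            variants=proband_variants, deletions=deletions, mean_coverage=sample_mean_cov,
        )
        callsets[proband_id] = proband
        if has_mother:
            callsets[maternal_id] = SampleCallSet(
                sample_id=maternal_id, data_type=data_type, haplogroup=haplogroup,
                variants=maternal_variants, mean_coverage=mean_cov,
            )
        is_mutator = fam_idx == mutator_family and cfg.mutator is not None
        if is_mutator:
            plant_mutator(
                proband, cfg.mutator.snv_count, cfg.mutator.indel_count,
                seed=rng, maternal_callset=callsets.get(maternal_id),
                maternal_overlap=cfg.mutator.maternal_overlap,
            )
        pedigree_rows.append(
            {
                "family_id": family_id,
                "proband_sample": proband_id,
                "maternal_sample": maternal_id if has_mother else "",
                "data_type": data_type,
            }
        )
        truth_sample_rows.append(
            {
                "sample_id": proband_id, "family_id": family_id, "role": "proband",
                "data_type": data_type, "haplogroup": haplogroup,
                "mean_coverage": sample_mean_cov,
                "contaminated": is_contaminated, "low_coverage": fam_idx in low_coverage,
                "mutator": is_mutator,
            }
        )
        if has_mother:
            truth_sample_rows.append(
                {
                    "sample_id": maternal_id, "family_id": family_id, "role": "mother",
                    "data_type": data_type, "haplogroup": haplogroup,
                    "mean_coverage": mean_cov,
                    "contaminated": False, "low_coverage": False, "mutator": False,
                }
            )

        # phenotype terms: curated sets for planted families, sparse otherwise
        curated = getattr(plant, "hpo_terms", None) if plant_kind is not None else None
        if curated is not None:
            hpo_terms[proband_id] = list(curated)
        else:
            if plant_kind is not None or is_mutator:
                n_terms = int(rng.integers(3, 7))
            else:
                n_terms = int(rng.integers(0, 4))
            terms = rng.choice(_PHENO_POOL, size=min(n_terms, len(_PHENO_POOL)), replace=False)
            hpo_terms[proband_id] = [str(t) for t in terms]

    return SyntheticCohort(
        config=cfg,
        callsets=callsets,
        pedigree=pd.DataFrame(pedigree_rows),
        resources=resources,
        mitomap_records=mitomap_records,
        clinvar_records=clinvar_records,
        hpo_terms=hpo_terms,
        truth_variants=pd.DataFrame(truth_variant_rows),
        truth_samples=pd.DataFrame(truth_sample_rows),
        ontology_obo=toy_ontology_obo(),
    )


def _plain(obj):
    """Recursively convert tuples to lists so YAML can represent the config."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


# -- table writers (inverse of the annotate loaders) -------------------------


def _write_frequency_table(table: dict[Key, PopulationFrequency], path: Path) -> None:
    rows = [
        {
            "position": k[0], "ref": k[1], "alt": k[2],
            "hom_af": f.hom_af, "het_af": f.het_af,
            "het_ac": f.het_ac, "max_observed_hl": f.max_observed_hl,
        }
        for k, f in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["position", "ref", "alt", "hom_af", "het_af", "het_ac", "max_observed_hl"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _write_score_table(table: dict[Key, InSilicoScores], path: Path) -> None:
    rows = [
        {
            "position": k[0], "ref": k[1], "alt": k[2],
            "apogee2": s.apogee2, "hmtvar": s.hmtvar, "mitotip": s.mitotip,
            "pon_mt_trna": s.pon_mt_trna, "mlc": s.mlc,
        }
        for k, s in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["position", "ref", "alt", "apogee2", "hmtvar", "mitotip", "pon_mt_trna", "mlc"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _write_constraint_bed(mask: np.ndarray, path: Path) -> None:
    lines = []
    in_run = False
    start = 0
    for pos in range(1, MT_GENOME_LENGTH + 1):
        if mask[pos] and not in_run:
            in_run, start = True, pos
        elif not mask[pos] and in_run:
            in_run = False
            lines.append(f"chrM\t{start - 1}\t{pos - 1}\tregional_constraint")
    if in_run:
        lines.append(f"chrM\t{start - 1}\t{MT_GENOME_LENGTH}\tregional_constraint")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def _write_haplogroup_table(table: dict[str, set[Key]], path: Path) -> None:
    rows = [
        {"haplogroup": hg, "position": k[0], "ref": k[1], "alt": k[2]}
        for hg in sorted(table)
        for k in sorted(table[hg])
    ]
    pd.DataFrame(rows, columns=["haplogroup", "position", "ref", "alt"]).to_csv(path, sep="\t", index=False)
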