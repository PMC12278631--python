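"""HPO term propagation and the Mitochondrial Disease Criteria (MDC) score.

Reported HPO terms are expanded with every intermediate ancestor on
their is-a paths up to (but excluding) the "Phenotypic abnormality"
root (HP:0000118); terms outside that subtree — inheritance modifiers,
clinical course terms — are dropped with a warning.

The MDC score (0-12) estimates the clinical likelihood that a proband
has a mitochondrial disease.  It is computed from a config mapping HPO
branch terms to (domain, weight): a branch matches when it intersects
the expanded term set, each domain's subscore is capped, and the total
is capped at 12.  Categories: unlikely (0-1), possible (2-4), probable
(5-7), definite (8-12).  The exact published weight table is not
reproduced here; the shipped default config covers the muscular,
neurological, multisystem, metabolic, imaging, and histopathology
domains and is an editable approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import networkx as nx
import obonet
import yaml

from .core import MtError

PHENOTYPIC_ABNORMALITY = "HP:0000118"

CATEGORY_STRATA = (
    ("unlikely", 0, 1),
    ("possible", 2, 4),
    ("probable", 5, 7),
    ("definite", 8, 12),
)

MAX_SCORE = 12


@dataclass
class PhenotypeProfile:
    proband_id: str
    reported_terms: set[str]
    expanded_terms: set[str]


@dataclass
class MdcConfigEntry:
    branch: str  # HPO id whose subtree marks the feature
    domain: str
    weight: int


@dataclass
class MdcConfig:
    entries: list[MdcConfigEntry]
    domain_caps: dict[str, int]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.weight < 0:
                raise MtError(f"negative MDC weight for {e.branch}")
            if e.domain not in self.domain_caps:
                raise MtError(f"MDC entry {e.branch} names unknown domain {e.domain!r}")
        for domain, cap in self.domain_caps.items():
            if not 0 <= cap <= MAX_SCORE:
                raise MtError(f"domain cap for {domain!r} outside 0..{MAX_SCORE}")


@dataclass
class MdcResult:
    proband_id: str
    score: int
    category: str
    domain_subscores: dict[str, int] = field(default_factory=dict)


def load_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO ontology (edges point child -> parent)."""
    return obonet.read_obo(str(path))


def _is_a_parents(node: str, ontology: nx.MultiDiGraph) -> list[str]:
    return [
        parent
        for _, parent, key in ontology.out_edges(node, keys=True)
        if key == "is_a"
    ]


def _reaches_root(node: str, ontology: nx.MultiDiGraph, memo: dict[str, bool]) -> bool:
    if node == PHENOTYPIC_ABNORMALITY:
        return True
    if node in memo:
        return memo[node]
    memo[node] = False  # guard against cycles
    result = any(_reaches_root(p, ontology, memo) for p in _is_a_parents(node, ontology))
    memo[node] = result
    return result


def _ancestors_to_root(
    term: str, ontology: nx.MultiDiGraph, memo: dict[str, bool]
) -> set[str] | None:
    """Nodes on is-a paths from ``term`` up to the phenotypic-abnormality
    root, excluding the root; None when the term is not under the root."""
    if term == PHENOTYPIC_ABNORMALITY:
        return set()
    if not _reaches_root(term, ontology, memo):
        return None
    visited: set[str] = set()
    stack = [term]
    while stack:
        node = stack.pop()
        if node in visited or node == PHENOTYPIC_ABNORMALITY:
            continue
        if not _reaches_root(node, ontology, memo):
            continue  # ancestor on a path leaving the subtree
        visited.add(node)
        stack.extend(_is_a_parents(node, ontology))
    return visited


def expand_terms(reported_terms, ontology: nx.MultiDiGraph) -> set[str]:
    """Ancestor closure of the reported terms under HP:0000118.

    Unknown terms and terms outside the phenotypic-abnormality subtree
    are skipped with a warning.  Idempotent: expanding an expanded set
    changes nothing.
    """
    expanded: set[str] = set()
    memo: dict[str, bool] = {}
    for term in reported_terms:
        if term not in ontology:
            warnings.warn(f"unknown HPO term {term}; skipped", stacklevel=2)
            continue
        closure = _ancestors_to_root(term, ontology, memo)
        if closure is None:
            warnings.warn(
                f"HPO term {term} is not under {PHENOTYPIC_ABNORMALITY}; skipped", stacklevel=2
            )
            continue
        expanded |= closure
    return expanded


def build_profile(proband_id: str, reported_terms, ontology: nx.MultiDiGraph) -> PhenotypeProfile:
    reported = set(reported_terms)
    return PhenotypeProfile(
        proband_id=proband_id,
        reported_terms=reported,
        expanded_terms=expand_terms(reported, ontology),
    )


def mdc_category(score: int) -> str:
    """Map an MDC score to its clinical-likelihood stratum."""
    if not 0 <= score <= MAX_SCORE:
        raise MtError(f"MDC score outside 0..{MAX_SCORE}: {score}")
    for name, low, high in CATEGORY_STRATA:
        if low <= score <= high:
            return name
    raise AssertionError("strata are exhaustive")


def mdc_score(profile: PhenotypeProfile, config: MdcConfig | None = None) -> MdcResult:
    """Capped sum of domain subscores over matched config branches."""
    cfg = config or default_mdc_config()
    subscores: dict[str, int] = {domain: 0 for domain in cfg.domain_caps}
    for entry in cfg.entries:
        if entry.branch in profile.expanded_terms:
            subscores[entry.domain] += entry.weight
    subscores = {
        domain: min(cfg.domain_caps[domain], value) for domain, value in subscores.items()
    }
    score = min(MAX_SCORE, sum(subscores.values()))
    return MdcResult(
        proband_id=profile.proband_id,
        score=score,
        category=mdc_category(score),
        domain_subscores=subscores,
    )


def _parse_mdc_yaml(text: str) -> MdcConfig:
    data = yaml.safe_load(text)
    entries = [
        MdcConfigEntry(branch=str(e["branch"]), domain=str(e["domain"]), weight=int(e["weight"]))
        for e in data["entries"]
    ]
    caps = {str(k): int(v) for k, v in data["domain_caps"].items()}
    return MdcConfig(entries=entries, domain_caps=caps)


def load_mdc_config(path: str | Path) -> MdcConfig:
    return _parse_mdc_yaml(Path(path).read_text(encoding="utf-8"))


def default_mdc_config() -> MdcConfig:
    text = importlib_resources.files("mttriage").joinpath("data/mdc_default.yaml").read_text()
    return _parse_mdc_yaml(text)
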