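import pytest

from mttriage import CohortConfig, generate_cohort
from mttriage.phenotype import load_ontology
from mttriage.simulate import toy_ontology_obo


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (100 families, seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same cohort written out as a full fixture directory."""
    path = tmp_path_factory.mktemp("cohort")
    cohort.write(path)
    return path


@pytest.fixture(scope="session")
def ontology(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    path.write_text(toy_ontology_obo(), encoding="utf-8")
    return load_ontology(path)
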