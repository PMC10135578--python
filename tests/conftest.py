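import pytest
from hypothesis import HealthCheck, settings

from ecm_diseasome.records import CATEGORY_DIVISION, Category, MatrisomeCatalog, MatrisomeGene
from ecm_diseasome.synthetic_data import GeneratorConfig, generate, paper_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_gene(symbol: str, category: Category) -> MatrisomeGene:
    return MatrisomeGene(symbol, CATEGORY_DIVISION[category], category)


@pytest.fixture(scope="session")
def small_catalog() -> MatrisomeCatalog:
    """A hand-built catalog spanning both divisions and several categories."""
    return MatrisomeCatalog([
        make_gene("COL1A1", Category.COLLAGENS),
        make_gene("COL2A1", Category.COLLAGENS),
        make_gene("COL3A1", Category.COLLAGENS),
        make_gene("FBN1", Category.GLYCOPROTEINS),
        make_gene("ACAN", Category.PROTEOGLYCANS),
        make_gene("ANXA1", Category.ECM_AFFILIATED),
        make_gene("MMP2", Category.ECM_REGULATORS),
        make_gene("TGFB1", Category.SECRETED_FACTORS),
    ])


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The worked-example fixture tables (Stickler, Ullrich, PLG, repurposing)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return paper_fixtures(outdir)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small generated dataset for unit tests (fast)."""
    outdir = tmp_path_factory.mktemp("tiny")
    config = GeneratorConfig(seed=11, n_genes=200, n_variants=400, n_phewas=500,
                             n_diseases=60, n_associations=300, n_drug_links=50,
                             n_ppi=120, n_rare=80, n_rare_diseases=40,
                             n_duplicate_variants=10, n_invalid_p=5)
    return generate(config, outdir)


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """The standard study-condition dataset (generator defaults, seed 20)."""
    outdir = tmp_path_factory.mktemp("study")
    return generate(GeneratorConfig(seed=20), outdir)
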