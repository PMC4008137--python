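import pytest
from hypothesis import HealthCheck, settings

from orthoatlas import prep, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured compendium: mnp clusters, cell-culture
    signature, dominant CNS block, perturbation/control experiments."""
    return synthetic.GeneratorConfig(
        n_clusters=200,
        n_tissues=12,
        n_perturbations=8,
        cellculture_signature_size=10,
        mnp_fraction=0.05,
        seed=3,
    )


@pytest.fixture(scope="session")
def clusters(small_config):
    return synthetic.generate_ortholog_clusters(small_config)


@pytest.fixture(scope="session")
def ground_truth(small_config, clusters):
    return synthetic.generate_ground_truth(small_config, clusters)


@pytest.fixture(scope="session")
def compendia(small_config, clusters, ground_truth):
    return synthetic.generate_compendium(
        small_config, clusters, "SET1", truth=ground_truth
    )


@pytest.fixture(scope="session")
def meta_matrices(compendia, clusters):
    matrices, triplets = prep.prepare_species_matrices(compendia, clusters)
    return matrices, triplets


@pytest.fixture(scope="session")
def std_matrices(meta_matrices):
    matrices, _ = meta_matrices
    return {sp: prep.standardize_per_gene(m) for sp, m in matrices.items()}
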