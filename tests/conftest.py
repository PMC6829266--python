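import pytest

from neglog.features import AnnotationStore, build_homolog_terms
from neglog.homology import HomologyMap
from neglog.synthetic import generate_world, training_data


@pytest.fixture(scope="session")
def small_world():
    """A compact world for fast end-to-end tests."""
    return generate_world(
        n_families=12,
        family_size=3,
        n_go_modules=8,
        terms_per_module=4,
        deficient_fraction=0.5,
        n_seeds=400,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def default_world():
    """A world at the package's standard study conditions."""
    return generate_world(rng_seed=7)


@pytest.fixture(scope="session")
def default_training(default_world):
    positives, negatives, store, pool = training_data(default_world, rng_seed=7)
    return {
        "positives": positives,
        "negatives": negatives,
        "store": store,
        "pool": pool,
    }


@pytest.fixture()
def toy_store():
    """Hand-built annotations: two annotated proteins plus an unknown one."""
    store = AnnotationStore(
        target_terms={
            "p1": {"GO:0000001", "GO:0000002"},
            "p2": {"GO:0000001"},
            "h1": {"GO:0000003"},
            "h2": {"GO:0000002"},
        }
    )
    hmap = HomologyMap(
        neighbors={
            "p1": {"h1": 1e-30, "h2": 1e-25},
            "h1": {"p1": 1e-30},
            "h2": {"p1": 1e-25},
        }
    )
    return build_homolog_terms(store, hmap)
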