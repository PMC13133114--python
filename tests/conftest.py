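import logging

import numpy as np
import pytest

import featsieve as fs

# keep stage-level INFO logging out of test output
logging.getLogger("featsieve").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec() -> fs.SyntheticSpec:
    """Toy study world: one novel planted signal, one KG-known, one lit-known."""
    return fs.SyntheticSpec(
        n_patients=1500,
        n_features=24,
        prevalence=0.2,
        planted_features=[
            {"feature_id": "serum_marker_x", "effect": 1.2},
            {"feature_id": "known_kg_factor", "effect": 1.0, "kg_known": True},
            {"feature_id": "known_lit_factor", "effect": 1.0, "lit_known": True},
        ],
        confounders=[{"covariate": "age", "strength": 0.8}],
        missing_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def bundle(small_spec) -> fs.SyntheticBundle:
    return fs.generate_bundle(small_spec)


@pytest.fixture(scope="session")
def small_kg(bundle) -> fs.KnowledgeGraph:
    return fs.load_kg(bundle.kg_triples, lexicon=bundle.lexicon)


@pytest.fixture(scope="session")
def count_provider(bundle) -> fs.OfflineCountProvider:
    return fs.OfflineCountProvider(bundle.term_counts, bundle.pair_counts)


@pytest.fixture(scope="session")
def llm_provider(bundle) -> fs.ScriptedLLMProvider:
    return fs.ScriptedLLMProvider(bundle.llm_script, default=(2, 2, 2))


@pytest.fixture(scope="session")
def cascade_result(bundle, small_kg, count_provider, llm_provider) -> fs.CascadeResult:
    """One full cascade run shared by the integration-level tests."""
    return fs.run_cascade(
        bundle.cohort,
        small_kg,
        bundle.lexicon,
        count_provider,
        llm_provider,
        bundle.target_name,
        bundle.target_entities,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
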