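import numpy as np
import pytest

from violex import (
    EmbeddingModel,
    FrameSchema,
    RewriteDictionary,
    default_dictionary,
    default_mwe_list,
    default_schema,
    default_tagger,
)


@pytest.fixture(scope="session")
def dictionary() -> RewriteDictionary:
    return default_dictionary()


@pytest.fixture(scope="session")
def tagger():
    return default_tagger()


@pytest.fixture(scope="session")
def schema() -> FrameSchema:
    return default_schema()


@pytest.fixture(scope="session")
def mwe_list() -> list[str]:
    return default_mwe_list()


@pytest.fixture(scope="session")
def axis_embedding(schema) -> EmbeddingModel:
    """Hand-crafted 6-d embedding: one axis per frame field.

    Every seed term of field *i* sits (almost) on axis *i*; a few extra
    narrative tokens sit on the axis of the field they should fill.  This
    makes the nearest-prototype assignment computable by inspection.
    """
    dim = len(schema.fields)
    vectors: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(99)
    for i, spec in enumerate(schema.fields):
        axis = np.zeros(dim)
        axis[i] = 1.0
        for seed in spec.seed_terms:
            vectors[seed] = axis + rng.normal(0, 0.01, dim)
    field_axis = {spec.name: i for i, spec in enumerate(schema.fields)}
    extra = {
        "tonight": "TIME",
        "punched": "MODE_INSTRUMENT",
        "arm": "BODY_PART",
        "home": "LOCATION",
        "fist": "MODE_INSTRUMENT",
        "afternoon": "TIME",
        "occipital": "LESION_TYPE",
    }
    for tok, fname in extra.items():
        axis = np.zeros(dim)
        axis[field_axis[fname]] = 1.0
        vectors.setdefault(tok, axis + rng.normal(0, 0.01, dim))
    # one token deliberately far from every prototype
    vectors["causing"] = -np.ones(dim) / np.sqrt(dim)
    vocab = sorted(vectors)
    return EmbeddingModel(vocab, np.stack([vectors[t] for t in vocab]))
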