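import pytest

from notesect import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """30 synthetic annotated notes, shared across tests (read-only)."""
    return generate_corpus(GeneratorConfig(seed=11, n_notes=30))


@pytest.fixture(scope="session")
def tiny_corpus():
    """3 short notes for round-trip and IO tests."""
    return generate_corpus(GeneratorConfig(seed=5, n_notes=3, mean_tokens=120.0))
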