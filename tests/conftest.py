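"""Shared fixtures: synthetic studies at the sizes the tests need."""

import pytest

from chromexpress import GeneratorSpec, generate_tensor, worked_example_small


@pytest.fixture(scope="session")
def medium_ds():
    """600-transcript default-panel study (fast path, no genomic tracks)."""
    return generate_tensor(GeneratorSpec(seed=11, n_transcripts=600))


@pytest.fixture(scope="session")
def operon_ds():
    """Study with operons and miRNA loci for the transfer analyses."""
    return generate_tensor(
        GeneratorSpec(seed=23, n_transcripts=400, n_operons=60, n_mirnas=80)
    )


@pytest.fixture(scope="session")
def worked():
    return worked_example_small()
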