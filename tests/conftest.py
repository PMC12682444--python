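from __future__ import annotations

import pytest

from ethnosurvey import (
    SurveyDataset,
    UseRecord,
    load_reference_margins,
    load_species_registry,
    realize_reference_dataset,
    reconstruct_np,
)


def make_dataset(triples, n_informants):
    """Build a dataset from bare (informant, species, category) triples."""
    return SurveyDataset(
        records=tuple(UseRecord(i, s, c) for i, s, c in triples),
        n_informants=n_informants,
    )


@pytest.fixture(scope="session")
def registry():
    return load_species_registry()


@pytest.fixture(scope="session")
def reference_margins():
    return load_reference_margins()


@pytest.fixture(scope="session")
def reference_cells(reference_margins):
    return reconstruct_np(reference_margins)


@pytest.fixture(scope="session")
def reference_dataset():
    """Informant-level dataset realizing the printed reference margins."""
    return realize_reference_dataset()
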