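import logging

import pytest

from oxymet import StudyConfig, simulate_study_bundle
from oxymet.data_model_io import derive_metabolite_classification
from oxymet.data_model_io import select_species


#: deliberately small study used by most integration-style tests
SMALL_STUDY = dict(
    n_bacteria=40,
    n_archaea=6,
    n_unicellular_eukaryotes=12,
    n_multicellular_eukaryotes=12,
    n_global_reactions=300,
    n_global_compounds=400,
)

#: desk-scale study for replicate loops: large enough that the integral
#: network is representative of per-species composition, small enough for
#: ~0.3 s per replicate
REPLICATE_STUDY = dict(
    n_bacteria=80,
    n_archaea=8,
    n_unicellular_eukaryotes=28,
    n_multicellular_eukaryotes=28,
    n_global_reactions=1000,
    n_global_compounds=1400,
    descriptors=("AlogP98",),
    descriptor_signs=(1,),
)


@pytest.fixture(autouse=True)
def _quiet_logging():
    logging.getLogger("oxymet").setLevel(logging.ERROR)
    yield
    logging.getLogger("oxymet").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study_bundle(StudyConfig(seed=7, **SMALL_STUDY))


@pytest.fixture(scope="session")
def small_networks(small_bundle):
    return small_bundle.networks()


@pytest.fixture(scope="session")
def small_classification(small_bundle):
    return derive_metabolite_classification(
        small_bundle.classification, small_bundle.links
    )


@pytest.fixture(scope="session")
def small_groups(small_bundle):
    return select_species(small_bundle.metadata, "nonredundant_groups")
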