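"""Shared fixtures: small cohorts and fitted models reused across tests."""

import numpy as np
import pytest

import gblica


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 40 subjects, 2 networks of 6x6x6
    voxels, 30 genera, 3 planted components, sparsity 0.1, noise 0.1."""
    return gblica.make_joint_dataset(seed=0)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Linked factorization of the default cohort at its planted order."""
    c = default_cohort
    lica_input = gblica.standardize_modalities(
        c.modalities, c.modality_names, c.subject_ids
    )
    model = gblica.fit_lica(lica_input, n_components=3, seed=0)
    return lica_input, model


@pytest.fixture()
def abundance_fixture():
    """3 samples x 4 taxa count table with two OTUs sharing a genus."""
    return gblica.AbundanceTable(
        counts=np.array([[3, 5, 2, 0],
                         [1, 0, 7, 4],
                         [0, 2, 0, 9]]),
        taxonomy=[
            "k__Bacteria;p__Bacteroidetes;f__Prevotellaceae;g__Prevotella_9",
            "k__Bacteria;p__Bacteroidetes;f__Prevotellaceae;g__Prevotella_9",
            "k__Bacteria;p__Firmicutes;f__Lachnospiraceae;g__Blautia",
            "k__Bacteria;p__Actinobacteria;f__Bifidobacteriaceae;g__Bifidobacterium",
        ],
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["otu1", "otu2", "otu3", "otu4"],
    )
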