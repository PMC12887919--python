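import pytest

from toothprot.io_formats import GroupDataset, QuantRecord, SpecimenDesign


def make_design(batch="group1", n_treatment=2, n_control=2, offset=0):
    design = []
    for j in range(n_treatment):
        design.append(
            SpecimenDesign(f"T{offset + j + 1}", batch, "treatment", f"L{j + 1}")
        )
    for j in range(n_control):
        design.append(
            SpecimenDesign(f"C{offset + j + 1}", batch, "control", f"L{j + 101}")
        )
    return design


def make_record(accession, abundances, q=0.01, n_peptides=3, n_psms=9,
                peptides=None, gene=None):
    return QuantRecord(
        accession=accession,
        gene=gene,
        q_value=q,
        n_peptides=n_peptides,
        n_psms=n_psms,
        abundances=abundances,
        peptide_abundances=peptides,
    )


def make_dataset(records, batch="group1", design=None):
    return GroupDataset(
        batch=batch, records=list(records), design=design or make_design(batch)
    )


@pytest.fixture
def design_g1():
    return make_design("group1")


@pytest.fixture
def two_batch_design():
    return make_design("group1") + make_design("group2", offset=2)
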