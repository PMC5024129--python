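import pytest

from akhtrace.peptides import parse_peptide_notation
from akhtrace.simulate import GeneratorConfig, generate_precursors


@pytest.fixture(scope="session")
def cgigas_akh():
    return parse_peptide_notation("pQVSFSTNWGSamide")


@pytest.fixture(scope="session")
def locusta_akh1():
    return parse_peptide_notation("pQLNFTPNWGTamide")


@pytest.fixture(scope="session")
def annelid_proto():
    return parse_peptide_notation("pQFSFSLPGKWGNamide")


@pytest.fixture(scope="session")
def clean_pset():
    """Small mutation-free synthetic precursor set shared across tests."""
    return generate_precursors(GeneratorConfig(n_precursors=60, seed=11))
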