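import numpy as np
import pytest

from startscreen.folding import NussinovFolder
from startscreen.synthetic_data import SyntheticSpec, make_species_fixture


@pytest.fixture(scope="session")
def oracle():
    """Plain pair-maximization oracle (no helix penalty)."""
    return NussinovFolder()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Default synthetic species: 100 CDS, 10 planted 20-bp stems, seed 42."""
    d = tmp_path_factory.mktemp("species")
    fasta, truth = make_species_fixture(SyntheticSpec(), d / "syn.fna", d / "truth.tsv")
    return fasta, truth


def read_truth(truth_path):
    """cds_id -> planted_kind from a fixture truth TSV."""
    rows = open(truth_path).read().splitlines()[1:]
    return {line.split("\t")[0]: line.split("\t")[1] for line in rows}
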