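import numpy as np
import pytest

from ssrherit.genotype_io import AlleleFrequencyTable, GenotypeTable


@pytest.fixture
def tiny_genepop(tmp_path):
    """Standard-dialect GENEPOP file: 3 individuals, 2 loci, one missing call."""
    text = (
        "tiny example\n"
        "locA\n"
        "locB\n"
        "POP\n"
        "ind1 , 101103 200200\n"
        "ind2 , 101101 200202\n"
        "ind3 , 0000 202204\n"
    )
    path = tmp_path / "tiny.gen"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_table(tmp_path):
    """The same three genotypes as a delimited table."""
    text = (
        "id\tlocA_a1\tlocA_a2\tlocB_a1\tlocB_a2\n"
        "ind1\t101\t103\t200\t200\n"
        "ind2\t101\t101\t200\t202\n"
        "ind3\t0\t0\t202\t204\n"
    )
    path = tmp_path / "tiny.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def five_ind_table():
    """Hand-checkable 5-individual, 2-locus table with missing calls."""
    calls = np.array(
        [
            [[101, 101], [200, 202]],
            [[101, 103], [0, 0]],
            [[103, 103], [202, 202]],
            [[0, 0], [200, 200]],
            [[101, 103], [200, 204]],
        ]
    )
    return GenotypeTable(["a", "b", "c", "d", "e"], ["L1", "L2"], calls)


@pytest.fixture
def halfhalf_freqs():
    """Seven loci, two equifrequent alleles each."""
    return AlleleFrequencyTable(
        {f"L{j}": {101: 0.5, 103: 0.5} for j in range(1, 8)}
    )


def make_pair_table(g1, g2, n_loci=None):
    """Two-individual table from per-locus genotype tuples."""
    n_loci = n_loci or len(g1)
    calls = np.array([[list(c) for c in g1], [list(c) for c in g2]])
    return GenotypeTable(["x", "y"], [f"L{j}" for j in range(n_loci)], calls)
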