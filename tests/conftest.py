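import numpy as np
import pandas as pd
import pytest

from durumdiv.io import MARKER_COLUMNS, GenotypeMatrix


def make_matrix(calls, accessions=None, chromosomes=None, alleles=None):
    """GenotypeMatrix from a plain call array with autogenerated metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    if accessions is None:
        accessions = [f"acc{i+1:03d}" for i in range(n)]
    if chromosomes is None:
        chromosomes = ["1A"] * l
    if alleles is None:
        alleles = [("A", "G")] * l
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j+1}" for j in range(l)],
            "chromosome": chromosomes,
            "position_bp": [(j + 1) * 1000 for j in range(l)],
            "allele_ref": [a[0] for a in alleles],
            "allele_alt": [a[1] for a in alleles],
        },
        columns=MARKER_COLUMNS,
    )
    return GenotypeMatrix(calls=calls, accessions=accessions, markers=markers)


@pytest.fixture
def toy_matrix():
    """4 accessions x 3 loci, no missing data."""
    return make_matrix([[0, 1, 2], [0, 0, 2], [1, 1, 0], [2, 0, 0]])
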