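import numpy as np
import pytest

from hrscan.afdata import AFTable, LineDesign


@pytest.fixture
def design() -> LineDesign:
    return LineDesign.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240801)


def make_table(af, design=None, chrom=None, pos=None, generation=None) -> AFTable:
    """Small AFTable helper for tests; af is (n_loci, n_lines)."""
    af = np.asarray(af, dtype=np.float64)
    n = af.shape[0]
    design = design or LineDesign.default()
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * n, dtype=object)
    pos = np.asarray(
        pos if pos is not None else np.arange(1, n + 1) * 1000, dtype=np.int64
    )
    return AFTable(
        chrom=chrom, pos=pos, af=af, design=design, generation=generation
    ).sort().validate()


@pytest.fixture
def toy_table(design) -> AFTable:
    rng = np.random.default_rng(5)
    return make_table(rng.uniform(0.1, 0.9, size=(30, 8)), design=design)
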