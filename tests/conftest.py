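import numpy as np
import pandas as pd
import pytest

from lekscan.data import AlleleCountTable, DesignSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def design_4_4_3():
    return DesignSpec(
        {
            **{f"S{i}": "success" for i in range(1, 5)},
            **{f"F{i}": "failure" for i in range(1, 5)},
            **{f"C{i}": "control" for i in range(1, 4)},
        }
    )


def make_table(minor, major, chrom="2L", start_pos=100, spacing=1000,
               line_ids=None):
    """Build a small AlleleCountTable from count matrices."""
    minor = np.asarray(minor)
    major = np.asarray(major)
    n_loci, n_lines = minor.shape
    if line_ids is None:
        line_ids = tuple(f"L{i+1}" for i in range(n_lines))
    if isinstance(chrom, str):
        chrom = [chrom] * n_loci
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_loci),
            "ref": "A",
            "alt": "T",
        }
    )
    return AlleleCountTable(loci, tuple(line_ids), minor, major)


@pytest.fixture
def random_table(rng):
    """11-line random table shaped like the real design."""
    n_loci = 60
    line_ids = tuple(
        [f"S{i}" for i in range(1, 5)]
        + [f"F{i}" for i in range(1, 5)]
        + [f"C{i}" for i in range(1, 4)]
    )
    depth = rng.integers(15, 46, size=(n_loci, 11))
    p = rng.uniform(0.05, 0.5, size=(n_loci, 1))
    minor = rng.binomial(depth, p)
    return make_table(minor, depth - minor, line_ids=line_ids)
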