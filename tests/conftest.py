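import numpy as np
import pandas as pd
import pytest

import haplogeo as hg
from haplogeo import datasets as ds


@pytest.fixture(scope="session")
def study_table() -> hg.HaplotypeTable:
    """The packaged haplotype-by-locality count table (with sequences)."""
    return ds.haplotype_table()


@pytest.fixture(scope="session")
def study_distances() -> hg.HaplotypeDistanceMatrix:
    return ds.haplotype_distances()


@pytest.fixture()
def toy_alignment() -> hg.HaplotypeAlignment:
    """Six samples, two populations, three haplotypes over 8 sites."""
    recs = [
        hg.AlignmentRecord("a1", "A", "ACGTACGT"),
        hg.AlignmentRecord("a2", "A", "ACGTACGT"),
        hg.AlignmentRecord("a3", "A", "ACGTACGA"),
        hg.AlignmentRecord("b1", "B", "ACGTACGA"),
        hg.AlignmentRecord("b2", "B", "ACGAACGA"),
        hg.AlignmentRecord("b3", "B", "ACGAACGA"),
    ]
    return hg.HaplotypeAlignment(recs)


def table_from_counts(counts: dict[str, list[int]], sequences=None) -> hg.HaplotypeTable:
    """Helper: build a HaplotypeTable from {population: counts} columns."""
    n = max(len(v) for v in counts.values())
    padded = {p: list(v) + [0] * (n - len(v)) for p, v in counts.items()}
    idx = pd.Index([f"h{i}" for i in range(n)], name="haplotype")
    return hg.HaplotypeTable(counts=pd.DataFrame(padded, index=idx),
                             sequences=sequences or {})


def expand_individuals(counts) -> np.ndarray:
    """Haplotype index per individual for brute-force oracles."""
    c = np.asarray(list(counts), dtype=int)
    return np.repeat(np.arange(len(c)), c)
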