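"""Per-population diversity indices for haplotype count data.

Implements the classic table of mtDNA diversity summaries: number of
haplotypes h, segregating sites S, unbiased haplotype diversity
Hd = n/(n-1) * (1 - sum p_i^2) (Nei 1987), mean pairwise sequence
differences Pi, and nucleotide diversity pi = Pi / L.

All functions return full-precision floats; rounding (3 dp, half away
from zero) happens only in the reporting helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import HaplotypeTable

__all__ = [
    "HaplotypeDistanceMatrix",
    "DiversitySummary",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "segregating_sites",
    "summarize_populations",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (0.4365 -> 0.437 at 3 dp)."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass
class HaplotypeDistanceMatrix:
    """Pairwise mutational-step counts between haplotypes.

    Symmetric, zero-diagonal, non-negative. Gap columns count as a fifth
    state (one step per differing column); N is treated as missing and
    never contributes a difference.
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.ids)
        if self.d.shape != (k, k):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({k}, {k})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "HaplotypeDistanceMatrix":
        ids = list(sequences)
        seqs = [sequences[h] for h in ids]
        L = {len(s) for s in seqs}
        if len(L) > 1:
            raise ValueError("haplotype sequences have unequal lengths")
        k = len(ids)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                steps = sum(
                    1
                    for a, b in zip(seqs[i], seqs[j])
                    if a != b and a != "N" and b != "N"
                )
                d[i, j] = d[j, i] = steps
        return cls(ids=ids, d=d)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(h) for h in ids]
        return self.d[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index), d=df.values)


@dataclass
class DiversitySummary:
    population: str
    n: int
    h: int
    S: int | None
    Hd: float
    Pi_pair: float | None
    pi: float | None  # fraction; multiply by 100 to report as %


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    c = np.asarray(list(counts), dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 sequences")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def mean_pairwise_differences(counts, dist: HaplotypeDistanceMatrix | np.ndarray) -> float:
    """Mean number of pairwise differences Pi over all C(n,2) sequence pairs."""
    c = np.asarray(list(counts), dtype=float)
    d = dist.d if isinstance(dist, HaplotypeDistanceMatrix) else np.asarray(dist, float)
    if d.shape != (len(c), len(c)):
        raise ValueError(
            f"counts length {len(c)} does not match distance matrix {d.shape}"
        )
    n = c.sum()
    if n < 2:
        return 0.0
    total = float(c @ d @ c) / 2.0  # c_i c_j d_ij over i<j
    return total / (n * (n - 1) / 2.0)


def nucleotide_diversity(Pi_pair: float, L: int) -> float:
    """Nucleotide diversity pi = Pi / L, as a fraction of sites."""
    if L <= 0:
        raise ValueError("alignment length must be positive")
    return Pi_pair / L


def segregating_sites(sequences: list[str]) -> int:
    """Columns with >= 2 observed states; gaps count as a state, N is missing."""
    if not sequences:
        return 0
    L = {len(s) for s in sequences}
    if len(L) > 1:
        raise ValueError("sequences have unequal lengths")
    S = 0
    for col in zip(*sequences):
        states = {c for c in col if c != "N"}
        if len(states) >= 2:
            S += 1
    return S


def summarize_populations(
    table: HaplotypeTable,
    dist: HaplotypeDistanceMatrix | None = None,
    L: int | None = None,
    groups: dict[str, list[str]] | None = None,
) -> list[DiversitySummary]:
    """One DiversitySummary per population (plus pooled groups on request).

    S is computed from haplotype sequences when the table carries them and
    omitted otherwise. Pi requires a distance matrix (or sequences, from
    which one is derived); pi additionally requires L. Empty populations
    are skipped with a warning.
    """
    if dist is None and table.sequences:
        dist = HaplotypeDistanceMatrix.from_sequences(table.sequences)

    columns: list[tuple[str, pd.Series]] = [
        (pop, table.counts[pop]) for pop in table.populations
    ]
    if groups:
        for name, pops in groups.items():
            columns.append((name, table.pooled(pops, name)))

    out: list[DiversitySummary] = []
    for name, col in columns:
        n = int(col.sum())
        if n == 0:
            warnings.warn(f"population {name!r} has no samples; skipped")
            continue
        present = col[col > 0]
        h = int((col > 0).sum())
        Hd = haplotype_diversity(col) if n >= 2 else 0.0
        S = None
        if table.sequences:
            S = segregating_sites([table.sequences[hap] for hap in present.index])
        Pi = None
        pi = None
        if dist is not None:
            sub = dist.submatrix(list(col.index))
            Pi = mean_pairwise_differences(col.values, sub)
            if L:
                pi = nucleotide_diversity(Pi, L)
        out.append(DiversitySummary(name, n, h, S, Hd, Pi, pi))
    return out


def diversity_table(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """Reporting layer: 3-dp half-away rounding, pi printed as a percentage."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "population": s.population,
                "n": s.n,
                "h": s.h,
                "S": s.S,
                "Hd": round_half_away(s.Hd, 3),
                "pi_pct": None if s.pi is None else round_half_away(100 * s.pi, 2),
                "Pi": None if s.Pi_pair is None else round_half_away(s.Pi_pair, 3),
            }
        )
    return pd.DataFrame(rows).set_index("population")
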