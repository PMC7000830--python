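"""Microsatellite diversity summaries and the allelic-richness test.

Per-locus summaries of a diploid genotype panel: observed heterozygosity
Ho, unbiased expected heterozygosity He = 2n/(2n-1) * (1 - sum p_i^2),
and the number of distinct alleles nA. Cross-study comparisons of allelic
richness use an unpaired pooled-reallocation randomization test: the
per-locus allele counts of the two groups are pooled and reallocated into
equal halves, and the upper-tail probability is the proportion of splits
whose group-A mean is at least the observed one. All C(2k, k) splits are
enumerated when that is feasible; otherwise Monte Carlo draws are used
with the (b+1)/(B+1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "LocusSummary",
    "RichnessTest",
    "locus_summary",
    "summarize_loci",
    "mean_alleles",
    "richness_test",
    "ENUMERATION_LIMIT",
]

# Full enumeration of pooled reallocations is used up to this many splits.
ENUMERATION_LIMIT = 200_000


@dataclass
class LocusSummary:
    locus: str
    n: int          # genotyped individuals (missing excluded)
    nA: int
    Ho: float
    He: float


def locus_summary(locus: str, genotypes) -> LocusSummary:
    """Summarize one locus from diploid genotypes.

    ``genotypes`` is an iterable of (allele1, allele2) pairs; pairs
    containing None are treated as missing and excluded from n with a
    warning.
    """
    pairs = list(genotypes)
    usable = [(a, b) for a, b in pairs if a is not None and b is not None]
    dropped = len(pairs) - len(usable)
    if dropped:
        warnings.warn(f"locus {locus}: {dropped} missing genotypes excluded")
    n = len(usable)
    if n < 1:
        raise ValueError(f"locus {locus}: no usable genotypes")
    alleles = [a for pair in usable for a in pair]
    counts = pd.Series(alleles).value_counts()
    p = counts / counts.sum()
    nA = len(counts)
    Ho = sum(1 for a, b in usable if a != b) / n
    if nA == 1:
        He = 0.0
    else:
        He = (2 * n) / (2 * n - 1) * (1.0 - float((p**2).sum()))
    return LocusSummary(locus=locus, n=n, nA=nA, Ho=Ho, He=He)


def summarize_loci(genotype_table: pd.DataFrame) -> list[LocusSummary]:
    """Summaries for a long-format genotype table with columns
    (individual, locus, allele1, allele2)."""
    out = []
    for locus, grp in genotype_table.groupby("locus", sort=True):
        gts = [
            (None if pd.isna(a) else a, None if pd.isna(b) else b)
            for a, b in zip(grp["allele1"], grp["allele2"])
        ]
        out.append(locus_summary(str(locus), gts))
    return out


def mean_alleles(summaries, usable=None) -> float:
    """Mean number of alleles per locus over a usable-locus subset.

    ``summaries`` is a list of LocusSummary or a mapping locus -> nA;
    ``usable`` restricts to those loci (default: all).
    """
    if isinstance(summaries, dict):
        nA = dict(summaries)
    else:
        nA = {s.locus: s.nA for s in summaries}
    loci = list(nA) if usable is None else list(usable)
    if not loci:
        raise ValueError("empty locus subset")
    missing = [l for l in loci if l not in nA]
    if missing:
        raise KeyError(f"loci without summaries: {missing}")
    return float(np.mean([nA[l] for l in loci]))


@dataclass
class RichnessTest:
    group_a: tuple
    group_b: tuple
    p: float
    method: str      # "enumeration" or "randomization"
    n_splits: int    # splits enumerated, or Monte Carlo draws
    observed_mean_a: float


def richness_test(
    group_a, group_b, n_rand: int = 10_000, seed: int = 0
) -> RichnessTest:
    """Upper-tail pooled-reallocation test for allelic-richness differences.

    ``group_a`` and ``group_b`` are per-locus allele counts over the same
    loci (equal length, >= 2). The 2k values are pooled; p is the
    probability that a random equal split gives a group-A mean at least as
    large as observed. Exact enumeration when C(2k, k) <= ENUMERATION_LIMIT,
    else ``n_rand`` Monte Carlo reallocations with p = (b+1)/(B+1).
    """
    a = [int(x) for x in group_a]
    b = [int(x) for x in group_b]
    if len(a) != len(b):
        raise ValueError("groups must cover the same loci (equal length)")
    k = len(a)
    if k < 2:
        raise ValueError("need at least two loci")
    pool = np.array(a + b)
    obs = sum(a)  # equal split sizes: sum and mean orderings coincide

    total = comb(2 * k, k)
    if total <= ENUMERATION_LIMIT:
        hits = 0
        for idx in combinations(range(2 * k), k):
            if pool[list(idx)].sum() >= obs:
                hits += 1
        return RichnessTest(
            tuple(a), tuple(b), hits / total, "enumeration", total, obs / k
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(2 * k)[:k]
        if pool[perm].sum() >= obs:
            hits += 1
    return RichnessTest(
        tuple(a), tuple(b), (hits + 1) / (n_rand + 1), "randomization", n_rand, obs / k
    )
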