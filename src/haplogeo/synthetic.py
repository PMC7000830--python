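"""Synthetic data generators with known ground truth.

Every input class the pipeline consumes can be generated here with the
answer recorded: multi-population haplotype alignments with specified
frequency spectra and a known inter-haplotype distance topology (star or
homoplasy-free tree), alignments with injected parallel mutations (to
exercise the network loop diagnostics), microsatellite genotype panels
drawn under Hardy-Weinberg from specified allele frequencies, and
pseudo-observed summary-statistic vectors drawn from either demographic
scenario (to exercise the ABC machinery).

Generators are deterministic given their seed. "Exact" mode realizes a
frequency spectrum with deterministic counts (required when downstream
values are pinned analytically); "sampled" mode draws multinomially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentRecord, HaplotypeAlignment
from .coalescent import simulate_coalescent, summarize_sample
from .diversity import (
    HaplotypeDistanceMatrix,
    haplotype_diversity,
    mean_pairwise_differences,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_haplotype_dataset",
    "inject_homoplasy",
    "make_msat_panel",
    "make_pseudo_observed",
]

BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Specification of a synthetic haplotype dataset.

    populations maps population name to either a list of per-haplotype
    counts (exact mode) or a (n, frequencies) pair; frequencies must sum
    to 1 and, in exact mode, n * freq must be integral for every
    haplotype. The number of haplotypes is the longest spectrum.
    """

    seed: int = 0
    L: int = 345
    mode: str = "exact"  # "exact" | "sampled"
    distance_model: str = "star"  # "star" | "tree"
    populations: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    partition: dict[str, int]  # sample id -> haplotype index
    counts: pd.DataFrame       # haplotype x population realized counts
    sequences: list[str]
    distances: HaplotypeDistanceMatrix
    Hd: dict[str, float]
    Pi: dict[str, float]


def _haplotype_sequences(
    n_haps: int, L: int, model: str, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Haplotype sequences over a random backbone plus their distance matrix.

    "star": haplotype 0 is central; haplotype i differs from it at one
    private site (pairwise distance 2 between non-central haplotypes).
    "tree": a random growing tree; each new haplotype attaches to a random
    existing one with one new mutation at a fresh site (homoplasy-free,
    additive distances).
    """
    if n_haps - 1 > L:
        raise ValueError("alignment too short for the requested haplotype count")
    base = rng.choice(list(BASES), size=L)
    seqs = [base.copy()]
    parents = [-1]
    sites = rng.permutation(L)[: n_haps - 1]
    for i in range(1, n_haps):
        parent = 0 if model == "star" else int(rng.integers(i))
        s = seqs[parent].copy()
        pos = sites[i - 1]
        s[pos] = BASES[(BASES.index(s[pos]) + 1) % 4]
        seqs.append(s)
        parents.append(parent)
    # tree distances: path lengths (each edge is one unique site)
    k = n_haps
    d = np.zeros((k, k))
    depth = [0] * k
    anc: list[set[int]] = [set()]
    for i in range(1, k):
        anc.append(anc[parents[i]] | {i})
        depth[i] = len(anc[i])
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = len(anc[i] ^ anc[j])
    return ["".join(s) for s in seqs], d


def _realize_counts(spec, mode: str, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (list, tuple, np.ndarray)) and not (
        len(spec) == 2 and np.isscalar(spec[0]) and isinstance(spec[1], (list, tuple, np.ndarray))
    ):
        return np.asarray(spec, dtype=int)
    n, freqs = spec
    freqs = np.asarray(freqs, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    if mode == "sampled":
        return rng.multinomial(int(n), freqs)
    exact = freqs * n
    counts = np.rint(exact)
    if not np.allclose(exact, counts, atol=1e-9):
        raise ValueError(
            f"spectrum {freqs.tolist()} x n={n} is not integral in exact mode"
        )
    return counts.astype(int)


def make_haplotype_dataset(
    config: SyntheticConfig,
) -> tuple[HaplotypeAlignment, GroundTruth]:
    """Generate a labelled alignment realizing the configured spectra.

    Ground truth records the true partition of samples into haplotypes,
    the realized counts, the haplotype distance matrix and the analytic
    per-population Hd and Pi implied by the realized counts.
    """
    if not config.populations:
        raise ValueError("config.populations is empty")
    rng = np.random.default_rng(config.seed)
    counts = {
        pop: _realize_counts(spec, config.mode, rng)
        for pop, spec in config.populations.items()
    }
    n_haps = max(len(c) for c in counts.values())
    counts = {
        pop: np.pad(c, (0, n_haps - len(c))) for pop, c in counts.items()
    }
    seqs, d = _haplotype_sequences(n_haps, config.L, config.distance_model, rng)

    records: list[AlignmentRecord] = []
    partition: dict[str, int] = {}
    for pop, c in counts.items():
        i = 0
        for hap, k in enumerate(c):
            for _ in range(int(k)):
                i += 1
                sid = f"{pop}_{i:04d}"
                records.append(AlignmentRecord(sid, pop, seqs[hap]))
                partition[sid] = hap
    aln = HaplotypeAlignment(records)

    hap_ids = [f"hap{i}" for i in range(n_haps)]
    dist = HaplotypeDistanceMatrix(ids=hap_ids, d=d)
    count_df = pd.DataFrame(
        {pop: c for pop, c in counts.items()},
        index=pd.Index(hap_ids, name="haplotype"),
    )
    Hd = {
        pop: haplotype_diversity(c) if c.sum() >= 2 else 0.0
        for pop, c in counts.items()
    }
    Pi = {pop: mean_pairwise_differences(c, d) for pop, c in counts.items()}
    truth = GroundTruth(
        partition=partition, counts=count_df, sequences=seqs,
        distances=dist, Hd=Hd, Pi=Pi,
    )
    return aln, truth


@dataclass
class HomoplasyRecord:
    site: int                  # 1-based injected column
    lineages: list[str]        # affected haplotype sequences (pre-injection)
    flipped_samples: list[str]
    derived_state: str
    n_parallel: int


def inject_homoplasy(
    aln: HaplotypeAlignment, site: int, n_parallel: int
) -> tuple[HaplotypeAlignment, HomoplasyRecord]:
    """Make one column hypervariable: a parallel mutation on n_parallel lineages.

    The same derived state is introduced at ``site`` on part of the samples
    (half, at least one) of each of the ``n_parallel`` most frequent
    haplotype classes, emulating a site that mutates independently on
    several branches of the genealogy. Each affected class thereby gains a
    derived twin that differs from it only at this column; removing the
    column merges the twins back, restoring the original partition.

    With a single affected lineage the new twin simply hangs off its
    parent and no reticulation appears. When the affected classes are
    mutationally adjacent (e.g. the core of a star or tree), the derived
    twins replicate the edges among their parents, and a median-joining
    network gains one independent loop per replicated edge (k affected
    classes forming a connected subtree yield k - 1 loops).
    """
    if not 1 <= site <= aln.L:
        raise ValueError(f"site {site} outside alignment of length {aln.L}")
    classes: dict[str, list[str]] = {}
    for r in aln.records:
        classes.setdefault(r.sequence, []).append(r.sample_id)
    eligible = [s for s, members in classes.items() if len(members) >= 2]
    eligible.sort(key=lambda s: (-len(classes[s]), s))
    targets = eligible[:n_parallel]
    if len(targets) < n_parallel:
        raise ValueError(
            f"only {len(targets)} haplotype classes with >= 2 samples, "
            f"need {n_parallel}"
        )
    col = site - 1
    observed = {s[col] for s in classes}
    unused = [b for b in BASES if b not in observed]
    derived = unused[0] if unused else BASES[(BASES.index(sorted(observed)[0]) + 1) % 4]
    flip: set[str] = set()
    for s in targets:
        members = classes[s]
        flip.update(members[: max(1, len(members) // 2)])
    records = []
    for r in aln.records:
        if r.sample_id in flip:
            s = r.sequence[:col] + derived + r.sequence[col + 1 :]
            records.append(AlignmentRecord(r.sample_id, r.population, s))
        else:
            records.append(r)
    rec = HomoplasyRecord(
        site=site, lineages=targets, flipped_samples=sorted(flip),
        derived_state=derived, n_parallel=n_parallel,
    )
    return HaplotypeAlignment(records), rec


def make_msat_panel(
    loci: Mapping[str, Sequence[float]],
    n: int,
    seed: int = 0,
    population: str = "POP",
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Diploid genotypes drawn under Hardy-Weinberg equilibrium.

    ``loci`` maps locus name to allele frequencies. Returns a long-format
    genotype table (individual, population, locus, allele1, allele2) and
    the true allele frequencies.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, np.ndarray] = {}
    for locus, freqs in loci.items():
        p = np.asarray(freqs, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"locus {locus}: frequencies must sum to 1")
        truth[locus] = p
        a1 = rng.choice(len(p), size=n, p=p)
        a2 = rng.choice(len(p), size=n, p=p)
        for i in range(n):
            rows.append(
                {
                    "individual": f"{population}_{i + 1:04d}",
                    "population": population,
                    "locus": locus,
                    "allele1": int(a1[i]) + 1,
                    "allele2": int(a2[i]) + 1,
                }
            )
    return pd.DataFrame(rows), truth


def make_pseudo_observed(
    scenario: int,
    params: dict[str, float],
    sample_sizes: tuple[int, int],
    seed: int = 0,
    L: int = 345,
) -> tuple[np.ndarray, dict]:
    """One pseudo-observed summary-statistic vector with its truth record."""
    rng = np.random.default_rng(seed)
    sample = simulate_coalescent(params, scenario, sample_sizes, rng, L=L)
    stats = summarize_sample(sample)
    truth = {"scenario": scenario, "params": dict(params), "seed": seed}
    return stats, truth
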