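"""Packaged fixtures: the published pilot-whale data tables.

Long-finned pilot whales (*Globicephala melas*) have an antitropical
distribution with two subspecies: *G. m. edwardii* in the Southern
Hemisphere (sampled in Tasmania, New Zealand and Chile) and *G. m. melas*
in the North Atlantic and Mediterranean. The fixtures below transcribe
the published mtDNA control-region haplotype-by-locality count table and
the cross-study microsatellite comparison table.

Caveats, recorded per haplotype/locality:

* The counts for CL, NWA, FI, UK, IB, NEA, GIB and MED, the NZ spectrum
  and the TAS totals for the three basin-shared haplotypes were validated
  by back-computing the published diversity indices. The three TAS
  private-haplotype counts (which sum to 60) and parts of the
  haplotype-to-column assignment are reconstructions and are flagged
  ``APPROXIMATE``; pinned analyses must not rely on them.
* Haplotype sequences are synthetic realizations of the mutation tree
  implied by the published pairwise-difference values (S+R one step from
  P+U, D, E+G and hap60; X one step from P+U; hap62 one step from hap60);
  they reproduce the validated inter-haplotype step counts but are not
  the GenBank sequences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import HaplotypeTable
from .diversity import HaplotypeDistanceMatrix

__all__ = [
    "LOCALITIES",
    "SUBSPECIES",
    "APPROXIMATE_LOCALITIES",
    "haplotype_counts",
    "haplotype_table",
    "haplotype_distances",
    "ALIGNMENT_LENGTH",
    "microsat_table",
    "interhemisphere_shared_loci",
    "intrapacific_shared_loci",
    "CHILE_USABLE_LOCI",
    "HOMOZYGOTE_EXCESS_LOCI",
]

ALIGNMENT_LENGTH = 345  # curated control-region fragment, sites

HAPLOTYPES = [
    "S+R", "P+U", "Q+Y", "R2", "T", "O", "V", "O2", "W", "Z",
    "E+G", "60", "62", "X", "D",
]

# locality -> {haplotype: count}; reconstruction caveats in module docstring
_COUNTS = {
    "TAS": {"S+R": 51, "P+U": 32, "Q+Y": 72, "T": 30, "O": 20, "V": 10},
    "NZ": {"S+R": 6, "P+U": 333, "Q+Y": 3, "O2": 1, "W": 14, "Z": 1},
    "CL": {"S+R": 31, "P+U": 45, "Q+Y": 12, "R2": 2},
    "NWA": {"S+R": 73, "P+U": 1, "X": 4},
    "FI": {"S+R": 55, "P+U": 17},
    "UK": {"S+R": 34, "P+U": 1, "E+G": 4},
    "IB": {"S+R": 39, "E+G": 1, "60": 1, "62": 1},
    "NEA": {"S+R": 20, "E+G": 1},
    "GIB": {"S+R": 44, "D": 20},
    "MED": {"S+R": 12, "D": 21},
}

LOCALITIES = list(_COUNTS)

SUBSPECIES = {
    "edwardii": ["TAS", "NZ", "CL"],
    "melas": ["NWA", "FI", "UK", "IB", "NEA", "GIB", "MED"],
}

# rows whose haplotype spectra are partly reconstructed, not validated
APPROXIMATE_LOCALITIES = {"TAS", "NZ", "IB"}

# mutation tree over the haplotypes: child -> (parent, steps); None = root.
# Every step is one unique site, so the tree is homoplasy-free and the
# implied distances are additive.
_HAP_TREE = {
    "S+R": None,
    "P+U": ("S+R", 1), "D": ("S+R", 1), "E+G": ("S+R", 1), "60": ("S+R", 1),
    "T": ("S+R", 1), "O": ("S+R", 1), "V": ("S+R", 1), "Z": ("S+R", 1),
    "Q+Y": ("P+U", 1), "R2": ("P+U", 2), "O2": ("P+U", 1), "W": ("P+U", 1),
    "X": ("P+U", 1),
    "62": ("60", 1),
}


def haplotype_counts() -> pd.DataFrame:
    """Haplotype x locality count matrix (1012 sequences, 15 haplotypes)."""
    df = pd.DataFrame(
        {loc: [(_COUNTS[loc].get(h, 0)) for h in HAPLOTYPES] for loc in LOCALITIES},
        index=pd.Index(HAPLOTYPES, name="haplotype"),
    )
    return df


def _haplotype_sequences() -> dict[str, str]:
    rng = np.random.default_rng(20200204)
    base = rng.choice(list("ACGT"), size=ALIGNMENT_LENGTH)
    edges = [h for h in HAPLOTYPES if _HAP_TREE[h] is not None]
    n_sites = sum(_HAP_TREE[h][1] for h in edges)
    perm = iter(rng.permutation(ALIGNMENT_LENGTH)[:n_sites])
    site_of = {h: [next(perm) for _ in range(_HAP_TREE[h][1])] for h in edges}
    seqs: dict[str, str] = {}

    def build(h: str) -> np.ndarray:
        if _HAP_TREE[h] is None:
            return base.copy()
        parent, _ = _HAP_TREE[h]
        s = build(parent)
        for pos in site_of[h]:
            s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
        return s

    for h in HAPLOTYPES:
        seqs[h] = "".join(build(h))
    return seqs


def haplotype_table(with_sequences: bool = True) -> HaplotypeTable:
    """The published count table as a HaplotypeTable.

    ``with_sequences=True`` attaches the synthetic tree-realization
    sequences (needed for networks and phi_ST); pass False for a
    counts-only table.
    """
    counts = haplotype_counts()
    seqs = _haplotype_sequences() if with_sequences else {}
    return HaplotypeTable(
        counts=counts, sequences=seqs, approximate=set(APPROXIMATE_LOCALITIES)
    )


def haplotype_distances() -> HaplotypeDistanceMatrix:
    """Pairwise mutational steps implied by the haplotype mutation tree."""
    return HaplotypeDistanceMatrix.from_sequences(_haplotype_sequences())


# ---------------------------------------------------------------------------
# Microsatellites: cross-study per-locus summaries.
# Columns: (n, nA, Ho, He) per study; None = not typed / not reported.

_MSAT = {
    # locus:       Tasmania & New Zealand,   Chile (this study),       North Atlantic
    "409/470":  ((262, 10, 0.844, 0.825), None,                    (52, 9, None, 0.567)),
    "415/416":  ((242, 9, 0.798, 0.801),  None,                    (52, 5, None, 0.567)),
    "464/465":  ((122, 9, 0.648, 0.681),  (44, 9, 0.676, 0.578),   (52, 6, None, 0.670)),
    "DlrFCB1":  ((264, 15, 0.777, 0.774), (44, 8, 0.682, 0.760),   None),
    "DlrFCB6":  ((256, 7, 0.672, 0.693),  (44, 7, 0.476, 0.716),   None),
    "EV1":      ((262, 14, 0.756, 0.773), (44, 10, 0.756, 0.739),  None),
    "EV37":     ((263, 10, 0.814, 0.775), (44, 15, 0.633, 0.858),  (52, 6, None, 0.748)),
    "EV94":     ((255, 7, 0.620, 0.686),  None,                    (52, 7, None, 0.772)),
    "GT23":     ((263, 5, 0.468, 0.439),  (44, 4, 0.341, 0.567),   None),
    "GT39":     ((122, 10, 0.787, 0.822), (44, 5, 0.636, 0.512),   None),
    "GT51":     ((253, 3, 0.300, 0.308),  (44, 4, 0.318, 0.492),   None),
    "GT575":    ((254, 11, 0.827, 0.836), (44, 7, 0.841, 0.828),   None),
    "MK5":      ((244, 6, 0.623, 0.658),  (44, 7, 0.682, 0.670),   None),
    "MK9":      ((120, 4, 0.625, 0.618),  (44, 4, 0.591, 0.613),   None),
    "PPHO131":  ((248, 10, 0.734, 0.745), (44, 6, 0.714, 0.696),   None),
}

STUDIES = ["sw_pacific", "chile", "north_atlantic"]

# loci showing a homozygote excess in the Chilean panel; excluded from
# inter-hemisphere comparisons
HOMOZYGOTE_EXCESS_LOCI = ["DlrFCB6", "GT51"]

CHILE_USABLE_LOCI = [
    "464/465", "DlrFCB1", "EV1", "EV37", "GT23",
    "GT39", "GT575", "MK5", "MK9", "PPHO131",
]


def microsat_table() -> pd.DataFrame:
    """Long-format per-locus summaries: study, locus, n, nA, Ho, He."""
    rows = []
    for locus, per_study in _MSAT.items():
        for study, vals in zip(STUDIES, per_study):
            if vals is None:
                continue
            n, nA, Ho, He = vals
            rows.append(
                {"study": study, "locus": locus, "n": n, "nA": nA, "Ho": Ho, "He": He}
            )
    return pd.DataFrame(rows)


def _shared(study_a: str, study_b: str, exclude=()) -> tuple[list[int], list[int], list[str]]:
    df = microsat_table().pivot(index="locus", columns="study", values="nA")
    loci = [
        l for l in _MSAT
        if l not in exclude and pd.notna(df.loc[l, study_a]) and pd.notna(df.loc[l, study_b])
    ]
    a = [int(df.loc[l, study_a]) for l in loci]
    b = [int(df.loc[l, study_b]) for l in loci]
    return a, b, loci


def interhemisphere_shared_loci() -> tuple[list[int], list[int], list[str]]:
    """Per-locus allele counts for the five loci shared between the
    southwestern Pacific and North Atlantic panels (homozygote-excess loci
    excluded): (south, north, loci)."""
    return _shared("sw_pacific", "north_atlantic", exclude=HOMOZYGOTE_EXCESS_LOCI)


def intrapacific_shared_loci(usable_only: bool = False) -> tuple[list[int], list[int], list[str]]:
    """Per-locus allele counts shared between the southwestern Pacific and
    Chilean panels: (sw_pacific, chile, loci).

    By default all 12 shared loci are returned — the within-hemisphere
    comparison, for which the homozygote-excess exclusion does not apply.
    ``usable_only=True`` restricts to the 10 loci also used in
    cross-hemisphere work.
    """
    exclude = HOMOZYGOTE_EXCESS_LOCI if usable_only else ()
    return _shared("sw_pacific", "chile", exclude=exclude)
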