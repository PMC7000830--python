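"""Population genetic and phylogeographic structure statistics.

AMOVA fixation indices in the Excoffier-Smouse-Quattro sums-of-squared-
deviations formulation, on two levels (pairwise F_ST / phi_ST) or three
levels (among groups / among populations within groups / within
populations). F_ST uses haplotype identity only (delta_ij = 1 for
distinct haplotypes); phi_ST weights by inter-haplotype mutational
distance. Permutation p-values, Hudson's (2000) nearest-neighbour Snn
test, Nei's (1987) net nucleotide divergence d_A and correspondence
analysis of a presence/absence matrix complete the module.

Negative variance components (and hence negative fixation indices) are
reported as computed, never clamped: small negative values are the
expected behaviour of the estimator under panmixia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import HaplotypeTable
from .diversity import HaplotypeDistanceMatrix

__all__ = [
    "AmovaResult",
    "SnnResult",
    "DivergenceResult",
    "CAResult",
    "pairwise_fst",
    "pairwise_phist",
    "pairwise_matrix",
    "amova",
    "permutation_p",
    "snn_test",
    "net_divergence",
    "correspondence_analysis",
]


# ---------------------------------------------------------------------------
# AMOVA core

def _ssd(c: np.ndarray, D: np.ndarray) -> float:
    """Sum of squared deviations for one set: (1/n) * sum_{i<j} delta_ij."""
    n = c.sum()
    if n == 0:
        return 0.0
    return float(c @ D @ c) / 2.0 / n


def _identity_delta(k: int) -> np.ndarray:
    return 1.0 - np.eye(k)


def _delta_for(table: HaplotypeTable, dist: HaplotypeDistanceMatrix | None) -> np.ndarray:
    haps = table.haplotypes
    if dist is None:
        return _identity_delta(len(haps))
    return dist.submatrix(haps)


def _two_level(counts: np.ndarray, D: np.ndarray) -> tuple[float, float, float]:
    """Variance components (sigma_a, sigma_w) and F_ST for P populations.

    counts: (P, H) array of haplotype counts per population.
    """
    P = counts.shape[0]
    n = counts.sum(axis=1).astype(float)
    N = n.sum()
    total = counts.sum(axis=0)
    ssd_t = _ssd(total, D)
    ssd_w = sum(_ssd(counts[p], D) for p in range(P))
    ssd_a = ssd_t - ssd_w
    msd_a = ssd_a / (P - 1)
    msd_w = ssd_w / (N - P)
    n_c = (N - float(n @ n) / N) / (P - 1)
    sigma_w = msd_w
    sigma_a = (msd_a - msd_w) / n_c
    denom = sigma_a + sigma_w
    fst = sigma_a / denom if denom != 0 else 0.0
    return sigma_a, sigma_w, fst


def _counts_pair(table: HaplotypeTable, popA: str, popB: str) -> np.ndarray:
    for p in (popA, popB):
        if p not in table.populations:
            raise KeyError(f"unknown population {p!r}")
    c = np.vstack([table.counts[popA].values, table.counts[popB].values]).astype(float)
    if (c.sum(axis=1) < 2).any():
        raise ValueError("both populations need n >= 2")
    return c


def pairwise_fst(table: HaplotypeTable, popA: str, popB: str) -> float:
    """Haplotype-frequency F_ST between two populations (two-level AMOVA,
    delta_ij = 1 for distinct haplotypes). May be negative."""
    c = _counts_pair(table, popA, popB)
    D = _identity_delta(c.shape[1])
    return _two_level(c, D)[2]


def pairwise_phist(
    table: HaplotypeTable, dist: HaplotypeDistanceMatrix, popA: str, popB: str
) -> float:
    """Distance-weighted phi_ST between two populations."""
    c = _counts_pair(table, popA, popB)
    D = dist.submatrix(table.haplotypes)
    return _two_level(c, D)[2]


def pairwise_matrix(
    table: HaplotypeTable,
    dist: HaplotypeDistanceMatrix | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise F_ST (or phi_ST when ``dist`` given); structure values
    below the diagonal and, when ``n_perm`` > 0, permutation p-values above."""
    pops = table.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i <= j:
                continue
            if dist is None:
                out.loc[a, b] = pairwise_fst(table, a, b)
                stat = lambda t, a=a, b=b: pairwise_fst(t, a, b)
            else:
                out.loc[a, b] = pairwise_phist(table, dist, a, b)
                stat = lambda t, a=a, b=b: pairwise_phist(t, dist, a, b)
            if n_perm > 0:
                sub = _subtable(table, [a, b])
                out.loc[b, a] = permutation_p(
                    lambda t: stat(t), sub, scheme="individuals",
                    n_perm=n_perm, seed=seed + 7919 * i + j,
                )
    return out


def _subtable(table: HaplotypeTable, pops: list[str]) -> HaplotypeTable:
    return HaplotypeTable(
        counts=table.counts[pops].copy(), sequences=dict(table.sequences)
    )


@dataclass
class AmovaResult:
    levels: pd.DataFrame  # df, SSD, variance component, percent of variation
    F_CT: float
    F_SC: float | None
    F_ST: float
    p_values: dict[str, float] = field(default_factory=dict)


def amova(
    table: HaplotypeTable,
    grouping: dict[str, str],
    dist: HaplotypeDistanceMatrix | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA: among groups / among populations within groups /
    within populations.

    ``grouping`` maps each population to a group name. With every group a
    single population the middle level is empty and F_CT reduces exactly to
    the pairwise/overall F_ST of the populations. When ``n_perm`` > 0,
    p-values are attached: F_CT by permuting whole populations among
    groups, F_SC by permuting individuals among populations within groups,
    F_ST by permuting individuals among all populations.
    """
    pops = table.populations
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"populations without a group: {missing}")
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two groups")
    members = {g: [p for p in pops if grouping[p] == g] for g in groups}
    if any(len(m) == 0 for m in members.values()):
        raise ValueError("every group needs at least one population")

    D = _delta_for(table, dist)
    counts = table.counts.values.T.astype(float)  # (P, H)
    res = _amova_components(counts, members, pops, D)

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = (res["F_CT"], res["F_SC"], res["F_ST"])
        hits = [0, 0, 0]
        pooled, sizes = _expand(counts)
        for _ in range(n_perm):
            # F_CT: permute populations among groups
            perm_groups = _permute_grouping(members, rng)
            r1 = _amova_components(counts, perm_groups, pops, D)
            if r1["F_CT"] >= obs[0]:
                hits[0] += 1
            # F_SC: individuals among populations within groups
            c2 = _permute_within_groups(counts, members, pops, rng)
            r2 = _amova_components(c2, members, pops, D)
            if r2["F_SC"] is not None and obs[1] is not None and r2["F_SC"] >= obs[1]:
                hits[1] += 1
            # F_ST: individuals among all populations
            c3 = _recount(rng.permutation(pooled), sizes, counts.shape[1])
            r3 = _amova_components(c3, members, pops, D)
            if r3["F_ST"] >= obs[2]:
                hits[2] += 1
        p_values = {
            "F_CT": (hits[0] + 1) / (n_perm + 1),
            "F_SC": (hits[1] + 1) / (n_perm + 1),
            "F_ST": (hits[2] + 1) / (n_perm + 1),
        }

    return AmovaResult(
        levels=res["levels"], F_CT=res["F_CT"], F_SC=res["F_SC"],
        F_ST=res["F_ST"], p_values=p_values,
    )


def _amova_components(counts, members, pops, D):
    G = len(members)
    P = counts.shape[0]
    n = counts.sum(axis=1).astype(float)
    N = n.sum()
    group_counts = {
        g: counts[[pops.index(p) for p in ps]].sum(axis=0) for g, ps in members.items()
    }
    n_g = {g: c.sum() for g, c in group_counts.items()}

    ssd_t = _ssd(counts.sum(axis=0), D)
    ssd_groups = sum(_ssd(c, D) for c in group_counts.values())
    ssd_wp = sum(_ssd(counts[p], D) for p in range(P))
    SSD_ag = ssd_t - ssd_groups
    SSD_ap = ssd_groups - ssd_wp
    SSD_wp = ssd_wp

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P

    msd_wp = SSD_wp / df_wp
    sigma_c = msd_wp

    sum_np2_over_ng = sum(
        sum(n[pops.index(p)] ** 2 for p in ps) / n_g[g] for g, ps in members.items()
    )
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        msd_ap = SSD_ap / df_ap
        sigma_b = (msd_ap - sigma_c) / n1
        F_SC: float | None = sigma_b / (sigma_b + sigma_c)
    else:
        sigma_b = 0.0
        F_SC = None

    n2 = (sum_np2_over_ng - float(n @ n) / N) / df_ag
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_ag
    msd_ag = SSD_ag / df_ag
    sigma_a = (msd_ag - sigma_c - n2 * sigma_b) / n3

    total = sigma_a + sigma_b + sigma_c
    levels = pd.DataFrame(
        {
            "df": [df_ag, df_ap, df_wp, N - 1],
            "SSD": [SSD_ag, SSD_ap, SSD_wp, SSD_ag + SSD_ap + SSD_wp],
            "variance": [sigma_a, sigma_b, sigma_c, total],
            "percent": [100 * v / total for v in (sigma_a, sigma_b, sigma_c)] + [100.0],
        },
        index=["among_groups", "among_populations_within_groups",
               "within_populations", "total"],
    )
    return {
        "levels": levels,
        "F_CT": sigma_a / total,
        "F_SC": F_SC,
        "F_ST": (sigma_a + sigma_b) / total,
    }


def _expand(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sizes = counts.sum(axis=1).astype(int)
    pooled = np.concatenate(
        [np.repeat(np.arange(counts.shape[1]), counts[p].astype(int)) for p in range(counts.shape[0])]
    )
    return pooled, sizes


def _recount(pooled: np.ndarray, sizes: np.ndarray, H: int) -> np.ndarray:
    out = np.zeros((len(sizes), H))
    start = 0
    for p, s in enumerate(sizes):
        out[p] = np.bincount(pooled[start : start + s], minlength=H)
        start += s
    return out


def _permute_grouping(members, rng) -> dict[str, list[str]]:
    all_pops = [p for ps in members.values() for p in ps]
    perm = rng.permutation(len(all_pops))
    out = {}
    start = 0
    for g, ps in members.items():
        out[g] = [all_pops[perm[start + i]] for i in range(len(ps))]
        start += len(ps)
    return out


def _permute_within_groups(counts, members, pops, rng) -> np.ndarray:
    out = counts.copy()
    for ps in members.values():
        idx = [pops.index(p) for p in ps]
        sub = counts[idx]
        pooled, sizes = _expand(sub)
        out[idx] = _recount(rng.permutation(pooled), sizes, counts.shape[1])
    return out


def permutation_p(
    statistic_fn,
    table: HaplotypeTable,
    scheme: str = "individuals",
    n_perm: int = 1000,
    seed: int = 0,
    grouping: dict[str, str] | None = None,
) -> float:
    """Permutation p-value p = (#{permuted >= observed} + 1) / (n_perm + 1).

    scheme "individuals": individuals are shuffled among populations
    (sample sizes fixed); ``statistic_fn(table) -> float``.
    scheme "populations": whole populations are shuffled among groups;
    ``statistic_fn(table, grouping) -> float`` and ``grouping`` is required.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if scheme == "individuals":
        obs = statistic_fn(table)
        counts = table.counts.values.T.astype(float)
        pooled, sizes = _expand(counts)
        hits = 0
        for _ in range(n_perm):
            c = _recount(rng.permutation(pooled), sizes, counts.shape[1])
            perm_table = HaplotypeTable(
                counts=pd.DataFrame(
                    c.T, index=table.counts.index, columns=table.counts.columns
                )
            )
            if statistic_fn(perm_table) >= obs:
                hits += 1
    elif scheme == "populations":
        if grouping is None:
            raise ValueError("scheme 'populations' needs a grouping")
        obs = statistic_fn(table, grouping)
        pops = list(grouping)
        labels = [grouping[p] for p in pops]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            g = {pops[i]: labels[perm[i]] for i in range(len(pops))}
            if statistic_fn(table, g) >= obs:
                hits += 1
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Hudson's Snn

@dataclass
class SnnResult:
    snn: float
    p: float
    n_perm: int
    note: str | None = None


def snn_test(
    labels: list[str],
    dist: np.ndarray | None = None,
    sequences: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> SnnResult:
    """Hudson's (2000) nearest-neighbour statistic with permutation p-value.

    Snn is the mean, over sequences, of the fraction of each sequence's
    nearest neighbours (ties at the minimal distance share weight equally;
    self excluded) that belong to its own population. Input is either a
    full pairwise distance matrix or raw sequences (Hamming distances).
    Snn is invariant under any global rescaling of the distances.
    """
    if dist is None:
        if sequences is None:
            raise ValueError("provide either dist or sequences")
        k = len(sequences)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = sum(a != b for a, b in zip(sequences[i], sequences[j]))
                dist[i, j] = dist[j, i] = d
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("labels and distance matrix disagree in size")
    if len(set(labels)) < 2:
        raise ValueError("Snn needs at least two populations")

    if np.all(dist == 0):
        return SnnResult(
            snn=float("nan"), p=1.0, n_perm=n_perm,
            note="all sequences identical; Snn undefined",
        )

    # Nearest-neighbour sets are label-independent: precompute them once.
    nearest: list[np.ndarray] = []
    for i in range(n):
        d = dist[i].copy()
        d[i] = np.inf
        m = d.min()
        nearest.append(np.flatnonzero(d == m))

    lab = np.asarray(labels)

    def snn_of(lab_arr: np.ndarray) -> float:
        total = 0.0
        for i in range(n):
            nb = nearest[i]
            total += np.mean(lab_arr[nb] == lab_arr[i])
        return total / n

    obs = snn_of(lab)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if snn_of(rng.permutation(lab)) >= obs:
            hits += 1
    return SnnResult(snn=obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Nei's net divergence

@dataclass
class DivergenceResult:
    dA: float
    dXY: float  # per-site mean between-population difference
    dX: float   # per-site within-X diversity
    dY: float
    sd: float | None = None


def net_divergence(
    countsX,
    countsY,
    dist: HaplotypeDistanceMatrix | np.ndarray,
    L: int,
    n_boot: int = 0,
    seed: int = 0,
) -> DivergenceResult:
    """Nei's net nucleotide divergence d_A = d_XY - (d_X + d_Y)/2.

    ``countsX``/``countsY`` are haplotype count vectors over the same
    haplotype set as ``dist``; all components are per-site (divided by L).
    Within-population diversities are frequency-weighted (averages over
    all n^2 ordered pairs), matching the between-population term, so that
    identical populations give d_A = 0 exactly. ``n_boot`` > 0 adds a
    bootstrap (over individuals) standard deviation.
    """
    x = np.asarray(list(countsX), dtype=float)
    y = np.asarray(list(countsY), dtype=float)
    D = dist.d if isinstance(dist, HaplotypeDistanceMatrix) else np.asarray(dist, float)

    def _da(x, y):
        nx, ny = x.sum(), y.sum()
        pi_xy = float(x @ D @ y) / (nx * ny)
        pi_x = float(x @ D @ x) / (nx * nx)
        pi_y = float(y @ D @ y) / (ny * ny)
        return pi_xy / L, pi_x / L, pi_y / L

    dxy, dx, dy = _da(x, y)
    dA = dxy - (dx + dy) / 2.0
    sd = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            xb = rng.multinomial(int(x.sum()), x / x.sum())
            yb = rng.multinomial(int(y.sum()), y / y.sum())
            dxyb, dxb, dyb = _da(xb.astype(float), yb.astype(float))
            vals[b] = dxyb - (dxb + dyb) / 2.0
        sd = float(vals.std(ddof=1))
    return DivergenceResult(dA=dA, dXY=dxy, dX=dx, dY=dy, sd=sd)


# ---------------------------------------------------------------------------
# Correspondence analysis

@dataclass
class CAResult:
    row_coords: pd.DataFrame  # principal coordinates, axes ordered by inertia
    col_coords: pd.DataFrame
    inertia: np.ndarray


def correspondence_analysis(presence: pd.DataFrame) -> CAResult:
    """Correspondence analysis via SVD of the standardized residuals.

    Rows are localities, columns haplotypes (typically a presence/absence
    matrix). Principal normalization: both row and column coordinates are
    scaled by the singular values. Axes are ordered by decreasing inertia;
    signs are arbitrary.
    """
    X = presence.values.astype(float)
    zero_rows = presence.index[X.sum(axis=1) == 0].tolist()
    zero_cols = presence.columns[X.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        raise ValueError(
            f"all-zero rows {zero_rows} / columns {zero_cols} not allowed in CA"
        )
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = int(np.sum(sv > 1e-12))
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(F, index=presence.index, columns=axes),
        col_coords=pd.DataFrame(G, index=presence.columns, columns=axes),
        inertia=sv**2,
    )
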