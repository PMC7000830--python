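"""Single-locus haploid coalescent simulator for two biogeographic scenarios.

The demographic question: did the northern population of an antitropical
species originate through a trans-equatorial founder event (colonization
through a small propagule, then isolation and instantaneous growth), or
through vicariance (a range split without any bottleneck)? Both scenarios
share the same backbone, viewed backward in time from the present:

* two demes, South (size Ne, constant) and North (size Ne_n);
* at generation t1 the North changes size: under scenario 1 (founder) it
  shrinks to the founder size Nf for the interval (t1, t2]; under
  scenario 2 (vicariance) it keeps size Ne_n;
* at generation t2 the North merges into the South (the colonization /
  split event); the merged ancestral population has size Ne.

mtDNA is maternally inherited and effectively haploid, so prior sizes are
used directly as haploid effective sizes (no ploidy factor). Mutations
follow the infinite-sites model at rate u per site per generation over L
sites; each mutation creates a new segregating site.

Times are in generations throughout. The priors are uniform on Ne, Nf,
t1 and t2 (with t2 > t1 enforced by rejection) and log-uniform on u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ScenarioPriors",
    "SimulatedSample",
    "sample_priors",
    "simulate_coalescent",
    "summarize_sample",
    "SUMMARY_STAT_NAMES",
]


@dataclass(frozen=True)
class ScenarioPriors:
    """Prior ranges for the demographic parameters (generations, haploid N).

    ne: ancestral / modern effective size, uniform.
    nf: founder propagule size, uniform (scenario 1 only).
    t2: time of the colonization / split event, uniform.
    t1: time of instantaneous growth in the North, uniform, with t2 > t1.
    u:  per-site per-generation mutation rate, log-uniform.
    L:  sequence length in sites.
    """

    ne: tuple[float, float] = (1_000.0, 100_000.0)
    nf: tuple[float, float] = (10.0, 1_000.0)
    t2: tuple[float, float] = (10_000.0, 35_000.0)
    t1: tuple[float, float] = (2_000.0, 15_000.0)
    u: tuple[float, float] = (1.5e-8, 1.5e-7)
    L: int = 345

    @classmethod
    def from_yaml(cls, path) -> "ScenarioPriors":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("ne", "nf", "t2", "t1", "u"):
            if key in cfg:
                lo, hi = cfg[key]
                kwargs[key] = (float(lo), float(hi))
        if "L" in cfg:
            kwargs["L"] = int(cfg["L"])
        return cls(**kwargs)


def sample_priors(
    scenario: int,
    rng: np.random.Generator | int,
    priors: ScenarioPriors = ScenarioPriors(),
) -> dict[str, float]:
    """One joint draw from the priors for the given scenario (1 or 2).

    The North's post-growth size ne_north is an independent draw from the
    ne prior. (t1, t2) pairs violating t2 > t1 are rejected and redrawn.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 (founder) or 2 (vicariance)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    while True:
        t1 = rng.uniform(*priors.t1)
        t2 = rng.uniform(*priors.t2)
        if t2 > t1:
            break
    params = {
        "ne": rng.uniform(*priors.ne),
        "ne_north": rng.uniform(*priors.ne),
        "t1": t1,
        "t2": t2,
        "u": math.exp(rng.uniform(math.log(priors.u[0]), math.log(priors.u[1]))),
    }
    if scenario == 1:
        params["nf"] = rng.uniform(*priors.nf)
    return params


@dataclass
class SimulatedSample:
    """A simulated mtDNA sample: leaves with deme labels and mutation content.

    ``sites`` has one row per segregating site with the derived-allele
    carrier counts in (South, North). ``leaf_haplotypes`` are hashable
    mutation signatures; leaves sharing a signature share a haplotype.
    """

    n_south: int
    n_north: int
    leaf_demes: np.ndarray
    leaf_haplotypes: list[tuple]
    sites: np.ndarray  # (n_sites, 2) carrier counts per deme
    L: int
    scenario: int
    params: dict[str, float] = field(default_factory=dict)


def _simulate_tree(params, scenario, n_s, n_n, rng):
    """Coalescent tree under the two-deme scenario; returns (parent, time).

    Node ids: leaves 0..n-1 (South first), internal nodes appended in
    coalescence order, so a parent always has a larger id than its children.
    """
    n = n_s + n_n
    parent = np.full(2 * n, -1, dtype=np.int64)
    time = np.zeros(2 * n)
    active = [list(range(n_s)), list(range(n_s, n))]
    next_id = n
    t = 0.0

    ne = params["ne"]
    ne_n = params["ne_north"]
    t1, t2 = params["t1"], params["t2"]
    nf = params.get("nf", ne_n)
    # epoch boundaries and North sizes; South is ne throughout
    north_size = [ne_n, nf if scenario == 1 else ne_n]
    boundaries = [t1, t2]
    epoch = 0
    merged = False

    expo = rng.exponential
    randint = rng.integers

    while True:
        k0, k1 = len(active[0]), len(active[1])
        if k0 + k1 <= 1:
            break
        if merged:
            sizes = (ne, 0.0)
        else:
            sizes = (ne, north_size[epoch])
        r0 = k0 * (k0 - 1) / (2.0 * sizes[0])
        r1 = k1 * (k1 - 1) / (2.0 * sizes[1]) if k1 > 1 else 0.0
        total = r0 + r1
        bound = math.inf if merged else boundaries[epoch]
        if total == 0.0:
            t = bound
        else:
            dt = expo(1.0 / total)
            if t + dt >= bound:
                t = bound
            else:
                t += dt
                deme = 0 if rng.random() * total < r0 else 1
                lin = active[deme]
                i = int(randint(len(lin)))
                j = int(randint(len(lin) - 1))
                if j >= i:
                    j += 1
                a, b = lin[i], lin[j]
                node = next_id
                next_id += 1
                time[node] = t
                parent[a] = node
                parent[b] = node
                for idx in sorted((i, j), reverse=True):
                    lin.pop(idx)
                lin.append(node)
                continue
        # hit a boundary
        if not merged:
            if epoch == 0:
                epoch = 1
            else:
                active[0].extend(active[1])
                active[1] = []
                merged = True
    n_nodes = next_id
    return parent[:n_nodes], time[:n_nodes]


def simulate_coalescent(
    params: dict[str, float],
    scenario: int,
    sample_sizes: tuple[int, int],
    rng: np.random.Generator | int,
    L: int = 345,
) -> SimulatedSample:
    """Simulate one mtDNA sample (genealogy + infinite-sites mutations).

    ``sample_sizes`` = (n_south, n_north); a deme with sample size 0 is
    simply omitted. A total sample of 1 has no branches and hence no
    segregating sites.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_s, n_n = sample_sizes
    if n_s < 0 or n_n < 0 or n_s + n_n == 0:
        raise ValueError("need a positive total sample size")
    n = n_s + n_n
    demes = np.array(["S"] * n_s + ["N"] * n_n)

    if n == 1:
        return SimulatedSample(
            n_south=n_s, n_north=n_n, leaf_demes=demes,
            leaf_haplotypes=[()], sites=np.zeros((0, 2), dtype=int),
            L=L, scenario=scenario, params=dict(params),
        )

    parent, time = _simulate_tree(params, scenario, n_s, n_n, rng)
    n_nodes = len(parent)
    root = n_nodes - 1

    edge_len = np.zeros(n_nodes)
    has_parent = parent >= 0
    edge_len[has_parent] = time[parent[has_parent]] - time[np.flatnonzero(has_parent)]
    total_len = edge_len.sum()

    u = params["u"]
    n_mut = rng.poisson(u * L * total_len)
    mut_count = np.zeros(n_nodes, dtype=np.int64)
    if n_mut > 0:
        edges = np.flatnonzero(edge_len > 0)
        probs = edge_len[edges] / edge_len[edges].sum()
        hit = rng.choice(edges, size=n_mut, p=probs)
        np.add.at(mut_count, hit, 1)

    # leaf counts per deme below every node (children have smaller ids)
    below = np.zeros((n_nodes, 2), dtype=np.int64)
    below[:n_s, 0] = 1
    below[n_s:n, 1] = 1
    for v in range(n_nodes - 1):
        below[parent[v]] += below[v]

    sites = []
    for v in np.flatnonzero(mut_count):
        if v == root:
            continue
        for _ in range(mut_count[v]):
            sites.append(below[v])
    sites_arr = (
        np.array(sites, dtype=int) if sites else np.zeros((0, 2), dtype=int)
    )

    # haplotype signature: mutated edges on the path to the root
    sig: list[tuple] = [()] * n_nodes
    for v in range(n_nodes - 2, -1, -1):
        p = parent[v]
        sig[v] = sig[p] + ((v,) if mut_count[v] > 0 and v != root else ())

    return SimulatedSample(
        n_south=n_s, n_north=n_n, leaf_demes=demes,
        leaf_haplotypes=[sig[i] for i in range(n)], sites=sites_arr,
        L=L, scenario=scenario, params=dict(params),
    )


SUMMARY_STAT_NAMES = [
    "h_S", "S_S", "Hd_S", "Pi_S",
    "h_N", "S_N", "Hd_N", "Pi_N",
    "Fst", "Pi_between", "shared_haps", "private_S", "private_N",
]


def summarize_sample(sample: SimulatedSample) -> np.ndarray:
    """Fixed-order summary-statistic vector (see SUMMARY_STAT_NAMES).

    Per deme: haplotype count h, segregating sites S, haplotype diversity
    Hd, mean pairwise differences Pi. Cross-deme: identity F_ST, mean
    between-deme pairwise differences, and shared/private haplotype counts.
    A deme with n < 2 contributes zeros for its within-deme statistics.
    """
    out = np.zeros(len(SUMMARY_STAT_NAMES))
    ns = (sample.n_south, sample.n_north)
    sites = sample.sites
    hap_sets: list[dict[tuple, int]] = []
    offset = [0, sample.n_south]
    for d in (0, 1):
        n_d = ns[d]
        haps: dict[tuple, int] = {}
        for i in range(offset[d], offset[d] + n_d):
            key = sample.leaf_haplotypes[i]
            haps[key] = haps.get(key, 0) + 1
        hap_sets.append(haps)
        base = 4 * d
        out[base + 0] = len(haps)
        if n_d >= 2:
            c = sites[:, d]
            seg = (c > 0) & (c < n_d)
            out[base + 1] = int(seg.sum())
            p2 = sum((v / n_d) ** 2 for v in haps.values())
            out[base + 2] = n_d / (n_d - 1) * (1.0 - p2)
            out[base + 3] = float((c * (n_d - c)).sum()) / (n_d * (n_d - 1) / 2)

    n_s, n_n = ns
    if n_s > 0 and n_n > 0:
        cs, cn = sites[:, 0], sites[:, 1]
        out[9] = float((cs * (n_n - cn) + cn * (n_s - cs)).sum()) / (n_s * n_n)
        a, b = hap_sets
        out[10] = len(set(a) & set(b))
        out[11] = len(set(a) - set(b))
        out[12] = len(set(b) - set(a))
        if n_s >= 2 and n_n >= 2:
            out[8] = _identity_fst(a, b)
    return out


def _identity_fst(haps_a: dict, haps_b: dict) -> float:
    """Two-level identity-delta AMOVA F_ST from two haplotype count dicts."""
    keys = sorted(set(haps_a) | set(haps_b), key=repr)
    ca = np.array([haps_a.get(k, 0) for k in keys], dtype=float)
    cb = np.array([haps_b.get(k, 0) for k in keys], dtype=float)
    na, nb = ca.sum(), cb.sum()
    N = na + nb

    def diff_pairs(c):
        t = c.sum()
        return (t * t - float(c @ c)) / 2.0

    ssd_w = diff_pairs(ca) / na + diff_pairs(cb) / nb
    ssd_t = diff_pairs(ca + cb) / N
    msd_a = ssd_t - ssd_w  # df = 1
    msd_w = ssd_w / (N - 2)
    n_c = (N - (na * na + nb * nb) / N)
    sigma_a = (msd_a - msd_w) / n_c
    denom = sigma_a + msd_w
    return float(sigma_a / denom) if denom != 0 else 0.0
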