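"""Structure statistics: AMOVA fixation indices, Snn, d_A, CA."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.stats

import haplogeo as hg

from conftest import expand_individuals, table_from_counts


def bruteforce_two_level(counts, D):
    """Independent two-level AMOVA from the expanded individual list."""
    pops = [expand_individuals(c) for c in counts]
    all_idx = np.concatenate(pops)
    n = np.array([len(p) for p in pops], dtype=float)
    N = len(all_idx)

    def ssd(idx):
        total = 0.0
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                total += D[idx[i], idx[j]]
        return total / len(idx)

    ssd_t = ssd(all_idx)
    ssd_w = sum(ssd(p) for p in pops)
    P = len(pops)
    msd_a = (ssd_t - ssd_w) / (P - 1)
    msd_w = ssd_w / (N - P)
    nc = (N - (n @ n) / N) / (P - 1)
    va = (msd_a - msd_w) / nc
    return va / (va + msd_w)


class TestPairwiseFst:
    def test_identical_frequencies_not_positive(self):
        table = table_from_counts({"A": [10, 5, 5], "B": [10, 5, 5]})
        assert hg.pairwise_fst(table, "A", "B") <= 1e-12

    def test_fixed_for_different_haplotypes_is_one(self):
        table = table_from_counts({"A": [8, 0], "B": [0, 8]})
        assert hg.pairwise_fst(table, "A", "B") == pytest.approx(1.0)

    def test_unknown_population_rejected(self, study_table):
        with pytest.raises(KeyError):
            hg.pairwise_fst(study_table, "CL", "ATLANTIS")

    def test_can_be_negative(self):
        table = table_from_counts({"A": [9, 1], "B": [8, 2]})
        assert hg.pairwise_fst(table, "A", "B") < 0


class TestPairwisePhist:
    def test_uniform_distances_reduce_to_fst(self, study_table, study_distances):
        ids = study_table.haplotypes
        uniform = hg.HaplotypeDistanceMatrix(
            ids=ids, d=3.0 * (1 - np.eye(len(ids)))
        )
        for a, b in [("CL", "NZ"), ("GIB", "MED"), ("FI", "UK")]:
            assert hg.pairwise_phist(study_table, uniform, a, b) == pytest.approx(
                hg.pairwise_fst(study_table, a, b), abs=1e-12
            )

    def test_two_haplotype_system_scaling_cancels(self, study_table, study_distances):
        # GIB vs MED segregate only S+R and D: phi_ST == F_ST
        assert hg.pairwise_phist(
            study_table, study_distances, "GIB", "MED"
        ) == pytest.approx(hg.pairwise_fst(study_table, "GIB", "MED"), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        counts = {"A": rng.integers(1, 8, 3), "B": rng.integers(1, 8, 3)}
        counts["A"][0] += 2
        counts["B"][1] += 2
        D = rng.integers(1, 7, (3, 3)).astype(float)
        D = np.triu(D, 1)
        D = D + D.T
        table = table_from_counts({k: list(v) for k, v in counts.items()})
        dist = hg.HaplotypeDistanceMatrix(ids=table.haplotypes, d=D)
        got = hg.pairwise_phist(table, dist, "A", "B")
        want = bruteforce_two_level([counts["A"], counts["B"]], D)
        assert got == pytest.approx(want)


class TestAmova:
    def test_degrees_of_freedom_for_subspecies_grouping(self, study_table):
        from haplogeo.datasets import SUBSPECIES

        grouping = {
            p: g for g, ps in SUBSPECIES.items() for p in ps
        }
        res = hg.amova(study_table, grouping)
        assert list(res.levels["df"][:3]) == [1, 8, 1002]

    def test_identical_compositions_give_null_components(self):
        # among-level SSDs vanish; the unbiased components are then 0 for
        # the group level and a small negative bias term (-sigma_c / n')
        # for the population level
        table = table_from_counts({p: [6, 3, 1] for p in "ABCD"})
        res = hg.amova(table, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        lv = res.levels
        assert lv.loc["among_groups", "SSD"] == pytest.approx(0, abs=1e-9)
        assert lv.loc["among_populations_within_groups", "SSD"] == pytest.approx(0, abs=1e-9)
        within = lv.loc["within_populations", "variance"]
        assert abs(lv.loc["among_groups", "variance"]) <= within / 10
        assert abs(lv.loc["among_populations_within_groups", "variance"]) <= within / 10

    def test_two_singleton_groups_collapse_to_pairwise_fst(self, study_table):
        res = hg.amova(
            hg.structure._subtable(study_table, ["GIB", "MED"]),
            {"GIB": "g1", "MED": "g2"},
        )
        assert res.F_CT == pytest.approx(hg.pairwise_fst(study_table, "GIB", "MED"))
        assert res.F_SC is None

    def test_needs_two_groups(self, study_table):
        with pytest.raises(ValueError):
            hg.amova(study_table, {p: "only" for p in study_table.populations})

    def test_ssd_reconstruction_from_components(self, study_table, study_distances):
        from haplogeo.datasets import SUBSPECIES
        from haplogeo.structure import _delta_for

        grouping = {p: g for g, ps in SUBSPECIES.items() for p in ps}
        res = hg.amova(study_table, grouping, dist=study_distances)
        lv = res.levels
        sa, sb, sc = lv["variance"][:3]
        counts = study_table.counts
        n = counts.sum(axis=0).astype(float)
        N = n.sum()
        members = {g: ps for g, ps in SUBSPECIES.items()}
        n_g = {g: n[ps].sum() for g, ps in members.items()}
        sum_np2_over_ng = sum((n[ps] ** 2).sum() / n_g[g] for g, ps in members.items())
        P, G = len(n), 2
        n1 = (N - sum_np2_over_ng) / (P - G)
        n2 = (sum_np2_over_ng - (n**2).sum() / N) / (G - 1)
        n3 = (N - sum(v**2 for v in n_g.values()) / N) / (G - 1)
        # expected mean squares: E[MSD] coefficients of the nested design
        msd_wp = sc
        msd_ap = sc + n1 * sb
        msd_ag = sc + n2 * sb + n3 * sa
        assert lv.loc["within_populations", "SSD"] == pytest.approx(
            (N - P) * msd_wp, abs=1e-9
        )
        assert lv.loc["among_populations_within_groups", "SSD"] == pytest.approx(
            (P - G) * msd_ap, abs=1e-9
        )
        assert lv.loc["among_groups", "SSD"] == pytest.approx(
            (G - 1) * msd_ag, abs=1e-9
        )


class TestPermutationP:
    def test_constant_statistic_gives_p_one(self, study_table):
        p = hg.permutation_p(
            lambda t: 1.0, study_table, scheme="individuals", n_perm=50, seed=0
        )
        assert p == 1.0

    def test_gib_med_fst_is_significant(self, study_table):
        sub = hg.structure._subtable(study_table, ["GIB", "MED"])
        p = hg.permutation_p(
            lambda t: hg.pairwise_fst(t, "GIB", "MED"),
            sub,
            scheme="individuals",
            n_perm=1000,
            seed=42,
        )
        assert p <= 0.01

    def test_null_p_values_uniform(self):
        # panmictic replicates: p should be ~ U(0,1)
        rng = np.random.default_rng(7)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        ps = []
        for s in range(200):
            a = rng.multinomial(50, freqs)
            b = rng.multinomial(50, freqs)
            table = table_from_counts({"A": list(a), "B": list(b)})
            ps.append(
                hg.permutation_p(
                    lambda t: hg.pairwise_fst(t, "A", "B"),
                    table,
                    scheme="individuals",
                    n_perm=199,
                    seed=s,
                )
            )
        res = scipy.stats.kstest(ps, "uniform")
        assert res.pvalue > 0.001

    def test_reproducible_given_seed(self, study_table):
        sub = hg.structure._subtable(study_table, ["FI", "GIB"])
        args = dict(scheme="individuals", n_perm=200, seed=5)
        f = lambda t: hg.pairwise_fst(t, "FI", "GIB")
        assert hg.permutation_p(f, sub, **args) == hg.permutation_p(f, sub, **args)


def bruteforce_snn(labels, D):
    """Naive nearest-neighbour fractions, ties split evenly."""
    n = len(labels)
    vals = []
    for i in range(n):
        dists = sorted((D[i, j], j) for j in range(n) if j != i)
        m = dists[0][0]
        ties = [j for d, j in dists if d == m]
        vals.append(sum(labels[j] == labels[i] for j in ties) / len(ties))
    return float(np.mean(vals))


class TestSnn:
    def test_fully_distinct_populations_give_one(self):
        seqs = ["AAAA"] * 5 + ["TTTT"] * 5
        labels = ["X"] * 5 + ["Y"] * 5
        res = hg.snn_test(labels, sequences=seqs, n_perm=200, seed=0)
        assert res.snn == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_random_labels_on_panmictic_cluster_average_half(self):
        rng = np.random.default_rng(3)
        D = rng.integers(1, 5, (10, 10)).astype(float)
        D = np.triu(D, 1)
        D = D + D.T
        vals = []
        for _ in range(300):
            labels = list(rng.permutation(["X"] * 5 + ["Y"] * 5))
            vals.append(bruteforce_snn(labels, D))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_micro_examples(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        D = rng.integers(0, 4, (n, n)).astype(float)
        D = np.triu(D, 1)
        D = D + D.T
        labels = ["X", "X", "X", "Y", "Y", "Y"]
        res = hg.snn_test(labels, dist=D, n_perm=10, seed=0)
        assert res.snn == pytest.approx(bruteforce_snn(labels, D))

    def test_invariant_under_distance_rescaling(self):
        rng = np.random.default_rng(1)
        D = rng.integers(1, 6, (8, 8)).astype(float)
        D = np.triu(D, 1)
        D = D + D.T
        labels = ["X"] * 4 + ["Y"] * 4
        a = hg.snn_test(labels, dist=D, n_perm=99, seed=2)
        b = hg.snn_test(labels, dist=17.0 * D, n_perm=99, seed=2)
        assert a.snn == pytest.approx(b.snn)
        assert a.p == b.p

    def test_all_identical_sequences_degenerate(self):
        res = hg.snn_test(["X", "X", "Y", "Y"], sequences=["AAAA"] * 4, n_perm=10)
        assert np.isnan(res.snn)
        assert res.p == 1.0
        assert res.note is not None


class TestNetDivergence:
    def test_fixed_populations_arithmetic(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = hg.net_divergence([5, 0], [0, 5], d, L=345)
        assert res.dA == pytest.approx(2 / 345)
        assert res.dX == 0 and res.dY == 0

    def test_equal_populations_give_zero(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = hg.net_divergence([4, 6], [4, 6], d, L=100)
        assert res.dA == pytest.approx(0.0, abs=1e-12)

    def test_identity_holds_with_components(self, study_table, study_distances):
        x = study_table.pooled(["TAS", "NZ", "CL"]).values
        y = study_table.pooled(["NWA", "FI", "UK", "IB", "NEA", "GIB", "MED"]).values
        res = hg.net_divergence(x, y, study_distances, L=345)
        assert res.dA == pytest.approx(res.dXY - (res.dX + res.dY) / 2)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_average(self, seed):
        rng = np.random.default_rng(seed)
        k = 3
        D = rng.integers(0, 6, (k, k)).astype(float)
        D = np.triu(D, 1)
        D = D + D.T
        x = rng.integers(1, 6, k)
        y = rng.integers(1, 6, k)
        x[0] += 1
        y[1] += 1
        res = hg.net_divergence(x, y, D, L=50)
        ix, iy = expand_individuals(x), expand_individuals(y)
        dxy = np.mean([D[i, j] for i in ix for j in iy]) / 50
        dx = np.mean([D[i, j] for i in ix for j in ix]) / 50
        dy = np.mean([D[i, j] for i in iy for j in iy]) / 50
        assert res.dA == pytest.approx(dxy - (dx + dy) / 2)


class TestCorrespondenceAnalysis:
    def test_identical_rows_identical_coordinates(self):
        m = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 1]],
            index=["r1", "r2", "r3"],
            columns=["c1", "c2", "c3"],
        )
        ca = hg.correspondence_analysis(m)
        assert np.allclose(ca.row_coords.loc["r1"], ca.row_coords.loc["r2"])

    def test_matches_eigendecomposition_oracle(self):
        m = pd.DataFrame(
            [[3, 0, 1], [0, 2, 1], [1, 1, 4]].copy(),
            index=list("abc"),
            columns=list("xyz"),
        ).astype(float)
        ca = hg.correspondence_analysis(m)
        X = m.values
        P = X / X.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        lam, U = scipy.linalg.eigh(S @ S.T)
        order = np.argsort(lam)[::-1]
        lam, U = lam[order], U[:, order]
        F = U * np.sqrt(np.clip(lam, 0, None)) / np.sqrt(r)[:, None]
        for ax in range(2):
            got = ca.row_coords.values[:, ax]
            want = F[:, ax]
            assert np.allclose(got, want, atol=1e-9) or np.allclose(
                got, -want, atol=1e-9
            )

    def test_all_zero_row_named_in_error(self):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            hg.correspondence_analysis(m)

    def test_first_axis_contrasts_hemispheres(self, study_table):
        presence = (study_table.counts.T > 0).astype(int)
        ca = hg.correspondence_analysis(presence)
        axis1 = ca.row_coords["axis1"]
        south = axis1[["TAS", "NZ", "CL"]]
        north_core = axis1[["UK", "IB", "NEA", "GIB", "MED"]]
        assert (np.sign(south) == np.sign(south.iloc[0])).all()
        assert (np.sign(north_core) == -np.sign(south.iloc[0])).all()
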