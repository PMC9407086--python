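"""Rst (AMOVA), MDS and neighbor joining against independent oracles."""

import itertools

import numpy as np
import pytest

from ylineage.distance import (
    DistanceMatrix,
    mds,
    neighbor_joining,
    pairwise_rst,
    rst_matrix,
)
from ylineage.profiles import STRProfile

LOCI = ["L1", "L2", "L3"]


def profiles_from_matrix(matrix, population, loci=None, prefix="s"):
    loci = loci or LOCI
    return [
        STRProfile(
            sample_id=f"{population}_{prefix}{i}",
            population=population,
            calls={l: [float(v)] for l, v in zip(loci, row)},
        )
        for i, row in enumerate(matrix)
    ]


def brute_force_rst(pop_matrices):
    """AMOVA oracle assembled from explicit pairwise squared distances."""
    all_rows = np.vstack(pop_matrices)
    N = all_rows.shape[0]
    K = len(pop_matrices)

    def ss_from_pairs(rows):
        m = rows.shape[0]
        total = 0.0
        for i, j in itertools.combinations(range(m), 2):
            total += ((rows[i] - rows[j]) ** 2).sum()
        return total / m

    ss_total = ss_from_pairs(all_rows)
    ss_within = sum(ss_from_pairs(g) for g in pop_matrices)
    ms_among = (ss_total - ss_within) / (K - 1)
    ms_within = ss_within / (N - K)
    n_c = (N - sum(g.shape[0] ** 2 for g in pop_matrices) / N) / (K - 1)
    sigma_a = (ms_among - ms_within) / n_c
    if sigma_a + ms_within == 0:
        return 0.0
    return sigma_a / (sigma_a + ms_within)


class TestPairwiseRst:
    def test_identical_populations_give_no_positive_differentiation(self):
        """Duplicated haplotype multisets have zero among-group mean
        squares; the unbiased estimator then lands at its floor value
        −1/(n_c − 1), reported raw (never a positive signal)."""
        rows = [[10, 20, 15], [11, 20, 15], [10, 21, 16], [12, 19, 15]]
        a = profiles_from_matrix(rows, "A")
        b = profiles_from_matrix(rows, "B")
        rst = pairwise_rst(a, b, LOCI)
        n_c = 4.0  # equal group sizes of 4
        assert rst == pytest.approx(-1 / (n_c - 1), abs=1e-12)
        assert rst <= 0

    def test_fixed_monomorphic_difference_gives_one(self):
        a = profiles_from_matrix([[10]] * 4, "A", loci=["L1"])
        b = profiles_from_matrix([[14]] * 4, "B", loci=["L1"])
        assert pairwise_rst(a, b, ["L1"]) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        a = profiles_from_matrix(rng.integers(8, 20, (6, 3)), "A")
        b = profiles_from_matrix(rng.integers(8, 20, (6, 3)), "B")
        assert pairwise_rst(a, b, LOCI) == pytest.approx(
            pairwise_rst(b, a, LOCI), abs=1e-14
        )

    def test_matches_brute_force_amova_on_random_instances(self, rng):
        for _ in range(100):
            na, nb = rng.integers(3, 9, 2)
            ga = rng.integers(8, 16, (na, 3)).astype(float)
            gb = rng.integers(8, 16, (nb, 3)).astype(float)
            a = profiles_from_matrix(ga, "A")
            b = profiles_from_matrix(gb, "B")
            assert pairwise_rst(a, b, LOCI) == pytest.approx(
                brute_force_rst([ga, gb]), abs=1e-10
            )

    def test_cnv_and_null_samples_are_dropped(self):
        a = profiles_from_matrix([[10], [11], [12]], "A", loci=["L1"])
        a.append(STRProfile("A_cnv", "A", {"L1": [10.0, 11.0]}))
        a.append(STRProfile("A_null", "A", {"L1": []}))
        b = profiles_from_matrix([[13], [14], [15]], "B", loci=["L1"])
        expected = brute_force_rst(
            [np.array([[10.0], [11.0], [12.0]]), np.array([[13.0], [14.0], [15.0]])]
        )
        assert pairwise_rst(a, b, ["L1"]) == pytest.approx(expected, abs=1e-12)

    def test_too_few_usable_samples_is_error(self):
        a = profiles_from_matrix([[10]], "A", loci=["L1"])
        b = profiles_from_matrix([[11], [12]], "B", loci=["L1"])
        with pytest.raises(ValueError):
            pairwise_rst(a, b, ["L1"])


class TestRstMatrix:
    def test_three_copies_of_same_population_show_no_differentiation(self):
        rows = [[10, 20, 15], [11, 21, 15], [12, 20, 16]]
        pops = {name: profiles_from_matrix(rows, name) for name in "ABC"}
        dist = rst_matrix(pops, LOCI)
        off_diag = dist.values[~np.eye(3, dtype=bool)]
        # estimator floor for duplicated data; no spurious positive signal
        assert np.all(off_diag <= 1e-12)
        assert np.allclose(off_diag, off_diag[0], atol=1e-12)

    def test_label_order_follows_input_order(self, rng):
        pops = {
            name: profiles_from_matrix(rng.integers(8, 20, (5, 3)), name)
            for name in ("X", "Y", "Z")
        }
        d1 = rst_matrix(pops, LOCI)
        reordered = {k: pops[k] for k in ("Z", "X", "Y")}
        d2 = rst_matrix(reordered, LOCI)
        f1, f2 = d1.to_frame(), d2.to_frame()
        assert np.allclose(
            f1.loc[d1.labels, d1.labels].to_numpy(),
            f2.loc[d1.labels, d1.labels].to_numpy(),
            atol=1e-12,
        )


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))

    def test_round_trip_tsv(self, tmp_path):
        values = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        dm = DistanceMatrix(labels=["a", "b", "c"], values=values)
        path = tmp_path / "d.tsv"
        dm.write(path)
        back = DistanceMatrix.read(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)

    def test_reads_phylip_square(self, tmp_path):
        path = tmp_path / "d.phy"
        path.write_text("3\nA 0.0 0.1 0.2\nB 0.1 0.0 0.3\nC 0.2 0.3 0.0\n")
        dm = DistanceMatrix.read(path)
        assert dm.labels == ["A", "B", "C"]
        assert dm.values[0, 2] == pytest.approx(0.2)


class TestMds:
    def _planar_matrix(self):
        pts = np.array([[0, 0], [3, 0], [0, 4], [5, 5]], float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return pts, DistanceMatrix(labels=list("ABCD"), values=d)

    def test_classical_recovers_planar_configuration(self):
        from scipy.spatial import procrustes

        pts, dm = self._planar_matrix()
        result = mds(dm, nonmetric=False)
        _, _, disparity = procrustes(pts, result.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_stress_history_is_non_increasing(self, rng):
        n = 7
        raw = rng.random((n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        result = mds(DistanceMatrix(labels=[f"p{i}" for i in range(n)], values=d))
        assert all(
            later <= earlier + 1e-12
            for earlier, later in zip(result.stress_history, result.stress_history[1:])
        )
        assert result.stress >= 0

    def test_duplicated_population_stays_coincident(self):
        pts = np.array([[0, 0], [0, 0], [3, 0], [0, 4]], float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        result = mds(DistanceMatrix(labels=list("ABCD"), values=d))
        coords = result.coordinates.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mds(DistanceMatrix(labels=list("abc"), values=np.zeros((3, 3))))


def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (leaf labels, pairwise path-length matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start each leaf as its own cluster; join random pairs with random
    # positive branch lengths, accumulating leaf depths
    clusters = [{l: 0.0 for l in [lab]} for lab in labels]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        li, lj = rng.uniform(0.1, 2.0, 2)
        for a in clusters[i]:
            for b in clusters[j]:
                dist[frozenset((a, b))] = clusters[i][a] + li + clusters[j][b] + lj
        merged = {a: v + li for a, v in clusters[i].items()}
        merged.update({b: v + lj for b, v in clusters[j].items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    values = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        values[a, b] = values[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, values


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        values = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels=list("ABC"), values=values))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_recovers_random_additive_trees_exactly(self, rng, n_taxa):
        for _ in range(5):
            labels, values = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(DistanceMatrix(labels=labels, values=values))
            recovered = tree.tip_tip_distances()
            ids = list(map(str, recovered.ids))
            for a, b in itertools.combinations(range(n_taxa), 2):
                got = recovered[ids.index(labels[a]), ids.index(labels[b])]
                assert got == pytest.approx(values[a, b], abs=1e-10)

    def test_deterministic_under_q_matrix_ties(self):
        # four equidistant taxa: every Q entry ties
        values = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=list("ABCD"), values=values)
        assert str(neighbor_joining(dm)) == str(neighbor_joining(dm))

    def test_small_perturbation_keeps_topology(self, rng):
        labels, values = random_additive_tree(rng, 6)
        tree1 = neighbor_joining(DistanceMatrix(labels=labels, values=values))
        noise = rng.uniform(-1e-6, 1e-6, values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        tree2 = neighbor_joining(
            DistanceMatrix(labels=labels, values=values + noise)
        )
        assert tree1.compare_rfd(tree2) == 0

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2)))
            )


class TestDivergenceRecovery:
    def test_outgroup_is_farther_than_sister_pair(self):
        """A pair split recently plus a long-isolated outgroup: the
        outgroup's Rst to each daughter exceeds the daughters' Rst."""
        from ylineage.panels import get_panel
        from ylineage.simulate import SimConfig, simulate_divergent_pair, simulate_population

        loci = list(get_panel("yfiler").single_copy_loci())
        d_ab, d_out = [], []
        for seed in range(4):
            cfg = SimConfig(
                n_founders=150, n_generations=80, n_sample=60,
                split_generations=20, seed=seed,
                microvariant_rate=0, duplication_rate=0,
            )
            a, b = simulate_divergent_pair(cfg)
            out = simulate_population(
                SimConfig(
                    n_founders=150, n_generations=500, n_sample=60,
                    seed=seed + 1000, population="out",
                    microvariant_rate=0, duplication_rate=0,
                )
            )
            d_ab.append(pairwise_rst(a.str_profiles, b.str_profiles, loci))
            d_out.append(
                (pairwise_rst(out.str_profiles, a.str_profiles, loci)
                 + pairwise_rst(out.str_profiles, b.str_profiles, loci)) / 2
            )
        assert np.mean(d_out) > np.mean(d_ab)
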