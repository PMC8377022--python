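import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from icuenterotype.abundance import AbundanceTable, table_from_frame
from icuenterotype.enterotype import (E1, E2, ch_index, jsd_matrix,
                                      pam_cluster, pam_objective, pcoa,
                                      select_k, silhouette)
from icuenterotype.synthetic import generate_cohort
from icuenterotype.taxonomy import TaxonLineage

from conftest import random_distance_matrix


def js_distance_reference(p, q):
    """Independent scalar Jensen-Shannon distance (log base 2)."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return np.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))


def _rel_table(rows, ids=None):
    rows = np.asarray(rows, float)
    taxa = [f"Bacteria;P{i};C;O;F;G{i}" for i in range(rows.shape[1])]
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    frame = pd.DataFrame(rows, index=ids, columns=taxa)
    return table_from_frame(frame, mode="relative")


class TestJsd:
    def test_identical_distributions_zero(self):
        table = _rel_table([[0.5, 0.5], [0.5, 0.5]])
        dm = jsd_matrix(table)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_maximal(self):
        table = _rel_table([[1.0, 0.0], [0.0, 1.0]])
        assert jsd_matrix(table).data[0, 1] == pytest.approx(1.0)

    def test_matches_scalar_reference(self):
        p, q = [0.5, 0.5, 0.0], [0.25, 0.25, 0.5]
        table = _rel_table([p, q])
        assert jsd_matrix(table).data[0, 1] == pytest.approx(
            js_distance_reference(p, q), rel=1e-12)

    def test_unnormalised_input_rejected(self):
        frame = pd.DataFrame([[0.7, 0.7]], index=["s"],
                             columns=["Bacteria;A;x;x;x;a", "Bacteria;B;x;x;x;b"])
        with pytest.raises(ValueError):
            jsd_matrix(AbundanceTable(
                frame, tuple(TaxonLineage.from_string(c) for c in frame.columns),
                "relative"))

    def test_metric_axioms_on_random_compositions(self, rng):
        comps = rng.dirichlet(np.ones(6), size=8)
        dm = jsd_matrix(_rel_table(comps)).data
        assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0)
        assert (dm >= 0).all() and (dm <= 1 + 1e-12).all()
        for i, j, k in itertools.permutations(range(8), 3):
            assert dm[i, k] <= dm[i, j] + dm[j, k] + 1e-12


def brute_force_pam(d, k):
    """Exhaustive search over all medoid subsets."""
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        obj = d[:, medoids].min(axis=1).sum()
        best = min(best, obj)
    return best


class TestPam:
    def test_two_separated_pairs_recovered(self):
        d = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
                     dtype=float)
        part = pam_cluster(DistanceMatrix(d, ["a", "b", "c", "d"]), 2)
        assert part.labels[0] == part.labels[1]
        assert part.labels[2] == part.labels[3]
        assert part.labels[0] != part.labels[2]

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_objective_matches_exhaustive_search(self, n, rng):
        for _ in range(3):
            d = random_distance_matrix(rng, n)
            dm = DistanceMatrix(d, [str(i) for i in range(n)])
            for k in range(1, n + 1):
                part = pam_cluster(dm, k)
                assert pam_objective(dm, part) == pytest.approx(
                    brute_force_pam(d, k), rel=1e-9)

    def test_k_equals_n_gives_zero_objective(self, rng):
        d = random_distance_matrix(rng, 6)
        dm = DistanceMatrix(d, [str(i) for i in range(6)])
        part = pam_cluster(dm, 6)
        assert pam_objective(dm, part) == 0.0
        assert sorted(part.medoids) == sorted(dm.ids)

    def test_k_above_n_rejected(self, rng):
        d = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            pam_cluster(DistanceMatrix(d, list("abcd")), 5)

    def test_deterministic(self, rng):
        d = random_distance_matrix(rng, 20)
        dm = DistanceMatrix(d, [str(i) for i in range(20)])
        a, b = pam_cluster(dm, 3), pam_cluster(dm, 3)
        assert np.array_equal(a.labels, b.labels) and a.medoids == b.medoids


class TestChIndex:
    @staticmethod
    def _dm_from_points(pts):
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(pts)),
                              [str(i) for i in range(len(pts))])

    def test_structure_beats_uniform_blob(self, rng):
        tight = np.vstack([rng.normal(0, 0.05, (10, 2)),
                           rng.normal(5, 0.05, (10, 2))])
        blob = rng.normal(0, 1, (20, 2))
        labels = np.repeat([0, 1], 10)
        assert ch_index(self._dm_from_points(tight), labels) > \
            ch_index(self._dm_from_points(blob), labels)

    def test_matches_direct_formula_on_coordinates(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = np.repeat([0, 1, 2], 4)
        dm = self._dm_from_points(pts)
        got = ch_index(dm, labels)
        # direct B/W computation on the embedded coordinates
        coords = pcoa(dm).coordinates
        overall = coords.mean(axis=0)
        b = sum((labels == c).sum() *
                ((coords[labels == c].mean(axis=0) - overall) ** 2).sum()
                for c in range(3))
        w = sum(((coords[labels == c] - coords[labels == c].mean(axis=0)) ** 2
                 ).sum() for c in range(3))
        expected = (b / 2) / (w / 9)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_scale_invariance(self, rng):
        pts = rng.normal(size=(10, 3))
        labels = np.repeat([0, 1], 5)
        dm = self._dm_from_points(pts)
        scaled = DistanceMatrix(dm.data * 3.7, dm.ids)
        assert ch_index(dm, labels) == pytest.approx(
            ch_index(scaled, labels), rel=1e-6)

    def test_degenerate_k_rejected(self, rng):
        dm = self._dm_from_points(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ch_index(dm, np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            ch_index(dm, np.arange(5))


class TestSilhouette:
    def test_perfect_pairs_near_one(self):
        d = np.array([[0, .1, 9, 9], [.1, 0, 9, 9],
                      [9, 9, 0, .1], [9, 9, .1, 0]])
        _, mean = silhouette(DistanceMatrix(d, list("abcd")),
                             np.array([0, 0, 1, 1]))
        assert mean > 0.95

    def test_singleton_gets_zero(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        widths, _ = silhouette(DistanceMatrix(d, list("abc")),
                               np.array([0, 0, 1]))
        assert widths[2] == 0.0

    def test_matches_hand_computation(self):
        # 6 points, two groups of 3; verify s(i) = (b-a)/max(a,b) by loop
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        widths, _ = silhouette(DistanceMatrix(d, [str(i) for i in range(6)]),
                               labels)
        for i in range(6):
            own = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([d[i, j] for j in own])
            b = np.mean([d[i, j] for j in other])
            assert widths[i] == pytest.approx((b - a) / max(a, b), rel=1e-9)

    def test_relabeling_invariance(self, rng):
        d = random_distance_matrix(rng, 10)
        dm = DistanceMatrix(d, [str(i) for i in range(10)])
        labels = rng.integers(0, 3, 10)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 10)
        _, s1 = silhouette(dm, labels)
        _, s2 = silhouette(dm, 2 - labels)
        assert s1 == pytest.approx(s2)
        assert ch_index(dm, labels) == pytest.approx(ch_index(dm, 2 - labels))


class TestSelectK:
    def test_two_enterotype_cohort_selects_k2(self, genus_table, cohort):
        from sklearn.metrics import adjusted_rand_score

        _, _, truth = cohort
        dm = jsd_matrix(genus_table)
        part, diag = select_k(dm, range(2, 11), table=genus_table)
        assert part.k == 2
        assert list(diag["k"]) == list(range(2, 11))
        ari = adjusted_rand_score(truth["enterotype"], part.named_labels())
        assert ari >= 0.9

    def test_e1_has_higher_bacteroides(self, genus_table):
        dm = jsd_matrix(genus_table)
        part, _ = select_k(dm, range(2, 11), table=genus_table)
        names = np.array(part.named_labels())
        bact = [c for c, lin in zip(genus_table.data.columns,
                                    genus_table.lineages)
                if lin.label_at("genus") == "Bacteroides"]
        means = genus_table.data[bact].sum(axis=1).groupby(names).mean()
        assert means[E1] > means[E2]

    def test_three_cluster_cohort_selects_k3(self, rng):
        # three archetypal compositions with modest noise
        arch = np.array([[20, 1, 1, 1, 1, 1], [1, 20, 1, 1, 1, 1],
                         [1, 1, 20, 1, 1, 1]], dtype=float)
        rows = np.vstack([rng.dirichlet(arch[i % 3] * 8) for i in range(45)])
        table = _rel_table(rows)
        part, _ = select_k(jsd_matrix(table), range(2, 11))
        assert part.k == 3

    def test_empty_feasible_range_rejected(self, rng):
        table = _rel_table(rng.dirichlet(np.ones(4), size=3))
        with pytest.raises(ValueError):
            select_k(jsd_matrix(table), range(4, 5))


class TestPcoa:
    def test_planar_configuration_recovered(self, rng):
        from scipy.spatial import procrustes
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(5, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            [str(i) for i in range(5)])
        emb = pcoa(dm, 2)
        _, _, disparity = procrustes(pts, emb.coordinates)
        assert disparity < 1e-6

    def test_equilateral_triangle_eigenstructure(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        emb = pcoa(DistanceMatrix(d, list("abc")))
        assert len(emb.eigenvalues) == 2
        assert emb.eigenvalues[0] == pytest.approx(emb.eigenvalues[1])

    def test_axes_orthogonal(self, genus_table):
        emb = pcoa(jsd_matrix(genus_table))
        gram = emb.coordinates.T @ emb.coordinates
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_truncation_warns_when_axes_exceed_positive(self, caplog):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        import logging

        with caplog.at_level(logging.WARNING, logger="icuenterotype.enterotype"):
            emb = pcoa(DistanceMatrix(d, list("abc")), n_axes=3)
        assert emb.coordinates.shape[1] == 2
        assert any("truncating" in r.message for r in caplog.records)
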