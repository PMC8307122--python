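"""IBS distances, classical MDS, and population assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from alltriage.ancestry import (
    GenotypePanel,
    assign_population,
    classical_mds,
    genotype_distance_matrix,
    intersect_common_sites,
    run_ancestry,
)
from alltriage.model import TriageError
from alltriage.synthetic_data import PanelSpec, PopulationSpec, generate_reference_panel


def panel_from(dosages, populations=None, samples=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypePanel(
        samples=samples or [f"S{i}" for i in range(n)],
        populations=populations or [None] * n,
        loci=[("chr1", 100 + j, "A", "G") for j in range(m)],
        dosages=dosages,
    )


class TestIntersectCommonSites:
    def _sites(self, loci):
        return pd.DataFrame(loci, columns=["chrom", "pos", "ref", "alt"])

    def test_subset_intersection(self):
        rng = np.random.default_rng(2)
        panel = panel_from(rng.integers(0, 3, size=(4, 100)))
        keep = [panel.loci[j] for j in range(0, 100, 5)] + [("chrX", 1, "A", "G")]
        out = intersect_common_sites(panel, self._sites(keep))
        assert len(out.loci) == 20
        assert out.loci == [panel.loci[j] for j in range(0, 100, 5)]  # order preserved

    def test_disjoint_lists_error(self):
        panel = panel_from([[0, 1], [1, 2]])
        with pytest.raises(TriageError, match="common-sites"):
            intersect_common_sites(panel, self._sites([("chr9", 1, "A", "G")]))

    def test_superset_leaves_panel_unchanged(self):
        panel = panel_from([[0, 1], [1, 2]])
        sites = self._sites(list(panel.loci) + [("chr9", 1, "A", "G")])
        out = intersect_common_sites(panel, sites)
        assert out.loci == panel.loci
        assert (out.dosages == panel.dosages).all()


class TestDistanceMatrix:
    def test_identical_vectors_zero_distance(self):
        D = genotype_distance_matrix(panel_from([[0, 1, 2], [0, 1, 2]]))
        assert D[0, 1] == 0.0

    def test_opposite_homozygotes_maximal_distance(self):
        D = genotype_distance_matrix(panel_from([[0, 0, 0], [2, 2, 2]]))
        assert D[0, 1] == 1.0

    def test_hand_computed_value(self):
        # sharing (2-0)/2, (2-0)/2, (2-2)/2 -> IBS 2/3 -> d = 1/3
        D = genotype_distance_matrix(panel_from([[0, 1, 2], [0, 1, 0]]))
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_missing_handled_pairwise_complete(self):
        D = genotype_distance_matrix(panel_from([[0, np.nan, 2], [0, 1, 0]]))
        # only loci 0 and 2 compared: sims 1 and 0 -> d = 1/2
        assert D[0, 1] == pytest.approx(0.5)

    def test_no_pairwise_complete_loci_errors_naming_pair(self):
        with pytest.raises(TriageError, match="S0.*S1"):
            genotype_distance_matrix(panel_from([[0, np.nan], [np.nan, 1]]))

    def test_properties_on_random_panels(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X = rng.integers(0, 3, size=(6, 30)).astype(float)
            X[rng.random(X.shape) < 0.1] = np.nan
            try:
                D = genotype_distance_matrix(panel_from(X))
            except TriageError:
                continue
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0)
            assert (D >= 0).all() and (D <= 1).all()


class TestClassicalMds:
    def test_two_points_closed_form(self):
        D = np.array([[0.0, 0.8], [0.8, 0.0]])
        coords, lam = classical_mds(D, k=1)
        assert sorted(coords[:, 0]) == pytest.approx([-0.4, 0.4])
        assert lam[0] == pytest.approx(0.8 ** 2 / 2)

    def test_unit_square_recovered_to_procrustes_residual(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords, lam = classical_mds(D, k=2)
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-8
        assert lam[0] >= lam[1] >= 0

    def test_duplicate_sample_identical_coordinates(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [0, 2]], dtype=float)
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords, _ = classical_mds(D, k=2)
        assert np.allclose(coords[1], coords[2], atol=1e-10)

    def test_agrees_with_independent_pcoa_oracle(self):
        """Cross-check against scikit-bio's principal coordinates
        analysis on random Euclidean distance matrices."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(19)
        for _ in range(5):
            pts = rng.normal(size=(6, 4))
            D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
            coords, lam = classical_mds(D, k=2)
            ref = pcoa(D, number_of_dimensions=2)
            ref_coords = ref.samples.to_numpy()
            assert np.allclose(np.sort(lam), np.sort(ref.eigvals.to_numpy()[:2]), atol=1e-8)
            for d in range(2):
                col, refcol = coords[:, d], ref_coords[:, d]
                assert np.allclose(col, refcol, atol=1e-8) or np.allclose(
                    col, -refcol, atol=1e-8
                )

    def test_embedding_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(8, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords, _ = classical_mds(D, k=2)
        perm = rng.permutation(8)
        coords_p, _ = classical_mds(D[np.ix_(perm, perm)], k=2)
        _, _, disparity = procrustes(coords[perm], coords_p)
        assert disparity < 1e-8

    def test_rejects_asymmetric_and_nonzero_diagonal(self):
        with pytest.raises(TriageError, match="symmetric"):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(TriageError, match="diagonal"):
            classical_mds(np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_negative_eigenvalues_truncated(self):
        # violates the triangle inequality, hence non-Euclidean
        D = np.array([[0, 4, 1], [4, 0, 1], [1, 1, 0]], dtype=float)
        coords, lam = classical_mds(D, k=3)
        assert (lam >= 0).all()
        assert np.isfinite(coords).all()


class TestAssignPopulation:
    def test_query_on_centroid_gets_label_with_zero_distance(self):
        coords = np.array([[0, 0], [0, 2], [0, 1], [5, 5], [5, 5]], dtype=float)
        assigned, dist, amb = assign_population(
            coords, ["a1", "a2", "q1", "b1", "q2"], ["A", "A", None, "B", None]
        )
        assert assigned == {"q1": "A", "q2": "B"}
        assert dist.set_index("sample").loc["q2", "B"] == pytest.approx(0.0)
        assert not amb["q1"]

    def test_equidistant_query_ties_lexicographically_and_flags(self):
        coords = np.array([[-1, 0], [1, 0], [0, 0]], dtype=float)
        assigned, _, amb = assign_population(coords, ["b", "a", "q"], ["B", "A", None])
        assert assigned["q"] == "A"
        assert amb["q"]

    def test_no_references_errors(self):
        with pytest.raises(TriageError, match="no labeled reference"):
            assign_population(np.zeros((2, 2)), ["q1", "q2"], [None, None])


class TestTwoPopulationRecovery:
    def test_divergent_panel_assignment_accuracy(self):
        """Two populations 0.5 apart in allele frequency over 500 loci:
        nearly all queries map back to their generating population."""
        spec = PanelSpec(
            populations=(
                PopulationSpec("POP_A", 50, divergence=0.5),
                PopulationSpec("POP_B", 50, divergence=0.5),
                PopulationSpec(None, 10, like="POP_A"),
                PopulationSpec(None, 10, like="POP_B"),
            ),
            n_loci=500,
            seed=101,
        )
        panel = generate_reference_panel(spec)
        result = run_ancestry(panel)
        truth = {s: ("POP_A" if i < 10 else "POP_B")
                 for i, s in enumerate(panel.samples[100:])}
        correct = sum(result.assigned_population[s] == t for s, t in truth.items())
        assert correct / len(truth) >= 0.95

    def test_identical_populations_show_no_axis_separation(self):
        spec = PanelSpec(
            populations=(
                PopulationSpec("X", 30, divergence=0.0),
                PopulationSpec("Y", 30, divergence=0.0),
            ),
            n_loci=300,
            seed=7,
        )
        panel = generate_reference_panel(spec)
        result = run_ancestry(panel)
        dim1 = result.coordinates[:, 0]
        a, b = dim1[:30], dim1[30:]
        between = (a.mean() - b.mean()) ** 2
        within = (a.var() + b.var()) / 2
        assert between / within < 0.5  # no separation beyond noise


class TestPanelTsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(4, 6)).astype(float)
        X[0, 0] = np.nan
        panel = panel_from(X, populations=["A", "A", None, "B"])
        p = tmp_path / "panel.tsv"
        panel.to_tsv(p)
        back = GenotypePanel.from_tsv(p)
        assert back.samples == panel.samples
        assert back.populations == panel.populations
        assert back.loci == panel.loci
        assert np.array_equal(back.dosages, panel.dosages, equal_nan=True)
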