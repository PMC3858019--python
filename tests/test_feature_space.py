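"""Unit tests for weight-center treatment, PCA projection and 3D distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcmspace.errors import (
    EmptyGroup,
    InsufficientData,
    InvalidMass,
    SpaceMismatch,
    UnknownHerb,
    ValidationError,
)
from tcmspace.feature_space import (
    CompoundDescriptorTable,
    SpaceEmbedding,
    centroid_distance_matrix,
    distance_summary,
    project,
    spatial_distance,
    weight_center,
)
from tcmspace.pairs import PairSet

from .oracles import pairwise_distances_loop


def make_table(rows, p=None):
    """rows: (compound_id, herb_id, mass, vector)"""
    p = p if p is not None else len(rows[0][3])
    data = [
        {"compound_id": c, "herb_id": h, "mass": m,
         **{f"d{i+1}": v for i, v in enumerate(vec)}}
        for c, h, m, vec in rows
    ]
    return CompoundDescriptorTable.from_dataframe(pd.DataFrame(data))


def random_table(rng, n_herbs=8, per_herb=4, p=6):
    rows = []
    for i in range(n_herbs):
        for j in range(per_herb):
            rows.append((f"c{i}_{j}", f"H{i}", 1.0, rng.normal(size=p)))
    return make_table(rows)


def embedding_from_coords(coords: dict, space_id="test") -> SpaceEmbedding:
    df = pd.DataFrame.from_dict(coords, orient="index", columns=["X", "Y", "Z"])
    df.index.name = "herb_id"
    p = pd.Series(1.0, index=["d1"])
    return SpaceEmbedding(
        coordinates=df.sort_index(),
        loadings=pd.DataFrame(np.eye(1, 3), index=["d1"], columns=["X", "Y", "Z"]),
        explained_variance_ratios=(1.0, 0.0, 0.0),
        cumulative_ratio=1.0,
        standardization_mean=p,
        standardization_sd=p,
        space_id=space_id,
    )


class TestTableValidation:
    def test_missing_column(self):
        with pytest.raises(ValidationError, match="herb_id"):
            CompoundDescriptorTable.from_dataframe(
                pd.DataFrame({"compound_id": ["c1"], "d1": [1.0], "d2": [2.0]})
            )

    def test_non_numeric_cell_reported(self):
        df = pd.DataFrame(
            {"compound_id": ["c1"], "herb_id": ["H1"], "d1": ["oops"], "d2": [2.0]}
        )
        with pytest.raises(ValidationError, match="c1"):
            CompoundDescriptorTable.from_dataframe(df)

    def test_nonpositive_mass(self):
        with pytest.raises(InvalidMass):
            make_table([("c1", "H1", 0.0, (1.0, 2.0))])

    def test_too_few_descriptors(self):
        with pytest.raises(ValidationError):
            CompoundDescriptorTable.from_dataframe(
                pd.DataFrame({"compound_id": ["c1"], "herb_id": ["H1"], "d1": [1.0]})
            )


class TestWeightCenter:
    def test_equal_mass_mean(self):
        hc = weight_center(
            make_table([("c1", "H1", 1.0, (0.0, 0.0)), ("c2", "H1", 1.0, (2.0, 4.0))])
        )
        assert hc.centroids.loc["H1"].tolist() == [1.0, 2.0]

    def test_single_compound_identity(self):
        hc = weight_center(make_table([("c1", "H1", 1.0, (3.5, -1.25, 7.0))]))
        assert hc.centroids.loc["H1"].tolist() == [3.5, -1.25, 7.0]

    def test_weighted_mean(self):
        hc = weight_center(
            make_table([("c1", "H1", 1.0, (0.0, 0.0)), ("c2", "H1", 3.0, (4.0, 4.0))])
        )
        assert hc.centroids.loc["H1"].tolist() == pytest.approx([3.0, 3.0], abs=1e-12)

    def test_linearity_under_pooling(self):
        rng = np.random.default_rng(0)
        rows_a = [(f"a{i}", "HA", float(m), rng.normal(size=4))
                  for i, m in enumerate(rng.uniform(0.5, 3, 5))]
        rows_b = [(f"b{i}", "HB", float(m), rng.normal(size=4))
                  for i, m in enumerate(rng.uniform(0.5, 3, 7))]
        pooled = [(c, "HP", m, v) for c, _, m, v in rows_a + rows_b]
        hc = weight_center(make_table(rows_a + rows_b))
        hp = weight_center(make_table(pooled))
        wa, wb = hc.total_mass["HA"], hc.total_mass["HB"]
        combined = (
            hc.centroids.loc["HA"] * wa + hc.centroids.loc["HB"] * wb
        ) / (wa + wb)
        np.testing.assert_allclose(hp.centroids.loc["HP"], combined, atol=1e-12)

    def test_duplicating_compounds_leaves_centroid_unchanged(self):
        rng = np.random.default_rng(1)
        rows = [(f"c{i}", "H1", 1.0, rng.normal(size=5)) for i in range(4)]
        doubled = rows + [(f"x{i}", "H1", 1.0, v) for i, (_, _, _, v) in enumerate(rows)]
        a = weight_center(make_table(rows)).centroids
        b = weight_center(make_table(doubled)).centroids
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_centroid_inside_coordinate_range(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        hc = weight_center(table)
        for herb in hc.herb_ids:
            sub = table.data[table.data["herb_id"] == herb][list(table.descriptor_columns)]
            assert (hc.centroids.loc[herb] >= sub.min() - 1e-12).all()
            assert (hc.centroids.loc[herb] <= sub.max() + 1e-12).all()

    def test_declared_herb_without_compounds(self):
        table = make_table([("c1", "H1", 1.0, (1.0, 2.0))])
        with pytest.raises(EmptyGroup, match="H2"):
            weight_center(table, herbs=["H1", "H2"])

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_scaling_all_masses_is_a_no_op(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"c{i}", "H1", float(m), rng.normal(size=3))
                for i, m in enumerate(rng.uniform(0.1, 2, 4))]
        scaled = [(c, h, m * 7.5, v) for c, h, m, v in rows]
        np.testing.assert_allclose(
            weight_center(make_table(rows)).centroids,
            weight_center(make_table(scaled)).centroids,
            atol=1e-12,
        )


class TestProject:
    def test_collinear_herbs_give_rank_one_embedding(self):
        t = np.linspace(0, 1, 8)
        rows = [(f"c{i}", f"H{i}", 1.0, (ti * 2, ti * 5, ti * -1)) for i, ti in enumerate(t)]
        emb = project(weight_center(make_table(rows)), n_components=2)
        assert emb.explained_variance_ratios[0] >= 0.999

    def test_ratio_properties_and_orthonormal_loadings(self):
        emb = project(weight_center(random_table(np.random.default_rng(3))))
        r = emb.explained_variance_ratios
        assert all(a >= b for a, b in zip(r, r[1:]))
        assert 0 < sum(r) <= 1 + 1e-12
        L = emb.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-8)

    def test_matches_sklearn_pca(self):
        from sklearn.decomposition import PCA

        hc = weight_center(random_table(np.random.default_rng(4), n_herbs=10, p=7))
        emb = project(hc, n_components=3)
        X = hc.centroids.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=3, svd_solver="full").fit(Xs)
        np.testing.assert_allclose(
            emb.explained_variance_ratios, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(emb.coordinates.to_numpy()), np.abs(ref.transform(Xs)), atol=1e-8
        )

    def test_full_projection_preserves_standardized_distances(self):
        hc = weight_center(random_table(np.random.default_rng(5), n_herbs=9, p=4))
        emb = project(hc, n_components=4)
        X = hc.centroids.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(
            pairwise_distances_loop(emb.coordinates.to_numpy()),
            pairwise_distances_loop(Xs),
            atol=1e-8,
        )

    def test_zero_variance_descriptor_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        rows = [(f"c{i}", f"H{i}", 1.0, (rng.normal(), rng.normal(), rng.normal(), 4.0))
                for i in range(8)]
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = project(weight_center(make_table(rows)))
        assert emb.dropped_descriptors == ("d4",)
        assert "d4" not in emb.loadings.index

    def test_insufficient_herbs(self):
        rows = [(f"c{i}", f"H{i}", 1.0, (float(i), 1.0, 2.0)) for i in range(3)]
        with pytest.raises(InsufficientData):
            project(weight_center(make_table(rows)), n_components=3)

    def test_deterministic_rerun(self):
        hc = weight_center(random_table(np.random.default_rng(8)))
        a, b = project(hc), project(hc)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.space_id == b.space_id


class TestSpatialDistance:
    def test_three_four_five_triple(self):
        emb = embedding_from_coords({"A": (0, 0, 0), "B": (1, 2, 2)})
        assert spatial_distance(emb.point("A"), emb.point("B")) == pytest.approx(3.0, abs=1e-15)

    def test_identity_and_symmetry(self):
        emb = embedding_from_coords({"A": (1.5, -2, 0.25), "B": (0, 1, 2)})
        a, b = emb.point("A"), emb.point("B")
        assert spatial_distance(a, a) == 0.0
        assert spatial_distance(a, b) == spatial_distance(b, a)

    def test_space_mismatch(self):
        e1 = embedding_from_coords({"A": (0, 0, 0)}, space_id="s1")
        e2 = embedding_from_coords({"A": (0, 0, 0)}, space_id="s2")
        with pytest.raises(SpaceMismatch):
            spatial_distance(e1.point("A"), e2.point("A"))

    def test_distance_matrix_matches_double_loop(self):
        rng = np.random.default_rng(9)
        coords = {f"H{i}": tuple(rng.normal(size=3)) for i in range(12)}
        emb = embedding_from_coords(coords)
        np.testing.assert_allclose(
            emb.distance_matrix().to_numpy(),
            pairwise_distances_loop(emb.coordinates.to_numpy()),
            atol=1e-12,
        )

    def test_centroid_distance_matrix_diagnostic(self):
        hc = weight_center(random_table(np.random.default_rng(10)))
        np.testing.assert_allclose(
            centroid_distance_matrix(hc).to_numpy(),
            pairwise_distances_loop(hc.centroids.to_numpy()),
            atol=1e-12,
        )


class TestDistanceSummary:
    def test_unit_square_diagonals(self):
        emb = embedding_from_coords(
            {"A": (0, 0, 0), "B": (1, 0, 0), "C": (1, 1, 0), "D": (0, 1, 0)}
        )
        report = distance_summary(emb, PairSet.from_pairs([("A", "C"), ("B", "D")]))
        assert report.pair_set_mean == pytest.approx(np.sqrt(2), abs=1e-12)
        assert report.global_mean == pytest.approx((4 + 2 * np.sqrt(2)) / 6, abs=1e-12)

    def test_all_pairs_equals_global_mean(self):
        rng = np.random.default_rng(11)
        coords = {f"H{i}": tuple(rng.normal(size=3)) for i in range(6)}
        emb = embedding_from_coords(coords)
        all_pairs = [(a, b) for i, a in enumerate(sorted(coords)) for b in sorted(coords)[i + 1:]]
        report = distance_summary(emb, PairSet.from_pairs(all_pairs))
        assert report.pair_set_mean == pytest.approx(report.global_mean, abs=1e-12)

    def test_global_mean_matches_double_loop(self):
        rng = np.random.default_rng(12)
        coords = {f"H{i}": tuple(rng.normal(size=3)) for i in range(9)}
        emb = embedding_from_coords(coords)
        report = distance_summary(emb, PairSet.from_pairs([("H0", "H1")]))
        m = pairwise_distances_loop(emb.coordinates.to_numpy())
        n = len(coords)
        brute = m[np.triu_indices(n, k=1)].mean()
        assert report.global_mean == pytest.approx(brute, abs=1e-12)

    def test_unknown_herb(self):
        emb = embedding_from_coords({"A": (0, 0, 0), "B": (1, 1, 1)})
        with pytest.raises(UnknownHerb, match="Z"):
            distance_summary(emb, PairSet.from_pairs([("A", "Z")]))
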