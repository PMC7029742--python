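import numpy as np
import pandas as pd
import pytest

from lakescape.clade_test import (
    CladeMap,
    CladeTestError,
    association_test,
    clade_map_from_lineages,
    clustering_score,
    clustering_test,
    projection_score,
    run_clade_tests,
)
from lakescape.io_prep import ENV_COLUMNS
from lakescape import cca, filter_low_abundance, metadata_to_frame, simulate
from lakescape.synthetic import SimulationConfig, default_clades


def _frame(pts):
    pts = np.asarray(pts, dtype=float)
    return pd.DataFrame(pts, index=[f"o{i}" for i in range(len(pts))],
                        columns=["CCA1", "CCA2"])


class TestScores:
    def test_single_pair_345(self):
        coords = _frame([(0, 0), (3, 4)])
        assert clustering_score(coords, ("o0", "o1")) == pytest.approx(5.0)

    def test_collinear_three_points(self):
        coords = _frame([(0, 0), (1, 0), (2, 0)])
        assert clustering_score(coords, ("o0", "o1", "o2")) == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        coords = _frame(pts)
        total = sum(np.linalg.norm(pts[i] - pts[j])
                    for i in range(6) for j in range(i + 1, 6))
        got = clustering_score(coords, tuple(coords.index))
        assert got == pytest.approx(total, abs=1e-12)

    def test_singleton_clade_rejected(self):
        with pytest.raises(CladeTestError):
            clustering_score(_frame([(0, 0)]), ("o0",))

    def test_clustering_score_rigid_motion_invariant(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([5.0, -2.0])
        a = clustering_score(_frame(pts), tuple(f"o{i}" for i in range(8)))
        b = clustering_score(_frame(moved), tuple(f"o{i}" for i in range(8)))
        assert a == pytest.approx(b, abs=1e-9)

    def test_projection_x_components(self):
        coords = _frame([(3, 4), (1, 0)])
        assert projection_score(coords, ("o0", "o1"), (1, 0)) == pytest.approx(4.0)

    def test_projection_normalizes_direction(self):
        coords = _frame([(3, 4)])
        assert projection_score(coords, ("o0",), (0, 2)) == pytest.approx(4.0)

    def test_projection_antisymmetric(self):
        rng = np.random.default_rng(2)
        coords = _frame(rng.normal(size=(5, 2)))
        members = tuple(coords.index)
        v = (0.6, -0.8)
        assert projection_score(coords, members, v) == pytest.approx(
            -projection_score(coords, members, tuple(-x for x in v)))

    def test_zero_vector_rejected(self):
        with pytest.raises(CladeTestError):
            projection_score(_frame([(1, 1)]), ("o0",), (0, 0))


class TestCladeMap:
    def test_overlapping_membership_rejected(self):
        with pytest.raises(CladeTestError, match="both"):
            CladeMap(rank="phylum", clades={"A": ("x", "y"), "B": ("y",)})

    def test_built_from_lineages_with_min_size(self, tiny_table):
        cm = clade_map_from_lineages(tiny_table, "phylum", min_size=2)
        assert set(cm.clades) == {"Cyanobacteria"}


class TestClusteringTest:
    def test_planted_coincident_clade_detected(self, coords_cloud):
        # 10 coincident points among a dispersed cloud
        tight = pd.DataFrame(np.full((10, 2), 0.01),
                             index=[f"t{i}" for i in range(10)],
                             columns=["CCA1", "CCA2"])
        coords = pd.concat([coords_cloud, tight])
        cm = CladeMap(rank="phylum", clades={
            "tight": tuple(tight.index),
            "loose": tuple(coords_cloud.index),
        })
        df = clustering_test(coords, cm, n=1000, seed=0)
        row = df.set_index("clade").loc["tight"]
        assert row["p_clust"] == 0.0
        assert row["q_clust"] <= 0.05

    def test_clade_equal_to_pool_has_p_one(self, coords_cloud):
        members = tuple(coords_cloud.index)
        cm = CladeMap(rank="phylum", clades={"all": members})
        df = clustering_test(coords_cloud, cm, n=100, seed=0, pool=members)
        assert df["p_clust"].iloc[0] == 1.0

    def test_clade_larger_than_pool_rejected(self, coords_cloud):
        cm = CladeMap(rank="phylum", clades={"A": tuple(coords_cloud.index)})
        with pytest.raises(CladeTestError):
            clustering_test(coords_cloud, cm, n=100, seed=0,
                            pool=tuple(coords_cloud.index[:10]))


class TestAssociationTest:
    def _eig(self):
        return pd.DataFrame([[1.0, 0.0]], index=["TP"],
                            columns=["CCA1", "CCA2"])

    def test_planted_positive_association(self, coords_cloud):
        rng = np.random.default_rng(3)
        shifted = pd.DataFrame(rng.normal(size=(12, 2)) + [4.0, 0.0],
                               index=[f"t{i}" for i in range(12)],
                               columns=["CCA1", "CCA2"])
        cm = CladeMap(rank="phylum", clades={"planted": tuple(shifted.index)})
        df = association_test(pd.concat([coords_cloud, shifted]), cm,
                              self._eig(), n=1000, seed=0)
        row = df.iloc[0]
        assert row["direction"] == "positive"
        assert row["q_assoc"] <= 0.05

    def test_origin_symmetric_clade_not_flagged(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(100, 2))
        coords = _frame(np.vstack([pts, -pts]))  # exactly symmetric
        cm = CladeMap(rank="phylum", clades={"sym": tuple(coords.index)})
        df = association_test(coords, cm, self._eig(), n=1000, seed=1)
        assert 0.3 < df["u"].iloc[0] < 0.7
        assert df["direction"].iloc[0] == "none"

    def test_direction_swaps_under_vector_negation(self, coords_cloud):
        shifted = coords_cloud + [3.0, 0.0]
        cm = CladeMap(rank="phylum", clades={"A": tuple(shifted.index)})
        eig = pd.DataFrame([[1.0, 0.0], [-1.0, 0.0]], index=["v", "neg_v"],
                           columns=["CCA1", "CCA2"])
        df = association_test(shifted, cm, eig, n=1000, seed=2)
        by = df.set_index("vector")
        assert by.loc["v", "direction"] == "positive"
        assert by.loc["neg_v", "direction"] == "negative"
        assert by.loc["v", "p_assoc"] == pytest.approx(
            by.loc["neg_v", "p_assoc"])

    def test_zero_variance_clade_rejected(self):
        coords = _frame([(1.0, 1.0), (1.0, 1.0)])
        cm = CladeMap(rank="phylum", clades={"A": ("o0", "o1")})
        with pytest.raises(CladeTestError, match="variance"):
            association_test(coords, cm, self._eig(), n=100, seed=0)


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(n_lakes=30, n_otus=400, depth=4000,
                           clades=default_clades(400))
    ds = simulate(cfg, seed=11)
    table = filter_low_abundance(ds.table, 5)
    md = metadata_to_frame(ds.metadata)
    ordn = cca(table.to_frame(), md[list(ENV_COLUMNS)])
    return ds, table, ordn


class TestRunCladeTests:

    def test_planted_clustered_phylum_flagged(self, small_dataset):
        ds, table, ordn = small_dataset
        df = run_clade_tests(ordn, table, ranks=("phylum",),
                             n_clustering=500, n_association=500, seed=5)
        planted = ds.truth["planted_clustered"]
        q = df.loc[df["clade"] == planted, "q_clust"].iloc[0]
        assert q <= 0.05

    def test_planted_associated_phylum_signed_correctly(self, small_dataset):
        ds, table, ordn = small_dataset
        df = run_clade_tests(ordn, table, ranks=("phylum",),
                             n_clustering=500, n_association=500, seed=5)
        planted = ds.truth["planted_associated"]
        row = df[(df["clade"] == planted) & (df["vector"] == "TP")].iloc[0]
        assert row["direction"] == "positive"

    def test_deterministic_under_seed(self, small_dataset):
        _, table, ordn = small_dataset
        a = run_clade_tests(ordn, table, ranks=("phylum",), n_clustering=200,
                            n_association=200, seed=9)
        b = run_clade_tests(ordn, table, ranks=("phylum",), n_clustering=200,
                            n_association=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_lineages_give_empty_result(self, small_dataset, caplog):
        _, table, ordn = small_dataset
        from lakescape.io_prep import OtuTable
        bare = OtuTable(sample_ids=table.sample_ids, otu_ids=table.otu_ids,
                        counts=table.counts)
        with caplog.at_level("WARNING"):
            df = run_clade_tests(ordn, bare, ranks=("phylum",), seed=0)
        assert len(df) == 0
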