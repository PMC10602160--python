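import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from isynpro import (
    ContigCountMatrix,
    SelectionThresholds,
    build_trajectories,
    cluster_trajectories,
    hopkins,
    trajectory_projection,
)


def matrix_from_counts(data, index):
    return ContigCountMatrix(pd.DataFrame(data, index=index))


@pytest.fixture
def toy_matrix():
    # column totals 250,000 -> cpm = 4 * count
    filler = 250_000
    data = {
        "virus": [2, 500, 10, filler - 512],
        "t24": [8, 400, 1, filler - 409],
        "t48": [8, 300, 2, filler - 310],
        "t72": [2, 200, 3, filler - 205],
        "restim": [2, 100, 0, filler - 102],
    }
    return matrix_from_counts(data, ["up", "down", "faint", "bulk"])


class TestBuildTrajectories:
    def test_log2_fold_change_no_pseudocount(self, toy_matrix):
        traj = build_trajectories(toy_matrix, pseudo_cpm=0.0)
        # contig "up": cpm 8 at t24 vs 2*4=8 in virus -> log2(32/8) = 2
        assert traj.log2fc.loc["up", "t24"] == pytest.approx(np.log2(32 / 8))

    def test_detection_filter_discards_never_detected(self, toy_matrix):
        traj = build_trajectories(toy_matrix, SelectionThresholds())
        # "faint" cpm is {4, 8, 12, 0}: above the floor somewhere -> retained
        assert traj.detect_mask.loc["faint"]
        low = toy_matrix.counts.copy()
        low.loc["faint"] = [10, 0, 0, 0, 0]
        traj2 = build_trajectories(ContigCountMatrix(low), SelectionThresholds())
        assert not traj2.detect_mask.loc["faint"]

    def test_detect_mode_all_is_stricter(self, toy_matrix):
        any_mask = build_trajectories(toy_matrix, detect_mode="any").detect_mask
        all_mask = build_trajectories(toy_matrix, detect_mode="all").detect_mask
        assert (all_mask <= any_mask).all()
        assert not all_mask.loc["faint"]  # cpm 0 at restim fails the strict mode

    def test_pseudocount_keeps_ratios_finite(self):
        m = matrix_from_counts(
            {"virus": [0, 100], "t24": [50, 50]}, ["new", "old"]
        )
        traj = build_trajectories(m)
        val = traj.log2fc.loc["new", "t24"]
        assert np.isfinite(val) and val > 0

    def test_scale_invariance(self, toy_matrix):
        traj = build_trajectories(toy_matrix)
        scaled = ContigCountMatrix(toy_matrix.counts * 10)
        traj10 = build_trajectories(scaled)
        # frequencies unchanged -> cpm unchanged -> identical trajectories
        pd.testing.assert_frame_equal(traj.log2fc, traj10.log2fc)

    def test_missing_baseline_rejected(self, toy_matrix):
        m = ContigCountMatrix(toy_matrix.counts.drop(columns="virus"))
        with pytest.raises(ValueError, match="baseline"):
            build_trajectories(m)


class TestHopkins:
    def test_uniform_data_near_half(self, rng):
        hs = [
            hopkins(rng.uniform(size=(200, 4)), m=20, seed=int(s))
            for s in rng.integers(0, 2**31, size=100)
        ]
        mean_h = np.mean([h.H for h in hs])
        assert 0.43 < mean_h < 0.57
        assert all(0 <= h.H <= 1 and 0 <= h.p_value <= 1 for h in hs)

    def test_planted_clusters_detected(self, rng):
        centers = np.array([[0.2] * 4, [0.8] * 4])
        X = np.vstack(
            [c + rng.normal(scale=0.05, size=(100, 4)) for c in centers]
        )
        res = hopkins(X, m=20, seed=11)
        assert res.H > 0.75
        assert res.p_value < 0.01

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            hopkins(rng.uniform(size=(9, 2)))

    def test_seeded_determinism(self, rng):
        X = rng.uniform(size=(50, 3))
        a = hopkins(X, m=10, seed=5)
        b = hopkins(X, m=10, seed=5)
        assert a.H == b.H and a.p_value == b.p_value


def archetype_data(rng, n_per=60, sigma=0.2):
    arch = {
        "flat": np.zeros(4),
        "transient_up": np.array([2.0, 2.5, 0.5, 0.0]),
        "monotone_down": np.array([-0.5, -1.5, -2.5, -3.0]),
    }
    rows, truth = [], []
    for name, base in arch.items():
        rows.append(base + rng.normal(scale=sigma, size=(n_per, 4)))
        truth += [name] * n_per
    X = pd.DataFrame(
        np.vstack(rows),
        index=[f"c{i}" for i in range(3 * n_per)],
        columns=["t24", "t48", "t72", "restim"],
    )
    return X, truth


class TestClusterTrajectories:
    def test_recovers_planted_archetypes(self, rng):
        X, truth = archetype_data(rng)
        res = cluster_trajectories(X, k_range=range(2, 10), seed=0)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_identical_trajectories_degenerate(self):
        X = pd.DataFrame(
            np.ones((20, 4)), index=[f"c{i}" for i in range(20)]
        )
        res = cluster_trajectories(X)
        assert res.degenerate
        assert res.k == 1
        assert (res.labels == 1).all()

    def test_row_permutation_invariance(self, rng):
        X, _ = archetype_data(rng, n_per=30)
        res1 = cluster_trajectories(X, k_range=range(2, 6))
        perm = rng.permutation(len(X))
        res2 = cluster_trajectories(X.iloc[perm], k_range=range(2, 6))
        aligned = res2.labels.loc[X.index]
        assert adjusted_rand_score(res1.labels, aligned) == pytest.approx(1.0)

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(2, 4)))
        with pytest.raises(ValueError):
            cluster_trajectories(X, k_range=range(4, 8))

    def test_kmeans_alternative(self, rng):
        X, truth = archetype_data(rng, n_per=30)
        res = cluster_trajectories(X, k_range=range(2, 6), method="kmeans", seed=3)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.9


class TestTrajectoryProjection:
    def test_equal_frequencies_on_diagonal(self):
        m = matrix_from_counts(
            {
                "virus": [10, 10],
                "t24": [10, 30],
                "t48": [10, 30],
                "t72": [10, 30],
                "restim": [10, 30],
            },
            ["diag", "other"],
        )
        proj = trajectory_projection(m)
        row = proj.loc["diag"]
        assert row.nunique() == 1  # same frequency on every axis

    def test_restim_only_contig_at_origin(self):
        m = matrix_from_counts(
            {"virus": [0, 5], "t24": [0, 5], "t48": [0, 5], "t72": [0, 5],
             "restim": [7, 5]},
            ["late", "other"],
        )
        proj = trajectory_projection(m)
        assert proj.loc["late", ["freq_t24", "freq_t48", "freq_t72"]].eq(0).all()
        assert proj.loc["late", "freq_restim"] > 0

    def test_row_count_matches_retained(self, toy_matrix):
        retained = pd.Index(["up", "down"])
        proj = trajectory_projection(toy_matrix, retained=retained)
        assert len(proj) == 2
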