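import numpy as np
import pytest

from hippoparc.clustering import Partition
from hippoparc.graph import RoiGraph
from hippoparc.metrics import (
    age_regression,
    dice,
    fisher_z,
    group_fc_test,
    group_maps,
    parcel_region_fc,
    silhouette,
)
import pandas as pd

from conftest import dice_oracle, random_partition_labels, random_similarity, silhouette_oracle


class TestSilhouette:
    def test_perfect_separation(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 2.0
        A[3:, 3:] = 2.0
        g = RoiGraph(A)
        part = Partition(np.array([1, 1, 1, 2, 2, 2]), 2)
        assert silhouette(part, g) == pytest.approx(1.0)

    def test_zero_when_within_equals_between(self):
        A = np.full((6, 6), 1.0)
        np.fill_diagonal(A, 2.0)
        g = RoiGraph(A)
        part = Partition(np.array([1, 1, 1, 2, 2, 2]), 2)
        assert silhouette(part, g) == pytest.approx(0.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        A = random_similarity(rng, 6)
        labels = np.array([1, 2, 1, 2, 2, 1])
        val = silhouette(Partition(labels, 2), RoiGraph(A))
        assert val == pytest.approx(silhouette_oracle(labels, A), abs=1e-12)

    def test_singleton_rejected(self):
        rng = np.random.default_rng(1)
        g = RoiGraph(random_similarity(rng, 4))
        with pytest.raises(ValueError, match="singleton"):
            silhouette(Partition(np.array([1, 2, 2, 2]), 2), g)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(2)
        A = random_similarity(rng, 9)
        labels = np.array([1, 1, 2, 2, 3, 3, 1, 2, 3])
        swapped = np.select([labels == 1, labels == 2, labels == 3], [3, 1, 2])
        assert silhouette(Partition(labels, 3), RoiGraph(A)) == pytest.approx(
            silhouette(Partition(swapped, 3), RoiGraph(A)), abs=1e-12
        )


class TestDice:
    def test_identical_and_disjoint(self):
        x = np.array([1, 1, 2, 2, 3, 3])
        assert dice(x, x, 3) == 1.0
        y = np.array([2, 2, 3, 3, 1, 1])
        assert dice(x, y, 3, matching="optimal_overlap") == 1.0
        assert dice(x, y, 3, matching="identity") == 0.0

    def test_hand_counted_overlap(self):
        # cluster 1: |X|=4, |Y|=4, overlap 2 -> 4/8; cluster 2: 6, 6, overlap 4 -> 8/12
        x = np.array([1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        y = np.array([1, 1, 2, 2, 2, 2, 2, 2, 1, 1])
        got = dice(x, y, 2, matching="identity")
        assert got == pytest.approx(0.5 * (2 * 2 / 8 + 2 * 4 / 12))
        assert got == pytest.approx(dice_oracle(x, y, 2), abs=1e-12)

    def test_optimal_at_least_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 15))
            k = int(rng.integers(2, 4))
            x = random_partition_labels(rng, n, k)
            y = random_partition_labels(rng, n, k)
            assert dice(x, y, k) >= dice(x, y, k, matching="identity") - 1e-12

    def test_differing_k_rejected(self):
        with pytest.raises(ValueError, match="different k"):
            dice(np.array([1, 2]), np.array([1, 3, 3])[:2] * 0 + 3, 3)


class TestGroupMaps:
    def test_identical_subjects(self):
        vol = np.array([[[1, 1, 2, 2, 3]]])
        freq, mpm = group_maps([vol, vol, vol], 3)
        np.testing.assert_array_equal(mpm, vol)
        assert set(np.unique(freq)) <= {0.0, 1.0}

    def test_majority_wins_and_tie_to_lower_label(self):
        base = np.array([[[1, 1, 2]]])
        variant = np.array([[[2, 1, 2]]])
        freq, mpm = group_maps([base, base, variant], 3)
        assert mpm[0, 0, 0] == 1  # majority 2 vs 1
        # tie: two subjects say 1, two say 2 at one voxel
        _, mpm2 = group_maps([base, base, variant, variant], 3)
        assert mpm2[0, 0, 0] == 1  # tie broken to the lower label

    def test_background_stays_zero(self):
        vol = np.array([[[0, 1, 2]]])
        _, mpm = group_maps([vol], 2)
        assert mpm[0, 0, 0] == 0


class TestFisherZ:
    def test_anchors(self):
        assert fisher_z(0.0) == pytest.approx(0.0)
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0))
        assert np.isfinite(fisher_z(1.0))  # clipped, not infinite

    def test_parcel_region_fc_table(self):
        rng = np.random.default_rng(4)
        t = 80
        shared = rng.standard_normal(t)
        roi_ts = np.vstack([shared + 0.01 * rng.standard_normal(t) for _ in range(4)])
        labels = np.array([1, 1, 2, 2])
        regions = {
            "copy": np.vstack([shared] * 5),  # r ~ 1 -> z finite via clipping
            "noise": rng.standard_normal((6, t)),
            "tiny": rng.standard_normal((2, t)),  # below min voxel count
        }
        tab = parcel_region_fc(roi_ts, labels, regions, min_region_voxels=5)
        assert set(tab["region"]) == {"copy", "noise"}
        z_copy = tab[tab["region"] == "copy"]["z"]
        assert np.isfinite(z_copy).all() and (z_copy > 3).all()


class TestGroupFcTest:
    def make_tables(self, z_matrix):
        tables = []
        for srow in z_matrix:
            tables.append(
                pd.DataFrame(
                    {
                        "parcel": 1,
                        "region": [f"r{i}" for i in range(len(srow))],
                        "r": np.tanh(srow),
                        "z": srow,
                    }
                )
            )
        return tables

    def test_all_zero_not_significant_and_zero_variance_excluded(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1e-6, size=(6, 4))
        z[:, 0] = 0.7  # constant across subjects -> zero variance -> excluded
        out = group_fc_test(self.make_tables(z))
        assert "r0" not in set(out["region"])
        assert not out["significant"].any()

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(6)
        z = rng.normal(0, 0.1, size=(12, 5))
        z[:, 2] += 1.5
        out = group_fc_test(self.make_tables(z))
        sig = out[out["significant"]]
        assert "r2" in set(sig["region"])
        # group z carries the sign of the effect
        assert out[out["region"] == "r2"]["z_group"].iloc[0] > 0

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            group_fc_test(self.make_tables(np.zeros((2, 3))))


class TestAgeRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(7)
        age = rng.uniform(20, 50, 30)
        sex = rng.integers(0, 2, 30).astype(float)
        fc = -0.02 * age
        fit = age_regression(fc, age, sex)
        assert fit.beta1 == pytest.approx(-0.02, abs=1e-10)
        assert abs(fit.r_age) == pytest.approx(1.0, abs=1e-9)

    def test_pure_sex_effect_leaves_no_age_correlation(self):
        rng = np.random.default_rng(8)
        m = 24
        rs = []
        for _ in range(300):
            age = rng.uniform(20, 50, m)
            sex = rng.integers(0, 2, m).astype(float)
            fc = 0.8 * sex + 0.3 * rng.standard_normal(m)
            rs.append(age_regression(fc, age, sex).r_age)
        assert np.mean(np.abs(rs)) < 2 / np.sqrt(m)

    def test_matches_normal_equations_oracle(self):
        age = np.array([20.0, 25.0, 30.0, 35.0, 40.0, 45.0])
        sex = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        fc = np.array([0.5, 0.45, 0.42, 0.40, 0.33, 0.31])
        X = np.column_stack([np.ones(6), age, sex])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ fc)
        fit = age_regression(fc, age, sex)
        assert fit.beta0 == pytest.approx(beta_oracle[0], abs=1e-10)
        assert fit.beta1 == pytest.approx(beta_oracle[1], abs=1e-10)
        assert fit.beta2 == pytest.approx(beta_oracle[2], abs=1e-10)
        # residuals orthogonal to the design columns
        assert np.allclose(X.T @ fit.residuals, 0, atol=1e-9)

    def test_literal_adjustment_is_pure_age_component(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(20, 50, 20)
        sex = rng.integers(0, 2, 20).astype(float)
        fc = 0.1 - 0.01 * age + 0.2 * sex + 0.05 * rng.standard_normal(20)
        fit = age_regression(fc, age, sex, subtract_residuals=True)
        np.testing.assert_allclose(fit.fc_adjusted, fit.beta0 + fit.beta1 * age, atol=1e-10)
        assert abs(fit.r_age) == pytest.approx(1.0, abs=1e-9)

    def test_single_sex_drops_covariate(self):
        rng = np.random.default_rng(10)
        age = rng.uniform(20, 50, 10)
        sex = np.zeros(10)
        fc = -0.01 * age + 0.01 * rng.standard_normal(10)
        fit = age_regression(fc, age, sex)
        assert np.isnan(fit.beta2)
        assert fit.beta1 < 0
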