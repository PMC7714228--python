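import numpy as np
import pytest

from conftest import toy_model
from emgsynergy.errors import DegenerateDataError
from emgsynergy.synergy_typing import (SynergyFeature, assign_patient_synergy,
                                       build_features, cluster_features,
                                       corr_distance, mean_silhouette,
                                       per_synergy_variance,
                                       representative_movements,
                                       _corr_dist_matrix)


def zprofile(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std()


def planted_profiles(n_groups=3, per_group=8, n_mov=17, seed=0, noise=0.05):
    """Groups of mutually correlated z-profiles around distinct archetypes."""
    rng = np.random.default_rng(seed)
    archetypes = []
    for g in range(n_groups):
        a = rng.uniform(0, 0.1, n_mov)
        a[g::n_groups] = rng.uniform(0.8, 1.0, len(a[g::n_groups]))
        archetypes.append(a)
    profiles, labels = [], []
    for g, a in enumerate(archetypes):
        for _ in range(per_group):
            profiles.append(zprofile(a + rng.normal(0, noise, n_mov)))
            labels.append(g)
    return np.array(profiles), np.array(labels)


class TestCorrDistance:
    def test_identical_vectors_have_distance_zero(self):
        u = np.array([1.0, 2.0, 5.0])
        assert corr_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_have_distance_two(self):
        u = np.array([1.0, 2.0, 5.0])
        assert corr_distance(u, -u) == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_value(self):
        d = corr_distance(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert d == pytest.approx(1 - 0.9819805, abs=1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            corr_distance(np.ones(3), np.array([1.0, 2, 3]))


class TestBuildFeatures:
    def test_toy_profile_arithmetic(self):
        model = toy_model(W=[[1.0], [1.0]], H=[[1.0, 1.0, 2.0, 2.0]])
        feats = build_features(model, [1, 1, 2, 2], movement_list=(1, 2))
        np.testing.assert_allclose(feats[0].profile, [-1.0, 1.0], atol=1e-12)

    def test_profiles_are_z_scored(self, rng):
        H = rng.random((3, 170)) + 0.05
        W = rng.random((5, 3)) + 0.05
        labels = np.repeat(np.arange(1, 18), 10)
        feats = build_features(toy_model(W, H), labels)
        for f in feats:
            assert f.profile.mean() == pytest.approx(0.0, abs=1e-9)
            assert f.profile.std() == pytest.approx(1.0, abs=1e-9)

    def test_missing_movement_is_error(self):
        model = toy_model(W=[[1.0]], H=[[1.0, 2.0]])
        with pytest.raises(DegenerateDataError, match="movement 2"):
            build_features(model, [1, 1], movement_list=(1, 2))

    def test_constant_activation_is_untypable(self):
        model = toy_model(W=[[1.0]], H=[[3.0, 3.0, 3.0, 3.0]])
        with pytest.raises(DegenerateDataError, match="untypable"):
            build_features(model, [1, 1, 2, 2], movement_list=(1, 2))

    def test_variance_share_attached_when_envelope_given(self, rng):
        W = rng.random((4, 2)) + 0.1
        H = rng.random((2, 40)) + 0.1
        E = W @ H
        labels = np.repeat([1, 2], 20)
        feats = build_features(toy_model(W, H, E), labels,
                               movement_list=(1, 2), E=E)
        assert all(f.explained_variance_share is not None for f in feats)


class TestPerSynergyVariance:
    def test_single_synergy_share_equals_global_vaf(self, rng):
        W = rng.random((4, 1)) + 0.1
        H = rng.random((1, 30)) + 0.1
        E = W @ H + 0.01 * rng.random((4, 30))
        model = toy_model(W, H, E)
        assert per_synergy_variance(E, W, H, 0) == pytest.approx(
            model.global_vaf, abs=1e-9)

    def test_symmetric_block_synergies_have_equal_shares(self):
        # two synergies on disjoint channels and disjoint samples with
        # identical energy
        W = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        H = np.zeros((2, 20))
        H[0, :10] = 2.0
        H[1, 10:] = 2.0
        E = W @ H
        s0 = per_synergy_variance(E, W, H, 0)
        s1 = per_synergy_variance(E, W, H, 1)
        assert abs(s0 - s1) < 1.0

    def test_out_of_range_index_rejected(self, rng):
        W = rng.random((3, 2))
        H = rng.random((2, 5))
        with pytest.raises(IndexError):
            per_synergy_variance(W @ H, W, H, 2)


class TestClusterFeatures:
    def test_planted_groups_recovered_exactly(self):
        X, labels = planted_profiles(n_groups=3, per_group=8)
        model = cluster_features(X, k_range=range(2, 8), restarts=20, seed=0)
        assert model.n_clusters == 3
        # partition identical up to relabeling
        for g in range(3):
            assigned = model.assignment[labels == g]
            assert len(set(assigned.tolist())) == 1

    def test_duplicated_features_co_assigned_same_k(self):
        X, _ = planted_profiles(n_groups=3, per_group=5, seed=3)
        base = cluster_features(X, k_range=range(2, 6), restarts=20, seed=1)
        doubled = cluster_features(np.vstack([X, X]), k_range=range(2, 6),
                                   restarts=20, seed=1)
        assert doubled.n_clusters == base.n_clusters
        n = len(X)
        np.testing.assert_array_equal(doubled.assignment[:n],
                                      doubled.assignment[n:])

    def test_null_structure_has_no_clear_winner(self):
        rng = np.random.default_rng(42)
        X = np.array([zprofile(rng.normal(size=17)) for _ in range(40)])
        model = cluster_features(X, k_range=range(2, 10), restarts=10, seed=0)
        sil = np.array(sorted(model.silhouette_by_k.values()))
        assert sil.max() < 0.35          # flat/low curve
        assert sil[-1] - sil[-2] < 0.05  # no k wins decisively

    def test_feature_order_invariance_up_to_relabeling(self):
        X, _ = planted_profiles(n_groups=3, per_group=6, seed=7)
        perm = np.random.default_rng(1).permutation(len(X))
        a = cluster_features(X, k_range=range(2, 6), restarts=20, seed=5)
        b = cluster_features(X[perm], k_range=range(2, 6), restarts=20, seed=5)
        assert a.n_clusters == b.n_clusters
        # co-membership structure identical
        unpermuted = b.assignment[np.argsort(perm)]
        co_a = a.assignment[:, None] == a.assignment[None, :]
        co_b = unpermuted[:, None] == unpermuted[None, :]
        np.testing.assert_array_equal(co_a, co_b)

    def test_k_range_exceeding_sample_count_rejected(self):
        X, _ = planted_profiles(n_groups=2, per_group=3)
        with pytest.raises(ValueError, match="features"):
            cluster_features(X, k_range=range(2, 16))

    def test_silhouette_matches_sklearn_oracle(self):
        from sklearn.metrics import silhouette_score
        X, _ = planted_profiles(n_groups=4, per_group=8, seed=11, noise=0.4)
        D = _corr_dist_matrix(X, X)
        np.fill_diagonal(D, 0.0)
        labels = np.random.default_rng(2).integers(0, 4, size=len(X))
        ours = mean_silhouette(D, labels)
        theirs = silhouette_score(np.maximum(D, 0.0), labels,
                                  metric="precomputed")
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestRepresentativeMovements:
    def test_single_spike_centroid_primary_only(self):
        centroid = np.zeros(17)
        centroid[4] = 5.0  # movement id 5
        primary, secondary = representative_movements(centroid)
        assert primary == 5
        assert secondary is None

    def test_flat_centroid_has_no_representatives(self):
        assert representative_movements(np.ones(17)) == (None, None)

    def test_tie_broken_toward_lower_movement_id(self):
        centroid = np.zeros(17)
        centroid[6] = centroid[11] = 5.0
        primary, _ = representative_movements(centroid)
        assert primary == 7

    def test_secondary_requires_one_sd_margin(self):
        centroid = np.zeros(17)
        centroid[2] = 6.0
        centroid[9] = 3.0
        primary, secondary = representative_movements(centroid)
        assert primary == 3
        m, s = centroid.mean(), centroid.std()
        assert (secondary == 10) == (centroid[9] >= m + s)

    def test_invariant_to_shift_and_positive_rescale(self, rng):
        centroid = rng.normal(size=17)
        base = representative_movements(centroid)
        assert representative_movements(centroid + 3.7) == base
        assert representative_movements(centroid * 2.9) == base


class TestAssignPatientSynergy:
    @pytest.fixture()
    def fitted(self):
        X, _ = planted_profiles(n_groups=3, per_group=8, seed=5)
        model = cluster_features(X, k_range=range(2, 6), restarts=20, seed=0)
        return X, model

    def test_centroid_itself_assigns_with_zero_distance(self, fitted):
        _, model = fitted
        for j in range(model.n_clusters):
            assert assign_patient_synergy(model.centroids[j], model) == j + 1

    def test_anticorrelated_profile_is_untyped(self, fitted):
        _, model = fitted
        probe = zprofile(-model.centroids[0])
        assert assign_patient_synergy(probe, model) == 0

    def test_training_features_reassign_to_own_cluster(self, fitted):
        X, model = fitted
        for x, lab in zip(X, model.assignment):
            assert assign_patient_synergy(x, model) == lab

    def test_accepts_feature_objects(self, fitted):
        X, model = fitted
        f = SynergyFeature(profile=X[0], subject_id="p1", synergy_index=0)
        assert assign_patient_synergy(f, model) == model.assignment[0]
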