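import numpy as np
import pytest

from conftest import SMALL_PROTOCOL, TINY_PROTOCOL, make_pool
from emgsynergy import simulate
from emgsynergy.dimensionality import (compare_configurations, estimate_k,
                                       split_pool)
from emgsynergy.errors import DegenerateDataError
from emgsynergy.ninapro_io import EmgRecording, FOREARM10_ROLES, RING_ROLES
from emgsynergy.preprocess import PooledEnvelope, pool_movements


class TestSplitPool:
    def test_sizes_are_75_25(self, rng):
        E = rng.random((3, 100))
        sp = split_pool(E, seed=0)
        assert sp.extraction.shape == (3, 75)
        assert sp.validation.shape == (3, 25)

    def test_same_seed_gives_identical_partition(self, rng):
        E = rng.random((3, 40))
        a = split_pool(E, seed=9)
        b = split_pool(E, seed=9)
        np.testing.assert_array_equal(a.extraction_idx, b.extraction_idx)

    def test_parts_are_disjoint_and_exhaustive(self, rng):
        E = rng.random((2, 37))
        sp = split_pool(E, seed=3)
        merged = np.sort(np.concatenate([sp.extraction_idx, sp.validation_idx]))
        np.testing.assert_array_equal(merged, np.arange(37))

    def test_temporal_order_preserved_within_parts(self, rng):
        E = np.arange(30.0)[None, :]
        sp = split_pool(E, seed=1)
        assert (np.diff(sp.extraction[0]) > 0).all()

    def test_degenerate_pool_rejected(self):
        with pytest.raises(DegenerateDataError):
            split_pool(np.ones((2, 5)), seed=0)


def _noiseless_pool(k_true, seed=0, n=10):
    truth = simulate.make_ground_truth(n, k_true, seed=seed, noise_sd=0.0,
                                       protocol=SMALL_PROTOCOL)
    rec = simulate.synthesize(truth, seed=seed, carrier=False)
    return pool_movements(rec, keep_roles=rec.channel_roles)


class TestEstimateK:
    def test_noiseless_three_synergies_recovered(self):
        pool = _noiseless_pool(3, seed=4)
        res = estimate_k(pool, n_repeats=5, seed=0, k_max=5)
        assert res.chosen_k == 3
        assert not res.saturated
        assert res.criteria_met[2]
        # representable from rank 3 on: validation VAF saturates
        assert (res.per_k_global_vaf[2:] >= 99.9).all()
        assert not res.criteria_met[:2].any()

    def test_single_synergy_low_noise(self):
        truth = simulate.make_ground_truth(10, 1, seed=2, noise_sd=0.05,
                                           protocol=SMALL_PROTOCOL)
        rec = simulate.synthesize(truth, seed=2)
        from emgsynergy.preprocess import preprocess
        res = estimate_k(preprocess(rec), n_repeats=5, seed=0,
                         stop_when_met=True)
        assert res.chosen_k == 1

    def test_deterministic_under_master_seed(self):
        pool = _noiseless_pool(2, seed=6)
        a = estimate_k(pool, n_repeats=3, seed=5, k_max=3)
        b = estimate_k(pool, n_repeats=3, seed=5, k_max=3)
        assert a.chosen_k == b.chosen_k
        np.testing.assert_array_equal(a.per_k_global_vaf, b.per_k_global_vaf)

    def test_invariant_to_channel_order_and_global_rescaling(self):
        pool = _noiseless_pool(2, seed=8, n=8)
        base = estimate_k(pool, n_repeats=3, seed=1, k_max=4)
        perm = np.random.default_rng(0).permutation(pool.n_channels)
        shuffled = PooledEnvelope(
            E=pool.E[perm] * 3.0 / 3.0,  # reorder only; scale handled below
            movement_of_sample=pool.movement_of_sample,
            channel_roles=tuple(pool.channel_roles[i] for i in perm),
            channel_scale=pool.channel_scale[perm],
            envelope_rate=pool.envelope_rate,
        )
        assert estimate_k(shuffled, n_repeats=3, seed=1,
                          k_max=4).chosen_k == base.chosen_k
        scaled = PooledEnvelope(
            E=pool.E * 7.5,
            movement_of_sample=pool.movement_of_sample,
            channel_roles=pool.channel_roles,
            channel_scale=pool.channel_scale,
            envelope_rate=pool.envelope_rate,
        )
        assert estimate_k(scaled, n_repeats=3, seed=1,
                          k_max=4).chosen_k == base.chosen_k

    def test_validation_vaf_curve_non_decreasing_up_to_noise(self):
        _, pool = make_pool(k_true=3, seed=9, protocol=TINY_PROTOCOL)
        res = estimate_k(pool, n_repeats=5, seed=2, k_max=6)
        diffs = np.diff(res.per_k_global_vaf)
        assert (diffs >= -1.0).all()  # soft: sampling noise below 1 VAF point

    def test_saturation_flagged_when_no_rank_qualifies(self):
        _, pool = make_pool(k_true=3, seed=10, protocol=TINY_PROTOCOL)
        res = estimate_k(pool, n_repeats=2, seed=0, global_threshold=99.999,
                         local_threshold=99.9, k_max=4)
        assert res.saturated
        assert res.chosen_k == 4
        assert not res.criteria_met.any()

    def test_invalid_thresholds_rejected(self):
        _, pool = make_pool(k_true=2, seed=1, protocol=TINY_PROTOCOL)
        with pytest.raises(ValueError):
            estimate_k(pool, global_threshold=0.0)


class TestCompareConfigurations:
    def _recording_with_duplicate_extras(self, seed=0):
        # FDS/EDS columns literally duplicate two ring channels: they add
        # no dimensionality, so both electrode sets see the same rank
        truth = simulate.make_ground_truth(8, 3, seed=seed, noise_sd=0.0,
                                           protocol=TINY_PROTOCOL)
        rec = simulate.synthesize(truth, seed=seed)
        sig = np.column_stack([rec.signal, rec.signal[:, 0], rec.signal[:, 1]])
        return EmgRecording(signal=sig, sampling_rate=rec.sampling_rate,
                            movement_label=rec.movement_label,
                            repetition_label=rec.repetition_label,
                            channel_roles=FOREARM10_ROLES)

    def test_redundant_extra_channels_leave_rank_unchanged(self):
        rec = self._recording_with_duplicate_extras()
        res = compare_configurations(rec, ["ring8", "forearm10"],
                                     n_repeats=3, seed=0, stop_when_met=True)
        assert res["ring8"].chosen_k == res["forearm10"].chosen_k

    def test_independent_extra_source_raises_rank(self):
        # synergy 4 loads (almost) only on FDS/EDS: invisible to the ring
        truth = simulate.make_ground_truth(10, 4, seed=3, noise_sd=0.0,
                                           protocol=TINY_PROTOCOL)
        W = truth.W_true.copy()
        W[:, :3] *= np.array([1.0] * 8 + [0.02, 0.02])[:, None]
        W[:, 3] = np.array([0.02] * 8 + [1.0, 0.9])
        truth.W_true = W
        rec = simulate.synthesize(truth, seed=3)
        res = compare_configurations(rec, ["ring8", "forearm10"],
                                     n_repeats=3, seed=0, stop_when_met=True)
        assert res["forearm10"].chosen_k >= res["ring8"].chosen_k

    def test_identical_sets_give_identical_results(self):
        rec = self._recording_with_duplicate_extras(seed=5)
        res = compare_configurations(rec, {"a": RING_ROLES, "b": RING_ROLES},
                                     n_repeats=2, seed=4, stop_when_met=True)
        assert res["a"].chosen_k == res["b"].chosen_k
        np.testing.assert_array_equal(res["a"].per_k_global_vaf,
                                      res["b"].per_k_global_vaf)

    def test_empty_set_rejected(self):
        rec = self._recording_with_duplicate_extras(seed=6)
        with pytest.raises(ValueError, match="empty"):
            compare_configurations(rec, {"none": ()}, n_repeats=1)
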