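"""Discrete estimators against enumeration oracles, and their nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammaflow import infotheory as it
from gammaflow.validation import enumeration_oracle_cmi


class TestEquipopulatedBin:
    def test_small_example(self):
        ds = it.equipopulated_bin(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        np.testing.assert_array_equal(ds.symbols, [0, 0, 1, 1])

    def test_uniform_draws_fill_bins_equally(self, rng):
        ds = it.equipopulated_bin(rng.uniform(size=1000), 4)
        np.testing.assert_array_equal(np.bincount(ds.symbols.ravel()),
                                      [250, 250, 250, 250])

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            it.equipopulated_bin(np.ones(100), 3)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        g = np.random.default_rng(seed)
        x = g.standard_normal(97)
        a = it.equipopulated_bin(x, 3).symbols
        b = it.equipopulated_bin(np.exp(0.5 * x) + 2, 3).symbols
        np.testing.assert_array_equal(a, b)


class TestEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1], 2.0),
        ([5, 0, 0], 0.0),
        ([3, 1], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
    ])
    def test_closed_form(self, counts, expected):
        assert it.entropy(np.array(counts)) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            it.entropy(np.zeros(4))


class TestMutualInformation:
    def test_identity_response_four_classes(self):
        s = np.repeat(np.arange(4), 25)
        ds = it.DiscreteSeries(symbols=s.copy(), n_bins=4)
        est = it.mutual_information(ds, s, correction="none")
        assert est.value == pytest.approx(2.0, abs=1e-12)

    def test_plugin_against_closed_form_joint(self):
        # joint counts [[2, 1], [1, 2]]: MI = 0.0817 bits
        r = np.array([0, 0, 1, 0, 1, 1])
        s = np.array([0, 0, 0, 1, 1, 1])
        ds = it.DiscreteSeries(symbols=r, n_bins=2)
        est = it.mutual_information(ds, s, correction="none")
        assert est.value == pytest.approx(0.0817, abs=5e-5)

    def test_corrected_null_mi_near_zero(self):
        vals = []
        g = np.random.default_rng(0)
        for _ in range(200):
            r = g.standard_normal(200)
            s = g.integers(0, 4, size=200)
            vals.append(it.mutual_information(r, s, n_bins=4).value)
        assert abs(np.mean(vals)) < 0.02

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            it.mutual_information(np.arange(10.0), np.zeros(10), n_bins=2)

    def test_mi_bounded_by_marginal_entropies(self, rng):
        r = rng.integers(0, 3, size=500)
        s = (r + rng.integers(0, 2, size=500)) % 4
        ds = it.DiscreteSeries(symbols=r, n_bins=3)
        est = it.mutual_information(ds, s, correction="none")
        hr = it.entropy(np.bincount(r))
        hs = it.entropy(np.bincount(s))
        assert -1e-12 <= est.value <= min(hr, hs) + 1e-12


class TestConditionalEstimatorsAgainstEnumeration:
    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_plugin_cmi_matches_enumeration(self, seed):
        g = np.random.default_rng(seed)
        shape = tuple(g.integers(2, 5, size=3))
        counts = g.integers(0, 15, size=shape).astype(float)
        counts[0, 0, 0] += 1      # nonempty
        assert it._cmi_plugin_bits(counts) == pytest.approx(
            enumeration_oracle_cmi(counts), abs=1e-10)

    def test_deterministic_copy_gives_one_bit(self, rng):
        # X_t = Y_{t-1}, Y iid fair, X_past uninformative
        n_trials, n_time = 4, 2001
        y = np.stack([rng.permutation(np.tile([0.0, 1.0], n_time // 2 + 1)
                                      [:n_time]) for _ in range(n_trials)])
        x = np.roll(y, 1, axis=1)
        trip = it.embed_series(x, y, fs_hz=1000.0, lag_ms=1.0, step_ms=1.0)
        est = it.transfer_entropy(trip, n_bins=2, correction="none")
        assert est.value == pytest.approx(1.0, abs=0.02)

    def test_duplicated_conditioner_removes_all_information(self, rng):
        y = rng.standard_normal((3, 1500))
        x = np.roll(y, 1, axis=1) + 0.1 * rng.standard_normal((3, 1500))
        trip = it.embed_series(x, y, fs_hz=1000.0, lag_ms=1.0, z=y)
        est = it.lagged_conditional_information(trip, n_bins=3,
                                                correction="none")
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_te_nonnegative(self, rng):
        x = rng.standard_normal((3, 1000))
        y = rng.standard_normal((3, 1000))
        trip = it.embed_series(x, y, fs_hz=1000.0)
        assert it.transfer_entropy(trip, correction="none").value >= 0

    def test_lci_with_independent_conditioner_keeps_information(self, rng):
        # X_t fully determined by Y_past; conditioning on independent Z
        # leaves ~H(Y) = 1 bit
        n = 4000
        y = rng.integers(0, 2, size=(2, n)).astype(float)
        x = np.roll(y, 1, axis=1)
        z = rng.standard_normal((2, n))
        trip = it.embed_series(x, y, fs_hz=1000.0, lag_ms=1.0, z=z)
        est = it.lagged_conditional_information(trip, n_bins=2,
                                                correction="none")
        assert est.value > 0.9


class TestEmbedding:
    def test_pasts_precede_present_and_respect_trials(self, rng):
        x = np.arange(40.0).reshape(2, 20)
        trip = it.embed_series(x, x, fs_hz=1000.0, lag_ms=5.0, step_ms=1.0)
        np.testing.assert_array_equal(trip.x_t - trip.x_past, 5.0)
        assert trip.x_t.shape[0] == 2

    def test_time_mask_blocks_straddling_windows(self):
        x = np.arange(30.0)[None, :]
        mask = np.ones(30, bool)
        mask[10] = False
        trip = it.embed_series(x, x, fs_hz=1000.0, lag_ms=4.0, step_ms=1.0,
                               time_mask=mask)
        # no embedding window [t-4, t] may contain sample 10
        assert not np.any((trip.x_t >= 10) & (trip.x_past <= 10))


class TestBootstrapNull:
    def test_independent_series_z_small(self, rng):
        x = rng.standard_normal((8, 2000))
        y = rng.standard_normal((8, 2000))
        trip = it.embed_series(x, y, fs_hz=1000.0)
        est = it.bootstrap_null_zscore(trip, rng=rng)
        assert abs(est.z) < 3

    def test_coupled_series_z_large(self, rng):
        y = rng.standard_normal((8, 2000))
        x = np.roll(y, 10, axis=1) + 0.5 * rng.standard_normal((8, 2000))
        trip = it.embed_series(x, y, fs_hz=1000.0, lag_ms=10.0)
        est = it.bootstrap_null_zscore(trip, rng=rng)
        assert est.z > 5

    def test_single_trial_rejected(self, rng):
        trip = it.embed_series(rng.standard_normal((1, 500)),
                               rng.standard_normal((1, 500)), fs_hz=1000.0)
        with pytest.raises(ValueError):
            it.bootstrap_null_zscore(trip, rng=rng)

    def test_derangement_has_no_fixed_points(self, rng):
        for n in (2, 3, 5, 8):
            p = it._derangement(n, rng)
            assert not np.any(p == np.arange(n))
            assert sorted(p) == list(range(n))


class TestGroupSignificance:
    def test_positive_units_detected_null_units_not(self, rng):
        pos = rng.normal(4.0, 1.0, size=(10, 8))
        nul = rng.normal(0.0, 1.0, size=(10, 8))
        out = it.group_significance(np.vstack([pos, nul]), q=0.05)
        assert out["significant"][:10].all()
        assert out["significant"][10:].sum() <= 2
        assert 0.5 <= out["fraction_significant"] <= 0.6

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            it.group_significance(np.zeros((3, 1)))


class TestSensoryInformation:
    def test_scene_index_response_is_two_bits(self):
        n_trials, n_scenes, L = 8, 4, 300
        resp = np.repeat(np.arange(n_scenes)[None, :], n_trials, axis=0)
        resp = np.repeat(resp, L, axis=1).astype(float)
        est = it.sensory_information(resp, fs_hz=1000.0, correction="none",
                                     n_boot=20,
                                     rng=np.random.default_rng(0))
        assert est.value == pytest.approx(2.0, abs=1e-9)
        assert est.z > 3

    def test_constant_response_guarded_to_zero(self):
        resp = np.ones((4, 1200))
        est = it.sensory_information(resp, fs_hz=1000.0)
        assert est.value == 0.0 and "constant-response" in est.flags

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            it.sensory_information(np.zeros((1, 1200)), fs_hz=1000.0)
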