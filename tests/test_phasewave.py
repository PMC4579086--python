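"""Phase shifts, pair classification, blocks, geometry and wave speed."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gammaflow import phasewave as pw
from gammaflow.synth import wrap_phase


class TestPhaseShift:
    def test_sender_leading_is_positive(self):
        ps = np.full((1, 10), np.deg2rad(30.0))
        pr = np.zeros((1, 10))
        s = pw.phase_shift(ps, pr)
        assert np.allclose(np.rad2deg(s.shift), 30.0)
        assert s.mean_shift == pytest.approx(np.deg2rad(30.0))

    def test_wraps_to_short_way_around(self):
        s = pw.phase_shift(np.full((1, 4), np.deg2rad(170.0)),
                           np.full((1, 4), np.deg2rad(-170.0)))
        assert np.allclose(np.rad2deg(s.shift), -20.0)

    def test_equal_phases_zero(self):
        a = np.linspace(-3, 3, 50)[None, :]
        s = pw.phase_shift(a, a)
        assert np.allclose(s.shift, 0.0)
        assert s.plv == pytest.approx(1.0)

    def test_antisymmetry_mod_2pi(self, rng):
        a = rng.uniform(-np.pi, np.pi, size=(3, 200))
        b = rng.uniform(-np.pi, np.pi, size=(3, 200))
        fwd = pw.phase_shift(a, b).shift
        rev = pw.phase_shift(b, a).shift
        assert np.allclose(wrap_phase(fwd + rev), 0.0, atol=1e-12)


class TestRayleigh:
    def test_identical_angles_highly_significant(self):
        _, p = pw.rayleigh_test(np.full(50, 0.3))
        assert p < 1e-6

    def test_uniform_angles_rarely_rejected(self, rng):
        rejections = sum(
            pw.rayleigh_test(rng.uniform(-np.pi, np.pi, 1000))[1] < 0.01
            for _ in range(100))
        assert rejections <= 5

    def test_von_mises_power(self, rng):
        rejections = sum(
            pw.rayleigh_test(rng.vonmises(0.0, 1.0, 100))[1] < 0.01
            for _ in range(50))
        assert rejections > 45

    def test_too_few_angles_raise(self):
        with pytest.raises(ValueError):
            pw.rayleigh_test(np.zeros(5))


class TestAsymmetryAndClassification:
    @pytest.mark.parametrize("tab,tba,expected", [
        (5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (8.0, 4.0, 0.5)])
    def test_asymmetry_index_arithmetic(self, tab, tba, expected):
        assert pw.asymmetry_index(tab, tba) == pytest.approx(expected)

    def test_asymmetry_undefined_when_both_nonpositive(self):
        assert np.isnan(pw.asymmetry_index(-1.0, 0.0))

    def _table(self, values):
        rows = []
        for i, (tab, tba) in enumerate(values):
            rows.append({"sender": 2 * i, "receiver": 2 * i + 1,
                         "te_z": tab})
            rows.append({"sender": 2 * i + 1, "receiver": 2 * i,
                         "te_z": tba})
        return pd.DataFrame(rows)

    def test_rule_arithmetic(self):
        # pairs well above the exclusion floor
        table = self._table([(10, 0.5), (6, 5.5), (8, 4), (12, 11),
                             (9, 0.6), (0.1, 0.05)])
        out = pw.classify_pairs(table)
        cat = dict(zip(zip(out.a, out.b), out.category))
        assert cat[(0, 1)] == "strongly_asymmetric"     # ratio 20
        assert cat[(2, 3)] == "symmetric"               # rel diff 8.3%
        assert cat[(4, 5)] == "other"
        assert cat[(6, 7)] == "symmetric"
        assert cat[(10, 11)] == "excluded_low_TE"
        lead = out[(out.a == 0)].iloc[0]
        assert (lead.leading_sender, lead.leading_receiver) == (0, 1)

    def test_identical_te_all_symmetric(self):
        table = self._table([(5, 5)] * 6)
        out = pw.classify_pairs(table)
        assert (out.category == "symmetric").all()

    def test_few_pairs_warn_and_skip(self):
        table = self._table([(5, 1), (4, 2)])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = pw.classify_pairs(table)
        assert any("fewer than 5" in str(x.message) for x in w)
        assert (out.category == "unclassified").all()

    def test_invariant_to_pair_order(self):
        t1 = self._table([(10, 0.5), (6, 5.5), (8, 4), (12, 11), (9, 0.6)])
        t2 = t1.rename(columns={"sender": "receiver",
                                "receiver": "sender"})
        o1 = pw.classify_pairs(t1)
        o2 = pw.classify_pairs(t2)
        pd.testing.assert_series_equal(o1.category, o2.category)


class TestShiftCausationCorrelation:
    def test_monotone_relation_gives_rho_one(self):
        te = np.linspace(1, 10, 12)
        shift = np.tanh(te / 5)
        rho, p = pw.correlate_shift_causation(shift, te)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_permuted_null_centred_on_zero(self, rng):
        te = np.linspace(1, 10, 20)
        rhos = [pw.correlate_shift_causation(rng.permutation(te), te)[0]
                for _ in range(200)]
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_or_constant_raise(self):
        with pytest.raises(ValueError):
            pw.correlate_shift_causation(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            pw.correlate_shift_causation(np.ones(12), np.arange(12.0))


class TestBlocks:
    def test_all_positive_single_block(self):
        shift = np.full((3, 1000), 0.5)
        seg = pw.segment_blocks(shift, 1000.0)
        assert seg.blocks == [(0, 1000, 1)]

    def test_fast_alternation_yields_no_blocks(self):
        sign = np.tile(np.repeat([1.0, -1.0], 100), 5)
        shift = np.tile(sign, (3, 1))
        seg = pw.segment_blocks(shift, 1000.0, min_ms=300)
        assert seg.blocks == []

    def test_majority_vote_bookkeeping(self):
        n = 800
        shift = np.zeros((3, n))
        shift[0, :400] = shift[1, :400] = 1.0
        shift[2, :400] = -1.0
        shift[0, 400:] = shift[1, 400:] = -1.0
        shift[2, 400:] = 1.0
        seg = pw.segment_blocks(shift, 1000.0, min_ms=300)
        assert seg.blocks == [(0, 400, 1), (400, 800, -1)]

    def test_exact_ties_break_runs(self):
        shift = np.ones((4, 900))
        shift[:2, 400:500] = -1.0          # 2 vs 2: tie, unlabeled
        seg = pw.segment_blocks(shift, 1000.0, min_ms=300)
        assert seg.blocks == [(0, 400, 1), (500, 900, 1)]

    def test_balanced_durations_within_ten_percent(self, rng):
        shift = np.zeros((3, 6000))
        sign = np.repeat(rng.choice([1.0, -1.0], size=12,
                                    p=[0.75, 0.25]), 500)
        shift[:] = sign
        seg = pw.segment_blocks(shift, 1000.0)
        balanced = pw._balance_blocks(seg, rng)
        dur = {s: sum(e - b for b, e in balanced[s]) for s in (+1, -1)}
        if dur[+1] and dur[-1]:
            assert abs(dur[+1] - dur[-1]) / max(dur.values()) <= 0.1


class TestGeometry:
    positions = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0], [0.0, 4.0]])

    def test_receiver_at_origin(self):
        assert pw.projected_distance(self.positions, 0, 1, 1) == 0.0

    def test_sender_at_minus_spacing(self):
        assert pw.projected_distance(self.positions, 0, 1, 0) == -2.0

    def test_off_axis_candidate_excluded(self):
        # electrode at 90 degrees from the 0->1 axis
        assert pw.projected_distance(self.positions, 0, 1, 3) is None

    def test_upstream_beyond_sender_included(self):
        pos = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        assert pw.projected_distance(pos, 1, 2, 0) == -4.0

    def test_zero_axis_raises(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            pw.projected_distance(pos, 0, 1, 0)


class TestWaveSpeed:
    def test_slope_to_speed_arithmetic(self):
        d = np.array([-4.0, -3.0, -2.0, -1.0, 0.0])
        samples = np.column_stack([d, -1.134 * d])
        fit = pw.wave_speed(samples, 65.0)
        assert fit.speed_m_per_s == pytest.approx(0.36, rel=0.01)
        assert fit.slope_rad_per_mm == pytest.approx(-1.134, rel=0.01)

    def test_wrapped_profile_recovered(self):
        # true slope -1.134 rad/mm with shifts wrapped into (-pi, pi]
        d = np.array([-6.0, -4.0, -2.0, 0.0])
        samples = np.column_stack([d, wrap_phase(-1.134 * d)])
        fit = pw.wave_speed(samples, 65.0, max_slope_rad_per_mm=np.pi / 2)
        assert fit.speed_m_per_s == pytest.approx(0.36, rel=0.02)

    def test_zero_gradient_flags_infinite_speed(self):
        d = np.array([-3.0, -2.0, -1.0, 0.0])
        fit = pw.wave_speed(np.column_stack([d, np.zeros(4)]), 65.0)
        assert np.isinf(fit.speed_m_per_s)
        assert "near-synchronous" in fit.flags

    def test_too_few_distances_raise(self):
        d = np.array([-1.0, -1.0, 0.0])
        with pytest.raises(ValueError):
            pw.wave_speed(np.column_stack([d, d]), 65.0)

    def test_noiseless_planted_wave_slope_matches_k(self):
        import gammaflow as gf
        from gammaflow.synth import generate_wave_field
        cfg = gf.SyntheticConfig(n_rows=1, n_cols=4, spacing_mm=1.0,
                                 n_trials=2, n_scenes=4, phase_noise_sd=0.0,
                                 trial_phase_offset=False,
                                 direction_schedule=0.0, seed=0)
        phi = generate_wave_field(cfg)
        mean_shift = pw.pairwise_mean_shift(phi)
        # profile relative to the most downstream electrode (index 3)
        d = np.array([-3.0, -2.0, -1.0, 0.0])
        shifts = np.array([mean_shift[e, 3] for e in range(4)])
        fit = pw.wave_speed(np.column_stack([d, shifts]), 65.0,
                            max_slope_rad_per_mm=np.pi)
        k = 2 * np.pi * 65.0 / (1000.0 * 0.36)
        assert abs(fit.slope_rad_per_mm) == pytest.approx(k, rel=0.05)

    def test_speed_invariant_to_global_phase_constant(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=(2, 4, 300))
        m1 = pw.pairwise_mean_shift(phi)
        m2 = pw.pairwise_mean_shift(wrap_phase(phi + 1.23))
        np.testing.assert_allclose(wrap_phase(m1 - m2), 0.0, atol=1e-9)


class TestWaveProfile:
    def test_reanchors_to_minimum_shift_receiver(self):
        positions = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0],
                              [6.0, 0.0]])
        classified = pd.DataFrame([
            {"category": "strongly_asymmetric", "leading_sender": 0,
             "leading_receiver": 2},
            {"category": "strongly_asymmetric", "leading_sender": 3,
             "leading_receiver": 1},
        ])
        # electrode 1 (a strongly asymmetric receiver) lags receiver 2
        mean_shift = np.zeros((4, 4))
        mean_shift[1, 2] = -0.4
        mean_shift[0, 2] = 1.0
        profiles = pw.collect_wave_profile(positions, classified,
                                           mean_shift)
        prof = {d: s for d, s in profiles[0]}
        # origin re-anchored at electrode 1: its sample sits at (0, 0)
        assert prof[0.0] == pytest.approx(0.0)
        # old receiver now at +2 mm with shift +0.4
        assert prof[2.0] == pytest.approx(0.4)
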