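"""QC, normalization, time grid, and ensemble construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emgait import (
    PopulationConfig,
    StrideMatrix,
    build_ensemble,
    build_stride_matrices,
    detect_outlier_strides,
    generate_population,
    normalize_amplitude,
    pool_strides,
    select_strides_by_velocity,
    time_normalize,
)
from emgait.pipeline import condition_and_segment
from emgait.ensemble import INTER_SUBJECT, RVC, N_POINTS
from emgait.events import Stride


def matrix_from(values, scope="intra_session", muscle="m", side="left", horse="h", session="s1"):
    values = np.atleast_2d(values)
    idx = [(horse, session, i) for i in range(values.shape[0])]
    return StrideMatrix(muscle, side, scope, values, idx)


class TestOutliers:
    def test_tukey_fences_flag_single_spike(self):
        flags = detect_outlier_strides([1.0, 1.1, 0.9, 1.05, 5.0])
        assert flags.tolist() == [False, False, False, False, True]

    def test_identical_peaks_unflagged(self):
        assert not detect_outlier_strides([2.0] * 6).any()

    def test_too_few_strides_warns_and_skips(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            flags = detect_outlier_strides([1.0, 1.0, 50.0])
        assert not flags.any()

    def test_synthetic_outlier_recovery(self):
        """Through the real conditioning chain, the peak screen flags ≥ 90%
        of truth-outlier strides (3.5× amplitude inflation) with ≤ 5% false
        flags.  Per-stride peaks are read at the ground-truth stride
        boundaries so each peak maps 1:1 onto a truth flag."""
        cfg = PopulationConfig(
            n_horses=3, n_sessions=1, strides_per_trial=30, outlier_rate=0.1, seed=13
        )
        tp = fn = fp = tn = 0
        for rec in generate_population(cfg):
            env, _ = condition_and_segment(rec)
            truth = rec.truth
            edges = truth.impact_times[::2]
            n_strides = len(edges) - 1
            for ch in rec.channels:
                peaks = [
                    env[ch][int(np.ceil(edges[k] * rec.emg_rate)):int(np.ceil(edges[k + 1] * rec.emg_rate))].max()
                    for k in range(n_strides)
                ]
                flags = detect_outlier_strides(peaks)
                for f, o in zip(flags, truth.outlier_flags[:n_strides]):
                    tp += f and o
                    fn += (not f) and o
                    fp += f and not o
                    tn += (not f) and not o
        assert tp / max(tp + fn, 1) >= 0.90
        assert fp / max(fp + tn, 1) <= 0.05


class TestVelocitySelection:
    def _strides(self, velocities):
        return [
            Stride(i * 1.0, i * 1.0 + 0.75, "left_hind", velocity=v, index=i)
            for i, v in enumerate(velocities)
        ]

    def test_drops_largest_deviations_from_single_mean(self):
        """Velocities (3.0, 3.1, 3.2, 2.0), target 2: mean 2.825, so the two
        smallest deviations (3.0, 3.1) survive."""
        kept = select_strides_by_velocity(self._strides([3.0, 3.1, 3.2, 2.0]), target_n=2)
        assert [s.velocity for s in kept] == [3.0, 3.1]

    def test_identity_when_nothing_to_drop(self):
        strides = self._strides([3.0] * 10)
        assert select_strides_by_velocity(strides, target_n=10) == strides

    def test_tie_break_keeps_earlier_strides(self):
        kept = select_strides_by_velocity(self._strides([3.0] * 5), target_n=3)
        assert [s.index for s in kept] == [0, 1, 2]

    def test_underfull_returns_all_with_warning(self):
        strides = self._strides([3.0, 3.1])
        with pytest.warns(UserWarning, match="fewer than target"):
            assert select_strides_by_velocity(strides, target_n=10) == strides


class TestNormalize:
    def test_global_max_becomes_one(self):
        segs = [np.array([0.5, 2.4, 1.0]), np.array([0.1, 0.2, 0.3])]
        out = normalize_amplitude(segs, RVC(value=2.4))
        assert max(s.max() for s in out) == pytest.approx(1.0)

    def test_nonpositive_rvc_rejected(self):
        with pytest.raises(ValueError, match="RVC"):
            RVC(value=0.0)


class TestTimeNormalize:
    def test_linear_ramp_hits_grid_exactly(self):
        out = time_normalize(np.linspace(0.0, 1.0, 1500))
        assert np.allclose(out, np.arange(101) / 100.0, atol=1e-12)

    def test_identity_on_101_grid(self):
        x = np.sin(np.linspace(0, 3, 101))
        assert np.allclose(time_normalize(x), x, atol=1e-14)

    def test_sine_interpolation_error_small(self):
        n = 1500
        seg = np.sin(2 * np.pi * np.arange(n) / (n - 1))
        out = time_normalize(seg)
        exact = np.sin(2 * np.pi * np.arange(101) / 100.0)
        assert np.max(np.abs(out - exact)) < 1e-4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_normalize(np.array([1.0]))


class TestBuildEnsemble:
    def test_two_constant_rows(self):
        prof = build_ensemble(matrix_from([np.ones(101), 3 * np.ones(101)]))
        assert np.allclose(prof.mean_curve, 2.0)
        assert np.allclose(prof.sd_curve, np.sqrt(2.0))
        assert prof.n_strides == 2

    def test_identical_rows_zero_sd(self):
        row = np.linspace(0, 1, 101)
        prof = build_ensemble(matrix_from([row, row, row]))
        assert np.allclose(prof.sd_curve, 0.0)

    def test_matches_bruteforce_columns(self, rng):
        vals = rng.random((10, 101))
        prof = build_ensemble(matrix_from(vals))
        for i in range(101):
            col = vals[:, i]
            assert prof.mean_curve[i] == pytest.approx(col.mean(), abs=1e-12)
            assert prof.sd_curve[i] == pytest.approx(col.std(ddof=1), abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (5, 101), elements=st.floats(0, 1)))
    def test_commutes_with_row_permutation(self, vals):
        rng = np.random.default_rng(0)
        perm = rng.permutation(vals.shape[0])
        a = build_ensemble(matrix_from(vals))
        b = build_ensemble(matrix_from(vals[perm]))
        assert np.allclose(a.mean_curve, b.mean_curve)
        assert np.allclose(a.sd_curve, b.sd_curve)

    def test_single_row_mean_only(self):
        with pytest.warns(UserWarning, match="single stride"):
            prof = build_ensemble(matrix_from(np.ones(101)))
        assert prof.sd_curve is None


class TestPooling:
    def test_eight_horses_make_eighty_rows(self):
        ms = [matrix_from(np.random.default_rng(i).random((10, 101)), horse=f"h{i}") for i in range(8)]
        pooled = pool_strides(ms, INTER_SUBJECT)
        assert pooled.n_strides == 80
        assert pooled.scope == INTER_SUBJECT

    def test_two_sessions_concatenate(self):
        a = matrix_from(np.zeros((10, 101)), session="s1")
        b = matrix_from(np.ones((8, 101)), session="s2")
        pooled = pool_strides([a, b], "between_session")
        assert pooled.n_strides == 18
        assert [i[1] for i in pooled.stride_index[:10]] == ["s1"] * 10

    def test_single_matrix_identity_up_to_scope(self):
        m = matrix_from(np.random.default_rng(0).random((4, 101)))
        pooled = pool_strides([m], INTER_SUBJECT)
        assert np.array_equal(pooled.values, m.values)
        assert pooled.scope == INTER_SUBJECT

    def test_muscle_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cannot pool"):
            pool_strides([matrix_from(np.zeros((2, 101)), muscle="a"),
                          matrix_from(np.zeros((2, 101)), muscle="b")], "x")

    def test_column_count_enforced(self):
        with pytest.raises(ValueError, match="101"):
            matrix_from(np.zeros((2, 100)))


class TestChainOrder:
    def test_full_qc_chain_contracts(self):
        """After the outlier → RVC → normalize → select chain: exactly
        min(target_n, available) strides per matrix, all values ≤ 1 + tol,
        and with selection disabled (large target) the per-session max is
        exactly 1 — the RVC-defining sample."""
        cfg = PopulationConfig(n_horses=1, n_sessions=1, strides_per_trial=14, seed=17)
        rec = generate_population(cfg)[0]
        env, strides_by_side = condition_and_segment(rec)
        matrices, qc = build_stride_matrices(
            env, rec.emg_rate, strides_by_side, rec.channel_map,
            rec.horse_id, rec.session_id, target_n=10,
        )
        for ch, m in matrices.items():
            assert m.n_strides == 10
            assert m.values.shape[1] == N_POINTS
            assert m.values.max() <= 1.0 + 1e-9
            # the RVC-defining sample of the included strides is exactly 1
            assert qc["channels"][ch]["norm_peak_max"] == pytest.approx(1.0, abs=1e-12)

    def test_outlier_stride_excluded_before_rvc(self):
        """A stride peaking at 5× is excluded from the matrix and from the
        RVC, so surviving maxima still reach 1."""
        cfg = PopulationConfig(
            n_horses=1, n_sessions=1, strides_per_trial=14, outlier_rate=0.0, seed=19
        )
        rec = generate_population(cfg)[0]
        env, strides_by_side = condition_and_segment(rec)
        ch = "mono_burst_left"
        # inject a synthetic 5x amplitude stride into the envelope
        s = strides_by_side["left"][4]
        i0 = int(np.ceil(s.start_time * rec.emg_rate))
        i1 = int(np.ceil(s.end_time * rec.emg_rate))
        env[ch] = env[ch].copy()
        env[ch][i0:i1] *= 5.0
        matrices, qc = build_stride_matrices(
            env, rec.emg_rate, strides_by_side, rec.channel_map,
            rec.horse_id, rec.session_id, target_n=10_000,
        )
        assert qc["channels"][ch]["outliers_removed"] >= 1
        assert (rec.horse_id, rec.session_id, 4) not in matrices[ch].stride_index
        assert qc["channels"][ch]["norm_peak_max"] == pytest.approx(1.0, abs=1e-12)
        assert matrices[ch].values.max() <= 1.0 + 1e-9
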