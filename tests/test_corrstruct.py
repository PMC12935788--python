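"""Delay-embedded correlation matrices and eigenspectra."""

import numpy as np
import pytest

from vococoord.corrstruct import (
    ComboSpec,
    CorrelationMatrix,
    build_delay_matrix,
    cross_correlation,
    eigenspectrum,
    resample_to_grid,
    spectrum_flatness,
)
from vococoord.errors import (
    InsufficientOverlapError,
    InvalidMatrixError,
    InvalidSpecError,
    MissingChannelError,
    UndefinedCorrelationError,
    UndefinedSpectrumError,
)
from vococoord.types import FeatureTrajectory, RecordingFeatures

from .oracles import brute_cross_correlation, brute_delay_matrix


def _rec(channels_arrays, rate=100.0, masks=None):
    channels = {}
    for i, vals in enumerate(channels_arrays):
        name = f"c{i + 1}"
        mask = None if masks is None else masks[i]
        channels[name] = FeatureTrajectory(name=name, values=vals, rate_hz=rate, mask=mask)
    return RecordingFeatures(
        recording_id="r", subject_id="s", category="A",
        duration_s=len(channels_arrays[0]) / rate, channels=channels,
    )


def _combo(n, D=15, name="t"):
    return ComboSpec(name, tuple(f"c{i + 1}" for i in range(n)), n_delays=D,
                     mask_policy="none")


class TestCrossCorrelation:
    def test_identity_at_zero_lag(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(300)
        assert cross_correlation(a, a, lag=0) == pytest.approx(1.0, abs=1e-12)

    def test_shifted_sinusoid_recovers_at_matching_lag(self):
        t = np.arange(400) / 100.0
        a = np.sin(2 * np.pi * 2.0 * t)
        k = 7
        b = np.concatenate([np.zeros(k), a])[:400]  # a delayed by k frames
        mask_b = np.ones(400, dtype=bool)
        mask_b[:k] = False  # exclude the zero-padded edge
        assert cross_correlation(a, b, lag=k, mask_b=mask_b) >= 0.99

    @pytest.mark.parametrize("lag", [-5, -1, 0, 1, 3, 8])
    def test_matches_brute_force_with_masks(self, lag):
        rng = np.random.default_rng(lag + 100)
        a = rng.standard_normal(180)
        b = rng.standard_normal(180)
        ma = rng.random(180) > 0.2
        mb = rng.random(180) > 0.2
        expected, n = brute_cross_correlation(a, b, ma, mb, lag)
        got = cross_correlation(a, b, lag=lag, mask_a=ma, mask_b=mb)
        assert n >= 25
        assert got == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_raises(self):
        a = np.arange(30.0)
        mask = np.zeros(30, dtype=bool)
        mask[:5] = True
        with pytest.raises(InsufficientOverlapError):
            cross_correlation(a, a, lag=0, mask_a=mask, mask_b=mask)

    def test_zero_variance_raises(self):
        a = np.ones(100)
        b = np.arange(100.0)
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation(a, b, lag=0)


class TestComboSpec:
    def test_delay_step_must_be_whole_frames(self):
        with pytest.raises(InvalidSpecError):
            ComboSpec("bad", ("c1",), delay_step_ms=7.0, grid_rate_hz=100.0)

    def test_default_geometry(self):
        c = ComboSpec("x", ("c1", "c2"))
        assert c.n_delays == 15
        assert c.delay_step_ms == 10.0
        assert c.delay_frames == 1
        assert c.size == 30


class TestBuildDelayMatrix:
    def test_single_channel_trace_is_fifteen(self):
        rng = np.random.default_rng(1)
        rec = _rec([rng.standard_normal(1000)])
        M = build_delay_matrix(rec, _combo(1))
        assert np.trace(M.matrix) == pytest.approx(15.0, abs=1e-9)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(2)
        rec = _rec([rng.standard_normal(500) for _ in range(3)])
        M = build_delay_matrix(rec, _combo(3)).matrix
        assert np.allclose(M, M.T, atol=1e-9)
        assert np.allclose(np.diag(M), 1.0, atol=1e-9)
        assert M.min() >= -1.0 - 1e-9 and M.max() <= 1.0 + 1e-9

    def test_duplicated_channels_halve_the_rank(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(800)
        rec = _rec([x, x.copy()])
        spec = eigenspectrum(build_delay_matrix(rec, _combo(2)))
        assert (np.abs(spec.eigenvalues) < 1e-8).sum() >= 15

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        D = int(rng.integers(1, 6))
        T = int(rng.integers(60, 201))
        series = [rng.standard_normal(T) for _ in range(n)]
        masks = [rng.random(T) > 0.1 for _ in range(n)]
        rec = _rec(series, masks=masks)
        combo = ComboSpec("t", tuple(f"c{i + 1}" for i in range(n)), n_delays=D,
                          mask_policy="none")
        try:
            M = build_delay_matrix(rec, combo, min_valid_frames=40)
        except InsufficientOverlapError:
            pytest.skip("degenerate instance")
        expected = brute_delay_matrix(series, masks, D, combo.delay_frames)
        assert np.abs(M.matrix - expected).max() < 1e-12

    def test_missing_channel_raises(self):
        rec = _rec([np.random.default_rng(0).standard_normal(300)])
        with pytest.raises(MissingChannelError):
            build_delay_matrix(rec, _combo(2))

    def test_too_few_joint_frames_excludes_recording(self):
        rng = np.random.default_rng(4)
        mask = np.zeros(300, dtype=bool)
        mask[:50] = True
        rec = _rec([rng.standard_normal(300)], masks=[mask])
        with pytest.raises(InsufficientOverlapError):
            build_delay_matrix(rec, _combo(1))

    def test_channel_order_permutation_preserves_eigenvalues(self):
        rng = np.random.default_rng(5)
        rec = _rec([rng.standard_normal(400) for _ in range(3)])
        c1 = ComboSpec("a", ("c1", "c2", "c3"), mask_policy="none")
        c2 = ComboSpec("b", ("c3", "c1", "c2"), mask_policy="none")
        e1 = eigenspectrum(build_delay_matrix(rec, c1)).eigenvalues
        e2 = eigenspectrum(build_delay_matrix(rec, c2)).eigenvalues
        assert np.abs(e1 - e2).max() < 1e-9

    def test_channel_scaling_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 400))
        m1 = build_delay_matrix(_rec([x, y]), _combo(2)).matrix
        m2 = build_delay_matrix(_rec([x * 37.5, y]), _combo(2)).matrix
        assert np.abs(m1 - m2).max() < 1e-12

    def test_laryngeal_mask_applied_to_all_channels(self):
        # voiced mask on F0 must restrict the pairing of the other channel too
        rng = np.random.default_rng(7)
        f0 = rng.standard_normal(600) + 200
        env = rng.standard_normal(600)
        voiced = rng.random(600) > 0.3
        channels = {
            "F0": FeatureTrajectory("F0", f0, 100.0, mask=voiced),
            "ENV": FeatureTrajectory("ENV", env, 100.0),
        }
        rec = RecordingFeatures("r", "s", "A", 6.0, channels)
        combo = ComboSpec("F0xENV", ("F0", "ENV"), n_delays=3)
        M = build_delay_matrix(rec, combo)
        # ENV auto-correlation block must equal the masked computation
        masked_env = np.where(voiced, env, np.nan)
        expected = brute_delay_matrix(
            [masked_env], [voiced & np.ones(600, bool)], 3, 1
        )
        env_block = M.matrix[3:6, 3:6]
        assert np.abs(env_block - expected).max() < 1e-12


class TestEigenSpectrum:
    def test_identity_matrix_gives_unit_spectrum(self):
        combo = _combo(1)
        M = CorrelationMatrix(combo=combo, matrix=np.eye(15), n_valid_pairs=100)
        s = eigenspectrum(M)
        assert len(s) == 15
        assert np.allclose(s.eigenvalues, 1.0)

    def test_rank_one_constant_matrix(self):
        combo = _combo(1)
        M = CorrelationMatrix(combo=combo, matrix=np.ones((15, 15)), n_valid_pairs=100)
        s = eigenspectrum(M)
        assert s.eigenvalues[0] == pytest.approx(15.0, abs=1e-9)
        assert np.abs(s.eigenvalues[1:]).max() < 1e-9

    def test_signed_sum_equals_trace(self):
        rng = np.random.default_rng(8)
        rec = _rec([rng.standard_normal(500) for _ in range(2)])
        M = build_delay_matrix(rec, _combo(2))
        s = eigenspectrum(M)
        assert s.eigenvalues.sum() == pytest.approx(np.trace(M.matrix), abs=1e-6)
        assert np.all(np.diff(s.eigenvalues) <= 1e-12)  # sorted descending

    def test_nan_matrix_raises(self):
        combo = _combo(1)
        bad = np.eye(15)
        bad[3, 4] = np.nan
        with pytest.raises(InvalidMatrixError):
            eigenspectrum(CorrelationMatrix(combo=combo, matrix=bad, n_valid_pairs=10))


class TestSpectrumFlatness:
    def test_uniform_spectrum_is_one(self):
        assert spectrum_flatness(np.ones(15)) == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        s = np.zeros(15)
        s[0] = 15.0
        assert spectrum_flatness(s) == pytest.approx(0.0)

    def test_concentrated_example_matches_direct_entropy(self):
        # one eigenvalue of 8, fourteen of 0.5: H computed independently
        s = np.array([8.0] + [0.5] * 14)
        p = s / s.sum()
        expected = -(p * np.log(p)).sum() / np.log(15)
        assert spectrum_flatness(s) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(UndefinedSpectrumError):
            spectrum_flatness(np.zeros(15))


class TestResampleToGrid:
    def test_identity_when_rates_match(self):
        tr = FeatureTrajectory("x", np.arange(50.0), 100.0)
        vals, mask = resample_to_grid(tr, 100.0)
        assert np.allclose(vals, np.arange(50.0))
        assert mask.all()

    def test_downsampling_ands_contributing_masks(self):
        vals = np.arange(100.0)
        mask = np.ones(100, dtype=bool)
        mask[40:43] = False
        tr = FeatureTrajectory("F0", vals, 1000.0, mask=mask)
        out_vals, out_mask = resample_to_grid(tr, 100.0)
        assert out_vals.size == 10
        assert not out_mask[4]  # grid frame 4 sits on invalid native frames
        assert out_mask[[0, 1, 2, 3, 5, 6, 7, 8]].all()
        assert np.isnan(out_vals[4])
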