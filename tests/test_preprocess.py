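import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import subspace_angles

from striaparc import (
    MotionTrace,
    apply_exclusion,
    bandpass_regress,
    build_nuisance_design,
    compcor_components,
    despike,
    discard_initial_frames,
    framewise_displacement,
)


class TestFramewiseDisplacement:
    def test_zero_trace(self):
        assert np.all(framewise_displacement(MotionTrace(np.zeros((20, 6)))) == 0)

    def test_translation_step(self):
        params = np.zeros((10, 6))
        params[5:, 0] = 0.1
        fd = framewise_displacement(MotionTrace(params))
        assert fd[5] == pytest.approx(0.1)
        assert fd[0] == 0 and np.all(np.delete(fd, 5) == 0)

    def test_rotation_step_arc_length(self):
        params = np.zeros((10, 6))
        params[5:, 4] = 0.002
        fd = framewise_displacement(MotionTrace(params))
        assert fd[5] == pytest.approx(0.002 * 50)

    def test_offset_invariance_and_linearity(self, rng):
        params = rng.standard_normal((30, 6)) * 0.1
        fd = framewise_displacement(MotionTrace(params))
        shifted = framewise_displacement(MotionTrace(params + 7.3))
        np.testing.assert_allclose(shifted, fd, atol=1e-10)
        np.testing.assert_allclose(
            framewise_displacement(MotionTrace(3.0 * params)), 3.0 * fd, atol=1e-10
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        offset=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.0, 10.0, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_offset_invariance_and_scaling_property(self, offset, scale, seed):
        params = np.random.default_rng(seed).standard_normal((20, 6))
        fd = framewise_displacement(MotionTrace(params))
        np.testing.assert_allclose(
            framewise_displacement(MotionTrace(params + offset)), fd, atol=1e-8
        )
        np.testing.assert_allclose(
            framewise_displacement(MotionTrace(params * scale)), scale * fd,
            atol=1e-8, rtol=1e-9,
        )

    def test_non_finite_rejected(self):
        bad = np.zeros((5, 6))
        bad[2, 1] = np.nan
        with pytest.raises(ValueError):
            framewise_displacement(MotionTrace(bad))


class TestExclusion:
    @pytest.mark.parametrize(
        "scale_trans, rot_deg, fd_like, expect",
        [
            (0.5, 0.3, 0.12, True),    # typical retained subject
            (0.5, 0.3, 0.31, False),   # mean FD over threshold
            (1.6, 0.3, 0.05, False),   # translation over threshold
            (0.5, 1.6, 0.05, False),   # rotation over threshold
        ],
    )
    def test_rules(self, scale_trans, rot_deg, fd_like, expect):
        T = 100
        params = np.zeros((T, 6))
        # constant offsets set the maxima without contributing to FD ...
        params[:, 0] = scale_trans
        params[:, 3] = np.radians(rot_deg)
        # ... and a small alternating jitter sets mean FD exactly
        amp = fd_like * T / (T - 1)
        params[:, 1] += (np.arange(T) % 2) * amp
        report = apply_exclusion({"s": MotionTrace(params)})
        row = report.rows.iloc[0]
        assert bool(row["included"]) is expect


class TestCompCor:
    @staticmethod
    def _detrend(v):
        """Independent detrend oracle: residual of v on [1, t] by lstsq."""
        t = np.arange(len(v), dtype=float)
        D = np.column_stack([np.ones_like(t), t])
        return v - D @ np.linalg.lstsq(D, v, rcond=None)[0]

    def test_rank_one_recovers_shared_series(self, rng):
        shared = rng.standard_normal(80)
        X = np.tile(shared, (12, 1)) * rng.uniform(0.5, 2.0, size=(12, 1))
        comps = compcor_components(X, n_components=1)
        r = np.corrcoef(comps[:, 0], self._detrend(shared))[0, 1]
        assert abs(r) > 0.9999

    def test_two_orthogonal_sources_spanned(self, rng):
        t = np.arange(100)
        s1 = np.sin(2 * np.pi * t / 25)
        s2 = np.cos(2 * np.pi * t / 10)
        X = np.vstack([np.tile(s1, (10, 1)), np.tile(s2, (10, 1))])
        X = X + 1e-6 * rng.standard_normal(X.shape)
        comps = compcor_components(X, n_components=2)
        basis = np.column_stack([self._detrend(s1), self._detrend(s2)])
        angles = subspace_angles(comps, basis)
        assert np.max(angles) < 1e-3

    def test_orthonormal_columns(self, rng):
        comps = compcor_components(rng.standard_normal((30, 60)), 5)
        np.testing.assert_allclose(comps.T @ comps, np.eye(5), atol=1e-10)

    def test_insufficient_rank_warns(self, rng):
        X = rng.standard_normal((3, 40))
        with pytest.warns(UserWarning, match="3 components"):
            comps = compcor_components(X, n_components=5)
        assert comps.shape[1] == 3


class TestDespike:
    def test_clean_series_untouched(self, rng):
        x = rng.standard_normal(50) * 0.1
        np.testing.assert_array_equal(despike(x), x)

    def test_spike_winsorized_to_boundary(self):
        x = np.array([0.0, 1.0, -1.0, 0.5, -0.5, 0.2, -0.2, 30.0])
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        out = despike(x, mad_threshold=3)
        assert out[-1] == pytest.approx(med + 3 * 1.4826 * mad)
        np.testing.assert_array_equal(out[:-1], x[:-1])

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="MAD"):
            out = despike(np.full(10, 2.5))
        np.testing.assert_array_equal(out, np.full(10, 2.5))


class TestNuisanceDesign:
    def test_23_regressors(self, rng):
        design = build_nuisance_design(
            MotionTrace(rng.standard_normal((60, 6)) * 0.1),
            rng.standard_normal((15, 60)),
            rng.standard_normal((15, 60)),
        )
        assert design.n_regressors == 23
        assert design.to_frame().shape == (60, 23)

    def test_derivatives_and_trend_contracts(self, rng):
        design = build_nuisance_design(
            MotionTrace(rng.standard_normal((40, 6))),
            rng.standard_normal((10, 40)),
            rng.standard_normal((10, 40)),
        )
        df = design.to_frame()
        assert np.all(df.iloc[0][[f"motion_deriv_{i}" for i in range(1, 7)]] == 0)
        assert np.all(np.diff(df["linear_trend"]) > 0)


class TestBandpassRegress:
    TR = 3.5

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(200) * self.TR
        x = np.sin(2 * np.pi * 0.05 * t)
        design = np.linspace(-1, 1, 200)[:, None]
        out = bandpass_regress(x[None], design, tr_seconds=self.TR)[0]
        assert np.abs(out).max() >= 0.9 * np.abs(x).max()

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(200) * self.TR
        x = np.sin(2 * np.pi * 0.13 * t)
        out = bandpass_regress(x[None], np.linspace(-1, 1, 200)[:, None],
                               tr_seconds=self.TR)[0]
        assert np.abs(out).max() <= 0.1 * np.abs(x).max()

    def test_motion_variance_removed(self, rng):
        T = 150
        motion = MotionTrace(np.cumsum(rng.standard_normal((T, 6)), axis=0) * 0.01)
        design = build_nuisance_design(
            motion, rng.standard_normal((8, T)), rng.standard_normal((8, T))
        )
        t = np.arange(T) * self.TR
        signal = np.sin(2 * np.pi * 0.03 * t)
        data = 2.0 * motion.params[:, 0] + signal
        out = bandpass_regress(data[None], design, tr_seconds=self.TR)[0]
        from striaparc.preprocess import _bandlimit
        filt_col = _bandlimit(motion.params[:, 0][None], (0.009, 0.1), self.TR)[0]
        r = np.corrcoef(out, filt_col)[0, 1]
        assert abs(r) < 0.02

    def test_residuals_orthogonal_to_filtered_design(self, rng):
        T = 120
        design = build_nuisance_design(
            MotionTrace(rng.standard_normal((T, 6)) * 0.05),
            rng.standard_normal((10, T)),
            rng.standard_normal((10, T)),
        )
        data = rng.standard_normal((5, T))
        out = bandpass_regress(data, design, tr_seconds=self.TR)
        from striaparc.preprocess import _bandlimit
        Df = _bandlimit(design.matrix.T, (0.009, 0.1), self.TR).T
        dots = out @ Df / T
        assert np.abs(dots).max() < 1e-8

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_regress(rng.standard_normal((1, 50)),
                             np.ones((50, 1)), band=(0.009, 0.2), tr_seconds=3.5)


def test_discard_initial_frames():
    x = np.arange(24, dtype=float).reshape(2, 12)
    out = discard_initial_frames(x)
    assert out.shape == (2, 8)
    np.testing.assert_array_equal(out, x[:, 4:])
    with pytest.raises(ValueError):
        discard_initial_frames(np.zeros((2, 3)))
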