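"""Post-ICA processing stages: trim, detrend, despike, bandpass, pipeline."""

import numpy as np
import pandas as pd
import pytest

import capdyn as cd
from capdyn.preprocess import PreprocessConfig, PreprocessError, zscore
from capdyn.synthetic import make_pattern_set, simulate_subject, transition_matrix

from conftest import make_ts


def _col(y):
    return np.asarray(y, float).reshape(-1, 1)


class TestTrim:
    def test_drops_leading_then_tail(self):
        ts = make_ts(np.arange(400).reshape(200, 2))
        out = cd.trim_scan(ts, 5, 155)
        assert out.n_frames == 155
        assert np.array_equal(out.data, ts.data[5:160])

    def test_exact_fit_removes_nothing_from_end(self):
        ts = make_ts(np.arange(320).reshape(160, 2))
        out = cd.trim_scan(ts, 5, 155)
        assert np.array_equal(out.data, ts.data[5:])

    def test_too_short_scan_errors_with_minimum(self):
        ts = make_ts(np.zeros((159, 2)))
        with pytest.raises(PreprocessError, match="160"):
            cd.trim_scan(ts, 5, 155)


class TestDetrend:
    def test_exact_line_maps_to_zero(self):
        t = np.arange(50)
        out = cd.detrend_linear(make_ts(_col(3 + 0.5 * t)))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_constant_maps_to_zero(self):
        out = cd.detrend_linear(make_ts(np.full((30, 2), 7.0)))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        t = np.arange(128)
        y = np.sin(2 * np.pi * 0.05 * t * 2.0) + 2.0 + 0.1 * t
        out = cd.detrend_linear(make_ts(_col(y))).data[:, 0]
        # independent least-squares fit via the normal equations
        x = np.column_stack([np.ones_like(t), t]).astype(float)
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(out, y - x @ beta, atol=1e-9)

    def test_refit_line_is_zero(self):
        rng = np.random.default_rng(0)
        out = cd.detrend_linear(make_ts(rng.standard_normal((80, 3)))).data
        for j in range(3):
            slope, intercept = np.polyfit(np.arange(80), out[:, j], 1)
            assert abs(slope) < 1e-9 and abs(intercept) < 1e-9


class TestDespike:
    def _oracle(self, y, c1=2.5, c2=4.0, window=9):
        base = pd.Series(y).rolling(window, center=True, min_periods=1).median()
        base = base.to_numpy()
        resid = y - base
        sigma = 1.4826 * np.median(np.abs(resid))
        if sigma == 0:
            return y
        s = resid / sigma
        a = np.abs(s)
        s2 = np.where(a > c1, np.sign(s) * (c1 + (c2 - c1) * np.tanh((a - c1) / (c2 - c1))), s)
        return base + sigma * s2

    def test_below_threshold_series_unchanged(self):
        y = np.cos(2 * np.pi * np.arange(120) / 30)  # smooth, no excursions
        assert np.allclose(self._oracle(y), y)  # oracle confirms: nothing to clip
        out = cd.despike(make_ts(_col(y))).data[:, 0]
        assert np.array_equal(out, y)

    def test_spike_compressed_per_formula(self):
        rng = np.random.default_rng(0)
        y = 0.5 * rng.standard_normal(200)
        y[50] += 8.0
        out = cd.despike(make_ts(_col(y))).data[:, 0]
        assert np.allclose(out, self._oracle(y), atol=1e-12)
        assert out[50] < y[50]

    def test_constant_series_unchanged(self):
        y = np.full(50, 3.0)
        out = cd.despike(make_ts(_col(y))).data[:, 0]
        assert np.array_equal(out, y)

    def test_output_residuals_bounded_by_c2(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(300)
        y[::37] += rng.choice([-1, 1], size=y[::37].size) * 20.0
        out = cd.despike(make_ts(_col(y))).data[:, 0]
        base_in = pd.Series(y).rolling(9, center=True, min_periods=1).median().to_numpy()
        sigma = 1.4826 * np.median(np.abs(y - base_in))
        assert np.all(np.abs(out - base_in) / sigma < 4.0)

    def test_idempotent_in_clean_limit(self):
        """A series whose standardized residuals all sit below c1 passes
        through untouched, so a second application changes nothing."""
        t = np.arange(150)
        y = np.sin(2 * np.pi * t / 40)  # smooth: residuals well below c1
        once = cd.despike(make_ts(_col(y)))
        assert np.allclose(once.data[:, 0], y, atol=1e-12)
        twice = cd.despike(once)
        assert np.array_equal(twice.data, once.data)


class TestBandpass:
    def _sine(self, f, t_n=1024, tr=2.0):
        return np.sin(2 * np.pi * f * np.arange(t_n) * tr)

    def test_dc_rejected(self):
        out = cd.bandpass(make_ts(_col(np.full(1024, 5.0)))).data
        assert np.abs(out).max() < 1e-6 * 5.0

    def test_passband_gain_near_unity(self):
        y = self._sine(0.05)
        out = cd.bandpass(make_ts(_col(y))).data[200:-200, 0]
        assert np.sqrt((out**2).mean()) >= 0.9 * np.sqrt((y[200:-200] ** 2).mean())

    def test_stopband_attenuated(self):
        y = self._sine(0.2)
        out = cd.bandpass(make_ts(_col(y))).data[200:-200, 0]
        assert np.sqrt((out**2).mean()) <= 0.1 * np.sqrt((y[200:-200] ** 2).mean())

    def test_infeasible_band_for_tr(self):
        ts = make_ts(np.zeros((100, 1)), tr=10.0)  # Nyquist 0.05 Hz
        with pytest.raises(PreprocessError, match="Nyquist"):
            cd.bandpass(ts, 0.01, 0.1)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 400, 3))
        bp = lambda d: cd.bandpass(make_ts(d)).data
        assert np.allclose(bp(2.0 * x - 3.0 * y), 2.0 * bp(x) - 3.0 * bp(y), atol=1e-9)

    @pytest.mark.parametrize("design", ["butter", "fft"])
    def test_both_designs_reject_dc(self, design):
        out = cd.bandpass(make_ts(_col(np.full(512, 2.0))), design=design).data
        assert np.abs(out).max() < 1e-6


class TestPipeline:
    def test_matches_manual_stage_composition_bitwise(self):
        rng = np.random.default_rng(5)
        ts = make_ts(rng.standard_normal((200, 4)))
        cfg = PreprocessConfig(zscore_components=False)
        auto = cd.run_postica_pipeline(ts, cfg)
        manual = cd.bandpass(
            cd.despike(cd.detrend_linear(cd.trim_scan(ts, 5, 155)), 2.5, 4.0, 9),
            0.01, 0.1, 5,
        )
        assert np.array_equal(auto.data, manual.data)

    def test_all_stages_disabled_is_identity(self):
        rng = np.random.default_rng(6)
        ts = make_ts(rng.standard_normal((50, 3)))
        cfg = PreprocessConfig(
            do_trim=False, do_detrend=False, do_despike=False,
            do_bandpass=False, zscore_components=False,
        )
        assert np.array_equal(cd.run_postica_pipeline(ts, cfg).data, ts.data)

    def test_cleanup_improves_correlation_with_planted_signal(self):
        """Injected drift and spikes: post-pipeline correlation with the
        clean state signal exceeds the raw correlation."""
        ps = make_pattern_set(8, 3, rng=np.random.default_rng(7))
        p = transition_matrix((1 / 3,) * 3, 0.8)
        clean, lab = simulate_subject(ps, 200, p, 0.3, 0.0, np.random.default_rng(8))
        dirty = clean.copy()
        dirty += 0.1 * np.arange(200)[:, None]  # drift 0.1/frame
        for f in (40, 90, 150):
            dirty[f] += 6.0
        ts = make_ts(dirty)
        out = cd.run_postica_pipeline(ts, PreprocessConfig(zscore_components=False))
        ref = clean[5:160]

        def mean_corr(a, b):
            return np.mean([np.corrcoef(a[:, j], b[:, j])[0, 1]
                            for j in range(a.shape[1])])

        assert mean_corr(out.data, ref) > mean_corr(dirty[5:160], ref)

    def test_zscore_gives_unit_variance(self):
        rng = np.random.default_rng(9)
        ts = make_ts(rng.standard_normal((200, 3)) * 5 + 2)
        out = cd.run_postica_pipeline(ts)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.data.std(axis=0), 1.0, atol=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(PreprocessError):
            PreprocessConfig(despike_c1=4.0, despike_c2=2.5)
        with pytest.raises(PreprocessError):
            PreprocessConfig(despike_window=8)
        with pytest.raises(PreprocessError):
            PreprocessConfig(band_low_hz=0.2, band_high_hz=0.1)
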