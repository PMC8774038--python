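import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mi_erd import (
    BAND_ALPHA,
    BAND_ALPHA_BETA,
    BAND_BETA,
    band_power,
    build_feature_matrix,
    erd_value,
)
from mi_erd.data_io import ChannelMap, EpochSet, InputError, make_montage

FS = 160.0
N = 320


def dft_band_power(segment: np.ndarray, low_hz: float, high_hz: float,
                   fs: float) -> float:
    """Independent oracle: direct DFT, one-sided PSD, bin sum times bin width.

    Same normalisation convention as a rectangular-window periodogram:
    Pxx[k] = 2|X_k|^2 / (fs n) (factor 2 dropped at DC and Nyquist).
    """
    n = len(segment)
    t = np.arange(n)
    power = 0.0
    df = fs / n
    for k in range(n // 2 + 1):
        f = k * df
        if not (low_hz <= f <= high_hz):
            continue
        xk = np.sum(segment * np.exp(-2j * np.pi * k * t / n))
        scale = 1.0 if k in (0, n // 2) else 2.0
        power += scale * np.abs(xk) ** 2 / (fs * n)
    return power * df


class TestBandPower:
    def test_pure_alpha_sine_matches_dft_oracle(self):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        got = band_power(x, BAND_ALPHA, FS)
        want = dft_band_power(x, 8, 13, FS)
        assert got == pytest.approx(want, rel=1e-12)
        assert want > 0

    def test_alpha_sine_has_negligible_beta_power(self):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        assert band_power(x, BAND_BETA, FS) < 0.01 * band_power(x, BAND_ALPHA, FS)

    def test_zero_segment(self):
        assert band_power(np.zeros(N), BAND_ALPHA, FS) == 0.0

    def test_too_short_segment_raises(self):
        with pytest.raises(InputError):
            band_power(np.zeros(100), BAND_ALPHA, FS)

    def test_matches_dft_oracle_on_random_segments(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            x = rng.standard_normal(N)
            for band in (BAND_ALPHA, BAND_BETA, BAND_ALPHA_BETA):
                got = band_power(x, band, FS)
                want = dft_band_power(x, band.low_hz, band.high_hz, FS)
                assert got == pytest.approx(want, rel=1e-9)

    def test_band_additivity(self):
        # AB covers A and B plus the single 13.5 Hz boundary bin between them.
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.standard_normal(N)
            pa = band_power(x, BAND_ALPHA, FS)
            pb = band_power(x, BAND_BETA, FS)
            pab = band_power(x, BAND_ALPHA_BETA, FS)
            boundary = dft_band_power(x, 13.5, 13.5, FS)
            assert pab >= max(pa, pb) - 1e-12
            assert pab == pytest.approx(pa + pb + boundary, rel=1e-9)

    def test_fir_variant_tracks_periodogram(self):
        t = np.arange(4 * N) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        p_fir = band_power(x, BAND_ALPHA, FS, method="fir")
        # a 10 Hz unit sine has mean-square 0.5; the FIR variant's transition
        # band overlaps 10 Hz slightly, so agreement is approximate
        assert p_fir == pytest.approx(0.5, rel=0.15)


class TestErdValue:
    @pytest.mark.parametrize("task,rest,expected",
                             [(1.0, 1.0, 0.0), (0.5, 1.0, -0.5), (2.0, 1.0, 1.0)])
    def test_formula_identities(self, task, rest, expected):
        assert erd_value(task, rest) == pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    @settings(derandomize=True, max_examples=100)
    def test_exact_relative_change(self, task, rest):
        assert erd_value(task, rest) == pytest.approx((task - rest) / rest, rel=1e-12)

    def test_negative_power_raises(self):
        with pytest.raises(InputError):
            erd_value(-1.0, 1.0)

    def test_zero_rest_power_is_finite(self):
        assert np.isfinite(erd_value(1.0, 0.0))


def _epochs_from_trials(trials: np.ndarray, labels, fs=FS, n_ch=None):
    n_ch = n_ch or trials.shape[1]
    mont = ChannelMap(names=make_montage().names[:n_ch])
    return EpochSet(data=trials, labels=list(labels), fs=fs,
                    n_pre=trials.shape[2] // 2, n_post=trials.shape[2] // 2,
                    channels=mont)


class TestFeatureMatrix:
    def test_shape_and_descriptors(self):
        rng = np.random.default_rng(1)
        ep = _epochs_from_trials(rng.standard_normal((10, 64, 640)), ["A", "B"] * 5)
        fm = build_feature_matrix(ep, BAND_ALPHA)
        assert fm.values.shape == (10, 64)
        assert fm.descriptors[0] == ("FC5", "ERD_A")
        assert len(fm.descriptors) == 64
        assert fm.labels == ["A", "B"] * 5

    def test_task_copy_of_rest_gives_zero_erd(self):
        rng = np.random.default_rng(2)
        rest = rng.standard_normal((3, 4, 320))
        trials = np.concatenate([rest, rest], axis=2)
        fm = build_feature_matrix(_epochs_from_trials(trials, "ABA"), BAND_ALPHA)
        assert np.allclose(fm.values, 0.0, atol=1e-12)

    def test_planted_alpha_attenuation_at_c3(self):
        # task-window alpha amplitude scaled by sqrt(0.5) at C3 only
        rng = np.random.default_rng(3)
        n_trials, n_ch = 30, 10
        mont_names = make_montage().names[:n_ch]
        c3 = mont_names.index("C3")
        t = np.arange(320) / FS
        trials = 0.05 * rng.standard_normal((n_trials, n_ch, 640))
        for i in range(n_trials):
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            alpha = np.sin(2 * np.pi * 10.0 * np.arange(640) / FS
                           + phases[:, None])
            alpha[c3, 320:] *= np.sqrt(0.5)
            trials[i] += alpha
        fm = build_feature_matrix(_epochs_from_trials(trials, "A" * n_trials),
                                  BAND_ALPHA)
        mean_erd = fm.values.mean(axis=0)
        assert mean_erd[c3] == pytest.approx(-0.5, abs=0.1)
        others = np.delete(mean_erd, c3)
        assert np.all(np.abs(others) < 0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        trials = rng.standard_normal((5, 3, 640))
        ep1 = _epochs_from_trials(trials, "AABBA", n_ch=3)
        ep2 = _epochs_from_trials(trials * 37.5, "AABBA", n_ch=3)
        fm1 = build_feature_matrix(ep1, BAND_ALPHA_BETA)
        fm2 = build_feature_matrix(ep2, BAND_ALPHA_BETA)
        assert np.allclose(fm1.values, fm2.values, rtol=1e-9)

    def test_csv_serialisation(self):
        rng = np.random.default_rng(5)
        ep = _epochs_from_trials(rng.standard_normal((4, 2, 640)), "ABAB", n_ch=2)
        df = build_feature_matrix(ep, BAND_BETA).to_frame()
        assert list(df.columns) == ["FC5_ERD_B", "FC3_ERD_B", "label"]
        assert len(df) == 4
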