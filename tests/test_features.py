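import numpy as np
import pytest
import pywt

from driftseize.features import (
    DEFAULT_BANDS,
    FeatureRegistry,
    band_ratio,
    decorrelation_time,
    default_registry,
    extract_features,
    hjorth_parameters,
    power_spectrum,
    relative_band_power,
    spectral_edge,
    statistical_moments,
    summary_spectral_features,
    wavelet_energies,
)
from driftseize.signal_io import EpochArray

RATE = 256.0
N = int(5 * RATE)
BAND = {b.name: b for b in DEFAULT_BANDS}


def tone(freq, amp=1.0, n=N, rate=RATE, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / rate + phase)


class TestPowerSpectrum:
    def test_tone_mass_concentrated_at_carrier(self):
        f, p = power_spectrum(tone(10.0), RATE)
        df = f[1] - f[0]
        assert df <= 0.5
        near = (f >= 9.0) & (f <= 11.0)
        assert p[near].sum() / p.sum() >= 0.90

    def test_parseval_for_zero_mean_input(self, rng):
        x = rng.standard_normal(N)
        x -= x.mean()
        f, p = power_spectrum(x, RATE)
        assert p.sum() * (f[1] - f[0]) == pytest.approx(x.var(), rel=0.05)

    def test_zero_input_zero_spectrum(self):
        _, p = power_spectrum(np.zeros(N), RATE)
        np.testing.assert_allclose(p, 0.0)


class TestRelativeBandPower:
    def test_alpha_tone(self):
        f, p = power_spectrum(tone(10.0), RATE)
        assert relative_band_power(f, p, BAND["alpha"]) >= 0.95
        assert relative_band_power(f, p, BAND["delta"]) <= 0.02

    def test_band_equal_to_total_band_is_one(self):
        f, p = power_spectrum(tone(10.0), RATE)
        whole = type(BAND["alpha"])("all", 0.5, 128.0)
        assert relative_band_power(f, p, whole) == pytest.approx(1.0)

    def test_flat_epoch_flagged_invalid(self):
        f, p = power_spectrum(np.full(N, 3.0), RATE)
        assert np.isnan(relative_band_power(f, p, BAND["alpha"]))


class TestBandRatio:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.4, 0.2, 2.0), (0.0, 0.5, 0.0)]
    )
    def test_arithmetic(self, a, b, expected):
        assert band_ratio(a, b) == pytest.approx(expected, rel=1e-9)

    def test_zero_denominator_guarded(self):
        r = band_ratio(0.3, 0.0)
        assert np.isfinite(r) and r == pytest.approx(0.3 / 1e-12)


class TestSpectralEdge:
    def test_single_line_edge_at_carrier_for_any_percentile(self):
        f, p = power_spectrum(tone(10.0), RATE)
        for pct in (0.25, 0.5, 0.9):
            ef, _ = spectral_edge(f, p, pct)
            assert ef == pytest.approx(10.0, abs=0.3)

    def test_two_equal_lines_median_edge_at_lower_line(self):
        f, p = power_spectrum(tone(5.0) + tone(20.0, phase=1.0), RATE)
        ef, ep = spectral_edge(f, p, 0.5)
        assert ef == pytest.approx(5.0, abs=0.3)
        # edge power is the cumulative power up to the edge: half the total
        total = p[(f >= 0.5) & (f < 100.0)].sum() * (f[1] - f[0])
        assert ep == pytest.approx(0.5 * total, rel=0.05)

    def test_white_noise_median_edge_near_range_midpoint(self, rng):
        edges = []
        for _ in range(200):
            f, p = power_spectrum(rng.standard_normal(N), RATE)
            edges.append(spectral_edge(f, p, 0.5)[0])
        assert np.mean(edges) == pytest.approx(50.25, abs=2.0)


class TestSummarySpectral:
    def test_alpha_tone(self):
        f, p = power_spectrum(tone(10.0), RATE)
        peak, total, mean_f = summary_spectral_features(f, p)
        assert peak == pytest.approx(10.0, abs=0.3)
        assert mean_f == pytest.approx(10.0, abs=0.3)

    def test_mean_frequency_of_two_equal_lines(self):
        f, p = power_spectrum(tone(4.0) + tone(16.0, phase=1.2), RATE)
        _, _, mean_f = summary_spectral_features(f, p)
        assert mean_f == pytest.approx(10.0, abs=0.5)

    def test_amplitude_scaling_law(self):
        f1, p1 = power_spectrum(tone(10.0), RATE)
        f2, p2 = power_spectrum(tone(10.0, amp=2.0), RATE)
        peak1, total1, _ = summary_spectral_features(f1, p1)
        peak2, total2, _ = summary_spectral_features(f2, p2)
        assert total2 == pytest.approx(4 * total1, rel=1e-9)
        assert peak2 == peak1


class TestWaveletEnergies:
    def test_zeros(self):
        np.testing.assert_allclose(wavelet_energies(np.zeros(N)), 0.0)

    def test_quadratic_scaling(self, rng):
        x = rng.standard_normal(N)
        np.testing.assert_allclose(
            wavelet_energies(3.0 * x), 9.0 * wavelet_energies(x), rtol=1e-9
        )

    def test_parseval_with_approximation(self, rng):
        x = rng.standard_normal(N)
        details = wavelet_energies(x)
        approx = pywt.wavedec(x, "db4", mode="periodization", level=5)[0]
        assert details.sum() + np.sum(approx**2) == pytest.approx(
            np.sum(x**2), rel=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_energies(np.zeros(16))


class TestStatisticalMoments:
    def test_constant(self):
        mean, var, skew, kurt = statistical_moments(np.full(100, 5.0))
        assert (mean, var) == (5.0, 0.0)
        assert np.isnan(skew) and np.isnan(kurt)

    def test_symmetric_two_point_signal(self):
        x = np.tile([-1.0, 1.0], 640)
        mean, var, skew, kurt = statistical_moments(x)
        assert mean == 0.0
        assert var == pytest.approx(1.0)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0)

    def test_gaussian_noise_moments(self):
        skews, kurts = [], []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(1280)
            _, _, s, k = statistical_moments(x)
            skews.append(s)
            kurts.append(k)
        assert abs(np.mean(skews)) < 0.2
        assert np.mean(kurts) == pytest.approx(3.0, abs=0.5)


class TestHjorth:
    def test_constant_signal(self):
        act, mob, comp = hjorth_parameters(np.full(64, 2.0))
        assert act == 0.0
        assert np.isnan(mob) and np.isnan(comp)

    def test_white_noise_mobility_sqrt2(self):
        mobs = [
            hjorth_parameters(np.random.default_rng(s).standard_normal(1280))[1]
            for s in range(10)
        ]
        assert np.mean(mobs) == pytest.approx(np.sqrt(2.0), abs=0.05)

    def test_sinusoid_complexity_near_one(self):
        comps = [
            hjorth_parameters(tone(10.0, phase=ph))[2]
            for ph in np.linspace(0, np.pi, 8)
        ]
        assert np.mean(comps) == pytest.approx(1.0, abs=0.05)


class TestDecorrelationTime:
    def test_white_noise_first_lag(self, rng):
        hits = sum(
            decorrelation_time(rng.standard_normal(1280), RATE) == 1 / RATE
            for _ in range(50)
        )
        assert hits > 45  # ACF of i.i.d. noise ~ 0 at lag 1

    @pytest.mark.parametrize("freq", [5.0, 10.0, 20.0])
    def test_sinusoid_closed_form(self, freq):
        expected = np.arccos(1 / np.e) / (2 * np.pi * freq)
        got = decorrelation_time(tone(freq), RATE)
        assert abs(got - expected) <= 1 / RATE

    def test_slow_ar1_exceeds_white_noise(self, rng):
        w = rng.standard_normal(1280)
        ar = np.empty(1280)
        ar[0] = w[0]
        for i in range(1, 1280):
            ar[i] = 0.99 * ar[i - 1] + np.sqrt(1 - 0.99**2) * w[i]
        assert decorrelation_time(ar, RATE) > decorrelation_time(w, RATE)


class TestRegistryAndExtraction:
    def test_default_registry_has_59_unique_serialisable_entries(self, tmp_path):
        reg = default_registry()
        assert len(reg) == 59
        path = tmp_path / "registry.json"
        reg.to_json(path)
        reg2 = FeatureRegistry.from_json(path)
        assert reg2.names == reg.names
        assert [e.kind for e in reg2.entries] == [e.kind for e in reg.entries]

    def test_wrong_size_registry_rejected_without_override(self):
        reg = default_registry()
        small = FeatureRegistry(entries=reg.entries[:10], bands=reg.bands)
        ep = EpochArray(np.zeros((1, 1, N)), [0.0], 5.0)
        with pytest.raises(ValueError, match="expected 59"):
            extract_features(ep, registry=small)
        fm = extract_features(ep, registry=small, allow_any_size=True)
        assert fm.values.shape == (1, 10)

    def test_matrix_shape_and_determinism(self, rng):
        x = rng.standard_normal((4, 3, N))
        ep = EpochArray(x, np.arange(4) * 5.0, 5.0)
        fm = extract_features(ep)
        assert fm.values.shape == (4, 3 * 59)
        fm2 = extract_features(EpochArray(x.copy(), np.arange(4) * 5.0, 5.0))
        np.testing.assert_array_equal(fm.values, fm2.values)

    def test_duplicated_epoch_gives_identical_rows(self, rng):
        x = rng.standard_normal((1, 2, N))
        ep = EpochArray(np.vstack([x, x]), [0.0, 5.0], 5.0)
        fm = extract_features(ep)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_columns_agree_with_single_channel_calls(self, rng):
        from driftseize.features import _channel_feature_row

        x = rng.standard_normal((2, 3, N))
        ep = EpochArray(x, [0.0, 5.0], 5.0)
        fm = extract_features(ep)
        reg = default_registry()
        for ei in range(2):
            for ci in range(3):
                row = _channel_feature_row(x[ei, ci], RATE, reg)
                np.testing.assert_array_equal(
                    fm.values[ei, ci * 59 : (ci + 1) * 59], row
                )

    def test_channel_permutation_equivariance(self, rng):
        x = rng.standard_normal((2, 3, N))
        fm = extract_features(EpochArray(x, [0.0, 5.0], 5.0))
        perm = [2, 0, 1]
        fmp = extract_features(EpochArray(x[:, perm], [0.0, 5.0], 5.0))
        for new_ci, old_ci in enumerate(perm):
            np.testing.assert_array_equal(
                fmp.values[:, new_ci * 59 : (new_ci + 1) * 59],
                fm.values[:, old_ci * 59 : (old_ci + 1) * 59],
            )

    def test_dc_offset_moves_only_offset_sensitive_features(self, rng):
        x = rng.standard_normal(N)
        ep = EpochArray(
            np.stack([x, x + 7.0])[:, None, :], [0.0, 5.0], 5.0
        )
        fm = extract_features(ep)
        names = fm.feature_names
        offset_sensitive = {"moment_mean", "wavelet_energy_d5"}
        for j, name in enumerate(names):
            if name in offset_sensitive:
                continue
            # spectral features use constant detrend; Hjorth/decorr/variance
            # are offset-free by construction
            assert fm.values[0, j] == pytest.approx(
                fm.values[1, j], rel=1e-6, abs=1e-9
            ), name

    def test_invalid_epoch_propagates_to_mask(self, rng):
        x = rng.standard_normal((2, 1, N))
        x[1] = 0.0  # flat epoch: NaN skew/kurt etc.
        fm = extract_features(EpochArray(x, [0.0, 5.0], 5.0))
        assert fm.valid_mask.tolist() == [True, False]

    def test_relative_band_powers_in_unit_interval_sum_below_one(self, rng):
        fm = extract_features(
            EpochArray(rng.standard_normal((5, 1, N)), np.arange(5) * 5.0, 5.0)
        )
        rel = fm.values[:, :8]
        assert (rel >= 0).all() and (rel <= 1).all()
        # notch-gap bands (47-53, 97-103 Hz) carry white-noise power
        assert (rel.sum(axis=1) < 1).all()
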