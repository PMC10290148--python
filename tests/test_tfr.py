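"""Time-frequency analysis: DPSS wavelet construction, the A^2/2 sinusoid
calibration, agreement with a direct short-time DFT multitaper oracle, band
averaging, dB conversion, period combination, and topographies."""

import numpy as np
import pandas as pd
import pytest

from oscispeech import tfr
from oscispeech.core import PARIETO_OCCIPITAL


FS = 256.0


@pytest.fixture(scope="module")
def bank():
    return tfr.make_tapered_wavelets(tfr.DEFAULT_FREQS, FS)


class TestWaveletBank:
    def test_single_taper_at_time_bandwidth_two(self, bank):
        """floor(TB) - 1 = 1 taper for the default full time-bandwidth 2."""
        assert all(w.shape[0] == 1 for w in bank.wavelets)

    def test_window_length_is_five_cycles(self, bank):
        i = np.flatnonzero(bank.freqs == 10.0)[0]
        n = bank.wavelets[i].shape[1]
        assert n / FS == pytest.approx(5.0 / 10.0, abs=1.5 / FS)

    def test_tapers_orthonormal(self):
        """Higher-order DPSS families are mutually orthonormal."""
        b = tfr.make_tapered_wavelets([10.0], FS, time_bandwidth=4.0)
        assert b.wavelets[0].shape[0] == 3
        tapers = np.abs(b.wavelets[0]) * np.sign(
            np.real(b.wavelets[0] * np.exp(-0j))
        )
        # recover the real tapers by removing the carrier
        n = b.wavelets[0].shape[1]
        c = (n - 1) // 2
        carrier = np.exp(2j * np.pi * 10.0 * (np.arange(n) - c) / FS)
        real_tapers = np.real(b.wavelets[0] / carrier)
        gram = real_tapers @ real_tapers.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)

    def test_low_frequencies_dropped_when_window_exceeds_epoch(self):
        b = tfr.make_tapered_wavelets(
            np.arange(1.0, 11.0), FS, epoch_duration=2.0
        )
        assert b.freqs.min() >= 2.5  # 5 cycles / f <= 2 s  =>  f >= 2.5
        assert len(b.dropped_freqs) > 0

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            tfr.make_tapered_wavelets([10.0], FS, n_cycles=0)
        with pytest.raises(ValueError):
            tfr.make_tapered_wavelets([10.0], FS, time_bandwidth=1.0)


class TestSpectrogram:
    def test_zero_epoch_gives_zero_power(self, bank):
        spec = tfr.spectrogram(np.zeros((2, 1344)), bank)
        assert np.all(spec.power == 0.0)

    def test_sinusoid_recovers_half_amplitude_squared(self, bank):
        """A 2-uV 10-Hz sinusoid yields 2e-12 V^2 at (10 Hz, center)."""
        t = np.arange(1344) / FS
        x = 2e-6 * np.cos(2 * np.pi * 10.0 * t + 1.1)
        spec = tfr.spectrogram(x, bank)
        i = np.flatnonzero(spec.freqs == 10.0)[0]
        assert spec.power[0, i, 672] == pytest.approx(2e-12, rel=0.05)

    def test_matches_direct_stft_oracle(self, bank):
        """Convolution implementation equals the brute-force windowed-DFT
        multitaper estimate at interior window centers."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, int(2 * FS))) * 1e-6
        centers = np.arange(int(0.8 * FS), int(1.2 * FS), 7)
        bank = tfr.make_tapered_wavelets(tfr.DEFAULT_FREQS, FS, epoch_duration=2.0)
        spec = tfr.spectrogram(x, bank)
        oracle = tfr.multitaper_stft_oracle(x, bank, centers)
        ours = spec.power[:, :, centers]
        ok = ~np.isnan(oracle)
        rel = np.abs(ours[ok] - oracle[ok]) / np.abs(oracle[ok])
        assert rel.max() < 1e-6

    def test_nan_rejected(self, bank):
        x = np.zeros(1344)
        x[3] = np.nan
        with pytest.raises(ValueError):
            tfr.spectrogram(x, bank)

    def test_valid_fraction_shrinks_at_low_frequencies(self, bank):
        spec = tfr.spectrogram(np.zeros(1344), bank)
        frac = spec.valid_mask.mean(axis=1)
        assert np.all(np.diff(frac) >= 0)  # longer windows at lower f

    def test_two_tones_give_separate_ridges(self, bank):
        t = np.arange(1344) / FS
        x = 1e-6 * (np.cos(2 * np.pi * 10 * t) + np.cos(2 * np.pi * 20 * t))
        spec = tfr.spectrogram(x, bank)
        valid = spec.valid_mask.all(axis=0)
        prof = spec.power[0][:, valid].mean(axis=1)
        f = spec.freqs
        p10, p15, p20 = prof[f == 10][0], prof[f == 15][0], prof[f == 20][0]
        assert p15 < 0.1 * min(p10, p20)

    def test_band_limited_noise_power_is_parseval_consistent(self, bank):
        """Summed in-band spectrogram power approximates the time-domain
        variance of a band-limited component within 10%."""
        from oscispeech.synthgen import _band_noise

        rng = np.random.default_rng(11)
        x = _band_noise(int(30 * FS), FS, 10.0, 4.0, rng)[0] * 2e-6
        var = x.var()
        spec = tfr.spectrogram(x, bank)
        sel = spec.valid_mask.all(axis=0)
        bin_vals = spec.power[0][:, sel].mean(axis=1)
        # Reconstruct variance by integrating the implied PSD: each bin reads
        # S(f) * kappa_f, where kappa_f is the bank's response to unit-PSD
        # noise; calibrate kappa_f independently from white noise.
        rng2 = np.random.default_rng(12)
        w = rng2.standard_normal(int(30 * FS)) * 1e-6
        spec_w = tfr.spectrogram(w, bank)
        kappa = spec_w.power[0][:, spec_w.valid_mask.all(axis=0)].mean(axis=1) / (
            1e-12 / (FS / 2.0)
        )  # response to unit PSD
        psd = bin_vals / kappa
        recovered = np.trapezoid(psd, spec.freqs)
        assert recovered == pytest.approx(var, rel=0.10)


class TestBandPower:
    def _flat_spec(self, bank, value=3e-12, n=1344, n_ch=34):
        power = np.full((n_ch, len(bank.freqs), n), value)
        times = np.arange(n) / FS
        valid = np.ones((len(bank.freqs), n), dtype=bool)
        return tfr.Spectrogram(power, bank.freqs.copy(), times, valid, FS)

    def test_constant_spectrogram_returns_constant(self, bank, montage):
        spec = self._flat_spec(bank)
        out = tfr.band_period_power(spec, tfr.ALPHA_BAND, montage, (1.0, 3.0))
        assert out == pytest.approx(3e-12)

    def test_linearity_in_power(self, bank, montage):
        spec = self._flat_spec(bank)
        doubled = tfr.Spectrogram(
            2 * spec.power, spec.freqs, spec.times, spec.valid_mask, FS
        )
        a = tfr.band_period_power(spec, tfr.BETA_BAND, montage, (1.0, 3.0))
        b = tfr.band_period_power(doubled, tfr.BETA_BAND, montage, (1.0, 3.0))
        assert b == pytest.approx(2 * a)

    def test_empty_window_rejected(self, bank, montage):
        spec = self._flat_spec(bank)
        spec.valid_mask[:] = False
        with pytest.raises(ValueError):
            tfr.band_period_power(spec, tfr.ALPHA_BAND, montage, (1.0, 3.0))

    def test_band_edges_inclusive(self, bank, montage):
        spec = self._flat_spec(bank)
        spec.power[:, ~((bank.freqs >= 7) & (bank.freqs <= 15)), :] = 99.0
        out = tfr.band_period_power(spec, tfr.ALPHA_BAND, montage, (1.0, 3.0))
        assert out == pytest.approx(3e-12)  # 7 and 15 Hz included, rest ignored


class TestScalarOps:
    @pytest.mark.parametrize(
        "power,expected",
        [(1e-12, 0.0), (1e-11, 10.0), (2e-12, 10 * np.log10(2))],
    )
    def test_db_conversion(self, power, expected):
        assert tfr.to_db(power) == pytest.approx(expected, abs=1e-6)

    def test_db_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tfr.to_db(0.0)

    def test_db_roundtrip(self):
        x = np.array([1e-13, 5e-12, 2e-10])
        np.testing.assert_allclose(tfr.from_db(tfr.to_db(x)), x, rtol=1e-12)

    def test_combine_periods_linear_mean(self):
        assert tfr.combine_periods(1e-12, 3e-12) == pytest.approx(2e-12)
        assert tfr.combine_periods(2e-12, 2e-12) == pytest.approx(2e-12)

    def test_combine_periods_bounded_by_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(1e-13, 1e-10, 2)
            for domain in ("linear", "db"):
                c = tfr.combine_periods(a, b, domain=domain)
                assert min(a, b) <= c <= max(a, b)

    def test_power_ratio(self):
        assert tfr.power_ratio(2e-12, 1e-12) == pytest.approx(2.0)
        assert tfr.power_ratio(3e-12, 3e-12) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tfr.power_ratio(-1e-12, 1e-12)

    def test_ratio_summary_violin_statistics(self):
        """Per-subject ratio summaries report median and central 50%/95%
        intervals; equal alpha and beta power give a degenerate ratio of 1."""
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject": ["S1"] * 50 + ["S2"] * 50,
                "alpha_db": [10.0] * 50 + [13.0] * 50,
                "beta_db": [10.0] * 100,
            }
        )
        out = tfr.ratio_summary(table)
        assert list(out.columns) == ["subject", "q025", "q25", "median", "q75", "q975"]
        s1 = out[out["subject"] == "S1"].iloc[0]
        s2 = out[out["subject"] == "S2"].iloc[0]
        assert s1["median"] == pytest.approx(1.0)
        assert s2["median"] == pytest.approx(10 ** 0.3)
        assert s1["q025"] <= s1["q25"] <= s1["median"] <= s1["q75"] <= s1["q975"]

    def test_ratio_exceeds_one_iff_alpha_db_larger(self):
        rng = np.random.default_rng(1)
        a_db = rng.uniform(-5, 25, 50)
        b_db = rng.uniform(-5, 25, 50)
        ratio = tfr.power_ratio(tfr.from_db(a_db), tfr.from_db(b_db))
        np.testing.assert_array_equal(ratio > 1, a_db > b_db)


class TestTopography:
    def test_constant_spectrogram_gives_constant_map(self, bank, montage):
        power = np.full((34, len(bank.freqs), 400), 4e-12)
        times = np.arange(400) / FS
        valid = np.ones((len(bank.freqs), 400), dtype=bool)
        spec = tfr.Spectrogram(power, bank.freqs.copy(), times, valid, FS)
        m = tfr.channel_topography([spec], montage, (7, 15), (0.2, 1.0))
        assert len(m) == 32
        assert np.allclose(m.to_numpy(), 4e-12)

    def test_empty_collection_rejected(self, montage):
        with pytest.raises(ValueError):
            tfr.channel_topography([], montage, (7, 15), (0.0, 1.0))

    def test_alpha_map_peaks_parieto_occipitally(self, small_band_power, montage):
        """With a parieto-occipital alpha field in the generator, the alpha
        topography's strongest channels lie in the parieto-occipital group."""
        _, _, specs, clean = small_band_power
        tl = clean.timeline
        m = tfr.channel_topography(specs, montage, (7, 15), tl.during_window)
        top = m.sort_values(ascending=False).index[:5]
        assert set(top) <= set(PARIETO_OCCIPITAL)

    def test_proportion_change_map(self):
        pre = pd.Series([1.0, 2.0], index=["A1", "A2"])
        assert (tfr.topography_proportion_change(pre, pre) == 0).all()
        assert (tfr.topography_proportion_change(2 * pre, pre) == 1).all()
        with pytest.raises(ValueError):
            tfr.topography_proportion_change(pre, 0 * pre)

    def test_boost_shows_positive_parieto_occipital_change(
        self, small_band_power, montage
    ):
        """The 3-dB during-stimulus alpha boost appears as a positive
        proportion change (~10^0.3 - 1 = 1.0) over parieto-occipital sites."""
        _, _, specs, clean = small_band_power
        tl = clean.timeline
        pre = tfr.channel_topography(specs, montage, (7, 15), tl.pre_window)
        dur = tfr.channel_topography(specs, montage, (7, 15), tl.during_window)
        change = tfr.topography_proportion_change(dur, pre)
        po = change[list(PARIETO_OCCIPITAL)]
        assert (po > 0).all()
        assert po.mean() == pytest.approx(10 ** 0.3 - 1, rel=0.5)


class TestExtractTable:
    def test_table_schema_and_recovery(self, small_band_power):
        params, table, _, _ = small_band_power
        for col in (
            "alpha_pre_db", "alpha_during_db", "alpha_db",
            "beta_pre_db", "beta_during_db", "beta_db", "score", "subject",
        ):
            assert col in table.columns
        r = np.corrcoef(table["truth_alpha_db"], table["alpha_db"])[0, 1]
        assert r > 0.9
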