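import numpy as np
import pytest

from gistate.spectral import (
    band_edges,
    band_powers,
    power_spectrum,
    validate_df,
)

from conftest import make_segment, tone_segment


class TestPowerSpectrum:
    def test_grid_spacing_is_0_3_cpm(self):
        spec = power_spectrum(tone_segment(9.6))
        np.testing.assert_allclose(np.diff(spec.freqs_cpm), 0.3)

    def test_on_grid_tone_peaks_at_its_bin(self):
        spec = power_spectrum(tone_segment(9.6))
        assert spec.df_cpm == pytest.approx(9.6)
        # oracle: explicit DFT projection onto the 9.6 cpm bin dominates
        assert spec.power[np.argmin(np.abs(spec.freqs_cpm - 9.6))] == np.max(spec.power)

    def test_all_zero_segment_has_zero_power(self):
        spec = power_spectrum(make_segment(np.zeros(600)))
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_parseval(self, rng):
        x = rng.standard_normal(600)
        seg = make_segment(x)
        spec = power_spectrum(seg)
        # energy oracle: full two-sided DFT of the padded, mean-removed window
        xm = x - x.mean()
        full = np.fft.fft(xm, n=2000)
        assert np.sum(np.abs(full) ** 2) / 2000 == pytest.approx(
            np.sum(xm**2), rel=1e-9
        )
        # one-sided power stored by the pipeline matches the two-sided DFT
        one_sided = np.abs(np.fft.rfft(xm, n=2000)) ** 2
        np.testing.assert_allclose(spec.power, one_sided, rtol=1e-12)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            power_spectrum(make_segment(np.zeros(599)))

    def test_scale_invariance_of_df_and_percentages(self, rng):
        seg = tone_segment(9.6)
        seg.samples = seg.samples + 0.3 * rng.standard_normal(600)
        a = power_spectrum(seg)
        seg_scaled = make_segment(7.5 * seg.samples)
        b = power_spectrum(seg_scaled)
        assert b.df_cpm == a.df_cpm
        assert b.p_norm == pytest.approx(a.p_norm, rel=1e-9)
        assert b.p_brady == pytest.approx(a.p_brady, rel=1e-9)


class TestBandEdges:
    @pytest.mark.parametrize(
        "df, band, expected",
        [
            (9.4, "normo", (8.4, 10.4)),
            (10.3, "normo", (9.3, 11.3)),
            (9.1, "brady", (6.1, 8.1)),
            (9.6, "tachy", (10.6, 12.6)),
            (9.0, "normo", (8.0, 10.0)),
        ],
    )
    def test_published_band_triplets(self, df, band, expected):
        edges = band_edges(df)
        lo, hi = getattr(edges, band)
        assert (lo, hi) == pytest.approx(expected)

    def test_bands_are_contiguous_2cpm_intervals(self):
        e = band_edges(11.7)
        assert e.normo[1] - e.normo[0] == pytest.approx(2.0)
        assert e.brady[1] == e.normo[0] and e.normo[1] == e.tachy[0]

    def test_low_df_rejected(self):
        with pytest.raises(ValueError):
            band_edges(2.9)


class TestBandPowers:
    def test_single_bin_spectrum_all_power_in_normo(self):
        # idealized single-bin line: band attribution must be all-normo
        spec = power_spectrum(tone_segment(9.6))
        spec.power = np.zeros_like(spec.power)
        spec.power[np.argmin(np.abs(spec.freqs_cpm - 9.6))] = 1.0
        p_b, p_n, p_t, total = band_powers(spec, band_edges(9.6))
        assert p_n == pytest.approx(100.0, abs=1e-9)
        assert p_b == pytest.approx(0.0, abs=1e-9)
        assert p_t == pytest.approx(0.0, abs=1e-9)
        assert total > 0

    def test_real_tone_concentrates_in_normo(self):
        # a real windowed tone leaks a little into neighbouring bins, but the
        # normogastric band still holds the overwhelming share
        spec = power_spectrum(tone_segment(9.6))
        p_b, p_n, p_t, _ = band_powers(spec, band_edges(9.6))
        assert p_n > 90.0
        assert p_b < 5.0 and p_t < 5.0

    def test_flat_spectrum_matches_bin_count_oracle(self):
        spec = power_spectrum(tone_segment(9.0))
        spec.power = np.ones_like(spec.power)  # idealized white spectrum
        edges = band_edges(9.0)
        p_b, p_n, p_t, total = band_powers(spec, edges)
        # oracle: count 0.3 cpm bin centres in each half-open band / [6, 15)
        f = spec.freqs_cpm
        n_total = np.sum((f >= 6 - 1e-9) & (f < 15 - 1e-9))
        for p, (lo, hi) in zip((p_b, p_n, p_t), (edges.brady, edges.normo, edges.tachy)):
            n_band = np.sum((f >= lo - 1e-9) & (f < hi - 1e-9) & (f >= 6 - 1e-9) & (f < 15 - 1e-9))
            assert p == pytest.approx(100.0 * n_band / n_total, rel=1e-9)
        # each band holds roughly 2 of the 9 cpm
        assert p_n == pytest.approx(100 * 2 / 9, abs=2.0)

    def test_two_equal_tones_split_brady_normo(self):
        # equal tones in the brady (6.9 cpm) and normo (9.0 cpm) bands of DF 9
        t = np.arange(600) / 10.0
        x = np.sin(2 * np.pi * 6.9 / 60 * t) + np.sin(2 * np.pi * 9.0 / 60 * t)
        spec = power_spectrum(make_segment(x))
        edges = band_edges(9.0)
        p_b, p_n, p_t, total = band_powers(spec, edges)
        # brute-force oracle: independent DFT + direct bin-range sums
        xm = x - x.mean()
        power = np.abs(np.fft.rfft(xm, n=2000)) ** 2
        f = np.fft.rfftfreq(2000, d=0.1) * 60.0
        in_total = (f >= 6 - 1e-9) & (f < 15 - 1e-9)

        def oracle(lo, hi):
            sel = in_total & (f >= lo - 1e-9) & (f < hi - 1e-9)
            return 100.0 * power[sel].sum() / power[in_total].sum()

        assert p_b == pytest.approx(oracle(*edges.brady), rel=1e-9)
        assert p_n == pytest.approx(oracle(*edges.normo), rel=1e-9)
        assert p_t == pytest.approx(oracle(*edges.tachy), rel=1e-9)
        # and the equal tones split the power about evenly
        assert p_b == pytest.approx(50.0, abs=3.0)
        assert p_n == pytest.approx(50.0, abs=3.0)
        assert p_t < 4.0

    def test_zero_total_power_flagged(self):
        spec = power_spectrum(make_segment(np.zeros(600)))
        p_b, p_n, p_t, total = band_powers(spec, band_edges(9.0))
        assert total == 0.0
        assert np.isnan(p_b) and np.isnan(p_n) and np.isnan(p_t)

    def test_band_sum_bounded_by_100(self, rng):
        seg = make_segment(rng.standard_normal(600))
        spec = power_spectrum(seg)
        edges = band_edges(max(spec.df_cpm, 6.0))
        p_b, p_n, p_t, _ = band_powers(spec, edges)
        assert p_b + p_n + p_t <= 100.0 + 1e-9


class TestValidateDF:
    @staticmethod
    def _segments(rng, n=20, tone_cpm=9.6, tone_amp=1.0, noise=0.1):
        segs = []
        t = np.arange(600) / 10.0
        for i in range(n):
            x = tone_amp * np.sin(
                2 * np.pi * tone_cpm / 60 * t + rng.uniform(0, 2 * np.pi)
            )
            x = x + noise * rng.standard_normal(600)
            segs.append(power_spectrum(make_segment(x, index=i)))
        return segs

    def test_strong_tone_is_validated(self, rng):
        v = validate_df(self._segments(rng))
        assert v.validated
        assert v.global_peak_cpm == pytest.approx(9.6)
        assert v.anova_p < 1e-6
        assert v.global_peak_cpm not in v.local_peaks_cpm

    def test_white_noise_not_validated(self):
        n_false = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            segs = self._segments(rng, tone_amp=0.0, noise=1.0)
            if validate_df(segs).validated:
                n_false += 1
        assert n_false <= 1  # at most one chance-level false validation

    def test_rival_equal_peak_blocks_validation(self, rng):
        t = np.arange(600) / 10.0
        segs = []
        for i in range(20):
            x = np.sin(2 * np.pi * 6.9 / 60 * t + rng.uniform(0, 2 * np.pi))
            x += np.sin(2 * np.pi * 9.9 / 60 * t + rng.uniform(0, 2 * np.pi))
            x += 0.05 * rng.standard_normal(600)
            segs.append(power_spectrum(make_segment(x, index=i)))
        v = validate_df(segs)
        assert not v.validated
        # the rival peak is found and its contrast is non-significant
        assert any(p >= v.alpha for p in v.contrast_p)

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError):
            validate_df(self._segments(rng, n=4))


def test_noisy_df_recovery_within_one_bin(rng):
    """DF of a 9.6 cpm tone at >= 10 dB SNR lands within one bin nearly always."""
    t = np.arange(600) / 10.0
    hits = 0
    n_trials = 100
    for _ in range(n_trials):
        x = np.sin(2 * np.pi * 9.6 / 60 * t + rng.uniform(0, 2 * np.pi))
        x = x + np.sqrt(0.05) * rng.standard_normal(600)  # ~10 dB in-band SNR
        spec = power_spectrum(make_segment(x))
        hits += abs(spec.df_cpm - 9.6) <= 0.3 + 1e-9
    assert hits >= 95
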