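"""Spectral quantification: periodograms, normalization, bands and clusters."""

import numpy as np
import pytest

from sleepcortex.errors import (
    DegenerateInputError,
    FormatError,
    InsufficientDataError,
    SpecError,
)
from sleepcortex.hypnogram import Hypnogram
from sleepcortex.spectral import (
    BANDS,
    BAND_NAMES,
    CLUSTERS,
    CLUSTER_NAMES,
    FULL_FREQS,
    MASTOIDS,
    N_FULL_BINS,
    N_NORM_BINS,
    NORM_FREQS,
    PsgRecording,
    SCALP_CHANNELS,
    StageSpectrum,
    band_bin_mask,
    band_cluster_power,
    bandpass,
    periodogram_4s,
    reference_to_linked_mastoids,
    relative_power,
    select_windows,
    sleep_indexes,
    stage_spectrum,
)

from conftest import TOY_STAGES

FS = 128.0


def _recording(data, labels=SCALP_CHANNELS + MASTOIDS, fs=FS):
    return PsgRecording(labels, fs, data)


class TestReferencing:
    def test_zero_mastoids_leave_scalp_unchanged(self, rng):
        data = rng.standard_normal((21, 256))
        data[19:] = 0.0
        out = reference_to_linked_mastoids(_recording(data))
        assert out.labels == SCALP_CHANNELS
        np.testing.assert_array_equal(out.data, data[:19])

    def test_constant_reference_arithmetic(self):
        data = np.zeros((21, 128))
        data[:19] = 5.0
        data[19] = 2.0  # A1
        data[20] = 4.0  # A2
        out = reference_to_linked_mastoids(_recording(data))
        np.testing.assert_allclose(out.data, 2.0)

    def test_matches_sample_by_sample_recomputation(self, rng):
        data = rng.standard_normal((21, 512))
        rec = _recording(data)
        out = reference_to_linked_mastoids(rec)
        for ci, ch in enumerate(SCALP_CHANNELS):
            for t in (0, 100, 511):
                expected = data[ci, t] - (data[19, t] + data[20, t]) / 2.0
                assert out.data[ci, t] == pytest.approx(expected, rel=1e-12)

    def test_missing_mastoid_is_error(self, rng):
        rec = PsgRecording(SCALP_CHANNELS, FS, rng.standard_normal((19, 128)))
        with pytest.raises(FormatError, match="mastoid"):
            reference_to_linked_mastoids(rec)


def _sine_recording(freq, seconds=60, fs=FS, amplitude=1.0):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (19, 1))
    return PsgRecording(SCALP_CHANNELS, fs, data)


@pytest.mark.parametrize("method", ["fft", "filtfilt"])
class TestBandpass:
    def _gain_db(self, rec_out, rec_in):
        sl = slice(len(rec_in.data[0]) // 4, -len(rec_in.data[0]) // 4)  # skip edges
        return 20 * np.log10(
            np.std(rec_out.data[0, sl]) / np.std(rec_in.data[0, sl])
        )

    def test_passband_sinusoid_preserved(self, method):
        rec = _sine_recording(13.0)
        out = bandpass(rec, method=method)
        assert abs(self._gain_db(out, rec)) < 1.0

    def test_slow_drift_attenuated(self, method):
        rec = _sine_recording(0.05, seconds=200)
        out = bandpass(rec, method=method)
        assert self._gain_db(out, rec) < -20.0

    def test_dc_offset_removed(self, method):
        rec = PsgRecording(SCALP_CHANNELS, FS, np.full((19, 1280), 100.0))
        out = bandpass(rec, method=method)
        assert np.abs(out.data.mean()) < 1e-6

    def test_high_cut_above_nyquist_is_error(self, method):
        rec = _sine_recording(5.0, seconds=10)
        with pytest.raises(SpecError, match="Nyquist"):
            bandpass(rec, hi=70.0, method=method)


class TestPeriodogram:
    def test_on_bin_sinusoid_concentrates_half_squared_amplitude(self):
        a = 2.0
        t = np.arange(int(4 * FS)) / FS
        p = periodogram_4s(a * np.sin(2 * np.pi * 13.0 * t), FS)
        k13 = int(np.where(FULL_FREQS == 13.0)[0][0])
        assert p[k13] == pytest.approx(a**2 / 2, rel=1e-9)
        others = np.delete(p, k13)
        assert np.all(others < 1e-9 * p[k13])

    def test_zero_signal_gives_zero_power(self):
        assert np.all(periodogram_4s(np.zeros(int(4 * FS)), FS) == 0.0)

    def test_parseval_full_spectrum(self, rng):
        for _ in range(20):
            w = rng.standard_normal(int(4 * FS))
            p = periodogram_4s(w, FS, full=True)
            ms = np.mean((w - w.mean()) ** 2)
            assert p.sum() == pytest.approx(ms, rel=1e-9)

    def test_white_noise_spectrum_is_flat(self, rng):
        w = rng.standard_normal((10000, int(4 * FS)))
        mean_p = periodogram_4s(w, FS).mean(axis=0)
        assert np.all(np.abs(mean_p / mean_p.mean() - 1) < 0.05)

    def test_wrong_length_is_error(self):
        with pytest.raises(SpecError, match="length"):
            periodogram_4s(np.zeros(100), FS)

    def test_hann_taper_preserves_broadband_power_scale(self, rng):
        w = rng.standard_normal((2000, int(4 * FS)))
        rect = periodogram_4s(w, FS, taper="rect").mean()
        hann = periodogram_4s(w, FS, taper="hann").mean()
        assert hann == pytest.approx(rect, rel=0.05)


class TestWindowSelection:
    def test_single_epoch_yields_five_windows(self, rng):
        rec = _recording(rng.standard_normal((21, int(20 * FS))))
        hyp = Hypnogram(("N2",))
        w = select_windows(rec, hyp, {"N2", "N3"})
        assert w.shape == (5, 21, int(4 * FS))

    def test_mask_removes_windows(self, rng):
        rec = _recording(rng.standard_normal((21, int(20 * FS))))
        hyp = Hypnogram(("N2",))
        mask = np.zeros(5, bool)
        mask[2] = True
        assert select_windows(rec, hyp, {"N2"}, mask).shape[0] == 4

    def test_toy_hypnogram_nrem_window_count(self, rng):
        hyp = Hypnogram(TOY_STAGES)
        rec = _recording(
            rng.standard_normal((21, int(30 * 20 * FS))).astype(np.float32)
        )
        w = select_windows(rec, hyp, {"N2", "N3"})
        assert w.shape[0] == (10 + 8 + 2) * 5

    def test_no_eligible_windows_is_distinguished(self, rng):
        rec = _recording(rng.standard_normal((21, int(20 * FS))))
        with pytest.raises(InsufficientDataError):
            select_windows(rec, Hypnogram(("W",)), {"REM"})

    def test_windows_respect_lights_bounds(self, rng):
        rec = _recording(rng.standard_normal((21, int(4 * 20 * FS))))
        hyp = Hypnogram(("N2",) * 4, lights_off=1, lights_on=3)
        assert select_windows(rec, hyp, {"N2"}).shape[0] == 10


class TestStageSpectrum:
    def test_mean_of_identical_windows_is_single_periodogram(self, rng):
        w = rng.standard_normal((1, 19, int(4 * FS)))
        windows = np.repeat(w, 7, axis=0)
        spec = stage_spectrum(windows, FS, "NREM")
        np.testing.assert_allclose(
            spec.power, periodogram_4s(w[0], FS), rtol=1e-12
        )
        assert spec.n_windows == 7

    def test_arithmetic_mean_of_scaled_windows(self, rng):
        w = rng.standard_normal((19, int(4 * FS)))
        windows = np.stack([w, np.sqrt(3) * w])  # powers p and 3p
        spec = stage_spectrum(windows, FS, "NREM")
        np.testing.assert_allclose(spec.power, 2 * periodogram_4s(w, FS), rtol=1e-9)

    def test_empty_window_list_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            stage_spectrum(np.empty((0, 19, int(4 * FS))), FS, "REM")


def _spectrum_from(power):
    return StageSpectrum(state="NREM", power=power, n_windows=1)


class TestRelativePower:
    def test_flat_spectrum_gives_uniform_cells(self):
        rp = relative_power(_spectrum_from(np.full((19, N_FULL_BINS), 3.7)))
        np.testing.assert_allclose(rp.values, 100.0 / (19 * 98), rtol=1e-12)

    def test_concentrated_power(self):
        power = np.zeros((19, N_FULL_BINS))
        power[4, 10] = 42.0
        rp = relative_power(_spectrum_from(power))
        assert rp.values[4, 10] == pytest.approx(100.0)
        assert rp.values.sum() == pytest.approx(100.0)

    def test_bins_above_normalization_range_are_discarded(self):
        power = np.zeros((19, N_FULL_BINS))
        power[0, -1] = 5.0  # 30.00 Hz, outside 0.50-24.75
        power[0, 0] = 1.0
        rp = relative_power(_spectrum_from(power))
        assert rp.values.shape == (19, N_NORM_BINS)
        assert rp.values[0, 0] == pytest.approx(100.0)

    def test_zero_total_power_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            relative_power(_spectrum_from(np.zeros((19, N_FULL_BINS))))


class TestBandClusterPower:
    def test_bands_and_clusters_partition(self):
        bins_per_band = [int(band_bin_mask(b).sum()) for b in BAND_NAMES]
        assert bins_per_band == [18, 12, 16, 16, 36]
        assert sum(bins_per_band) == N_NORM_BINS == 98
        sizes = [len(CLUSTERS[c]) for c in CLUSTER_NAMES]
        assert sizes == [4, 3, 3, 3, 4, 2]
        assert sorted(ch for c in CLUSTER_NAMES for ch in CLUSTERS[c]) == sorted(
            SCALP_CHANNELS
        )

    def test_flat_input_bin_count_arithmetic(self):
        rp = relative_power(_spectrum_from(np.ones((19, N_FULL_BINS))))
        tab = band_cluster_power(rp)
        cell = 100.0 / (19 * 98)
        assert tab.cluster_band.loc["frontopolar", "delta"] == pytest.approx(
            4 * 18 * cell, rel=1e-12
        )
        assert tab.cluster_band.loc["parietal", "sigma"] == pytest.approx(
            3 * 16 * cell, rel=1e-12
        )

    def test_single_bin_concentration_maps_to_parietal_sigma(self):
        power = np.zeros((19, N_FULL_BINS))
        pz = SCALP_CHANNELS.index("Pz")
        k13 = int(np.where(FULL_FREQS == 13.0)[0][0])
        power[pz, k13] = 1.0
        tab = band_cluster_power(relative_power(_spectrum_from(power)))
        assert tab.cluster_band.loc["parietal", "sigma"] == pytest.approx(100.0)
        assert tab.cluster_band.to_numpy().sum() == pytest.approx(100.0)

    def test_grand_sum_conserved_for_random_input(self, rng):
        for _ in range(20):
            rp = relative_power(_spectrum_from(rng.random((19, N_FULL_BINS))))
            tab = band_cluster_power(rp)
            assert tab.cluster_band.to_numpy().sum() == pytest.approx(100.0, abs=1e-9)
            assert tab.channel_band.to_numpy().sum() == pytest.approx(100.0, abs=1e-9)


class TestSleepIndexes:
    def test_indexes_are_table_projections(self, rng):
        nrem = band_cluster_power(
            relative_power(_spectrum_from(rng.random((19, N_FULL_BINS))))
        )
        rem_rp = relative_power(_spectrum_from(rng.random((19, N_FULL_BINS))))
        rem_rp.state = "REM"
        rem = band_cluster_power(rem_rp)
        idx = sleep_indexes(nrem, rem)
        for cluster in CLUSTER_NAMES:
            assert idx.nrem_sigma[cluster] == nrem.cluster_band.loc[cluster, "sigma"]
            assert idx.rem_delta[cluster] == rem.cluster_band.loc[cluster, "delta"]
            assert idx.rem_beta[cluster] == rem.cluster_band.loc[cluster, "beta"]

    def test_state_mismatch_is_error(self, rng):
        tab = band_cluster_power(
            relative_power(_spectrum_from(rng.random((19, N_FULL_BINS))))
        )
        with pytest.raises(SpecError, match="NREM"):
            sleep_indexes(tab, tab)


class TestScaleAndMonotonicity:
    def test_relative_power_is_scale_invariant(self, rng):
        w = rng.standard_normal((40, 19, int(4 * FS)))
        rp1 = relative_power(stage_spectrum(w, FS, "NREM"))
        rp2 = relative_power(stage_spectrum(3.7 * w, FS, "NREM"))
        np.testing.assert_allclose(rp1.values, rp2.values, rtol=1e-9)

    def test_sigma_injection_moves_percentages_monotonically(self, rng):
        noise = rng.standard_normal((19, int(2 * 20 * FS)))
        hyp = Hypnogram(("N2", "N2"))
        t = np.arange(noise.shape[1]) / FS
        c3 = SCALP_CHANNELS.index("C3")
        results = []
        for amp in (0.0, 2.0, 4.0):
            data = noise.copy()
            data[c3] += amp * np.sin(2 * np.pi * 13.0 * t)
            rec = _recording(data, labels=SCALP_CHANNELS)
            w = select_windows(rec, hyp, {"N2", "N3"})
            tab = band_cluster_power(
                relative_power(stage_spectrum(w, FS, "NREM"))
            ).cluster_band
            results.append(tab)
        for lo, hi in zip(results, results[1:]):
            assert hi.loc["central", "sigma"] > lo.loc["central", "sigma"]
            for cluster in CLUSTER_NAMES:
                for band in BAND_NAMES:
                    if (cluster, band) != ("central", "sigma"):
                        assert hi.loc[cluster, band] < lo.loc[cluster, band]
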