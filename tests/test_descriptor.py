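"""Distraction descriptor: filtering, segmentation, artefact screening, and
the PSD / wavelet-phase-stability / coherence feature families."""

import numpy as np
import pytest

from incfrnn.descriptor import (
    DEFAULT_BANDS,
    EEGRecording,
    EpochSet,
    build_descriptor,
    coherence,
    fir_bandpass,
    psd,
    psd_features,
    reject_artifacts,
    segment,
    wps,
)

FS = 512.0


def sine_recording(freq, seconds=4.0, amp=1.0, n_ch=1, dc=0.0):
    t = np.arange(int(seconds * FS)) / FS
    x = amp * np.sin(2 * np.pi * freq * t) + dc
    return EEGRecording(
        np.tile(x, (n_ch, 1)), FS, tuple(f"C{i}" for i in range(n_ch)), []
    )


class TestFirBandpass:
    def test_passband_amplitude_preserved(self):
        rec = fir_bandpass(sine_recording(10.0), 8.0, 13.0)
        interior = rec.samples[0, 600:-600]
        assert np.abs(interior).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        rec = fir_bandpass(sine_recording(40.0), 8.0, 13.0)
        interior = rec.samples[0, 600:-600]
        assert np.abs(interior).max() < 0.05

    def test_dc_removed(self):
        rec = fir_bandpass(sine_recording(10.0, dc=5.0), 8.0, 13.0)
        interior = rec.samples[0, 600:-600]
        assert np.abs(interior.mean()) < 0.05

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError):
            fir_bandpass(sine_recording(10.0), 13.0, 8.0)

    def test_filter_and_segment_commute_on_interior(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 4096))
        onsets = np.array([1024, 2048])
        rec = EEGRecording(x, FS, ("C0",), onsets)
        a = segment(fir_bandpass(rec, 8.0, 13.0), 1.0)
        # filtering each epoch with generous context, then cutting
        b = fir_bandpass(rec, 8.0, 13.0)
        for i, onset in enumerate(onsets):
            direct = a.data[i, 0]
            assert np.allclose(direct, b.samples[0, onset : onset + 512])


class TestSegmentAndArtifacts:
    def make_rec(self, n_trials, spacing=1280, n=None):
        n = n or (n_trials * spacing)
        rng = np.random.default_rng(0)
        return EEGRecording(
            rng.uniform(-50, 50, size=(2, n)),
            FS,
            ("C0", "C1"),
            np.arange(n_trials) * spacing,
        )

    def test_one_epoch_per_valid_onset(self):
        epochs = segment(self.make_rec(150), 1.0)
        assert epochs.n_trials == 150
        assert epochs.data.shape == (150, 2, 512)

    def test_short_final_trial_dropped_with_warning(self, caplog):
        rec = self.make_rec(3, spacing=1280, n=2 * 1280 + 256)
        with caplog.at_level("WARNING"):
            epochs = segment(rec, 1.0)
        assert epochs.n_trials == 2
        assert "dropped" in caplog.text

    def test_artifact_trial_removed(self):
        rec = self.make_rec(5)
        rec.samples[1, 2 * 1280 + 100] = 150.0  # spike inside trial 2
        epochs = reject_artifacts(segment(rec, 1.0))
        assert epochs.n_trials == 4
        assert 2 not in epochs.kept_trial_ids

    def test_clean_trials_all_kept(self):
        epochs = reject_artifacts(segment(self.make_rec(5), 1.0))
        assert epochs.n_trials == 5

    def test_exactly_threshold_amplitude_kept(self):
        rec = self.make_rec(3)
        rec.samples[0, 100] = 100.0  # exactly at the screen, strict 'larger'
        epochs = reject_artifacts(segment(rec, 1.0))
        assert epochs.n_trials == 3

    def test_all_rejected_errors(self):
        rec = self.make_rec(2)
        rec.samples += 500.0
        with pytest.raises(ValueError, match="all trials"):
            reject_artifacts(segment(rec, 1.0))


class TestPsd:
    def test_constant_signal_power_at_dc(self):
        c, N = 3.0, 64
        spec = psd(np.full(N, c), FS)
        assert spec.power[0] == pytest.approx(N * c * c)
        assert np.allclose(spec.power[1:], 0.0, atol=1e-9)

    def test_bin_frequency_sine_two_bins(self):
        N = 512
        t = np.arange(N) / FS
        spec = psd(np.sin(2 * np.pi * 16.0 * t), FS)  # bin 16
        k = 16
        assert spec.power[k] == pytest.approx(N / 4)
        assert spec.power[N - k] == pytest.approx(N / 4)
        others = np.delete(spec.power, [k, N - k])
        assert np.abs(others).max() < 1e-9

    def test_parseval_identity(self, rng):
        for _ in range(20):
            x = rng.standard_normal(int(rng.integers(16, 600)))
            spec = psd(x, FS)
            energy = float(np.sum(x**2))
            assert spec.power.sum() == pytest.approx(energy, rel=1e-9)


class TestPsdFeatures:
    def _flat_spectrum(self):
        N = 512
        rngf = np.fft.fftfreq(N, 1 / FS)
        coeffs = np.ones(N)
        from incfrnn.descriptor import Spectrum

        return Spectrum(coeffs, np.full(N, 2.0), N, FS)

    def test_flat_spectrum(self):
        conc, pvar, _ = psd_features(self._flat_spectrum(), (8.0, 13.0))
        assert conc == pytest.approx(0.0, abs=1e-9)
        assert pvar == 0.0

    def test_single_dominant_peak_nondominant_near_zero(self):
        from incfrnn.descriptor import Spectrum

        N = 512
        power = np.full(N, 1e-9)
        power[10] = 100.0  # 10 Hz bin at fs 512, N 512
        spec = Spectrum(np.zeros(N), power, N, FS)
        _, _, ndom = psd_features(spec, (8.0, 13.0))
        assert ndom == pytest.approx(0.0, abs=1e-6)

    def test_two_distant_equal_peaks_split_power(self):
        from incfrnn.descriptor import Spectrum

        N = 512
        power = np.zeros(N)
        power[9] = 50.0   # 9 Hz
        power[13] = 50.0  # 13 Hz, > 2 Hz away
        spec = Spectrum(np.zeros(N), power, N, FS)
        _, _, ndom = psd_features(spec, (8.0, 13.0))
        assert ndom == pytest.approx(0.5)

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            psd_features(self._flat_spectrum(), (8.0, 9.0))


class TestWps:
    def test_identical_trials_give_perfect_stability(self, rng):
        trial = rng.standard_normal(512)
        es = EpochSet(np.tile(trial, (20, 1, 1)), FS, ("C0",), tuple(range(20)))
        assert wps(es, "C0", (8.0, 13.0)).gamma == pytest.approx(1.0, abs=1e-9)

    def test_random_phases_give_low_stability(self, rng):
        es = EpochSet(
            rng.standard_normal((500, 1, 512)), FS, ("C0",), tuple(range(500))
        )
        assert wps(es, "C0", (8.0, 13.0)).gamma < 0.1

    def test_gamma_in_unit_interval_on_random_epochs(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 8))
            es = EpochSet(
                rng.standard_normal((m, 1, 128)), FS, ("C0",), tuple(range(m))
            )
            assert 0.0 <= wps(es, "C0", (8.0, 13.0)).gamma <= 1.0

    def test_single_trial_errors(self, rng):
        es = EpochSet(rng.standard_normal((1, 1, 128)), FS, ("C0",), (0,))
        with pytest.raises(ValueError):
            wps(es, "C0", (8.0, 13.0))


class TestCoherence:
    def test_scaled_copy_perfect_coherence(self, rng):
        x = rng.standard_normal((10, 512))
        es = EpochSet(np.stack([x, 2 * x], 1), FS, ("A", "B"), tuple(range(10)))
        cv = coherence(es, "A", "B", (8.0, 13.0))
        assert cv.band_mean == pytest.approx(1.0, abs=1e-6)
        in_band = (cv.freqs >= 8) & (cv.freqs <= 13)
        assert np.allclose(cv.cxy[in_band], 1.0, atol=1e-6)

    def test_independent_noise_low_coherence(self, rng):
        es = EpochSet(
            rng.standard_normal((200, 2, 512)), FS, ("A", "B"), tuple(range(200))
        )
        assert coherence(es, "A", "B", (8.0, 13.0)).band_mean < 0.2

    def test_values_in_unit_interval_on_random_epochs(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 8))
            es = EpochSet(
                rng.standard_normal((m, 2, 128)), FS, ("A", "B"), tuple(range(m))
            )
            cv = coherence(es, "A", "B", (8.0, 13.0))
            valid = ~np.isnan(cv.cxy)
            assert np.all((cv.cxy[valid] >= 0) & (cv.cxy[valid] <= 1))

    def test_single_trial_errors(self, rng):
        es = EpochSet(rng.standard_normal((1, 2, 128)), FS, ("A", "B"), (0,))
        with pytest.raises(ValueError):
            coherence(es, "A", "B", (8.0, 13.0))


class TestBuildDescriptor:
    def make_bands(self, rng, n_trials=12):
        channels = ("T5", "T6", "O1", "OZ", "O2")
        out = {}
        for name in DEFAULT_BANDS:
            out[name] = EpochSet(
                rng.standard_normal((n_trials, 5, 256)),
                FS,
                channels,
                tuple(range(n_trials)),
            )
        return out

    def test_default_grid_emits_44_features(self, rng):
        table = build_descriptor(self.make_bands(rng))
        assert table.shape == (12, 44)
        families = {c.split("_")[0] for c in table.columns}
        assert families == {"psd", "wps", "coh"}

    def test_selected_subset_expressible_by_name(self, rng):
        """The 12-feature descriptor of the authentication model is a named
        column selection: PSD+WPS of every channel plus two coherence pairs."""
        table = build_descriptor(self.make_bands(rng))
        wanted = ["coh_O1-OZ_alpha", "coh_OZ-O2_alpha"] + [
            f"wps_{ch}_alpha" for ch in ("T5", "T6", "O1", "OZ", "O2")
        ] + [
            f"psd_{ch}_alpha_concavity" for ch in ("T5", "T6", "O1", "OZ", "O2")
        ]
        assert len(wanted) == 12
        sub = table[wanted]
        assert sub.shape == (12, 12)

    def test_empty_pair_list_drops_coherence_columns(self, rng):
        table = build_descriptor(self.make_bands(rng), pairs=())
        assert not [c for c in table.columns if c.startswith("coh")]
        assert table.shape == (12, 40)

    def test_unknown_channel_errors(self, rng):
        with pytest.raises(KeyError):
            build_descriptor(self.make_bands(rng), channels=("T5", "XX"))

    def test_labels_column(self, rng):
        labels = ["target"] * 6 + ["nontarget"] * 6
        table = build_descriptor(self.make_bands(rng), labels=labels)
        assert list(table["class"]) == labels
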