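"""Average removal, zero-phase band-pass, windowing, DWT, artifact mask."""

import numpy as np
import pytest
from scipy import signal

from weareeg.core_io import Recording
from weareeg.preprocess import (ArtifactPolicy, WindowPlan, bandpass,
                                dwt_enhance, make_windows, reject_artifacts,
                                remove_average)


def _rec(x, fs=256.0):
    x = np.atleast_2d(x)
    return Recording(x, fs, [f"C{i}" for i in range(x.shape[0])])


class TestRemoveAverage:
    def test_antisymmetric_pair_unchanged(self, rng):
        c = rng.normal(size=100)
        rec = _rec(np.vstack([c, -c]))
        out = remove_average(rec)
        assert np.allclose(out.samples, rec.samples)

    def test_common_offset_removed_exactly(self, rng):
        x = rng.normal(size=(3, 100))
        x -= x.mean(axis=0, keepdims=True)
        out = remove_average(_rec(x + 50e-6))
        assert np.allclose(out.samples, x)

    def test_per_sample_mean_zero(self, rng):
        out = remove_average(_rec(rng.normal(size=(4, 256))))
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-15

    def test_single_channel_across_mode_rejected(self):
        with pytest.raises(ValueError):
            remove_average(_rec(np.zeros((1, 10))))

    def test_running_mean_removes_slow_drift(self):
        t = np.arange(256 * 10) / 256
        drift = 100e-6 * t
        out = remove_average(_rec(drift), mode="running-mean", length_s=1.0)
        inner = out.samples[0, 256:-256]
        assert np.abs(inner).max() < 1e-6


class TestBandpass:
    def test_passband_amplitude_and_zero_lag(self):
        fs = 256.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(_rec(x), 1, 20, order=4, zero_phase=True).samples[0]
        mid = slice(int(3 * fs), int(17 * fs))  # past the edge transients
        amp = np.abs(out[mid]).max()
        assert 0.98 <= amp <= 1.005
        lag = np.argmax(signal.correlate(out[mid], x[mid], mode="full"))
        assert lag == len(out[mid]) - 1  # peak at zero lag

    def test_dc_removed(self):
        x = np.full(256 * 4, 1.0)
        out = bandpass(_rec(x), 1, 20).samples[0]
        assert np.sqrt(np.mean(out**2)) < 1e-3

    def test_50hz_attenuated_by_40db(self):
        fs = 256.0
        # magnitude-response oracle: forward-backward pass applies |H|^2
        sos = signal.butter(4, [1, 20], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[50.0], fs=fs)
        assert -40 * np.log10(np.abs(h[0])) > 40
        # and the filtered signal itself, past the edge transients
        t = np.arange(int(fs * 20)) / fs
        out = bandpass(_rec(np.sin(2 * np.pi * 50 * t)), 1, 20).samples[0]
        mid = slice(int(3 * fs), int(17 * fs))
        assert -20 * np.log10(np.abs(out[mid]).max()) > 40

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_rec(np.zeros(100), fs=100.0), 1, 60)

    def test_zero_phase_nearly_idempotent_in_passband(self):
        fs = 256.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        once = bandpass(_rec(x), 1, 20)
        twice = bandpass(once, 1, 20)
        mid = slice(int(3 * fs), int(17 * fs))
        ratio = (np.abs(twice.samples[0, mid]).max()
                 / np.abs(once.samples[0, mid]).max())
        assert 0.98 <= ratio <= 1.0


class TestWindows:
    def test_seizure_plan_count(self):
        rec = _rec(np.zeros(int(256 * 60)), fs=256.0)
        assert len(make_windows(rec, WindowPlan(4.0, 0.5))) == 113

    def test_single_exact_window(self):
        rec = _rec(np.zeros(256 * 4), fs=256.0)
        ws = make_windows(rec, WindowPlan(4.0, 4.0))
        assert len(ws) == 1
        assert ws[0].data.shape == (1, 1024)

    def test_workload_plan_step(self):
        plan = WindowPlan.from_overlap(56.0, 0.60)
        assert plan.step_s == pytest.approx(22.4)
        assert plan.overlap_fraction == pytest.approx(0.60)

    def test_overlap_fraction_of_seizure_plan(self):
        assert WindowPlan(4.0, 0.5).overlap_fraction == pytest.approx(0.875)

    def test_short_record_warns_and_returns_empty(self):
        rec = _rec(np.zeros(256), fs=256.0)
        with pytest.warns(UserWarning):
            assert make_windows(rec, WindowPlan(4.0, 0.5)) == []

    def test_no_overlap_partitions_span(self, rng):
        x = rng.normal(size=(1, 256 * 12))
        rec = _rec(x, fs=256.0)
        ws = make_windows(rec, WindowPlan(4.0, 4.0))
        rebuilt = np.concatenate([w.data for w in ws], axis=1)
        assert np.array_equal(rebuilt, x)

    def test_times_are_absolute(self):
        rec = Recording(np.zeros((1, 256 * 8)), 256.0, ["C0"],
                        start_time=100.0)
        ws = make_windows(rec, WindowPlan(4.0, 2.0))
        assert [w.start_s for w in ws] == [100.0, 102.0, 104.0]

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            WindowPlan(4.0, 5.0)


class TestDWT:
    def test_parseval_energy_conservation(self, rng):
        x = rng.normal(size=1024)
        coeffs = dwt_enhance(x, "db4", 4)
        energy = sum((c**2).sum() for c in coeffs)
        assert energy == pytest.approx((x**2).sum(), rel=1e-9)

    def test_impulse_perfect_reconstruction(self):
        import pywt

        x = np.zeros(256)
        x[100] = 1.0
        coeffs = dwt_enhance(x, "db4", 4)
        back = pywt.waverec(coeffs, "db4", mode="periodization")
        assert np.allclose(back, x, atol=1e-10)

    @pytest.mark.parametrize("freq,band_idx", [(48.0, 4), (24.0, 3),
                                               (12.0, 2), (6.0, 1)])
    def test_sinusoid_energy_localizes_to_octave_band(self, freq, band_idx):
        """4-level dyadic bands at 256 Hz: d1~[64,128], d2~[32,64],
        d3~[16,32], d4~[8,16], a4~[0,8] — a sinusoid's energy should
        concentrate in its octave (coeffs returned coarse-to-fine)."""
        fs = 256.0
        t = np.arange(1024) / fs
        x = np.sin(2 * np.pi * freq * t)
        coeffs = dwt_enhance(x, "db8", 4)
        energies = np.array([(c**2).sum() for c in coeffs])
        # freq<8 -> a4 (index 0); [8,16) -> d4 (1); [16,32) -> d3 (2);
        # [32,64) -> d2 (3); [64,128) -> d1 (4)
        expected = {48.0: 3, 24.0: 2, 12.0: 1, 6.0: 0}[freq]
        assert int(np.argmax(energies)) == expected

    def test_unsupported_family_lists_supported(self):
        with pytest.raises(ValueError, match="db4"):
            dwt_enhance(np.zeros(64), "nosuchwavelet", 2)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            dwt_enhance(np.zeros(8), "db4", 4)


class TestArtifactRejection:
    def _windows(self, x, fs=128.0):
        return make_windows(_rec(x, fs=fs), WindowPlan(4.0, 0.5))

    def test_clean_background_unmasked(self, background_60s):
        ws = make_windows(background_60s, WindowPlan(4.0, 0.5))
        _, mask = reject_artifacts(ws)
        assert mask.sum() == 0

    def test_inserted_blink_masks_overlapping_windows_only(self,
                                                           background_60s):
        x = background_60s.samples.copy()
        blink_at = int(30 * background_60s.fs)
        x[0, blink_at] += 500e-6
        ws = make_windows(background_60s.copy_with(samples=x),
                          WindowPlan(4.0, 0.5))
        _, mask = reject_artifacts(ws)
        hit = {i for i, w in enumerate(ws)
               if w.start_s <= 30.0 < w.start_s + 4.0}
        assert set(np.flatnonzero(mask)) == hit

    def test_infinite_thresholds_mask_nothing(self, background_60s):
        ws = make_windows(background_60s, WindowPlan(4.0, 0.5))
        _, mask = reject_artifacts(
            ws, ArtifactPolicy(max_abs_uv=np.inf, max_rms_ratio=np.inf))
        assert not mask.any()
        assert len(mask) == len(ws)
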