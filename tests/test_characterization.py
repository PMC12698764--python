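"""Front-end noise math (IRN/DR/NFB/ENOB), CMRR estimation, and the
IFCN guideline check."""

import math

import numpy as np
import pytest

from weareeg import synth
from weareeg.characterization import (LOG2_DB, characterize_noise, cmrr,
                                      dynamic_range, enob, ifcn_check, irn_pp,
                                      irn_rms, noise_free_bits,
                                      sinusoid_peak_amplitude)
from weareeg.core_io import AcquisitionSpec
from weareeg.synth import SynthSpec


class TestIRN:
    def test_all_zero_stream(self):
        with pytest.warns(UserWarning):
            assert irn_rms(np.zeros(100)) == 0.0

    def test_hand_computed_rms_without_dc_removal(self):
        with pytest.warns(UserWarning):
            assert irn_rms(np.array([3.0, 4.0]),
                           remove_dc=False) == pytest.approx(3.5355, abs=1e-3)

    def test_dc_removal_discounts_offset(self):
        x = np.random.default_rng(0).normal(scale=1.0, size=20000) + 100.0
        assert irn_rms(x) == pytest.approx(1.0, rel=0.05)

    def test_generator_round_trip_within_5pct(self):
        spec = SynthSpec(fs=250.0, duration_s=60.0, noise_rms_uv=0.16,
                         channel_labels=("IN1",), seed=2)
        rec = synth.gen_noise_floor(spec)
        est = irn_rms(rec.samples[0]) * 1e6
        assert est == pytest.approx(0.16, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            irn_rms(np.array([]))

    def test_peak_to_peak_rule(self):
        assert irn_pp(1.0) == pytest.approx(6.6)
        assert irn_pp(0.0) == 0.0
        assert irn_pp(0.14) == pytest.approx(0.924)
        with pytest.raises(ValueError):
            irn_pp(-1.0)


class TestScalarFigures:
    """Printed reference values: an EEG front-end datasheet row measured
    at VREF 4.5 V, PGA gain 24."""

    def test_dynamic_range_datasheet_row(self):
        assert dynamic_range(4.5, 24, 0.14e-6) == pytest.approx(119.5,
                                                                abs=0.05)

    def test_dynamic_range_rounding_band_for_measured_row(self):
        # 0.16 uV prints 118.24 dB; the printed 0.16 is itself rounded
        assert dynamic_range(4.5, 24, 0.16e-6) == pytest.approx(118.24,
                                                                abs=0.25)

    def test_enob_datasheet_row(self):
        assert enob(4.5, 24, 0.14e-6) == pytest.approx(19.85, abs=0.01)

    def test_nfb_datasheet_and_device_rows(self):
        assert noise_free_bits(4.5, 24, 0.98e-6) == pytest.approx(18.54,
                                                                  abs=0.01)
        assert noise_free_bits(4.5, 24, 1.07e-6) == pytest.approx(18.41,
                                                                  abs=0.01)

    def test_log_laws(self):
        assert (dynamic_range(4.5, 24, 0.07e-6)
                - dynamic_range(4.5, 24, 0.14e-6)) == pytest.approx(6.02,
                                                                    abs=0.01)
        assert (enob(4.5, 24, 0.07e-6)
                - enob(4.5, 24, 0.14e-6)) == pytest.approx(1.0)
        assert (noise_free_bits(4.5, 24, 2.0e-6)
                - noise_free_bits(4.5, 24, 1.0e-6)) == pytest.approx(-1.0)

    def test_dr_enob_algebraic_identity(self):
        dr = dynamic_range(4.5, 24, 0.2e-6)
        nb = enob(4.5, 24, 0.2e-6)
        assert dr == pytest.approx(nb * LOG2_DB, rel=1e-12)

    def test_nfb_enob_relation_under_66_rule(self):
        """nfb(6.6*rms) = enob(rms) + log2(2*sqrt(2)/6.6) exactly."""
        rms = 0.33e-6
        lhs = noise_free_bits(4.5, 24, irn_pp(rms))
        rhs = enob(4.5, 24, rms) + math.log2(2 * math.sqrt(2) / 6.6)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_noise_infinite(self):
        assert dynamic_range(4.5, 24, 0.0) == math.inf

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range(0.0, 24, 1e-6)
        with pytest.raises(ValueError):
            noise_free_bits(4.5, 24, 1e-6, formula="bogus")


class TestCharacterizePipeline:
    def test_round_trip_recovers_generator_rms(self):
        spec = SynthSpec(fs=250.0, duration_s=60.0, noise_rms_uv=0.16,
                         channel_labels=("IN1",), seed=5)
        rec = synth.gen_noise_floor(spec)
        report = characterize_noise(rec, AcquisitionSpec(fs=250.0))
        assert report.irn_rms_uv == pytest.approx(0.16, rel=0.05)
        assert report.irn_pp_uv == pytest.approx(6.6 * report.irn_rms_uv)
        assert report.dr_db == pytest.approx(
            dynamic_range(4.5, 24, report.irn_rms_uv * 1e-6))

    def test_figures_decrease_as_noise_increases(self):
        quiet = SynthSpec(fs=250.0, duration_s=60.0, noise_rms_uv=0.16,
                          channel_labels=("IN1",), seed=5)
        loud = SynthSpec(fs=250.0, duration_s=60.0, noise_rms_uv=0.32,
                         channel_labels=("IN1",), seed=5)
        a = characterize_noise(synth.gen_noise_floor(quiet))
        b = characterize_noise(synth.gen_noise_floor(loud))
        assert b.dr_db < a.dr_db
        assert b.nfb_bits < a.nfb_bits
        assert b.enob_bits < a.enob_bits


class TestCMRR:
    def test_closed_form_ratio(self):
        """100 mV peak in, 3.5355 uV residual -> 20*log10 ratio 89.03 dB."""
        rec = synth.gen_common_mode_stream(fs=250.0, duration_s=150.0,
                                           test_freq=50.0,
                                           residual_uv_peak=3.5355,
                                           noise_rms_uv=0.0)
        res = cmrr(rec, vin_p=0.1, test_freq=50.0)
        assert res.cmrr_db == pytest.approx(89.03, abs=0.1)

    def test_unity_ratio_is_zero_db(self):
        rec = synth.gen_common_mode_stream(fs=250.0, duration_s=150.0,
                                           test_freq=50.0,
                                           residual_uv_peak=1.0,
                                           noise_rms_uv=0.0)
        res = cmrr(rec, vin_p=1.0e-6, test_freq=50.0)
        assert res.cmrr_db == pytest.approx(0.0, abs=0.05)

    def test_amplitude_recovered_in_noise_within_2pct(self):
        rec = synth.gen_common_mode_stream(fs=250.0, duration_s=150.0,
                                           test_freq=50.0,
                                           residual_uv_peak=5.0,
                                           noise_rms_uv=0.3, seed=1)
        amp = sinusoid_peak_amplitude(rec.samples[0], 250.0, 50.0) * 1e6
        assert amp == pytest.approx(5.0, rel=0.02)

    def test_short_stream_rejected(self):
        rec = synth.gen_common_mode_stream(fs=250.0, duration_s=30.0,
                                           test_freq=50.0,
                                           residual_uv_peak=1.0)
        with pytest.raises(ValueError):
            cmrr(rec, vin_p=0.1)

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError):
            sinusoid_peak_amplitude(np.zeros(100), 250.0, 0.5)


class TestIFCN:
    def test_wearable_spec_row_passes(self):
        check = ifcn_check(fs=250.0, resolution_uv=0.023,
                           input_impedance_mohm=1000.0, cmrr_db=110.0,
                           irn_pp_uv=1.07)
        assert check.overall is True
        assert all(r.passed for r in check.results)

    def test_slow_sampling_fails_that_guideline(self):
        check = ifcn_check(fs=199.0, resolution_uv=0.023,
                           input_impedance_mohm=1000.0, cmrr_db=110.0,
                           irn_pp_uv=1.07)
        assert check.overall is False
        failed = [r.name for r in check.results if r.passed is False]
        assert failed == ["sampling_rate"]

    def test_boundary_values_inclusive(self):
        check = ifcn_check(fs=200.0, resolution_uv=0.5,
                           input_impedance_mohm=100.0, cmrr_db=110.0,
                           irn_pp_uv=1.5)
        assert check.overall is True

    def test_missing_measurement_indeterminate(self):
        check = ifcn_check(fs=250.0, resolution_uv=0.023)
        assert check.overall is None
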