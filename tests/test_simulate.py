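"""Baseband I/Q simulation: closed form, noise model, single channel."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import breathradar as br
from breathradar.exceptions import (
    AliasingError,
    ConfigMismatchError,
    NearWavelengthWarning,
)


class TestSynthesizeTx:
    def test_phase_zero_at_origin_and_unit_envelope(self):
        cfg = br.RadarConfig(carrier_frequency_hz=1000.0,
                             intermediate_frequency_hz=10.0,
                             sample_rate_hz=100.0)
        tx = br.synthesize_tx(cfg, duration_s=1.0)
        assert tx.in_phase[0] == pytest.approx(1.0)
        assert tx.quadrature[0] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(
            tx.in_phase**2 + tx.quadrature**2, 1.0, rtol=1e-12
        )

    def test_phase_noise_is_seed_reproducible(self):
        cfg = br.RadarConfig(carrier_frequency_hz=1000.0,
                             intermediate_frequency_hz=10.0,
                             sample_rate_hz=100.0,
                             tx_phase_noise_std_rad=0.05)
        a = br.synthesize_tx(cfg, 1.0, seed=3)
        b = br.synthesize_tx(cfg, 1.0, seed=3)
        np.testing.assert_array_equal(a.in_phase, b.in_phase)

    def test_if_above_nyquist_rejected(self):
        cfg = br.RadarConfig(carrier_frequency_hz=1e9,
                             intermediate_frequency_hz=60.0,
                             sample_rate_hz=100.0)
        with pytest.raises(AliasingError):
            br.synthesize_tx(cfg, 1.0)


class TestSimulateBaseband:
    def test_zero_motion_zero_distance_gives_half_a_on_i(self, config):
        m = br.normal_breathing(peak_to_peak_m=0.0, duration_s=1.0)
        ch = br.PropagationChannel(nominal_distance_m=0.0, attenuation=0.8)
        iq = br.simulate_baseband(m, ch, config)
        np.testing.assert_allclose(iq.in_phase, 0.4, rtol=1e-15)
        np.testing.assert_allclose(iq.quadrature, 0.0, atol=1e-15)

    def test_eighth_wavelength_distance_rotates_to_minus_q(self, config, lam):
        # static phase = -4*pi*(lambda/8)/lambda = -pi/2 -> (I, Q) = (0, -A/2)
        m = br.normal_breathing(peak_to_peak_m=0.0, duration_s=1.0)
        ch = br.PropagationChannel(nominal_distance_m=lam / 8.0)
        iq = br.simulate_baseband(m, ch, config)
        np.testing.assert_allclose(iq.in_phase, 0.0, atol=1e-12)
        np.testing.assert_allclose(iq.quadrature, -0.5, rtol=1e-12)

    @given(
        d0_frac=st.floats(min_value=0.0, max_value=0.99),
        p2p=st.floats(min_value=0.0, max_value=3e-2),
        attenuation=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_constant_envelope_without_noise(self, config, lam, d0_frac,
                                             p2p, attenuation):
        m = br.normal_breathing(peak_to_peak_m=p2p, duration_s=4.0)
        ch = br.PropagationChannel(nominal_distance_m=d0_frac * lam,
                                   attenuation=attenuation)
        iq = br.simulate_baseband(m, ch, config)
        np.testing.assert_allclose(
            iq.envelope(), attenuation / 2.0, rtol=1e-12
        )

    def test_half_wavelength_distance_shift_is_invisible(self, config, lam):
        m = br.normal_breathing(duration_s=4.0)
        a = br.simulate_baseband(
            m, br.PropagationChannel(nominal_distance_m=lam / 8), config
        )
        b = br.simulate_baseband(
            m, br.PropagationChannel(nominal_distance_m=lam / 8 + lam / 2),
            config,
        )
        np.testing.assert_allclose(a.in_phase, b.in_phase, atol=1e-12)
        np.testing.assert_allclose(a.quadrature, b.quadrature, atol=1e-12)

    def test_sample_rate_mismatch_rejected(self, config, optimum_channel):
        m = br.normal_breathing(sample_rate_hz=50.0)
        with pytest.raises(ConfigMismatchError):
            br.simulate_baseband(m, optimum_channel, config)

    def test_seeded_noise_is_bit_identical(self, config, optimum_channel):
        m = br.normal_breathing(duration_s=4.0)
        noise = br.NoiseModel(snr_db=20.0, seed=11)
        a = br.simulate_baseband(m, optimum_channel, config, noise)
        b = br.simulate_baseband(m, optimum_channel, config, noise)
        np.testing.assert_array_equal(a.in_phase, b.in_phase)
        np.testing.assert_array_equal(a.quadrature, b.quadrature)

    def test_distance_beyond_wavelength_warns(self, config, lam):
        m = br.normal_breathing(duration_s=1.0)
        ch = br.PropagationChannel(nominal_distance_m=2 * lam)
        with pytest.warns(NearWavelengthWarning):
            br.simulate_baseband(m, ch, config)

    def test_small_angle_quadrature_linearity(self, config, lam):
        # after rotating out the static phase, the quadrature branch is
        # approximately linear in x for |x| << lambda (small-angle oracle)
        m = br.normal_breathing(peak_to_peak_m=lam / 500, duration_s=10.0)
        ch = br.PropagationChannel(nominal_distance_m=lam / 8)
        iq = br.simulate_baseband(m, ch, config)
        z = (iq.in_phase + 1j * iq.quadrature) * np.exp(1j * np.pi / 2)
        linear_pred = 0.5 * (-4 * np.pi * m.samples / lam)
        max_angle = 4 * np.pi * abs(m.samples).max() / lam
        assert np.abs(z.imag - linear_pred).max() <= 0.5 * max_angle**2


class TestSingleChannel:
    @staticmethod
    def _fundamental_power(s, fs, f0):
        spec = np.abs(np.fft.rfft(s - s.mean())) ** 2
        freqs = np.fft.rfftfreq(s.size, 1.0 / fs)
        return spec[np.argmin(np.abs(freqs - f0))]

    def test_null_point_suppresses_fundamental(self, config, lam):
        m = br.normal_breathing()  # 0.5 Hz exact bin over 60 s
        powers = {}
        for name, d0 in [("optimum", lam / 8), ("null", lam / 4)]:
            ch = br.PropagationChannel(nominal_distance_m=d0)
            s = br.simulate_single_channel(m, ch, config)
            powers[name] = self._fundamental_power(s, 100.0, 0.5)
        assert powers["null"] < powers["optimum"] * 1e-4

    def test_zero_motion_gives_constant_output(self, config, optimum_channel):
        m = br.normal_breathing(peak_to_peak_m=0.0, duration_s=1.0)
        s = br.simulate_single_channel(m, optimum_channel, config)
        assert np.ptp(s) == pytest.approx(0.0, abs=1e-15)


class TestExplicitMixingChain:
    def test_matches_closed_form_on_scaled_link(self):
        # scaled-down RF so the carrier is representable on the grid
        cfg = br.RadarConfig(carrier_frequency_hz=220.0,
                             intermediate_frequency_hz=20.0,
                             sample_rate_hz=50.0)
        lam = br.wavelength(cfg)
        m = br.normal_breathing(rate_hz=0.5, peak_to_peak_m=lam / 50,
                                duration_s=10.0, sample_rate_hz=50.0)
        ch = br.PropagationChannel(nominal_distance_m=lam / 8)
        closed = br.simulate_baseband(m, ch, cfg)
        mixed = br.simulate_baseband_mixing(m, ch, cfg, oversample=200)
        sl = slice(50, -50)  # skip filter edge transients
        np.testing.assert_allclose(
            mixed.in_phase[sl], closed.in_phase[sl], atol=5e-3
        )
        np.testing.assert_allclose(
            mixed.quadrature[sl], closed.quadrature[sl], atol=5e-3
        )
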