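"""Arctangent demodulation: phase extraction, inversion, DC offsets."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import breathradar as br
from breathradar.exceptions import DegenerateSampleError, IllConditionedArcWarning


def _simulate(motion, d0, config, noise=None):
    ch = br.PropagationChannel(nominal_distance_m=d0)
    return br.simulate_baseband(motion, ch, config, noise)


class TestExtractPhase:
    def test_positive_real_axis_is_zero_phase(self):
        iq = br.BasebandIQ(np.full(16, 0.5), np.zeros(16), 100.0)
        np.testing.assert_allclose(br.extract_phase(iq), 0.0, atol=1e-15)

    def test_negative_imaginary_axis_is_minus_half_pi(self):
        iq = br.BasebandIQ(np.zeros(16), np.full(16, -0.5), 100.0)
        np.testing.assert_allclose(br.extract_phase(iq), -np.pi / 2,
                                   rtol=1e-15)

    def test_zero_envelope_rejected(self):
        i = np.full(16, 0.5)
        q = np.zeros(16)
        i[7] = 0.0
        with pytest.raises(DegenerateSampleError, match="sample 7"):
            br.extract_phase(br.BasebandIQ(i, q, 100.0))

    def test_matches_simulator_phase_up_to_2pi_k(self, config, lam):
        # round-trip oracle against the simulator's stored phase
        m = br.normal_breathing()
        ch = br.PropagationChannel(nominal_distance_m=lam / 8)
        iq = br.simulate_baseband(m, ch, config)
        phi_true = br.baseband_phase(m, ch, config)
        gamma = br.extract_phase(iq)
        k = (gamma - phi_true) / (2 * np.pi)
        np.testing.assert_allclose(k, np.round(k.mean()), atol=1e-9)

    def test_unwrapping_tracks_multi_turn_rotation(self):
        # a phase ramp of several turns must come back continuous
        phi = np.linspace(0.0, 6 * np.pi, 500)
        iq = br.BasebandIQ(np.cos(phi), np.sin(phi), 100.0)
        np.testing.assert_allclose(br.extract_phase(iq), phi, atol=1e-12)


class TestArctangentDemodulate:
    @pytest.mark.parametrize("d0_frac", [0.0, 1 / 8, 1 / 4, 3 / 8])
    def test_recovers_motion_within_micrometre(self, config, lam, d0_frac):
        m = br.normal_breathing()  # 0.5 Hz, 3 mm p2p
        iq = _simulate(m, d0_frac * lam, config)
        sig = br.arctangent_demodulate(iq, config)
        truth = m.samples - m.samples.mean()
        assert np.abs(sig.displacement_m - truth).max() < 1e-6

    def test_recovery_is_distance_invariant(self, config, lam):
        # the quadrature receiver's defining advantage: identical output
        # at optimum (lambda/8) and null (lambda/4) distances
        m = br.normal_breathing()
        recovered = [
            br.arctangent_demodulate(_simulate(m, f * lam, config),
                                     config).displacement_m
            for f in (0.0, 1 / 8, 1 / 4, 3 / 8)
        ]
        for other in recovered[1:]:
            np.testing.assert_allclose(recovered[0], other, atol=1e-9)

    def test_zero_motion_zero_distance_recovers_zero(self, config):
        m = br.normal_breathing(peak_to_peak_m=0.0, duration_s=1.0)
        sig = br.arctangent_demodulate(_simulate(m, 0.0, config), config,
                                       remove_mean=False)
        np.testing.assert_allclose(sig.displacement_m, 0.0, atol=1e-15)

    def test_raw_output_recovers_distance_modulo_half_wavelength(
        self, config, lam
    ):
        # static target at lambda/8: unwrapped phase is -pi/2, so the raw
        # xbar reports exactly d0 (no 2*pi*k ambiguity hit here)
        m = br.normal_breathing(peak_to_peak_m=0.0, duration_s=1.0)
        sig = br.arctangent_demodulate(_simulate(m, lam / 8, config), config,
                                       remove_mean=False)
        assert sig.displacement_m.mean() == pytest.approx(lam / 8, rel=1e-12)

    def test_phase_displacement_invariant(self, config, lam):
        m = br.normal_breathing(duration_s=10.0)
        sig = br.arctangent_demodulate(_simulate(m, lam / 8, config), config)
        scale = config.propagation_speed / (
            4 * np.pi * config.rf_frequency_hz
        )
        np.testing.assert_allclose(
            sig.displacement_m, -sig.phase_rad * scale, atol=1e-18
        )
        assert sig.displacement_m.mean() == pytest.approx(0.0, abs=1e-15)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, config, lam, scale):
        m = br.normal_breathing(duration_s=4.0)
        iq = _simulate(m, lam / 8, config)
        scaled = br.BasebandIQ(iq.in_phase * scale, iq.quadrature * scale,
                               iq.sample_rate_hz)
        a = br.arctangent_demodulate(iq, config).displacement_m
        b = br.arctangent_demodulate(scaled, config).displacement_m
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("p2p_frac", [1e-2, 1e-3, 1e-4])
    def test_amplitude_ratio_approaches_unity(self, config, lam, p2p_frac):
        # demodulation is exactly linear; recovery holds at any small amplitude
        m = br.normal_breathing(peak_to_peak_m=p2p_frac * lam, duration_s=10.0)
        sig = br.arctangent_demodulate(_simulate(m, lam / 8, config), config)
        ratio = np.ptp(sig.displacement_m) / np.ptp(m.samples)
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_round_trip_identity_for_random_motions(self, config, lam):
        # arbitrary band-limited motion, p2p < lambda/4, noise off
        for seed in range(20):
            m = br.random_breathing_like(seed, duration_s=10.0,
                                         peak_to_peak_m=lam / 5)
            sig = br.arctangent_demodulate(_simulate(m, lam / 8, config),
                                           config)
            truth = m.samples - m.samples.mean()
            assert np.abs(sig.displacement_m - truth).max() < 1e-9


class TestDcOffsets:
    @staticmethod
    def _arc(center, radius, span, n=500):
        phi = np.linspace(0.0, span, n)
        return br.BasebandIQ(center[0] + radius * np.cos(phi),
                             center[1] + radius * np.sin(phi), 100.0)

    def test_recovers_offset_centre_from_half_circle(self):
        iq = self._arc((0.1, -0.05), 0.5, np.pi)
        ci, cq = br.estimate_dc_offsets(iq)
        assert ci == pytest.approx(0.1, abs=1e-6)
        assert cq == pytest.approx(-0.05, abs=1e-6)

    def test_centred_full_circle_gives_zero(self):
        iq = self._arc((0.0, 0.0), 0.5, 2 * np.pi)
        ci, cq = br.estimate_dc_offsets(iq)
        assert ci == pytest.approx(0.0, abs=1e-9)
        assert cq == pytest.approx(0.0, abs=1e-9)

    def test_tiny_arc_warns_and_falls_back(self):
        iq = self._arc((0.1, 0.2), 0.5, 1e-3)
        with pytest.warns(IllConditionedArcWarning):
            assert br.estimate_dc_offsets(iq) == (0.0, 0.0)

    def test_dc_correction_restores_recovery(self, config, lam):
        m = br.normal_breathing()
        noise = br.NoiseModel(dc_offset_i=0.08, dc_offset_q=-0.06)
        ch = br.PropagationChannel(nominal_distance_m=lam / 8)
        iq = br.simulate_baseband(m, ch, config, noise)
        sig = br.arctangent_demodulate(iq, config, correct_dc=True)
        truth = m.samples - m.samples.mean()
        assert np.abs(sig.displacement_m - truth).max() < 1e-6
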