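"""Circuit-model unit tests against independent complex-arithmetic oracles."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beadpulse as bp
from beadpulse.circuits import ShellLink, default_shell_link
from beadpulse.errors import ConfigError

from conftest import FREQS


def oracle_baseline(R_f, C_p, L_s, f):
    """Hand evaluation of jwL + R_f/(1 + jwR_fC_p) with cmath scalars."""
    w = 2 * math.pi * f
    return 1j * w * L_s + R_f / (1 + 1j * w * R_f * C_p)


class TestBaselineSpectrum:
    def test_purely_resistive_limit(self):
        ap = bp.ApertureModel(R_f=12345.0, C_p=0.0, L_s=0.0)
        z = bp.baseline_spectrum(ap, FREQS)
        assert np.allclose(z, 12345.0)
        assert np.allclose(np.angle(z), 0.0)

    def test_rc_corner_identity(self):
        ap = bp.ApertureModel(R_f=10e3, C_p=10e-12, L_s=0.0)
        f_corner = 1.0 / (2 * math.pi * ap.R_f * ap.C_p)
        z = bp.baseline_spectrum(ap, [f_corner])[0]
        assert abs(z) == pytest.approx(ap.R_f / math.sqrt(2), rel=1e-12)
        assert math.degrees(cmath.phase(z)) == pytest.approx(-45.0, abs=1e-9)

    def test_matches_hand_evaluation_at_default_carriers(self):
        ap = bp.ApertureModel(R_f=10e3, C_p=10e-12, L_s=1e-6)
        z = bp.baseline_spectrum(ap, FREQS)
        expected = [oracle_baseline(10e3, 10e-12, 1e-6, f) for f in FREQS]
        assert np.allclose(z, expected, rtol=1e-12)

    def test_phase_regimes(self, aperture):
        # resistive at low frequency, capacitive near the RC corner,
        # inductive once wL_s dominates (above the LC resonance)
        corner = 1.0 / (2 * math.pi * aperture.R_f * aperture.C_p)
        resonance = 1.0 / (
            2 * math.pi * math.sqrt(aperture.L_s * aperture.C_p)
        )
        low, high = 1.0, 10.0 * resonance
        ph = np.degrees(
            np.angle(bp.baseline_spectrum(aperture, [low, corner, high]))
        )
        assert abs(ph[0]) < 0.1
        assert ph[1] < -10.0
        assert ph[2] > 0.0

    def test_rejects_nonpositive_frequency(self, aperture):
        with pytest.raises(ConfigError):
            bp.baseline_spectrum(aperture, [45e3, -1.0])


class TestCoulterDeltaR:
    def test_zero_diameter(self, aperture):
        assert bp.coulter_delta_r(0.0, aperture) == 0.0

    def test_working_bead_amplitude(self, aperture):
        # direct evaluation of the DeBlois-Bean form at rho = 0.625 ohm m,
        # d = 8.2 um, D_eff = 33.85 um gives ~3.4e2 ohm
        d, d_eff, rho = 8.2e-6, aperture.d_eff, aperture.resistivity
        expected = (
            4 * rho * d**3 / (math.pi * d_eff**4)
            / (1 - 0.8 * (d / d_eff) ** 3)
        )
        got = bp.coulter_delta_r(d, aperture)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.4e2, rel=0.01)

    def test_monotone_in_diameter(self, aperture):
        sizes = [3.9e-6, 4.7e-6, 5.6e-6, 5.7e-6, 8.2e-6, 10.3e-6, 20.1e-6]
        values = [bp.coulter_delta_r(d, aperture) for d in sizes]
        assert np.all(np.diff(values) > 0)

    @given(st.floats(min_value=0.3e-6, max_value=3.385e-6))
    @settings(derandomize=True, max_examples=40)
    def test_cubic_scaling_for_small_beads(self, d):
        # d <= D_eff / 10: doubling the diameter multiplies dR by 8 +- 5%
        ap = bp.default_aperture()
        ratio = bp.coulter_delta_r(2 * d, ap) / bp.coulter_delta_r(d, ap)
        assert ratio == pytest.approx(8.0, rel=0.05)

    def test_rejects_oversized_bead(self, aperture):
        with pytest.raises(ConfigError):
            bp.coulter_delta_r(aperture.d_eff, aperture)


class TestBeadElement:
    def test_shell_removal_limit(self, aperture, working_bead):
        # a vanishing shell (R_sh huge, C_sh tiny) reduces to the
        # nonmetallized bead element at every carrier
        ghost = bp.BeadModel(
            diameter=8.2e-6, kind="metallized",
            delta_R=working_bead.delta_R, C_b=working_bead.C_b,
            R_sh=1e18, C_sh=1e-30, m_density=1e-9,
        )
        db_ghost = bp.bead_element(ghost, aperture, FREQS)
        db_bare = bp.bead_element(working_bead, aperture, FREQS)
        assert np.allclose(db_ghost, db_bare, rtol=1e-9)

    def test_dc_limit_is_delta_r(self, aperture, working_bead):
        db = bp.bead_element(working_bead, aperture, 1e-3)
        assert db.real == pytest.approx(working_bead.delta_R, rel=1e-9)
        assert abs(db.imag) < 1e-6

    def test_nonmetallized_real_part_positive(self, aperture, working_bead):
        assert np.all(bp.bead_element(working_bead, aperture, FREQS).real > 0)

    def test_metallized_sign_pattern(self, aperture):
        # shell with R_sh << R_slab: positive at 45 kHz, negative at 2 MHz
        bead = bp.BeadModel.metallized(8.2e-6, 0.8, aperture)
        assert bead.R_sh < aperture.r_slab
        db = bp.bead_element(bead, aperture, FREQS)
        assert db[0].real > 0
        assert db[3].real < 0

    def test_matches_hand_evaluation(self, aperture):
        bead = bp.BeadModel.metallized(8.2e-6, 0.5, aperture)
        r_slab = aperture.r_slab
        for f in FREQS:
            w = 2 * math.pi * f
            y = (
                1 / (r_slab + bead.delta_R)
                + 1j * w * bead.C_b
                + 1 / (bead.R_sh + 1 / (1j * w * bead.C_sh))
            )
            expected = 1 / y - r_slab
            got = complex(bp.bead_element(bead, aperture, f))
            assert got == pytest.approx(expected, rel=1e-12)


class TestTotalImpedance:
    def test_s_zero_reproduces_baseline(self, aperture, working_bead):
        db = bp.bead_element(working_bead, aperture, FREQS)
        z = bp.total_impedance(aperture, db, 0.0, FREQS)
        assert np.allclose(z, bp.baseline_spectrum(aperture, FREQS), rtol=0,
                           atol=0)

    def test_series_limit_without_parasitics(self):
        ap = bp.ApertureModel(R_f=10e3, C_p=0.0, L_s=0.0)
        bead = bp.BeadModel.nonmetallized(8.2e-6, ap)
        db = bp.bead_element(bead, ap, FREQS)
        z = bp.total_impedance(ap, db, 1.0, FREQS)
        assert np.allclose(z, ap.R_f + db, rtol=1e-14)

    def test_intermediate_s_matches_direct_evaluation(self, aperture,
                                                      working_bead):
        f = 2e6
        db = complex(bp.bead_element(working_bead, aperture, f))
        w = 2 * math.pi * f
        expected = 1j * w * aperture.L_s + 1 / (
            1j * w * aperture.C_p + 1 / (aperture.R_f + 0.5 * db)
        )
        got = complex(bp.total_impedance(aperture, db, 0.5, f))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rejects_out_of_range_s(self, aperture, working_bead):
        db = bp.bead_element(working_bead, aperture, FREQS)
        with pytest.raises(ConfigError):
            bp.total_impedance(aperture, db, -0.1, FREQS)


class TestMetallizationLinks:
    def test_endpoint_values(self):
        link = ShellLink(r0=625.0, c0=50e-12)
        assert bp.metallization_to_shell(0.0, link) == (math.inf, 0.0)
        assert bp.metallization_to_shell(1.0, link) == (625.0, 50e-12)

    @given(
        st.floats(min_value=1e-3, max_value=1.0),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_density(self, m1, m2):
        if m1 == m2:
            return
        lo, hi = sorted((m1, m2))
        r_lo, c_lo = bp.metallization_to_shell(lo)
        r_hi, c_hi = bp.metallization_to_shell(hi)
        assert r_lo > r_hi and c_lo < c_hi

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            bp.metallization_to_shell(1.5)

    def test_dose_link_endpoints_and_midpoint(self):
        p = bp.BindingParams(floor=0.002, ceiling=0.85, c50=20.0, hill=1.5)
        assert bp.dose_to_metallization(0.0, p) == p.floor
        assert bp.dose_to_metallization(1e9, p) == pytest.approx(
            p.ceiling, rel=1e-3
        )
        assert bp.dose_to_metallization(p.c50, p) == pytest.approx(
            0.5 * (p.floor + p.ceiling), rel=1e-12
        )
        with pytest.raises(ConfigError):
            bp.dose_to_metallization(-1.0, p)


class TestSpectralSignatures:
    """Qualitative fingerprints the circuit calibration must reproduce."""

    @pytest.mark.parametrize(
        "diameter", [3.9e-6, 4.7e-6, 5.6e-6, 5.7e-6, 8.2e-6, 10.3e-6, 20.1e-6]
    )
    def test_nonmetallized_positive_at_all_carriers(self, aperture, diameter):
        bead = bp.BeadModel.nonmetallized(diameter, aperture)
        dzp, _ = bp.peak_spectrum(bead, aperture, FREQS)
        assert np.all(dzp > 0)
        assert np.all(bp.bead_element(bead, aperture, FREQS).real > 0)

    def test_pulse_amplitude_ordering_with_size(self, aperture):
        sizes = [3.9e-6, 5.6e-6, 8.2e-6, 20.1e-6]
        dzp45 = [
            bp.peak_spectrum(
                bp.BeadModel.nonmetallized(d, aperture), aperture, FREQS
            )[0][0]
            for d in sizes
        ]
        assert np.all(np.diff(dzp45) > 0)

    def test_phase_change_peaks_at_2mhz(self, aperture, working_bead):
        _, dphip = bp.peak_spectrum(working_bead, aperture, FREQS)
        assert FREQS[np.argmax(np.abs(dphip))] == 2e6

    def test_conformal_layer_negative_everywhere(self, aperture):
        # a purely conductive layer (C_sh -> inf) dips at ALL carriers,
        # unlike the nanostructured shell whose dip is frequency-specific
        bead = bp.BeadModel.metallized(8.2e-6, 0.8, aperture)
        dzp_shell, _ = bp.peak_spectrum(bead, aperture, FREQS)
        dzp_conf, _ = bp.peak_spectrum(
            bead.with_conformal_shell(), aperture, FREQS
        )
        assert dzp_shell[0] > 0 and np.any(dzp_shell < 0)
        assert np.all(dzp_conf < 0)
        conf_db = bp.bead_element(
            bead.with_conformal_shell(), aperture, FREQS
        )
        assert np.all(conf_db.real < 0)


class TestValidation:
    def test_aperture_invariants(self):
        with pytest.raises(ConfigError):
            bp.ApertureModel(eta_slab=1.5)
        with pytest.raises(ConfigError):
            bp.ApertureModel(side_length=-1e-6)

    def test_bead_consistency(self, aperture):
        with pytest.raises(ConfigError):
            bp.BeadModel(
                diameter=8.2e-6, kind="nonmetallized", delta_R=300.0,
                C_b=1e-15, R_sh=625.0, C_sh=50e-12, m_density=0.0,
            )

    def test_shell_link_defaults_track_aperture(self, aperture):
        link = default_shell_link(aperture)
        assert link.r0 == pytest.approx(0.1 * aperture.r_slab)
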