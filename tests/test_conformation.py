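"""CD secondary structure, peak finding/shifts, and displacement scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    CDSpectrum,
    DisplacementSeries,
    GroundTruth,
    ValidationError,
    alpha_helix_content,
    assign_site,
    displacement_percentages,
    find_peak,
    find_peak_eem,
    helix_from_spectrum,
    make_cd,
    make_displacement,
    make_eem,
    make_emission_spectrum,
    mean_residue_ellipticity,
    peak_shift,
)


def _flat_cd(theta_mdeg, conc=2e-6, n=585, pathlength=0.1):
    wl = np.arange(200.0, 251.0, 1.0)
    return CDSpectrum(wl, np.full(wl.size, theta_mdeg), conc, n, pathlength)


class TestMRE:
    def test_direct_evaluation(self):
        # -22.66 / (10 * 2e-6 * 585 * 0.1)
        mre = mean_residue_ellipticity(_flat_cd(-22.66), 208.0)
        assert mre == pytest.approx(-22.66 / (10 * 2e-6 * 585 * 0.1), rel=1e-9)
        assert mre == pytest.approx(-19367.5, abs=0.05)

    def test_zero_ellipticity_zero_mre(self):
        assert mean_residue_ellipticity(_flat_cd(0.0), 208.0) == 0.0

    def test_inverse_linear_in_concentration(self):
        mre1 = mean_residue_ellipticity(_flat_cd(-20.0, conc=2e-6), 208.0)
        mre2 = mean_residue_ellipticity(_flat_cd(-20.0, conc=4e-6), 208.0)
        assert mre2 == pytest.approx(mre1 / 2.0)

    def test_out_of_range_wavelength_rejected(self):
        with pytest.raises(ValidationError):
            mean_residue_ellipticity(_flat_cd(-20.0), 300.0)

    def test_interpolates_between_grid_points(self):
        wl = np.array([200.0, 210.0, 220.0, 230.0, 240.0])
        theta = np.array([-10.0, -20.0, -10.0, -5.0, -1.0])
        spec = CDSpectrum(wl, theta, 2e-6, 585, 0.1)
        mre_205 = mean_residue_ellipticity(spec, 205.0)
        assert mre_205 == pytest.approx(-15.0 / (10 * 2e-6 * 585 * 0.1))


class TestAlphaHelix:
    def test_anchors(self):
        assert alpha_helix_content(-4000.0) == pytest.approx(0.0)
        assert alpha_helix_content(-33000.0) == pytest.approx(100.0)

    def test_53_percent_point(self):
        assert alpha_helix_content(-19370.0) == pytest.approx(53.0, abs=0.01)

    @settings(max_examples=50, derandomize=True)
    @given(mre=st.floats(-40000.0, 5000.0), bump=st.floats(1.0, 1000.0))
    def test_affine_and_strictly_decreasing(self, mre, bump):
        a, b = alpha_helix_content(mre), alpha_helix_content(mre - bump)
        assert b > a
        # affine: equal increments give equal changes
        c = alpha_helix_content(mre - 2 * bump)
        assert (c - b) == pytest.approx(b - a, rel=1e-9, abs=1e-9)

    def test_cd_generator_round_trip(self):
        truth = GroundTruth(alpha_helix_pct=53.0, seed=0)
        result = helix_from_spectrum(make_cd(truth))
        assert result.alpha_helix_pct == pytest.approx(53.0, abs=1e-8)

    def test_zero_helix_truth_hits_coil_anchor(self):
        truth = GroundTruth(alpha_helix_pct=0.0, seed=0)
        result = helix_from_spectrum(make_cd(truth))
        assert result.mre_208 == pytest.approx(-4000.0, rel=1e-9)


class TestPeakFinding:
    def test_gaussian_peak_located_subsample(self):
        wl, y = make_emission_spectrum(center_nm=337.0)
        peak = find_peak(wl, y)
        assert peak.position_nm == pytest.approx(337.0, abs=0.1)
        assert not peak.tie_flag

    def test_off_grid_center_refined(self):
        wl, y = make_emission_spectrum(center_nm=337.4)
        peak = find_peak(wl, y)
        assert peak.position_nm == pytest.approx(337.4, abs=0.1)

    def test_monotone_ramp_flags_edge(self):
        peak = find_peak(np.arange(10.0), np.arange(10.0))
        assert peak.tie_flag

    def test_plateau_flags_tie(self):
        y = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        peak = find_peak(np.arange(5.0), y)
        assert peak.tie_flag

    def test_eem_peak_I_found_despite_scatter(self):
        ex, em, z = make_eem()
        peak = find_peak_eem(ex, em, z, ex_window=(255, 305), em_window=(300, 400))
        assert peak.position_nm[0] == pytest.approx(280.0, abs=1.0)
        assert peak.position_nm[1] == pytest.approx(338.0, abs=0.5)

    def test_eem_global_max_is_peak_II_after_masking(self):
        # Peak II (225/340) is the taller aromatic signal; the Rayleigh
        # ridge is taller still but must be masked out
        ex, em, z = make_eem()
        peak = find_peak_eem(ex, em, z)
        assert peak.position_nm[0] == pytest.approx(225.0, abs=1.0)
        assert peak.position_nm[1] == pytest.approx(340.0, abs=0.5)


class TestPeakShift:
    def test_published_peak_I_shift_is_no_shift(self):
        ex, em, z_ref = make_eem(peaks=((280.0, 338.0, 587.254),
                                        (225.0, 340.0, 728.174)))
        _, _, z_smp = make_eem(peaks=((280.0, 337.0, 514.769),
                                      (225.0, 338.0, 411.384)))
        window = {"ex_window": (255, 305), "em_window": (300, 400)}
        ref = find_peak_eem(ex, em, z_ref, **window)
        smp = find_peak_eem(ex, em, z_smp, **window)
        shift = peak_shift(ref, smp, tolerance_nm=2.0)
        assert shift.shift_nm[1] == pytest.approx(-1.0, abs=0.2)
        assert shift.verdict == "no_shift"

    def test_identity_shift(self):
        wl, y = make_emission_spectrum()
        peak = find_peak(wl, y)
        shift = peak_shift(peak, peak)
        assert shift.shift_nm == 0.0
        assert shift.intensity_ratio == 1.0
        assert shift.verdict == "no_shift"

    def test_large_shift_verdict(self):
        wl, y1 = make_emission_spectrum(center_nm=338.0)
        _, y2 = make_emission_spectrum(center_nm=345.0)
        shift = peak_shift(find_peak(wl, y1), find_peak(wl, y2))
        assert shift.shift_nm == pytest.approx(7.0, abs=0.2)
        assert shift.verdict == "shifted"


class TestDisplacement:
    def test_proportionality(self):
        series = DisplacementSeries([0.0, 1e-6, 2e-6], [100.0, 80.0, 60.0])
        result = displacement_percentages(series)
        assert result.percentages == pytest.approx([100.0, 80.0, 60.0])

    def test_constant_series_stays_at_100(self):
        series = DisplacementSeries([0.0, 1e-6, 2e-6], [75.0, 75.0, 75.0])
        assert displacement_percentages(series).percentages == pytest.approx(
            [100.0, 100.0, 100.0])

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        base = np.array([100.0, 80.0, 60.0])
        series = DisplacementSeries([0.0, 1e-6, 2e-6], base * scale)
        assert displacement_percentages(series).percentages == pytest.approx(
            [100.0, 80.0, 60.0])

    def test_competitive_model_decreases_strictly(self):
        truth = GroundTruth(noise_sigma=0.0, seed=0)
        result = displacement_percentages(
            make_displacement(truth, shared_site=True))
        assert np.all(np.diff(result.percentages) < 0)

    def test_strong_fast_competitor_halves_signal(self):
        # competitor at 5x the probe's K, reaching 5x the probe concentration
        truth = GroundTruth(noise_sigma=0.0, seed=0, k_binding=5 * 3.0e5)
        result = displacement_percentages(make_displacement(
            truth, shared_site=True, conc_grid=np.linspace(0, 20e-6, 6),
            probe_tot_M=4e-6, k_probe=3.0e5))
        assert result.percentages[-1] < 50.0


class TestSiteAssignment:
    def _result(self, final_pct, probe):
        series = DisplacementSeries([0.0, 1e-6], [100.0, final_pct],
                                    probe_name=probe)
        return displacement_percentages(series)

    def test_warfarin_displaced_only(self):
        assert assign_site(self._result(75.0, "warfarin"),
                           self._result(96.0, "dansylsarcosine")) == "site_I"

    def test_dansylsarcosine_displaced_only(self):
        assert assign_site(self._result(97.0, "warfarin"),
                           self._result(60.0, "dansylsarcosine")) == "site_II"

    def test_both_flat_is_neither(self):
        assert assign_site(self._result(99.0, "warfarin"),
                           self._result(98.0, "dansylsarcosine")) == "neither"

    def test_both_displaced_is_both(self):
        assert assign_site(self._result(50.0, "warfarin"),
                           self._result(40.0, "dansylsarcosine")) == "both"

    def test_generator_round_trip(self):
        truth = GroundTruth(noise_sigma=0.0, seed=0)
        war = displacement_percentages(make_displacement(truth, shared_site=True))
        dan = displacement_percentages(make_displacement(
            truth, shared_site=False, probe_name="dansylsarcosine"))
        assert assign_site(war, dan) == "site_I"
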