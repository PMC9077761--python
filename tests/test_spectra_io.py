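"""CSV dialect round-trips, reader validation, and the JSON report."""

import numpy as np
import pytest

from specbind import (
    CDSpectrum,
    DecayCurve,
    DisplacementSeries,
    FormatError,
    GroundTruth,
    TitrationSeries,
    ValidationError,
    fit_stern_volmer,
    make_cd,
    make_decay,
    make_displacement,
    make_titration,
)
from specbind import spectra_io
from specbind.quenching import classify_mechanism


def _assert_close(a, b):
    np.testing.assert_allclose(a, b, rtol=1e-12)


class TestTitrationIO:
    def test_csv_round_trip(self, tmp_path, noisy_truth):
        series = make_titration(noisy_truth, 298.0, with_absorbance=True)
        path = tmp_path / "titration.csv"
        spectra_io.write_titration(series, path)
        back = spectra_io.read_titration(path)
        _assert_close(back.quencher_conc, series.quencher_conc)
        _assert_close(back.intensity, series.intensity)
        _assert_close(back.absorbance_ex, series.absorbance_ex)
        assert back.temperature_K == series.temperature_K
        assert back.corrected == series.corrected

    def test_ten_row_micromolar_file(self, tmp_path):
        path = tmp_path / "t.csv"
        rows = "\n".join(f"{c},{1000.0 / (1 + 0.067 * c)}" for c in range(10))
        path.write_text("# temperature_K = 298\nconc,intensity\n" + rows + "\n")
        series = spectra_io.read_titration(path)
        assert len(series) == 10
        assert series.quencher_conc[0] == 0.0
        assert series.quencher_conc[-1] == pytest.approx(9e-6)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("conc,signal\n0,100\n1,90\n")
        with pytest.raises(FormatError, match="intensity"):
            spectra_io.read_titration(path, temperature_K=298.0)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            spectra_io.read_titration(path, temperature_K=298.0)

    def test_out_of_order_concentrations_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("conc,intensity\n0,100\n2,80\n1,90\n")
        with pytest.raises(ValidationError):
            spectra_io.read_titration(path, temperature_K=298.0)

    def test_nonpositive_intensity_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("conc,intensity\n0,100\n1,0\n2,80\n")
        with pytest.raises(ValidationError):
            spectra_io.read_titration(path, temperature_K=298.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError, match="not found"):
            spectra_io.read_titration(tmp_path / "nope.csv", temperature_K=298.0)


class TestOtherRoundTrips:
    def test_decay(self, tmp_path):
        curve = make_decay(GroundTruth(seed=5))
        path = tmp_path / "decay.csv"
        spectra_io.write_decay(curve, path)
        back = spectra_io.read_decay(path)
        _assert_close(back.time_ns, curve.time_ns)
        _assert_close(back.counts, curve.counts)
        assert back.tail_start_ns == curve.tail_start_ns

    def test_cd(self, tmp_path):
        spectrum = make_cd(GroundTruth(seed=5), noise_mdeg=0.05)
        path = tmp_path / "cd.csv"
        spectra_io.write_cd(spectrum, path)
        back = spectra_io.read_cd(path)
        _assert_close(back.ellipticity_mdeg, spectrum.ellipticity_mdeg)
        assert back.protein_conc_M == spectrum.protein_conc_M
        assert back.n_residues == spectrum.n_residues

    def test_displacement(self, tmp_path):
        series = make_displacement(GroundTruth(seed=5))
        path = tmp_path / "disp.csv"
        spectra_io.write_displacement(series, path)
        back = spectra_io.read_displacement(path)
        _assert_close(back.intensity, series.intensity)
        assert back.probe_name == series.probe_name


class TestReport:
    def _quench_block(self, truth):
        fits = [fit_stern_volmer(make_titration(truth, t))
                for t in sorted(truth.k_sv_by_T)]
        verdict = classify_mechanism(fits)
        return {"fits": fits, "mechanism": verdict}

    def test_partial_report_has_only_requested_block(self, tmp_path,
                                                     noiseless_truth):
        path = tmp_path / "report.json"
        spectra_io.write_report({"quenching": self._quench_block(noiseless_truth)},
                                path)
        doc = spectra_io.read_report(path)
        assert set(doc["results"]) == {"quenching"}

    def test_full_report_is_schema_valid(self, tmp_path, noiseless_truth):
        from specbind import (
            fit_double_log, fit_vant_hoff, helix_from_spectrum,
            displacement_percentages, assign_site,
            make_titrations_by_temperature,
        )

        truth = noiseless_truth
        bindings = [fit_double_log(s)
                    for s in make_titrations_by_temperature(truth)]
        war = displacement_percentages(make_displacement(truth, shared_site=True))
        dan = displacement_percentages(
            make_displacement(truth, shared_site=False,
                              probe_name="dansylsarcosine"))
        results = {
            "quenching": self._quench_block(truth),
            "binding": bindings,
            "thermodynamics": fit_vant_hoff(bindings),
            "cd": helix_from_spectrum(make_cd(truth)),
            "displacement": {"series": [war, dan],
                             "site_assignment": assign_site(war, dan)},
        }
        path = tmp_path / "report.json"
        spectra_io.write_report(results, path, provenance={"inputs": []})
        doc = spectra_io.read_report(path)
        assert spectra_io.validate_report(doc) == []
        assert set(doc["results"]) == set(results)

    def test_schema_violation_is_reported(self, tmp_path):
        path = tmp_path / "report.json"
        spectra_io.write_report({"thermodynamics": {"force_type": "hbond_vdw"}},
                                path)
        problems = spectra_io.validate_report(spectra_io.read_report(path))
        assert any("delta_h_kj_per_mol" in p for p in problems)

    def test_round_trip_preserves_values_exactly(self, tmp_path,
                                                 noiseless_truth):
        block = self._quench_block(noiseless_truth)
        path = tmp_path / "report.json"
        spectra_io.write_report({"quenching": block}, path)
        doc = spectra_io.read_report(path)
        for fit, loaded in zip(block["fits"], doc["results"]["quenching"]["fits"]):
            # json round-trips Python floats exactly (repr precision)
            assert loaded["k_sv_per_M"] == fit.k_sv
            assert loaded["k_q_per_M_s"] == fit.k_q
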