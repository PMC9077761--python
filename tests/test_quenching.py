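"""Inner-filter correction, Stern-Volmer fitting, and mechanism rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    AbsorbancePair,
    InsufficientDataError,
    QuenchResult,
    TitrationSeries,
    ValidationError,
    classify_mechanism,
    compute_kq,
    correct_inner_filter,
    correct_series,
    fit_stern_volmer,
    make_titration,
)


def _sv_series(ksv, temperature=298.0, f0=1000.0, n=10):
    q = np.arange(n) * 1e-6
    return TitrationSeries(temperature, q, f0 / (1.0 + ksv * q))


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self):
        assert correct_inner_filter(100.0, AbsorbancePair(0.0, 0.0)) == 100.0

    def test_direct_evaluation(self):
        # 100 * 10**((0.1 + 0.1)/2) = 100 * 10**0.1
        out = correct_inner_filter(100.0, AbsorbancePair(0.1, 0.1))
        assert out == pytest.approx(125.89254117941675, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValidationError):
            AbsorbancePair(-0.01, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        a_ex=st.floats(0.0, 2.0), a_em=st.floats(0.0, 2.0),
        bump=st.floats(1e-6, 1.0),
    )
    def test_monotone_in_absorbance_and_never_decreases(self, a_ex, a_em, bump):
        base = correct_inner_filter(50.0, AbsorbancePair(a_ex, a_em))
        assert base >= 50.0
        assert correct_inner_filter(50.0, AbsorbancePair(a_ex + bump, a_em)) > base
        assert correct_inner_filter(50.0, AbsorbancePair(a_ex, a_em + bump)) > base

    def test_series_correction_recovers_generating_model(self, noiseless_truth):
        attenuated = make_titration(noiseless_truth, 298.0, with_absorbance=True)
        corrected = correct_series(attenuated)
        assert corrected.corrected
        fit = fit_stern_volmer(corrected)
        assert fit.k_sv == pytest.approx(6.702e4, rel=1e-8)


class TestSternVolmer:
    def test_noiseless_recovery_of_published_constant(self):
        """A series generated as F0/F = 1 + 6.702e4 [Q] returns that slope."""
        fit = fit_stern_volmer(_sv_series(6.702e4))
        assert fit.k_sv == pytest.approx(6.702e4, rel=1e-8)
        assert fit.r_corr == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_matches_closed_form_ols_slope(self, noisy_truth):
        series = make_titration(noisy_truth, 298.0)
        fit = fit_stern_volmer(series)
        x, y = series.quencher_conc, series.f0 / series.intensity
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.k_sv == pytest.approx(slope, rel=1e-12)

    def test_constant_intensity_gives_zero_slope(self):
        series = TitrationSeries(298.0, np.arange(5) * 1e-6, np.full(5, 800.0))
        assert fit_stern_volmer(series).k_sv == pytest.approx(0.0, abs=1e-9)

    def test_two_points_insufficient(self):
        series = TitrationSeries(298.0, [0.0, 1e-6], [100.0, 90.0])
        with pytest.raises(InsufficientDataError):
            fit_stern_volmer(series)

    def test_enhancement_is_flagged_not_fatal(self):
        series = TitrationSeries(
            298.0, np.arange(5) * 1e-6, [100.0, 95.0, 105.0, 85.0, 80.0])
        fit = fit_stern_volmer(series)
        assert len(fit.enhancement_flags) == 1

    def test_kq_consistency_with_fit(self):
        fit = fit_stern_volmer(_sv_series(5.0e4), tau0_s=5.073e-9)
        assert fit.k_q * fit.tau0_s == pytest.approx(fit.k_sv, rel=1e-15)


class TestComputeKq:
    @pytest.mark.parametrize(
        "ksv, expected",
        [(6.702e4, 1.321e13), (5.981e4, 1.179e13), (5.664e4, 1.116e13)],
    )
    def test_published_values_at_print_precision(self, ksv, expected):
        kq = compute_kq(ksv, 5.073e-9)
        assert kq == pytest.approx(expected, abs=0.5e10)  # 4 sig figs

    def test_nonpositive_tau0_rejected(self):
        with pytest.raises(ValidationError):
            compute_kq(1e4, 0.0)


def _result(temperature, ksv, tau0=5.073e-9):
    return QuenchResult(temperature_K=temperature, k_sv=ksv, k_sv_se=0.0,
                        r_corr=1.0, tau0_s=tau0)


class TestMechanismClassifier:
    def test_published_pattern_is_static(self):
        results = [_result(t, k) for t, k in
                   [(298, 6.702e4), (304, 5.981e4), (310, 5.664e4)]]
        verdict = classify_mechanism(results, lifetimes_ns=[5.073, 4.846, 4.717])
        assert verdict.verdict == "static"
        assert all(outcome == "static" for _, outcome in verdict.evidence)

    def test_collisional_pattern_is_dynamic(self):
        # K_q below the diffusion limit, K_SV rising with T, lifetime falling
        results = [_result(t, k, tau0=5e-6) for t, k in
                   [(298, 1.0e4), (304, 1.5e4), (310, 2.0e4)]]
        verdict = classify_mechanism(results, lifetimes_ns=[5.0, 4.0, 3.0])
        assert verdict.verdict == "dynamic"

    def test_conflicting_evidence_is_ambiguous(self):
        results = [_result(t, k) for t, k in [(298, 1.0e4), (310, 2.0e4)]]
        verdict = classify_mechanism(results)  # kq static, ksv dynamic
        assert verdict.verdict == "ambiguous"

    def test_single_temperature_without_lifetimes_is_ambiguous(self):
        verdict = classify_mechanism([_result(298, 6.702e4)])
        assert verdict.verdict == "ambiguous"
        assert ("ksv_decreases_with_T", "inconclusive") in verdict.evidence

    def test_input_order_does_not_matter(self):
        results = [_result(t, k) for t, k in
                   [(310, 5.664e4), (298, 6.702e4), (304, 5.981e4)]]
        shuffled = classify_mechanism(results, lifetimes_ns=[5.073, 4.846, 4.717])
        ordered = classify_mechanism(sorted(results, key=lambda r: r.temperature_K),
                                     lifetimes_ns=[5.073, 4.846, 4.717])
        assert shuffled.verdict == ordered.verdict
        assert shuffled.evidence == ordered.evidence

    def test_lifetime_drift_at_seven_percent_counts_as_invariant(self):
        """The published 7% drift must stay under the 10% default threshold."""
        results = [_result(t, k) for t, k in [(298, 6.702e4), (310, 5.664e4)]]
        verdict = classify_mechanism(results, lifetimes_ns=[5.073, 4.717])
        assert ("lifetime_invariant", "static") in verdict.evidence
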