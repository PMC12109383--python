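"""Stern-Volmer / double-log fits and quenching-mechanism classification."""

import warnings

import numpy as np
import pytest

from quenchlab.exceptions import DroppedPointWarning, EnhancementWarning, FitError
from quenchlab.quenching import (
    KQ_DIFFUSION_LIMIT,
    SternVolmerFit,
    classify_mechanism,
    double_log_fit,
    stern_volmer_fit,
)
from quenchlab.simulate import (
    STUDY_KSV_BY_T,
    STUDY_LADDER_M,
    EmissionModel,
    simulate_titration,
)
from quenchlab.titration import QuenchTable, build_quench_table


def _noisy_table(ksv, sigma, seed, ladder=STUDY_LADDER_M, temperature=298.0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = EmissionModel(ksv_true=ksv, noise_sigma=sigma, seed=seed)
        return build_quench_table(simulate_titration(model, ladder), temperature)


class TestSternVolmer:
    def test_exact_linear_data(self, exact_table):
        fit = stern_volmer_fit(exact_table(ksv=5e4))
        assert fit.ksv == pytest.approx(5e4, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_kq_identity_at_printed_precision(self, exact_table):
        # Ksv = 0.40e5 L/mol with tau0 = 1e-8 s; the printed Kq (4.02e12)
        # reflects an unrounded Ksv, so the identity is asserted within 1%.
        fit = stern_volmer_fit(exact_table(ksv=0.40e5, temperature=310.0))
        assert fit.kq == fit.ksv / fit.tau0  # exact identity
        assert fit.kq == pytest.approx(4.02e12, rel=0.01)

    def test_fixed_intercept_mode(self, exact_table):
        t = exact_table(ksv=5e4)
        fit = stern_volmer_fit(t, fix_intercept=True)
        assert fit.intercept == 1.0
        assert fit.fixed_intercept
        assert fit.ksv == pytest.approx(5e4, rel=1e-9)

    def test_negative_slope_warns_enhancement(self, ladder):
        t = QuenchTable(298.0, ladder, 100.0 * (1.0 + 1e4 * ladder))
        with pytest.warns(EnhancementWarning):
            fit = stern_volmer_fit(t)
        assert fit.ksv < 0

    def test_too_few_points(self):
        t = QuenchTable(298.0, [0.0, 1e-6], [10.0, 9.0])
        with pytest.raises(FitError):
            stern_volmer_fit(t)

    def test_noisy_recovery_median_within_2pct(self):
        errors = [
            abs(stern_volmer_fit(_noisy_table(5e4, 0.01, seed)).ksv - 5e4) / 5e4
            for seed in range(100)
        ]
        assert np.median(errors) < 0.02

    def test_ols_slope_equals_closed_form_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = rng.integers(3, 12)
            q = np.concatenate([[0.0], np.sort(rng.uniform(1e-7, 3e-5, n - 1))])
            q[1:] += np.arange(1, n) * 1e-12
            f = rng.uniform(1.0, 100.0, n)
            t = QuenchTable(298.0, q, f)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = stern_volmer_fit(t)
            y = t.f0 / t.f
            closed = np.sum((q - q.mean()) * (y - y.mean())) / np.sum((q - q.mean()) ** 2)
            assert fit.ksv == pytest.approx(closed, rel=1e-12, abs=1e-12)

    def test_generated_static_response_is_monotone(self):
        spectra = simulate_titration(EmissionModel(ksv_true=5e4, shift_at_saturation=0.0))
        t = build_quench_table(spectra, 298.0)
        assert np.all(np.diff(t.f) < 0)


class TestDoubleLog:
    def test_exact_single_site_recovery(self, ladder):
        ka, f0 = 7.16e4, 5000.0
        f = f0 / (1.0 + ka * ladder)  # (F0-F)/F = Ka [Q], n = 1 exactly
        fit = double_log_fit(QuenchTable(298.0, ladder, f))
        assert fit.ka == pytest.approx(ka, rel=1e-3)
        assert fit.n == pytest.approx(1.0, abs=1e-3)

    def test_ols_agrees_with_grid_search_oracle(self, ladder):
        # brute-force SSE minimization over (lg Ka, n) on the same log-log points
        ka, n_true, f0 = 7.16e4, 1.0, 5000.0
        f = f0 / (1.0 + ka * ladder)
        fit = double_log_fit(QuenchTable(298.0, ladder, f))
        x = np.log10(ladder[1:])
        y = np.log10((f0 - f[1:]) / f[1:])
        lg_ka = np.arange(4.5, 5.2, 0.0005)
        slope = np.arange(0.9, 1.1, 0.0005)
        sse = (
            (y[None, None, :] - (lg_ka[:, None, None] + slope[None, :, None] * x)) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.ka == pytest.approx(10.0 ** lg_ka[i], rel=5e-3)
        assert fit.n == pytest.approx(slope[j], abs=5e-3)

    def test_point_at_f0_dropped_with_warning(self, ladder):
        f = 5000.0 / (1.0 + 7e4 * ladder)
        f[1] = 5000.0  # no quenching at this concentration
        with pytest.warns(DroppedPointWarning):
            fit = double_log_fit(QuenchTable(298.0, ladder, f))
        assert fit.n_points == len(ladder) - 2

    def test_too_few_valid_points_lists_dropped(self, ladder):
        f = np.full(len(ladder), 5000.0)
        f[-1] = 4000.0
        with pytest.raises(FitError, match="dropped"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            double_log_fit(QuenchTable(298.0, ladder, f))

    def test_n_close_to_one_across_seeds(self):
        errors = [
            abs(double_log_fit(_noisy_table(5e4, 0.01, seed)).n - 1.0)
            for seed in range(50)
        ]
        assert np.median(errors) < 0.05


def _fit_from_ksv(temperature, ksv, tau0=1e-8):
    return SternVolmerFit(
        temperature=temperature,
        ksv=ksv,
        kq=ksv / tau0,
        tau0=tau0,
        intercept=1.0,
        r=1.0,
        se_ksv=0.0,
        n_points=8,
    )


class TestClassifyMechanism:
    def test_printed_constants_give_static_decreasing(self):
        fits = [_fit_from_ksv(t, k) for t, k in STUDY_KSV_BY_T.items()]
        call = classify_mechanism(fits)
        assert call.label == "static"
        assert call.ksv_temperature_trend == "decreasing"
        assert call.min_kq == pytest.approx(4.0e12)

    def test_low_kq_increasing_is_dynamic(self):
        fits = [_fit_from_ksv(t, k) for t, k in [(298, 10.0), (304, 12.0), (310, 14.0)]]
        call = classify_mechanism(fits)
        assert call.label == "dynamic"
        assert call.ksv_temperature_trend == "increasing"

    def test_exact_threshold_is_ambiguous(self):
        call = classify_mechanism([_fit_from_ksv(298.0, KQ_DIFFUSION_LIMIT * 1e-8)])
        assert call.label == "ambiguous"

    def test_single_temperature_flat_trend_with_caveat(self):
        call = classify_mechanism([_fit_from_ksv(298.0, 5e4)])
        assert call.label == "static"
        assert call.ksv_temperature_trend == "flat"
        assert any("single temperature" in e for e in call.evidence)

    def test_discordant_trend_noted_but_primary_rule_stands(self):
        fits = [_fit_from_ksv(t, k) for t, k in [(298, 4e4), (304, 5e4), (310, 6e4)]]
        call = classify_mechanism(fits)
        assert call.label == "static"
        assert any("discordance" in e for e in call.evidence)

    def test_simulated_mechanism_recovery(self):
        # collisional quenchers need mM-range ladders to be measurable;
        # the static scenario keeps the uM ladder of the titration design
        mm_ladder = tuple(q * 1000 for q in STUDY_LADDER_M)
        static_ksv = dict(STUDY_KSV_BY_T)
        dynamic_ksv = {298.0: 50.0, 304.0: 80.0, 310.0: 120.0}
        hits = {"static": 0, "dynamic": 0}
        for kind, ksv_by_t, ladder in (
            ("static", static_ksv, STUDY_LADDER_M),
            ("dynamic", dynamic_ksv, mm_ladder),
        ):
            for seed in range(50):
                fits = [
                    stern_volmer_fit(
                        _noisy_table(k, 0.01, seed * 997 + i, ladder, temperature=t)
                    )
                    for i, (t, k) in enumerate(sorted(ksv_by_t.items()))
                ]
                if classify_mechanism(fits).label == kind:
                    hits[kind] += 1
        assert hits["static"] >= 49
        assert hits["dynamic"] >= 49


def test_kq_tau0_identity_holds_in_every_fit(exact_table):
    for ksv in (1e3, 5e4, 2e5):
        for tau0 in (1e-8, 5e-9):
            fit = stern_volmer_fit(exact_table(ksv=ksv), tau0=tau0)
            assert fit.kq * fit.tau0 == fit.ksv
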