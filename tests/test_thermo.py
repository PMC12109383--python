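"""Van't Hoff regression, Gibbs energy and binding-force classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchlab.exceptions import DomainError, FitError
from quenchlab.thermo import (
    GAS_CONSTANT,
    classify_forces,
    discrepancy_notes,
    gibbs,
    vant_hoff,
)

STUDY_TEMPS = (298.0, 304.0, 310.0)
REPORTED_KA = {298.0: 7.16e4, 304.0: 5.56e4, 310.0: 5.45e4}


def ka_from(dh, ds, temps=STUDY_TEMPS):
    return [(t, math.exp(-dh / (GAS_CONSTANT * t) + ds / GAS_CONSTANT)) for t in temps]


class TestVantHoff:
    def test_exact_inversion(self):
        fit = vant_hoff(ka_from(25400.0, 173.46))
        assert fit.dh == pytest.approx(25400.0, rel=1e-9)
        assert fit.ds == pytest.approx(173.46, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_printed_ka_series_yields_negative_enthalpy(self):
        # three-point OLS oracle frozen by hand: slope of ln Ka on 1/T is
        # +2112 K, so dH = -R*slope ~ -17.56 kJ/mol and dS ~ +33.7 J/(mol K);
        # a decreasing Ka(T) series cannot give a positive enthalpy.
        fit = vant_hoff(sorted(REPORTED_KA.items()))
        assert fit.dh == pytest.approx(-1.756e4, rel=1e-3)
        assert fit.ds == pytest.approx(33.70, rel=1e-2)
        assert fit.dh < 0

    def test_discrepancy_note_flags_sign_conflict_with_reported_values(self):
        fit = vant_hoff(sorted(REPORTED_KA.items()))
        notes = discrepancy_notes(fit, reported_dh=25400.0, reported_ds=173.46)
        assert len(notes) == 1  # dH signs conflict; dS signs agree
        assert "dH" in notes[0]
        assert discrepancy_notes(fit, reported_dh=-17000.0) == []

    def test_two_temperatures_determine_the_line(self):
        fit = vant_hoff(ka_from(10000.0, 50.0, temps=(298.0, 310.0)))
        assert fit.dh == pytest.approx(10000.0, rel=1e-9)
        assert fit.r_squared == 1.0
        assert math.isnan(fit.se_dh) and math.isnan(fit.se_ds)

    def test_errors(self):
        with pytest.raises(FitError):
            vant_hoff([(298.0, 1e4)])
        with pytest.raises(FitError):
            vant_hoff([(298.0, 1e4), (298.0, 2e4)])
        with pytest.raises(DomainError):
            vant_hoff([(298.0, -1.0), (304.0, 1e4)])

    def test_noisy_recovery_medians_within_5pct(self):
        # population median relative error for dH at this noise level is
        # ~4.8%, close to the bound, so enough replicates are used to pin
        # the Monte Carlo median well below its sampling noise
        dh, ds = 25400.0, 173.46
        temps = np.asarray(STUDY_TEMPS)
        lnka = -dh / (GAS_CONSTANT * temps) + ds / GAS_CONSTANT
        err_dh, err_ds = [], []
        for seed in range(10000):
            rng = np.random.default_rng(seed)
            noisy = lnka + 0.02 * rng.standard_normal(3)
            fit = vant_hoff(list(zip(temps, np.exp(noisy))))
            err_dh.append(abs(fit.dh - dh) / dh)
            err_ds.append(abs(fit.ds - ds) / ds)
        assert np.median(err_dh) < 0.05
        assert np.median(err_ds) < 0.05


class TestGibbs:
    @pytest.mark.parametrize(
        "temperature, expected_kj",
        [(298.0, -26.29), (304.0, -27.33)],
    )
    def test_printed_thermodynamic_rows(self, temperature, expected_kj):
        res = gibbs(25400.0, 173.46, temperature)
        assert round(res.dg / 1000.0, 2) == expected_kj
        assert res.spontaneous

    def test_zero_case_not_spontaneous(self):
        res = gibbs(0.0, 0.0, 298.0)
        assert res.dg == 0.0
        assert not res.spontaneous

    def test_temperature_domain(self):
        with pytest.raises(DomainError):
            gibbs(1.0, 1.0, 0.0)

    def test_consistency_with_fitted_line(self):
        fit = vant_hoff(ka_from(25400.0, 173.46))
        for t in STUDY_TEMPS:
            lhs = gibbs(fit.dh, fit.ds, t).dg
            rhs = -GAS_CONSTANT * t * fit.predicted_ln_ka(t)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        dh=st.floats(-1e5, 1e5),
        ds=st.floats(-500.0, 500.0),
        t1=st.floats(200.0, 400.0),
        t2=st.floats(200.0, 400.0),
    )
    def test_linearity_in_temperature(self, dh, ds, t1, t2):
        dg1, dg2 = gibbs(dh, ds, t1).dg, gibbs(dh, ds, t2).dg
        assert dg2 - dg1 == pytest.approx(-ds * (t2 - t1), rel=1e-9, abs=1e-6)


class TestClassifyForces:
    @pytest.mark.parametrize(
        "dh, ds, label",
        [
            (25400.0, 173.46, "hydrophobic"),
            (-10000.0, 50.0, "electrostatic"),
            (10000.0, -50.0, "electrostatic+hydrophobic"),
            (-10000.0, -50.0, "vdw+hbond"),
            (50.0, 0.5, "indeterminate"),  # both inside the zero bands
            (50.0, 50.0, "indeterminate"),
            (10000.0, 0.5, "indeterminate"),
            (-50.0, -50.0, "indeterminate"),
            (10000.0, -0.5, "indeterminate"),
        ],
    )
    def test_quadrant_mapping_is_total(self, dh, ds, label):
        call = classify_forces(dh, ds)
        assert call.label == label

    @settings(derandomize=True, max_examples=200)
    @given(dh=st.floats(-1e6, 1e6), ds=st.floats(-1e4, 1e4))
    def test_mapping_deterministic_and_sign_consistent(self, dh, ds):
        call = classify_forces(dh, ds)
        assert call == classify_forces(dh, ds)
        if call.dh_sign == 0 or call.ds_sign == 0:
            assert call.label == "indeterminate"
        else:
            assert call.label in (
                "hydrophobic",
                "electrostatic",
                "electrostatic+hydrophobic",
                "vdw+hbond",
            )
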