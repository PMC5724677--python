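"""Incubation rate regression, truncation, QC rules and normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ols_normal_equations
from tauflux.errors import (
    InsufficientPointsError,
    InvalidInputError,
    PairingError,
    UndefinedStatisticError,
)
from tauflux.release_rates import (
    QC_EARLY_RELEASE,
    QC_LOW_FIT,
    QC_PASS,
    IncubationSeries,
    RateEstimate,
    apply_qc,
    control_correct,
    estimate_release_rate,
    fit_release_rate,
    normalize_rates,
    rates_from_tables,
    summarize_rates,
    tau_dfaa_ratio,
    truncate_series,
)

GRID = (0, 2, 4, 6, 8, 10, 12, 24)


def series(concs, analyte="Tau", times=GRID, **kw):
    kw.setdefault("n_individuals", 50)
    kw.setdefault("total_biomass_gC", 0.0176)
    return IncubationSeries("S", "A", analyte, tuple(times), tuple(concs), **kw)


class TestTruncation:
    def test_monotone_to_the_end(self):
        s = series([1 + 2 * t for t in GRID])
        comp = series([0.5 + t for t in GRID], analyte="Gly")
        assert truncate_series(s, [comp]) == 24

    def test_plateau_at_8(self):
        concs = [min(t, 8) * 40 + 1 for t in GRID]
        assert truncate_series(series(concs)) == 8

    def test_companion_decrease_cuts_at_3(self):
        times = (0, 1, 2, 3, 4, 5)
        s = series([1, 2, 3, 4, 5, 6], times=times)
        comp = series([1, 2, 3, 4, 3.5, 3], analyte="Gly", times=times)
        assert truncate_series(s, [comp]) == 3

    def test_never_past_first_violation(self):
        times = (0, 1, 2, 3, 4)
        s = series([1, 2, 2, 3, 4], times=times)  # flat step at 1→2
        assert truncate_series(s) == 1

    def test_tolerance_widens_plateau(self):
        times = (0, 1, 2, 3)
        s = series([0, 1, 1.05, 3], times=times)
        assert truncate_series(s, tol_nM=0.0) == 3  # strictly rising throughout
        assert truncate_series(s, tol_nM=0.1) == 1  # 1→1.05 no longer counts as a rise

    def test_mismatched_grid_rejected(self):
        s = series([1, 2, 3], times=(0, 1, 2))
        comp = series([1, 2, 3], analyte="Gly", times=(0, 1, 3))
        with pytest.raises(PairingError):
            truncate_series(s, [comp])


class TestFit:
    def test_noiseless_line(self):
        s = series([1 + 2 * t for t in (0, 1, 2, 3, 4)], times=(0, 1, 2, 3, 4))
        fit = fit_release_rate(s)
        assert fit.slope_nM_per_h == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 0.001

    def test_constant_series_degenerates_gracefully(self):
        fit = fit_release_rate(series([5.0] * len(GRID)))
        assert fit.slope_nM_per_h == 0.0
        assert fit.r_squared == 0.0
        assert fit.p_value == 1.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            fit_release_rate(series([0, 1, 2], times=(0, 1, 2)), t_c_h=1)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(4, 12)
            t = np.sort(rng.uniform(0.1, 24, n - 1))
            t = np.concatenate([[0.0], t])
            c = np.abs(rng.normal(5, 2) + rng.normal(2, 1) * t + rng.normal(0, 1, n))
            s = series(c, times=tuple(t))
            fit = fit_release_rate(s)
            slope, intercept, r2, p = ols_normal_equations(t, s.concs)
            assert fit.slope_nM_per_h == pytest.approx(slope, rel=1e-9)
            assert fit.intercept_nM == pytest.approx(intercept, rel=1e-9, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)
            assert fit.p_value == pytest.approx(p, rel=1e-9)


class TestQc:
    def test_table_like_pass(self):
        # r² just above the cut with a significant slope is retained
        t = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8.0])
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = np.abs(2 + 1.0 * t + rng.normal(0, 1.6, t.size))
            s = series(c, times=tuple(t))
            fit = fit_release_rate(s)
            if 0.60 <= fit.r_squared < 0.70 and fit.p_value <= 0.05:
                assert apply_qc(fit, s) == QC_PASS
                return
        pytest.fail("no qualifying draw found")

    def test_low_r2_rejected(self):
        rng = np.random.default_rng(1)
        c = np.abs(rng.normal(5, 1, len(GRID)))
        s = series(c)
        fit = fit_release_rate(s)
        assert fit.r_squared < 0.60
        assert apply_qc(fit, s) == QC_LOW_FIT

    def test_early_release_only(self):
        s = series([0, 5, 5, 5, 5, 5, 5, 5])
        fit = fit_release_rate(s)
        assert apply_qc(fit, s) == QC_EARLY_RELEASE

    def test_and_combinator_is_laxer(self):
        # significant p with r² < 0.6 passes under "and", fails under "or"
        rng = np.random.default_rng(7)
        t = np.linspace(0, 24, 20)
        for _ in range(100):
            c = np.abs(1 + 0.5 * t + rng.normal(0, 3.5, t.size))
            s = IncubationSeries("S", "A", "Tau", tuple(t), tuple(c),
                                 n_individuals=50, total_biomass_gC=0.0176)
            fit = fit_release_rate(s)
            if fit.r_squared < 0.60 and fit.p_value <= 0.05:
                assert apply_qc(fit, s, combine="or") == QC_LOW_FIT
                assert apply_qc(fit, s, combine="and") == QC_PASS
                return
        pytest.fail("no qualifying draw found")


class TestNormalisation:
    def test_printed_chamber(self):
        per_ind, per_gc = normalize_rates(31.68, 0.5, 50, 0.0176)
        assert per_ind == pytest.approx(316.8)
        assert per_gc == pytest.approx(0.9)

    def test_volume_linearity(self):
        a = normalize_rates(10, 0.5, 50, 0.01)
        b = normalize_rates(10, 1.0, 50, 0.01)
        assert b[0] == pytest.approx(2 * a[0]) and b[1] == pytest.approx(2 * a[1])

    @given(
        slope=st.floats(0.01, 100),
        vol=st.floats(0.1, 2),
        n=st.integers(1, 500),
        biomass=st.floats(1e-6, 1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rate_ratio_is_biomass_per_individual(self, slope, vol, n, biomass):
        per_ind, per_gc = normalize_rates(slope, vol, n, biomass)
        # pmol ind⁻¹ / µmol g⁻¹ = 10⁶ × g ind⁻¹, exactly
        assert per_ind / per_gc == pytest.approx(biomass / n * 1e6, rel=1e-12)

    def test_zero_chamber_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_rates(1, 0.5, 0, 0.01)


class TestControlCorrection:
    def test_zero_control_is_identity(self):
        s = series([1, 2, 3, 4, 5, 6, 7, 8])
        ctrl = IncubationSeries("S", "ctl", "Tau", GRID, (0,) * 8, is_control=True)
        assert control_correct(s, ctrl).concs_nM == s.concs_nM

    def test_self_subtraction_zeroes(self):
        s = series([1, 2, 3, 4, 5, 6, 7, 8])
        ctrl = IncubationSeries("S", "ctl", "Tau", GRID, s.concs_nM, is_control=True)
        assert all(c == 0 for c in control_correct(s, ctrl).concs_nM)

    def test_rising_control_scales_slope(self):
        t = np.array(GRID, dtype=float)
        s = series(1 + 10 * t)
        ctrl = IncubationSeries("S", "ctl", "Tau", GRID, tuple(1.0 * t), is_control=True)
        corrected = control_correct(s, ctrl)
        fit = fit_release_rate(corrected)
        assert fit.slope_nM_per_h == pytest.approx(9.0)

    def test_analyte_mismatch(self):
        s = series([1, 2, 3, 4, 5, 6, 7, 8])
        ctrl = IncubationSeries("S", "ctl", "Gly", GRID, (0,) * 8, is_control=True)
        with pytest.raises(PairingError):
            control_correct(s, ctrl)


class TestRatioAndSummary:
    def _est(self, analyte, rate, status=QC_PASS):
        return RateEstimate("S", "A", analyte, 1.0, 0.9, 0.01, 8, 8, status,
                            rate_per_individual_pmol_h=rate if status == QC_PASS else None)

    def test_tau_dfaa_ratio(self):
        ests = [self._est("Tau", 1.0), self._est("Gly", 2.0),
                self._est("Ala", 3.0), self._est("Arg", 5.0)]
        assert tau_dfaa_ratio(ests) == pytest.approx(0.1)

    def test_failing_dfaa_excluded(self):
        ests = [self._est("Tau", 1.0), self._est("Gly", 2.0),
                self._est("Ala", 99.0, status=QC_LOW_FIT)]
        assert tau_dfaa_ratio(ests) == pytest.approx(0.5)

    def test_no_dfaa_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            tau_dfaa_ratio([self._est("Tau", 1.0)])

    def test_summary_of_printed_rates(self):
        from tauflux.datasets import goa_community_rates, na_community_rates

        df = pd.concat([goa_community_rates(), na_community_rates()])
        summ = summarize_rates(df, by="region").set_index("region")
        goa = summ.loc["goa"]
        assert goa["mean_pmol_ind_h"] == pytest.approx(425.1, abs=0.05)
        assert goa["sd_pmol_ind_h"] == pytest.approx(96, abs=1)
        assert goa["mean_nmol_ind_d"] == pytest.approx(10.2, abs=0.05)
        na = summ.loc["na"]
        assert na["mean_pmol_ind_h"] == pytest.approx(24.4, abs=0.05)
        assert na["sd_pmol_ind_h"] == pytest.approx(0.3, abs=0.05)
        assert na["mean_nmol_ind_d"] == pytest.approx(0.6, abs=0.02)


class TestPipeline:
    def test_estimate_release_rate_end_to_end(self):
        t = np.array(GRID, dtype=float)
        s = series(np.round(1 + 31.68 * t, 6))
        est = estimate_release_rate(s)
        assert est.qc_status == QC_PASS
        assert est.rate_per_individual_pmol_h == pytest.approx(316.8, rel=1e-6)
        assert est.rate_per_gC_umol_h == pytest.approx(0.9, rel=1e-3)

    def test_rates_from_tables(self):
        rows = []
        t = np.array(GRID, dtype=float)
        for analyte, slope in (("Tau", 31.68), ("Gly", 10.0)):
            for time, conc in zip(t, 1 + slope * t):
                rows.append(dict(station="S", replicate="A", analyte=analyte,
                                 time_h=time, conc_nM=conc, is_control=False))
        for time in t:  # flat control
            rows.append(dict(station="S", replicate="ctl", analyte="Tau",
                             time_h=time, conc_nM=1.0, is_control=True))
        chambers = pd.DataFrame(
            [dict(station="S", replicate="A", volume_L=0.5,
                  n_individuals=50, total_biomass_gC=0.0176)]
        )
        out = rates_from_tables(pd.DataFrame(rows), chambers)
        assert len(out) == 2
        tau = out[out["analyte"] == "Tau"].iloc[0]
        assert tau["qc_status"] == QC_PASS
        assert tau["rate_pmol_ind_h"] == pytest.approx(316.8, rel=1e-6)
        assert tau["control_slope_nM_per_h"] == pytest.approx(0.0, abs=1e-12)
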