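import numpy as np
import pytest

from circmort import (
    HourlyCounts,
    SimConfig,
    aggregate_counts,
    fit_spline,
    make_report,
    rcs_basis,
    sample_records,
)

KNOTS = np.array([3.0, 12.0, 21.0])
MIDS = np.arange(24) + 0.5


class TestBasis:
    def test_finite_and_three_columns_at_knots(self):
        b = rcs_basis(KNOTS, KNOTS)
        assert b.shape == (3, 3)
        assert np.isfinite(b).all()

    def test_linear_functions_lie_in_span(self, rng):
        x = rng.uniform(0, 24, 50)
        y = 3.0 - 0.7 * x
        coef, *_ = np.linalg.lstsq(rcs_basis(x, KNOTS), y, rcond=None)
        assert np.allclose(rcs_basis(x, KNOTS) @ coef, y, atol=1e-10)

    def test_linear_tails_beyond_boundary_knots(self):
        """Second derivative of the restricted term vanishes outside the
        boundary knots (finite-difference check)."""
        coef = np.array([1.0, 2.0, 5.0])  # arbitrary spline in the basis
        for x0 in (KNOTS[2] + 0.5, 26.0, KNOTS[0] - 0.5, -3.0):
            h = 1e-3
            pts = np.array([x0 - h, x0, x0 + h])
            vals = rcs_basis(pts, KNOTS) @ coef
            second = (vals[0] - 2 * vals[1] + vals[2]) / h**2
            assert abs(second) < 1e-6

    def test_bad_knots_error(self):
        with pytest.raises(ValueError):
            rcs_basis(MIDS, np.array([3.0, 3.0, 21.0]))
        with pytest.raises(ValueError):
            rcs_basis(MIDS, np.array([3.0, 12.0]))


class TestFitSpline:
    def test_constant_counts_fit_flat(self):
        fit = fit_spline(HourlyCounts(counts=np.full(24, 57)))
        assert np.allclose(fit.fitted, 57.0, atol=1e-8)

    def test_linear_counts_zero_rss(self):
        counts = (10 + 3 * np.arange(24)).astype(int)
        fit = fit_spline(HourlyCounts(counts=counts), knots=KNOTS)
        assert fit.rss < 1e-10

    def test_shift_equivariance(self):
        counts = np.array([30 + ((h * 7) % 11) for h in range(24)])
        base = fit_spline(HourlyCounts(counts=counts), knots=KNOTS)
        shifted = fit_spline(HourlyCounts(counts=counts + 100), knots=KNOTS)
        assert np.allclose(shifted.fitted, base.fitted + 100.0, atol=1e-8)

    def test_default_knots_follow_percentile_rule(self):
        fit = fit_spline(HourlyCounts(counts=np.full(24, 100)))
        # uniform hours: 10/50/90 percentiles of the hour variable
        assert np.all(np.diff(fit.knots) > 0)
        assert fit.knots[1] == pytest.approx(12.0, abs=0.6)

    def test_log_link_keeps_fit_positive(self):
        counts = np.array([1, 0, 2, 1] * 6)
        fit = fit_spline(HourlyCounts(counts=counts), knots=KNOTS, link="log")
        assert (fit.fitted > 0).all()

    def test_acrophase_hour_recovered_from_cardioid_cohort(self):
        """Peak of the fitted spline lands within 2 h of a mid-day acrophase.

        The seam between hour 23 and hour 0 is deliberately not stitched, so
        only acrophases away from midnight are representable; near-seam peaks
        are a documented limitation of the non-periodic three-knot spline.
        """
        mu = 720.0  # noon
        rec = sample_records(SimConfig(n=50_000, rho=0.1, mu=mu, seed=8))
        fit = fit_spline(aggregate_counts(rec, "hour"))
        peak_hour = MIDS[int(np.argmax(fit.fitted))]
        assert abs(peak_hour - mu / 60.0) <= 2.0


class TestMakeReport:
    def test_full_synthetic_run_bundles_everything(self, small_cohort, tmp_path):
        summary = make_report(small_cohort, tmp_path, cause="cancer", n_boot=30, seed=1)
        assert set(summary) >= {"spline", "circadian_test", "excess_mass_test", "prevalence_ratios"}
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "temporal_pattern.svg").exists()
        assert set(summary["prevalence_ratios"]) == {
            "cancer",
            "ischemic_heart_disease",
            "pneumonia",
        }

    def test_zero_record_cause_noted_as_omitted(self, small_cohort, tmp_path):
        cancer_only = small_cohort[small_cohort["cause"] == "cancer"]
        summary = make_report(cancer_only, tmp_path, cause="pneumonia", n_boot=10, seed=0)
        assert summary["omitted"]
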