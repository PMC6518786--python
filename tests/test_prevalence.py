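import numpy as np
import pandas as pd
import pytest

from circmort import fit_pr, pr_plot_data, pr_report


def _balanced_two_hour_records(p0=0.2, p1=0.3, per_cell=200):
    """Records in hours 0 and 6 with identical sex/age composition, so the
    adjusted hour PR must equal the crude two-by-two ratio p1/p0 exactly."""
    rows = []
    for hour, p in ((0, p0), (6, p1)):
        for sex in ("male", "female"):
            n_cancer = int(round(p * per_cell))
            for i in range(per_cell):
                rows.append(
                    {
                        "time_of_day": hour * 60 + (i % 60),
                        "cause": "cancer" if i < n_cancer else "other",
                        # same age pattern in every (hour, sex) cell and at the
                        # same outcome positions, so adjustment changes nothing
                        "age": 60 + (i % 5),
                        "sex": sex,
                    }
                )
    return pd.DataFrame(rows)


class TestFitPR:
    def test_crude_two_sample_ratio_recovered_exactly(self):
        records = _balanced_two_hour_records()
        table = fit_pr(records, "cancer").table
        assert table.loc["hour_6", "pr"] == pytest.approx(0.3 / 0.2, abs=1e-8)
        lo, hi = table.loc["hour_6", ["ci_low", "ci_high"]]
        assert lo < 1.5 < hi

    def test_grouped_model_matches_individual_coefficients(self, small_cohort):
        ind = fit_pr(small_cohort, "cancer", model="individual").table
        grp = fit_pr(small_cohort, "cancer", model="grouped").table
        assert np.allclose(ind["coef"], grp["coef"], atol=1e-6)

    def test_parameter_recovery_within_robust_ses(self, rng):
        """True hour-6 PR 1.25 and sex PR 1.3: one large replicate lands
        within 3 robust SEs (the full replicate study lives in acceptance)."""
        n = 40_000
        hour = rng.integers(0, 24, n)
        male = rng.integers(0, 2, n)
        age = rng.integers(40, 100, n)
        p = 0.15 * np.where(hour == 6, 1.25, 1.0) * np.where(male == 1, 1.3, 1.0)
        y = rng.random(n) < p
        records = pd.DataFrame(
            {
                "time_of_day": hour * 60 + rng.integers(0, 60, n),
                "cause": np.where(y, "cancer", "other"),
                "age": age,
                "sex": np.where(male == 1, "male", "female"),
            }
        )
        table = fit_pr(records, "cancer").table
        for term, true_log in (("hour_6", np.log(1.25)), ("sex_male", np.log(1.3))):
            row = table.loc[term]
            assert abs(row.coef - true_log) < 3 * row.se_robust
            assert row.ci_low <= row.pr <= row.ci_high

    def test_preconditions(self, small_cohort):
        single_hour = small_cohort.assign(time_of_day=30)
        with pytest.raises(ValueError, match="two hours"):
            fit_pr(single_hour, "cancer")
        males = small_cohort[small_cohort["sex"] == "male"]
        with pytest.raises(ValueError, match="both sexes"):
            fit_pr(males, "cancer")
        with pytest.raises(ValueError, match="unknown cause"):
            fit_pr(small_cohort, "stroke")


class TestPRReport:
    def test_layout_matches_published_table(self, small_cohort):
        tables = {c: fit_pr(small_cohort, c) for c in ("cancer", "pneumonia")}
        report = pr_report(tables)
        assert report.shape == (26, 2)
        assert report.iloc[0, 0] == "Reference"
        assert report.index[0].startswith("During 0:00")
        assert report.index[12] == "During 12:00–12:59 pm"
        assert report.index[-2] == "Sex (male versus female)"
        # cells render as "PR (low–high)"
        assert "(" in report.iloc[6, 0] and "–" in report.iloc[6, 0]

    def test_single_cause_single_column(self, small_cohort):
        report = pr_report([fit_pr(small_cohort, "cancer")])
        assert report.shape == (26, 1)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            pr_report({})

    def test_mismatched_terms_error(self, small_cohort):
        a = fit_pr(small_cohort, "cancer")
        b = fit_pr(small_cohort, "pneumonia")
        b.table = b.table.drop(index="hour_5")
        with pytest.raises(ValueError, match="mismatched"):
            pr_report({"cancer": a, "pneumonia": b})

    def test_plot_data_pins_reference_hour(self, small_cohort):
        data = pr_plot_data({"cancer": fit_pr(small_cohort, "cancer")})["cancer"]
        assert data["hour"][0] == 0 and data["pr"][0] == 1.0
        assert len(data["hour"]) == 24
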