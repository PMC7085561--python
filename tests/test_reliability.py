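"""Agreement statistics: ANOVA oracle checks, fixture values, Bland-Altman."""

import numpy as np
import pytest

from msft import (
    PairedResults,
    agreement_table,
    bland_altman,
    cronbach_alpha,
    icc,
    interpret,
    load_paired_results,
    reliability_report,
)
from msft.errors import DataError, UndefinedStatisticError, ValidationError
from msft.reliability import interpret_alpha, interpret_icc


# ---------------------------------------------------------------------------
# independent oracle: explicit loop-based sums of squares

def icc_oracle(matrix, model, unit):
    m = [[float(v) for v in row] for row in matrix]
    n, k = len(m), len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((rm - grand) ** 2 for rm in row_means)
    ssw = sum((m[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    sse = sum(
        (m[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msb = ssb / (n - 1)
    if model == "oneway_random":
        denom = ssw / (n * (k - 1))
    else:
        denom = sse / ((n - 1) * (k - 1))
    if unit == "single":
        return (msb - denom) / (msb + (k - 1) * denom)
    return (msb - denom) / msb


def random_matrices(count, rng):
    for _ in range(count):
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        yield rng.normal(10, 3, (n, k)) + rng.normal(0, 2, (n, 1))


class TestIccAgainstOracle:
    @pytest.mark.parametrize("model", ["oneway_random", "twoway_consistency"])
    @pytest.mark.parametrize("unit", ["single", "average"])
    def test_matches_loop_based_anova_on_100_random_matrices(self, model, unit):
        rng = np.random.default_rng(20)
        for m in random_matrices(100, rng):
            est = icc(m, model=model, unit=unit)
            assert est.value == pytest.approx(icc_oracle(m, model, unit), abs=1e-9)

    def test_matches_pingouin_on_the_case_study(self, case_study):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for code, pairs in case_study.items():
            m = pairs.matrix
            long = pd.DataFrame(
                {
                    "subject": list(pairs.subject_ids) * 2,
                    "rater": ["a"] * len(pairs.subject_ids) + ["b"] * len(pairs.subject_ids),
                    "score": np.concatenate([m[:, 0], m[:, 1]]),
                }
            )
            ref = pg.intraclass_corr(
                data=long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")
            assert icc(m, "oneway_random", "single").value == pytest.approx(
                ref.loc["ICC(1,1)", "ICC"], abs=1e-6
            )
            assert icc(m, "twoway_consistency", "average").value == pytest.approx(
                ref.loc["ICC(C,k)", "ICC"], abs=1e-6
            )

    def test_identical_columns_give_unity(self):
        m = np.column_stack([[1, 2, 3, 4.0]] * 2)
        for model in ("oneway_random", "twoway_consistency"):
            for unit in ("single", "average"):
                assert icc(m, model, unit).value == pytest.approx(1.0)

    def test_degenerate_anova_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            icc(np.full((5, 2), 3.0))


class TestCronbachAlpha:
    def test_chair_stand_fixture_value(self, case_study):
        alpha = cronbach_alpha(case_study["chair_stand"].matrix)
        assert round(alpha, 2) == 0.93

    def test_arm_curl_fixture_value(self, case_study):
        assert round(cronbach_alpha(case_study["arm_curl"].matrix), 2) == 0.99

    def test_identical_columns_give_unity(self):
        assert cronbach_alpha(np.column_stack([[1, 2, 3.0]] * 2)) == pytest.approx(1.0)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(np.full((4, 2), 1.0))

    def test_equals_consistency_average_icc_for_two_raters(self):
        """Cronbach's alpha is identically ICC(consistency, average) at k=2."""
        rng = np.random.default_rng(99)
        for m in random_matrices(100, rng):
            m2 = m[:, :2]
            alpha = cronbach_alpha(m2)
            est = icc(m2, "twoway_consistency", "average").value
            assert abs(alpha - est) < 1e-12


class TestOnewayModelDivergence:
    def test_oneway_single_on_chair_stand_is_far_below_printed_column(self, case_study):
        """The one-way random single-measures coefficient on the chair-stand
        pairs is ~0.56: the case study's printed per-item column is numerically
        the consistency/average form, not the footnoted one-way model."""
        est = icc(case_study["chair_stand"].matrix, "oneway_random", "single")
        assert est.value == pytest.approx(0.56, abs=0.005)
        assert est.ci_low <= est.value <= est.ci_high


class TestConfidenceIntervals:
    def test_point_estimate_inside_interval_on_all_fixtures(self, case_study):
        for pairs in case_study.values():
            for model in ("oneway_random", "twoway_consistency"):
                for unit in ("single", "average"):
                    est = icc(pairs.matrix, model, unit)
                    assert est.ci_low <= est.value <= est.ci_high

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(11)
        medians = []
        for n in (5, 10, 50):
            widths = []
            for _ in range(40):
                subject = rng.normal(0, 2, (n, 1))
                m = subject + rng.normal(0, 1, (n, 2))
                est = icc(m, "twoway_consistency", "average")
                widths.append(est.ci_high - est.ci_low)
            medians.append(np.median(widths))
        assert medians[0] > medians[1] > medians[2]


class TestBlandAltman:
    def test_chair_stand_mean_difference(self, case_study):
        res = bland_altman(case_study["chair_stand"])
        assert res.mean_diff == pytest.approx(13 / 7)
        assert res.loa_low < res.mean_diff < res.loa_high

    def test_identical_methods_have_zero_spread(self):
        pairs = PairedResults(("a", "b", "c"), (1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        res = bland_altman(pairs)
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0

    def test_hand_computed_points(self):
        pairs = PairedResults(("a", "b", "c"), (10.0, 12.0, 14.0), (8.0, 12.0, 14.0))
        res = bland_altman(pairs)
        assert res.points[0] == (9.0, 2.0)
        assert res.points[1] == (12.0, 0.0)

    def test_limits_cover_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(2024)
        n = 5000
        truth = rng.normal(50, 10, n)
        a = truth + rng.normal(0, 1.0, n)
        b = truth + rng.normal(0, 1.0, n)
        pairs = PairedResults(tuple(range(n)), tuple(a), tuple(b))
        res = bland_altman(pairs)
        diffs = a - b
        inside = np.mean((diffs >= res.loa_low) & (diffs <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_plot_renders_reference_lines(self, case_study):
        import matplotlib

        matplotlib.use("Agg")
        from msft.reliability import plot_bland_altman

        ax = plot_bland_altman(bland_altman(case_study["arm_curl"]), title="arm curl")
        assert len(ax.lines) == 3  # mean + two limits
        import matplotlib.pyplot as plt

        plt.close(ax.figure)


class TestInterpretation:
    @pytest.mark.parametrize(
        "icc_v,alpha_v,expected",
        [
            (0.93, 0.93, ("excellent", "excellent")),
            (0.3, 0.4, ("poor", "unacceptable")),
            (0.75, 0.9, ("fair-to-good", "poor-to-good")),  # boundaries fall low
            (0.4, 0.5, ("poor", "unacceptable")),
        ],
    )
    def test_band_labels(self, icc_v, alpha_v, expected):
        assert interpret(icc_v, alpha_v) == expected

    def test_band_functions_cover_the_scale(self):
        assert interpret_icc(-0.2) == "poor"
        assert interpret_alpha(1.0) == "excellent"


class TestFixtureAndReport:
    def test_fixture_shape(self, case_study):
        assert len(case_study) == 6
        for pairs in case_study.values():
            assert len(pairs.subject_ids) == 7

    def test_incomplete_fixture_names_the_missing_cell(self, tmp_path):
        import pandas as pd

        from msft.reliability import load_paired_results as load

        text = "subject_id,test_code,method,value\n"
        rows = [(i, "chair_stand", m, 10) for i in range(1, 8) for m in ("sft", "msft")]
        rows.remove((4, "chair_stand", "msft", 10))
        text += "\n".join(",".join(map(str, r)) for r in rows)
        path = tmp_path / "broken.csv"
        path.write_text(text)
        with pytest.raises(DataError, match="subject 4.*chair_stand"):
            load(path)

    def test_report_alpha_column_matches_printed_study_values(self):
        table = agreement_table()
        printed = {
            "chair_stand": 0.93, "arm_curl": 0.99, "two_min_step": 0.98,
            "sit_reach": 0.99, "back_scratch": 0.99, "up_and_go": 0.97,
        }
        for code, expected in printed.items():
            assert table.loc[code, "cronbach_alpha"] == pytest.approx(expected, abs=0.01)
        np.testing.assert_allclose(table["icc"], table["cronbach_alpha"], atol=1e-12)
        assert (table["icc_label"] == "excellent").all()

    def test_report_states_the_icc_form_used(self, case_study):
        rep = reliability_report(case_study["up_and_go"], icc_model="oneway_random",
                                 icc_unit="single")
        assert rep.icc_model == "oneway_random"
        assert rep.icc_unit == "single"


class TestPairedResultsValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            PairedResults(("a", "b", "c"), (1.0, 2.0), (1.0, 2.0, 3.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            PairedResults(("a", "b"), (1.0, 2.0), (1.0, 2.0))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            PairedResults(("a", "b", "c"), (1.0, float("nan"), 3.0), (1.0, 2.0, 3.0))
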