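"""Per-level group comparisons, Bonferroni control, subgroup summaries."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate, stats

from attnscreen import (
    AttentionProfile,
    CohortSpec,
    SubjectRecord,
    bonferroni,
    compare_by_level,
    completion_split,
    contingency_summary,
    critical_t,
    default_config,
    run_session,
    simulate_cohort,
    two_sample_t,
)
from attnscreen.caras import CarasScores


def make_record(subject_id, group, level_means, completed=False, caras=None):
    """A SubjectRecord with crafted per-level means and a minimal real log."""
    log = run_session([60, 60], default_config())
    return SubjectRecord(
        subject_id=subject_id, group=group, log=log, completed=completed,
        level_means=level_means, caras=caras,
    )


class TestTwoSampleT:
    def test_matches_exact_arithmetic_oracle(self, rng):
        """Pooled t computed with exact Fractions on integer samples agrees
        to 12 significant digits."""
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            x1 = [int(v) for v in rng.integers(0, 100, n1)]
            x2 = [int(v) for v in rng.integers(0, 100, n2)]
            m1, m2 = Fraction(sum(x1), n1), Fraction(sum(x2), n2)
            ss1 = sum((Fraction(v) - m1) ** 2 for v in x1)
            ss2 = sum((Fraction(v) - m2) ** 2 for v in x2)
            df = n1 + n2 - 2
            pooled = (ss1 + ss2) / df
            if pooled == 0:
                continue
            denom2 = pooled * (Fraction(1, n1) + Fraction(1, n2))
            expected_t = float(m1 - m2) / math.sqrt(float(denom2))
            res = two_sample_t(x1, x2)
            assert res.df == df
            assert res.t == pytest.approx(expected_t, rel=1e-12)

    def test_agrees_with_scipy_pooled_ttest(self, rng):
        x1, x2 = rng.normal(50, 10, 30), rng.normal(45, 12, 20)
        res = two_sample_t(x1, x2)
        ref = stats.ttest_ind(x1, x2, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    @pytest.mark.parametrize("n1,n2,df", [(52, 23, 73), (38, 14, 50)])
    def test_degrees_of_freedom(self, rng, n1, n2, df):
        assert two_sample_t(rng.normal(0, 1, n1), rng.normal(0, 1, n2)).df == df

    def test_p_value_worked_example(self):
        """t = 1.42 at 73 degrees of freedom has two-sided p rounding to 0.160."""
        p = 2 * stats.t.sf(1.42, 73)
        # the implementation reproduces the same tail computation
        x1 = np.array([0.0, 1, 2, 3])
        x2 = x1 + 0.5
        res = two_sample_t(x1, x2)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), res.df), rel=1e-12)
        assert round(p, 3) == 0.160

    def test_identical_groups_give_t0_p1(self):
        res = two_sample_t([5, 5, 5], [5, 5])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_t([5, 5, 5], [7, 7])  # zero variance, unequal means
        with pytest.raises(ValueError):
            two_sample_t([1.0, np.inf], [2.0, 3.0])


class TestCriticalT:
    def test_printed_values(self):
        assert round(critical_t(0.05, 73), 2) == 1.99
        assert round(critical_t(0.05, 10_000_000), 2) == 1.96

    def test_matches_density_quadrature(self):
        """Oracle: integrate the t density up to the returned quantile."""
        q = critical_t(0.05, 10)
        mass, _ = integrate.quad(lambda x: stats.t.pdf(x, 10), -np.inf, q)
        assert mass == pytest.approx(0.975, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_t(0.0, 10)
        with pytest.raises(ValueError):
            critical_t(0.05, 0)


class TestBonferroni:
    def test_five_level_example(self):
        decisions = bonferroni([0.009, 0.02, 0.16, 0.004, 0.001], alpha=0.05)
        assert decisions == [True, False, False, True, True]

    def test_single_test(self):
        assert bonferroni([0.04], alpha=0.05) == [True]

    def test_all_ones_never_reject(self):
        assert bonferroni([1.0] * 5) == [False] * 5

    def test_rejections_subset_of_raw_and_monotone_in_alpha(self, rng):
        p = list(rng.uniform(0, 1, 20))
        corrected = bonferroni(p, alpha=0.05)
        raw = [v <= 0.05 for v in p]
        assert all(not c or r for c, r in zip(corrected, raw))
        wider = bonferroni(p, alpha=0.2)
        assert all(not c or w for c, w in zip(corrected, wider))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni([], alpha=0.05)
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.5])


class TestCompareByLevel:
    def test_df_50_for_completion_split_of_38_and_14(self, rng):
        recs = []
        for i in range(38):
            means = {l: float(rng.normal(65, 5)) for l in range(5)}
            recs.append(make_record(f"c{i}", "control", means, completed=True))
        for i in range(14):
            means = {l: float(rng.normal(55, 5)) for l in range(5)}
            recs.append(make_record(f"u{i}", "control", means, completed=False))
        comps = compare_by_level(
            recs,
            key=lambda r: "completed" if r.completed else "uncompleted",
            groups=("completed", "uncompleted"),
        )
        assert all(c.df == 50 for c in comps if c.testable)
        assert all(c.testable for c in comps)

    def test_level_with_too_few_subjects_is_not_testable(self, rng):
        recs = [
            make_record(f"a{i}", "control", {0: float(rng.normal(60, 5)), 1: 60.0 + i})
            for i in range(5)
        ]
        recs += [
            make_record(f"b{i}", "adhd", {0: float(rng.normal(50, 5))}) for i in range(5)
        ]
        comps = compare_by_level(recs, n_levels=2)
        assert comps[0].testable
        assert not comps[1].testable and math.isnan(comps[1].t)
        assert comps[1].n2 == 0

    def test_separated_profiles_all_levels_rejected(self):
        cohort = simulate_cohort(CohortSpec(seed=1))  # full 52 + 23 cohort
        comps = compare_by_level(cohort)
        testable = [c for c in comps if c.testable]
        assert testable and all(c.significant_bonferroni for c in testable)
        assert all(c.mean1 > c.mean2 for c in testable)

    def test_power_increases_with_profile_gap(self):
        """Expected corrected rejections are monotone over a mean-gap grid."""
        mean_rej = []
        for gap in (0, 6, 12):
            rejections = []
            for rep in range(12):
                spec = CohortSpec(
                    n_control=26, n_adhd=12, seed=900 + rep,
                    control_profile=AttentionProfile(60, 12, 0.7, "control"),
                    adhd_profile=AttentionProfile(60 - gap, 12, 0.7, "adhd"),
                )
                comps = compare_by_level(simulate_cohort(spec))
                rejections.append(
                    sum(c.significant_bonferroni for c in comps if c.testable)
                )
            mean_rej.append(np.mean(rejections))
        assert mean_rej[0] <= mean_rej[1] <= mean_rej[2]
        assert mean_rej[2] > mean_rej[0]


class TestCompletionSplit:
    def test_trivial_partitions(self):
        done = [make_record(f"d{i}", "control", {0: 60.0}, completed=True) for i in range(3)]
        not_done = [make_record(f"n{i}", "control", {0: 60.0}) for i in range(2)]
        assert completion_split(done) == (done, [])
        assert completion_split(not_done) == ([], not_done)
        a, b = completion_split(done + not_done)
        assert len(a) + len(b) == 5

    def test_agrees_with_engine_replay(self, small_cohort):
        done, not_done = completion_split(small_cohort)
        for r in done + not_done:
            replay = run_session(r.log.attention, default_config())
            assert replay.completed == r.completed


class TestContingencySummary:
    @staticmethod
    def _caras(effective, impulsive):
        return CarasScores(a=30, e=10, ae=20, ici=50.0,
                           effective=effective, impulsive=impulsive)

    def test_margins_of_a_23_subject_adhd_cohort(self):
        """Rows sum to subgroup sizes 10/13 and the group total to 23, with
        effective 11/ineffective 12 and impulsive 16/non-impulsive 7."""
        recs = []
        specs = [  # (completed, n, effective, impulsive)
            (True, 3, True, True), (True, 6, False, True), (True, 1, False, False),
            (False, 7, True, True), (False, 1, True, False), (False, 5, False, False),
        ]
        i = 0
        for completed, n, eff, imp in specs:
            for _ in range(n):
                recs.append(
                    make_record(f"s{i}", "adhd", {0: 50.0}, completed=completed,
                                caras=self._caras(eff, imp))
                )
                i += 1
        table = contingency_summary(recs)
        assert table.loc["adhd completed", "total"] == 10
        assert table.loc["adhd uncompleted", "total"] == 13
        assert table.loc["adhd total", "total"] == 23
        assert table.loc["adhd total", "effective"] == 11
        assert table.loc["adhd total", "ineffective"] == 12
        assert table.loc["adhd total", "impulsive"] == 16
        assert table.loc["adhd total", "non_impulsive"] == 7
        # each dichotomy partitions the group
        assert (
            table.loc["adhd total", "impulsive"]
            + table.loc["adhd total", "non_impulsive"]
            == 23
        )
        assert (
            table.loc["adhd total", "effective"]
            + table.loc["adhd total", "ineffective"]
            == 23
        )

    def test_unclassified_subjects_get_their_own_column(self):
        recs = [
            make_record("a", "control", {0: 60.0}, caras=self._caras(True, False)),
            make_record("b", "control", {0: 60.0}, caras=None),
        ]
        table = contingency_summary(recs)
        assert "unclassified" in table.columns
        assert table.loc["control total", "unclassified"] == 1
        assert table.loc["control total", "total"] == 2

    def test_fully_classified_cohort_has_no_unclassified_column(self):
        recs = [
            make_record("a", "control", {0: 60.0}, caras=self._caras(True, False)),
            make_record("b", "control", {0: 60.0}, caras=self._caras(False, True)),
        ]
        table = contingency_summary(recs)
        assert "unclassified" not in table.columns

    def test_empty_cohort_gives_empty_table(self):
        table = contingency_summary([])
        assert len(table) == 0
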