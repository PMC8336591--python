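import numpy as np
import pytest

from internof1 import (
    ContingencyTable2x2,
    SubjectGeneSetStat,
    cohort_summary,
    compare_cohorts,
    log_odds,
    w_statistic,
)
from internof1.inter import CohortSummary


def _stat(set_id, subject_id, q, var_q):
    return SubjectGeneSetStat(
        set_id=set_id,
        subject_id=subject_id,
        table=ContingencyTable2x2(0, 0, 0, 0),
        Q=q,
        varQ=var_q,
        fet_p=1.0,
    )


class TestCohortSummary:
    def test_single_subject(self):
        summary = cohort_summary([_stat("S", "a1", 1.2, 0.5)])
        assert summary.mean_Q == pytest.approx(1.2)
        assert summary.var_mean_Q == pytest.approx(0.5)
        assert summary.n_subjects == 1

    def test_two_subject_arithmetic(self):
        summary = cohort_summary(
            [_stat("S", "a1", 1.0, 2.0), _stat("S", "a2", 3.0, 2.0)]
        )
        assert summary.mean_Q == pytest.approx(2.0)
        assert summary.var_mean_Q == pytest.approx(1.0)  # (2+2)/4

    def test_negating_q_flips_mean_only(self):
        stats = [_stat("S", "a1", 0.4, 1.0), _stat("S", "a2", -1.0, 2.0)]
        flipped = [_stat("S", "a1", -0.4, 1.0), _stat("S", "a2", 1.0, 2.0)]
        assert cohort_summary(flipped).mean_Q == pytest.approx(
            -cohort_summary(stats).mean_Q
        )
        assert cohort_summary(flipped).var_mean_Q == pytest.approx(
            cohort_summary(stats).var_mean_Q
        )

    def test_mixed_sets_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            cohort_summary([_stat("S1", "a1", 0, 1), _stat("S2", "a2", 0, 1)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no subject"):
            cohort_summary([])


class TestWStatistic:
    def test_equal_means_give_null(self):
        a = CohortSummary("S", "A", 0.7, 0.2, 3)
        b = CohortSummary("S", "B", 0.7, 0.3, 3)
        w, p = w_statistic(a, b)
        assert w == 0.0
        assert p == 1.0

    def test_normal_tail_arithmetic(self):
        a = CohortSummary("S", "A", 1.0, 0.125, 2)
        b = CohortSummary("S", "B", 0.0, 0.125, 2)
        w, p = w_statistic(a, b)
        assert w == pytest.approx(2.0)
        assert p == pytest.approx(0.04550, abs=1e-5)

    def test_cohort_swap_negates_w(self):
        a = CohortSummary("S", "A", 1.3, 0.4, 3)
        b = CohortSummary("S", "B", -0.2, 0.6, 3)
        w_ab, p_ab = w_statistic(a, b)
        w_ba, p_ba = w_statistic(b, a)
        assert w_ba == pytest.approx(-w_ab)
        assert p_ba == pytest.approx(p_ab)

    def test_nonfinite_variance_rejected(self):
        a = CohortSummary("S", "A", 1.0, np.inf, 3)
        b = CohortSummary("S", "B", 0.0, 0.1, 3)
        with pytest.raises(ValueError, match="variance"):
            w_statistic(a, b)


def _cohort_stats(set_to_qvar, subjects, prefix):
    """Build per-subject stats: set_id -> (Q per subject, varQ)."""
    stats = []
    for subject in range(subjects):
        for set_id, (qs, var_q) in set_to_qvar.items():
            stats.append(_stat(set_id, f"{prefix}{subject}", qs[subject], var_q))
    return stats


class TestCompareCohorts:
    def test_negative_means_suppressed_to_one(self):
        a = _cohort_stats({"S": ([-0.5, -0.5], 0.01)}, 2, "a")
        b = _cohort_stats({"S": ([-1.2, -1.2], 0.01)}, 2, "b")
        (comp,) = compare_cohorts(a, b)
        assert comp.suppressed
        assert comp.q == 1.0
        assert not comp.significant

    def test_zero_mean_not_suppressed(self):
        a = _cohort_stats({"S": ([0.0, 0.0], 0.01)}, 2, "a")
        b = _cohort_stats({"S": ([-1.0, -1.0], 0.01)}, 2, "b")
        (comp,) = compare_cohorts(a, b)
        assert not comp.suppressed

    def test_single_set_q_equals_p(self):
        a = _cohort_stats({"S": ([1.0], 0.125)}, 1, "a")
        b = _cohort_stats({"S": ([0.0], 0.125)}, 1, "b")
        (comp,) = compare_cohorts(a, b)
        assert comp.W == pytest.approx(2.0)
        assert comp.q == pytest.approx(comp.p) == pytest.approx(0.04550, abs=1e-5)

    def test_all_null_pvalues_no_significance(self):
        sets = {f"S{i}": ([0.3, 0.3], 0.2) for i in range(5)}
        a = _cohort_stats(sets, 2, "a")
        b = _cohort_stats(sets, 2, "b")
        comps = compare_cohorts(a, b)
        assert all(c.p == 1.0 and not c.significant for c in comps)

    def test_shared_subject_rejected(self):
        a = _cohort_stats({"S": ([1.0], 0.1)}, 1, "x")
        b = _cohort_stats({"S": ([0.0], 0.1)}, 1, "x")
        with pytest.raises(ValueError, match="share"):
            compare_cohorts(a, b)

    def test_mismatched_collections_rejected(self):
        a = _cohort_stats({"S1": ([1.0], 0.1)}, 1, "a")
        b = _cohort_stats({"S2": ([0.0], 0.1)}, 1, "b")
        with pytest.raises(ValueError, match="collections"):
            compare_cohorts(a, b)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        sets = {
            f"S{i}": (list(rng.normal(0.5, 1, 3)), float(rng.uniform(0.05, 0.5)))
            for i in range(6)
        }
        sets_b = {
            f"S{i}": (list(rng.normal(0.0, 1, 3)), float(rng.uniform(0.05, 0.5)))
            for i in range(6)
        }
        a = _cohort_stats(sets, 3, "a")
        b = _cohort_stats(sets_b, 3, "b")
        forward = compare_cohorts(a, b)
        backward = compare_cohorts(b, a)
        for f, r in zip(forward, backward):
            assert r.W == pytest.approx(-f.W)
            assert r.p == pytest.approx(f.p)

    def test_suppression_never_creates_significance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sets = {
                f"S{i}": (list(rng.normal(-1, 2, 2)), float(rng.uniform(0.01, 0.3)))
                for i in range(8)
            }
            sets_b = {
                f"S{i}": (list(rng.normal(-1, 2, 2)), float(rng.uniform(0.01, 0.3)))
                for i in range(8)
            }
            comps = compare_cohorts(
                _cohort_stats(sets, 2, "a"), _cohort_stats(sets_b, 2, "b")
            )
            assert all(not (c.suppressed and c.significant) for c in comps)


class TestNullCalibration:
    def test_w_is_approximately_standard_normal_under_h0(self):
        """Both cohorts' tables generated from the same DEG probability:
        empirical P(|W| > 1.96) should be near 0.05."""
        rng = np.random.default_rng(2021)
        n_sets, subjects = 1000, 3
        universe, set_size, p_deg = 10_000, 200, 0.10
        rejections = 0
        for _ in range(n_sets):
            def draw_stats(prefix):
                stats = []
                for j in range(subjects):
                    g = rng.binomial(set_size, p_deg)
                    h = rng.binomial(universe - set_size, p_deg)
                    table = ContingencyTable2x2(
                        g, set_size - g, h, universe - set_size - h
                    )
                    q, var_q = log_odds(table)
                    stats.append(_stat("S", f"{prefix}{j}", q, var_q))
                return stats

            a = cohort_summary(draw_stats("a"))
            b = cohort_summary(draw_stats("b"))
            w, _ = w_statistic(a, b)
            rejections += abs(w) > 1.96
        assert 0.03 <= rejections / n_sets <= 0.07
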