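"""The Inter-N-of-1 cross-cohort test.

Per gene set, the per-subject continuity-corrected log odds ratios Q are
averaged within each cohort,

    Qbar_K = (1/S_K) sum_j Q_kj,   var(Qbar_K) = sum_j var(Q_kj) / S_K^2,

and the two cohorts contrasted with a normal-score statistic

    W = (Qbar_A - Qbar_B) / sqrt(var(Qbar_A) + var(Qbar_B)),

which is approximately standard normal under H0: theta_A = theta_B (equal
expected log-OR in the two cohorts).  Two-sided p-values 2*P(Z > |W|) are
BH-adjusted across all gene sets tested, after which the *negative-means
rule* overwrites the adjusted p with 1.0 for any set whose mean log-OR is
negative in both cohorts — a set impoverished of DEGs everywhere is not a
biologically interpretable discovery.  Suppression is applied after BH, on
the adjusted values, and never creates significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import SubjectGeneSetStat, bh_adjust

__all__ = [
    "CohortSummary",
    "CohortComparison",
    "cohort_summary",
    "w_statistic",
    "compare_cohorts",
    "comparisons_to_frame",
]


@dataclass
class CohortSummary:
    """Cohort-level mean log-OR for one gene set.

    ``mean_Q`` estimates the cohort expectation theta_K of the
    continuity-corrected log odds ratio; ``var_mean_Q`` is its variance
    under within-cohort independence.
    """

    set_id: str
    cohort_label: str
    mean_Q: float
    var_mean_Q: float
    n_subjects: int


@dataclass
class CohortComparison:
    """Cross-cohort contrast for one gene set."""

    set_id: str
    W: float
    p: float
    q: float
    mean_Q_A: float
    mean_Q_B: float
    suppressed: bool = False
    significant: bool = False


def cohort_summary(
    stats: Sequence[SubjectGeneSetStat], cohort_label: str = ""
) -> CohortSummary:
    """Average per-subject Q within a cohort for one gene set."""
    if len(stats) == 0:
        raise ValueError("no subject statistics given")
    set_ids = {s.set_id for s in stats}
    if len(set_ids) != 1:
        raise ValueError(f"statistics mix gene sets: {sorted(set_ids)}")
    n = len(stats)
    mean_q = float(np.mean([s.Q for s in stats]))
    var_mean_q = float(np.sum([s.varQ for s in stats]) / n**2)
    return CohortSummary(stats[0].set_id, cohort_label, mean_q, var_mean_q, n)


def w_statistic(a: CohortSummary, b: CohortSummary) -> tuple[float, float]:
    """Normal-score contrast of two cohort summaries and its two-sided p."""
    if a.set_id != b.set_id:
        raise ValueError("cohort summaries refer to different gene sets")
    denom = a.var_mean_Q + b.var_mean_Q
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("non-finite or nonpositive variance")
    w = (a.mean_Q - b.mean_Q) / np.sqrt(denom)
    p = min(1.0, 2.0 * float(norm.sf(abs(w))))
    return float(w), p


def _group_by_set(
    stats: Sequence[SubjectGeneSetStat],
) -> dict[str, list[SubjectGeneSetStat]]:
    grouped: dict[str, list[SubjectGeneSetStat]] = {}
    for s in stats:
        grouped.setdefault(s.set_id, []).append(s)
    return grouped


def compare_cohorts(
    cohort_a_stats: Sequence[SubjectGeneSetStat],
    cohort_b_stats: Sequence[SubjectGeneSetStat],
    fdr_level: float = 0.05,
) -> list[CohortComparison]:
    """Run the cross-cohort test over every gene set present in both cohorts.

    BH adjustment spans all N sets tested (N is whatever the caller passes
    in — 4 sets in the simulation design, thousands for a genome-wide GO
    screen).  The two cohorts must not share subjects: the contrast assumes
    independent groups.
    """
    subj_a = {s.subject_id for s in cohort_a_stats}
    subj_b = {s.subject_id for s in cohort_b_stats}
    shared = subj_a & subj_b
    if shared:
        raise ValueError(f"cohorts share subjects: {sorted(shared)}")
    by_set_a = _group_by_set(cohort_a_stats)
    by_set_b = _group_by_set(cohort_b_stats)
    if set(by_set_a) != set(by_set_b):
        raise ValueError("cohorts were profiled over different gene-set collections")

    comparisons: list[CohortComparison] = []
    for set_id in by_set_a:  # insertion order = input order
        summary_a = cohort_summary(by_set_a[set_id], "A")
        summary_b = cohort_summary(by_set_b[set_id], "B")
        w, p = w_statistic(summary_a, summary_b)
        comparisons.append(
            CohortComparison(
                set_id=set_id,
                W=w,
                p=p,
                q=np.nan,
                mean_Q_A=summary_a.mean_Q,
                mean_Q_B=summary_b.mean_Q,
            )
        )
    qvals = bh_adjust([c.p for c in comparisons])
    for comp, qv in zip(comparisons, qvals):
        comp.q = float(qv)
        # negative-means rule: overwrite adjusted p post hoc (strict <0 on both)
        if comp.mean_Q_A < 0 and comp.mean_Q_B < 0:
            comp.q = 1.0
            comp.suppressed = True
        comp.significant = bool(comp.q < fdr_level and not comp.suppressed)
    return comparisons


def comparisons_to_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [c.set_id for c in comparisons],
            "mean_Q_A": [c.mean_Q_A for c in comparisons],
            "mean_Q_B": [c.mean_Q_B for c in comparisons],
            "W": [c.W for c in comparisons],
            "p": [c.p for c in comparisons],
            "q": [c.q for c in comparisons],
            "suppressed": [c.suppressed for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )
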