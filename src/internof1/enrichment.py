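"""Per-subject gene-set statistics.

For one subject and one gene set, DEG status is cross-classified against
set membership in a 2x2 contingency table:

=============  =====  ========
               DEG    not DEG
=============  =====  ========
in gene set    g      g'
not in set     h      h'
=============  =====  ========

Two statistics are computed per table: a two-sided Fisher exact test on the
raw integer counts, and the continuity-corrected natural-log odds ratio

    Q = ln[ (g + 1/2)(h' + 1/2) / ((h + 1/2)(g' + 1/2)) ]

with Woolf-type variance

    var(Q) = 1/(g + 1/2) + 1/(g' + 1/2) + 1/(h + 1/2) + 1/(h' + 1/2).

Adding 1/2 to every cell keeps both quantities finite for any table,
including empty ones, which is what lets every subject contribute an effect
size to the downstream cross-cohort contrast.  The correction applies only
to Q/var(Q); the Fisher test uses the uncorrected counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, GeneSetCollection
from .mixenrich import DegCall

__all__ = [
    "ContingencyTable2x2",
    "SubjectGeneSetStat",
    "make_table",
    "fisher_two_sided",
    "log_odds",
    "bh_adjust",
    "subject_profile",
    "profile_to_frame",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """DEG-by-membership counts for one (gene set, subject)."""

    g: int       # DEGs inside the set
    g_not: int   # non-DEGs inside the set
    h: int       # DEGs outside the set
    h_not: int   # non-DEGs outside the set

    def __post_init__(self) -> None:
        for name in ("g", "g_not", "h", "h_not"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.g + self.g_not + self.h + self.h_not

    def as_array(self) -> np.ndarray:
        return np.array([[self.g, self.g_not], [self.h, self.h_not]], dtype=int)


@dataclass
class SubjectGeneSetStat:
    """One subject's enrichment evidence for one gene set."""

    set_id: str
    subject_id: str
    table: ContingencyTable2x2
    Q: float
    varQ: float
    fet_p: float
    fet_q: float = np.nan
    enriched: bool = False


def make_table(
    degs: DegCall, gene_set: GeneSet, universe: Sequence[str] | None = None
) -> ContingencyTable2x2:
    """Cross-classify DEG status with gene-set membership over the universe.

    The universe defaults to the genes carried by the DEG call (i.e. the
    post-filter analysis universe).  Gene sets are intersected with the
    universe first; DEGs outside the universe are a contract violation.
    """
    if universe is None:
        universe_set = set(degs.genes)
    else:
        universe_set = set(universe)
    deg_genes = degs.deg_genes()
    outside = deg_genes - universe_set
    if outside:
        example = sorted(outside)[0]
        raise ValueError(f"DEG {example!r} is not in the analysis universe")
    members = set(gene_set.genes) & universe_set
    if not members:
        raise ValueError(
            f"gene set {gene_set.set_id!r} has no genes in the analysis universe"
        )
    g = len(deg_genes & members)
    g_not = len(members) - g
    h = len(deg_genes) - g
    h_not = len(universe_set) - len(members) - h
    return ContingencyTable2x2(g, g_not, h, h_not)


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities no
    larger than that of the observed table, on uncorrected counts."""
    return float(min(1.0, fisher_exact(table.as_array(), alternative="two-sided")[1]))


def log_odds(table: ContingencyTable2x2) -> tuple[float, float]:
    """Continuity-corrected natural-log odds ratio Q and its variance."""
    g = table.g + 0.5
    g_not = table.g_not + 0.5
    h = table.h + 0.5
    h_not = table.h_not + 0.5
    q = float(np.log((g * h_not) / (h * g_not)))
    var_q = float(1.0 / g + 1.0 / g_not + 1.0 / h + 1.0 / h_not)
    return q, var_q


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def subject_profile(
    degs: DegCall,
    collection: GeneSetCollection,
    fdr_level: float = 0.05,
    subject_id: str = "",
) -> list[SubjectGeneSetStat]:
    """Per-gene-set statistics for one subject: table, Fisher p, Q, var(Q).

    BH adjustment is computed across all sets in the collection; a set is
    flagged enriched when its adjusted p is below ``fdr_level``.
    """
    if len(collection) == 0:
        raise ValueError("gene-set collection is empty")
    stats = []
    for gene_set in collection:
        table = make_table(degs, gene_set)
        q, var_q = log_odds(table)
        stats.append(
            SubjectGeneSetStat(
                set_id=gene_set.set_id,
                subject_id=subject_id,
                table=table,
                Q=q,
                varQ=var_q,
                fet_p=fisher_two_sided(table),
            )
        )
    qvals = bh_adjust([s.fet_p for s in stats])
    for stat, qv in zip(stats, qvals):
        stat.fet_q = float(qv)
        stat.enriched = bool(qv < fdr_level)
    return stats


def profile_to_frame(stats: Sequence[SubjectGeneSetStat]) -> pd.DataFrame:
    """Tabulate per-subject gene-set statistics (one row per set)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in stats],
            "set_id": [s.set_id for s in stats],
            "g": [s.table.g for s in stats],
            "g_not": [s.table.g_not for s in stats],
            "h": [s.table.h for s in stats],
            "h_not": [s.table.h_not for s in stats],
            "Q": [s.Q for s in stats],
            "varQ": [s.varQ for s in stats],
            "fet_p": [s.fet_p for s in stats],
            "fet_q": [s.fet_q for s in stats],
            "enriched": [s.enriched for s in stats],
        }
    )
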