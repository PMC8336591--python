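"""Transcript filtering for single-subject and cohort (GLM) analyses.

Two filtering regimes are provided:

* the paired-sample union filter used before single-subject analyses —
  within each subject's baseline/case pair, low-expression genes are
  dropped, the per-pair survivor lists are unioned across subjects, and a
  pseudocount is added so downstream log fold changes are always defined;
* the coefficient-of-variation filter used before cohort GLM analyses —
  genes with a zero count anywhere are dropped, the rest are ranked by CV
  and the top fraction retained.

Threshold semantics differ deliberately between the two study settings this
package models: the real-data pipeline drops genes with within-pair mean
``<= min_mean`` while the simulation pipeline drops genes with mean
``< min_mean``; both are explicit parameters here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CountMatrix

__all__ = [
    "PairedSample",
    "Cohort",
    "filter_pairs_union",
    "cv_filter",
    "sim_filter",
]


@dataclass(frozen=True)
class PairedSample:
    """One subject's paired two-condition samples (e.g. normal vs tumor)."""

    subject_id: str
    baseline_sample: str
    case_sample: str

    def __post_init__(self) -> None:
        if self.baseline_sample == self.case_sample:
            raise ValueError(
                f"subject {self.subject_id!r}: baseline and case samples are identical"
            )


@dataclass
class Cohort:
    """A labeled group of subjects, each contributing one paired sample."""

    label: str
    subjects: list[PairedSample]

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError(f"cohort {self.label!r} has no subjects")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cohort {self.label!r} has duplicate subject ids")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _check_pairs(matrix: CountMatrix, pairs: Sequence[PairedSample]) -> None:
    known = set(matrix.samples)
    for pair in pairs:
        for sample in (pair.baseline_sample, pair.case_sample):
            if sample not in known:
                raise ValueError(
                    f"subject {pair.subject_id!r}: sample {sample!r} not in matrix"
                )


def filter_pairs_union(
    matrix: CountMatrix,
    pairs: Sequence[PairedSample],
    min_mean: float = 5.0,
    pseudocount: float = 1.0,
    drop_at_threshold: bool = True,
) -> CountMatrix:
    """Union-of-pairs low-expression filter with pseudocount.

    Per pair, a gene is flagged removed when its within-pair mean is
    ``<= min_mean`` (or ``< min_mean`` with ``drop_at_threshold=False``).
    The final gene list is the union over pairs of retained genes, and the
    pseudocount is added to every retained count so zeros are eliminated.
    """
    if not pairs:
        raise ValueError("no paired samples given")
    _check_pairs(matrix, pairs)
    keep = np.zeros(matrix.n_genes, dtype=bool)
    for pair in pairs:
        pair_mean = 0.5 * (
            matrix.column(pair.baseline_sample) + matrix.column(pair.case_sample)
        )
        if drop_at_threshold:
            keep |= pair_mean > min_mean
        else:
            keep |= pair_mean >= min_mean
    if not keep.any():
        raise ValueError("no gene passes the expression filter in any pair")
    out = matrix.subset_genes(keep)
    return CountMatrix(out.genes, out.samples, out.counts + pseudocount)


def cv_filter(matrix: CountMatrix, top_fraction: float) -> CountMatrix:
    """Retain the top fraction of transcripts ranked by coefficient of variation.

    Transcripts with a zero count in any sample are removed first (the most
    conservative reading of a per-subject zero rule: it guarantees CV and log
    transforms are defined).  Remaining genes are ranked by sd/mean across all
    samples, descending, and the top ``ceil(top_fraction * n)`` kept.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if matrix.n_genes < 1:
        raise ValueError("matrix has no genes")
    nonzero = np.all(matrix.counts > 0, axis=1)
    if not nonzero.any():
        raise ValueError("all genes removed by the zero-count rule")
    sub = matrix.subset_genes(nonzero)
    means = sub.counts.mean(axis=1)
    sds = sub.counts.std(axis=1, ddof=1)
    cv = sds / means
    n_keep = math.ceil(top_fraction * sub.n_genes)
    # stable sort keeps input order among CV ties
    order = np.argsort(-cv, kind="stable")[:n_keep]
    mask = np.zeros(sub.n_genes, dtype=bool)
    mask[order] = True
    return sub.subset_genes(mask)


def sim_filter(
    matrix: CountMatrix,
    pairs: Sequence[PairedSample],
    mode: str,
    min_mean: float = 30.0,
    pseudocount: float = 1.0,
) -> CountMatrix:
    """Simulation-study preprocessing for either analysis branch.

    ``mode="glm"`` drops genes whose overall mean across all samples is
    strictly below ``min_mean`` and then adds the pseudocount;
    ``mode="s3"`` applies the per-pair mean rule (strict ``<``), unions the
    survivors across pairs, and adds the pseudocount.
    """
    if mode == "glm":
        keep = matrix.counts.mean(axis=1) >= min_mean
        if not keep.any():
            raise ValueError("no gene passes the expression filter")
        out = matrix.subset_genes(keep)
        return CountMatrix(out.genes, out.samples, out.counts + pseudocount)
    if mode == "s3":
        return filter_pairs_union(
            matrix, pairs, min_mean=min_mean, pseudocount=pseudocount,
            drop_at_threshold=False,
        )
    raise ValueError(f"mode must be 'glm' or 's3', got {mode!r}")
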