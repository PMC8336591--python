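"""Accuracy measurement and the simulation benchmark driver.

Precision/recall come in two flavors used in different study settings:

* *traditional* — tp/(tp+fp) and tp/(tp+fn), used when scoring the
  simulation against known truth;
* *adjusted* — (tp+0.5)/(tp+fp+1.0) and (tp+0.5)/(tp+fn+1.0), a
  small-sample correction used when scoring against an empirical reference
  standard.

In both modes the *zero rule* applies first: a method that makes no
positive predictions at all is assigned precision = recall = 0.

A similarity-matched variant accepts a pairwise similarity matrix between
set identifiers (e.g. an information-theoretic GO-term similarity) and
counts near-identical terms (similarity >= threshold) as matches; with an
identity matrix it reduces to exact matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision_recall",
    "similarity_matched_pr",
    "subsample_cohorts",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    predicted: set[str], truth: set[str], universe: Iterable[str]
) -> ConfusionCounts:
    """Cross-classify predicted vs true positive set ids over a universe."""
    universe = set(universe)
    if not predicted <= universe:
        raise ValueError(
            f"predictions outside universe: {sorted(predicted - universe)}"
        )
    if not truth <= universe:
        raise ValueError(f"truth outside universe: {sorted(truth - universe)}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall(
    counts: ConfusionCounts, mode: str = "traditional"
) -> tuple[float, float]:
    """Precision and recall with the zero rule.

    No positive predictions (tp + fp = 0) yields (0, 0) in both modes.
    """
    if mode not in ("traditional", "adjusted"):
        raise ValueError(f"mode must be 'traditional' or 'adjusted', got {mode!r}")
    if counts.tp + counts.fp == 0:
        return 0.0, 0.0
    if mode == "traditional":
        precision = counts.tp / (counts.tp + counts.fp)
        recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    else:
        precision = (counts.tp + 0.5) / (counts.tp + counts.fp + 1.0)
        recall = (counts.tp + 0.5) / (counts.tp + counts.fn + 1.0)
    return float(precision), float(recall)


def similarity_matched_pr(
    predicted: set[str],
    reference: set[str],
    similarity: pd.DataFrame | Mapping[tuple[str, str], float] | None = None,
    threshold: float = 0.70,
    mode: str = "traditional",
) -> tuple[float, float]:
    """Precision/recall where near-identical terms count as matches.

    A predicted set matches when its similarity to *any* reference set is
    ``>= threshold`` (identical ids always count as similarity 1); the
    precision denominator stays all predictions and the recall denominator
    all reference sets.  ``similarity=None`` uses the identity matrix.
    """

    def sim(x: str, y: str) -> float:
        if x == y:
            return 1.0
        if similarity is None:
            return 0.0
        if isinstance(similarity, pd.DataFrame):
            try:
                return float(similarity.loc[x, y])
            except KeyError:
                raise ValueError(f"missing similarity entry for ({x!r}, {y!r})")
        if (x, y) in similarity:
            return float(similarity[(x, y)])
        if (y, x) in similarity:
            return float(similarity[(y, x)])
        raise ValueError(f"missing similarity entry for ({x!r}, {y!r})")

    if not predicted:
        return 0.0, 0.0
    matched_pred = sum(
        1 for x in predicted if any(sim(x, y) >= threshold for y in reference)
    )
    matched_ref = sum(
        1 for y in reference if any(sim(x, y) >= threshold for x in predicted)
    )
    if mode == "adjusted":
        precision = (matched_pred + 0.5) / (len(predicted) + 1.0)
        recall = (matched_ref + 0.5) / (len(reference) + 1.0)
    elif mode == "traditional":
        precision = matched_pred / len(predicted)
        recall = matched_ref / len(reference) if reference else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(precision), float(recall)


def subsample_cohorts(
    cohort_a: Cohort,
    cohort_b: Cohort,
    s: int,
    n_draws: int,
    seed: int = 0,
) -> list[tuple[Cohort, Cohort]]:
    """Repeated without-replacement subsamples of ``s`` subjects per cohort.

    Draws are independent across repetitions (the same subsample may recur),
    but within one draw no subject is repeated.
    """
    if s > min(len(cohort_a), len(cohort_b)):
        raise ValueError(
            f"cannot draw {s} subjects from cohorts of sizes "
            f"{len(cohort_a)} and {len(cohort_b)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        idx_a = rng.choice(len(cohort_a), size=s, replace=False)
        idx_b = rng.choice(len(cohort_b), size=s, replace=False)
        out.append(
            (
                Cohort(cohort_a.label, [cohort_a.subjects[i] for i in idx_a]),
                Cohort(cohort_b.label, [cohort_b.subjects[i] for i in idx_b]),
            )
        )
    return out


def run_benchmark(
    grid: Iterable[tuple[dict, "SimulatedDataset"]],
    methods: Mapping[str, Callable] | None = None,
    fdr_level: float = 0.05,
    mode: str = "traditional",
) -> pd.DataFrame:
    """Score each method on each dataset of a simulation grid.

    Returns one row per (dataset, method) with the confusion counts over
    the dataset's gene sets and the per-replicate precision/recall (zero
    rule applied).  A method failure on a dataset is recorded as
    no-positives with a logged warning, never as a crash of the benchmark.
    """
    if methods is None:
        from .pipelines import SIMULATION_METHODS

        methods = SIMULATION_METHODS
    rows = []
    for entry, dataset in grid:
        universe = set(dataset.collection.set_ids())
        truth = dataset.truth_positive_sets()
        for name, method in methods.items():
            try:
                predicted = set(method(dataset, fdr_level))
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning(
                    "method %s failed on dataset %s: %s", name, entry, exc
                )
                warnings.warn(f"method {name} failed on dataset {entry}: {exc}",
                              stacklevel=2)
                predicted = set()
            counts = confusion(predicted, truth, universe)
            precision, recall = precision_recall(counts, mode)
            rows.append(
                {
                    "method": name,
                    "cohort_size": entry.get("cohort_size"),
                    "prop_coordinated": entry.get("prop_coordinated"),
                    "rep": entry.get("rep"),
                    "seed": entry.get("seed"),
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "precision": precision,
                    "recall": recall,
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame, mode: str = "traditional"
                        ) -> pd.DataFrame:
    """Per-configuration summary: per-rep medians/quartiles plus pooled PR.

    The pooled precision/recall aggregate the confusion counts across all
    replicates of a configuration before dividing (with the zero rule),
    which is how per-configuration benchmark points are usually drawn; the
    per-replicate medians and quartiles describe run-to-run spread.
    """
    def _summary(group: pd.DataFrame) -> pd.Series:
        pooled = ConfusionCounts(
            int(group["tp"].sum()), int(group["fp"].sum()),
            int(group["fn"].sum()), int(group["tn"].sum()),
        )
        pooled_precision, pooled_recall = precision_recall(pooled, mode)
        return pd.Series(
            {
                "n_reps": len(group),
                "precision_median": group["precision"].median(),
                "precision_q1": group["precision"].quantile(0.25),
                "precision_q3": group["precision"].quantile(0.75),
                "recall_median": group["recall"].median(),
                "recall_q1": group["recall"].quantile(0.25),
                "recall_q3": group["recall"].quantile(0.75),
                "pooled_precision": pooled_precision,
                "pooled_recall": pooled_recall,
            }
        )

    grouped = results.groupby(
        ["method", "cohort_size", "prop_coordinated"], sort=True
    )
    return grouped.apply(_summary, include_groups=False).reset_index()
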