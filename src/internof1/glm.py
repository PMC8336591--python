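"""Cohort-level GLM comparator methods.

Three designs are supported, mirroring the conventional analyses the
cross-cohort log-OR method is benchmarked against:

* ``simple``   — transcript level, case samples of cohort A vs cohort B;
* ``interaction`` — transcript level, (caseA - baselineA) vs
  (caseB - baselineB), i.e. the cohort-by-condition interaction with
  subject blocking;
* ``glm_egs`` — gene-set level: interaction DEGs followed by Fisher
  enrichment of gene sets (GLM+EGS).

The implementation is a deliberately simplified moderated paired test
rather than a full voom pipeline: counts are TMM-normalized and log-CPM
transformed, each subject is reduced to a within-pair log-ratio (which
captures subject blocking exactly in a paired design), and the two cohorts
are compared per gene with an empirical-Bayes moderated two-sample t
(per-gene variances shrunk toward a common prior with method-of-moments
prior degrees of freedom).  No per-sample quality weights are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import t as t_dist

from .enrichment import bh_adjust, fisher_two_sided, ContingencyTable2x2
from .io import CountMatrix, GeneSetCollection
from .preprocess import Cohort

__all__ = [
    "GlmResult",
    "tmm_factors",
    "log_cpm",
    "paired_interaction_test",
    "simple_contrast_test",
    "glm_egs",
]


@dataclass
class GlmResult:
    """Per-gene output of a transcript-level contrast."""

    design: str                 # "simple" or "interaction"
    genes: list[str]
    log2fc: np.ndarray          # estimated contrast on the log2 scale
    t: np.ndarray               # moderated t statistic
    p: np.ndarray
    q: np.ndarray               # BH-adjusted p
    df_prior: float = np.nan
    df_residual: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2fc": self.log2fc,
                "t": self.t,
                "p": self.p,
                "q": self.q,
            }
        )

    def degs(self, q_threshold: float = 0.05, lfc_threshold: float | None = None
             ) -> set[str]:
        """Genes declared differentially expressed (strict q < threshold and,
        when set, strict |log2FC| > lfc_threshold)."""
        mask = self.q < q_threshold
        if lfc_threshold is not None:
            mask &= np.abs(self.log2fc) > lfc_threshold
        return {g for g, m in zip(self.genes, mask) if m}


def tmm_factors(
    matrix: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    M-values (log2 relative expression vs a reference sample) are trimmed
    30% on each side and A-values 5% on each side; the factor is 2 raised to
    the precision-weighted mean of the surviving M-values.  Factors are
    normalized so their geometric mean is 1; multiplying library sizes by
    them gives effective library sizes.
    """
    counts = matrix.counts
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        bad = matrix.samples[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero total count")
    if ref_sample is None:
        # reference: sample whose upper-quartile/library ratio is closest to the mean
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                       for j in range(len(lib))])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = matrix.sample_index(ref_sample)

    factors = np.ones(len(lib))
    y_r = counts[:, ref]
    n_r = lib[ref]
    for j in range(len(lib)):
        if j == ref:
            continue
        y_k = counts[:, j]
        n_k = lib[j]
        ok = (y_k > 0) & (y_r > 0)
        if ok.sum() < 10:
            continue
        pk = y_k[ok] / n_k
        pr = y_r[ok] / n_r
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (n_k - y_k[ok]) / (n_k * y_k[ok]) + (n_r - y_r[ok]) / (n_r * y_r[ok])
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or np.sum(1.0 / w[keep]) == 0:
            continue
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def log_cpm(matrix: CountMatrix, factors: np.ndarray | None = None,
            prior_count: float = 0.5) -> np.ndarray:
    """log2 counts per million with TMM-effective library sizes."""
    if factors is None:
        factors = tmm_factors(matrix)
    eff = matrix.counts.sum(axis=0) * np.asarray(factors)
    return np.log2((matrix.counts + prior_count) / (eff + 1.0)[None, :] * 1e6)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances (moderated-t prior).

    Fits a scaled-F prior to the observed variances by method of moments on
    log(s^2) and returns the posterior variances and the prior degrees of
    freedom (np.inf when the observed variances show no excess spread).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s0 = np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        post = (df_prior * s0 + df * s2) / (df_prior + df)
    else:
        df_prior = np.inf
        s0 = np.exp(e_mean)
        post = np.full_like(s2, s0)
    return post, df_prior


def _moderated_two_sample(
    design: str,
    genes: list[str],
    values_a: np.ndarray,
    values_b: np.ndarray,
) -> GlmResult:
    """Moderated two-sample comparison of per-subject gene vectors.

    ``values_*`` are genes x subjects matrices of per-subject quantities
    (log-ratios for the interaction design, case log-CPM for the simple
    design).
    """
    na, nb = values_a.shape[1], values_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("design not estimable: need at least 2 subjects per cohort")
    mean_a = values_a.mean(axis=1)
    mean_b = values_b.mean(axis=1)
    df = na + nb - 2
    ss = ((values_a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (values_b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df
    s2_post, df_prior = _squeeze_var(s2, df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    effect = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, effect / se, 0.0)
    df_total = df + (df_prior if np.isfinite(df_prior) else 1e6)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    p = np.clip(p, 0.0, 1.0)
    return GlmResult(
        design=design,
        genes=genes,
        log2fc=effect,
        t=t_stat,
        p=p,
        q=bh_adjust(p),
        df_prior=float(df_prior),
        df_residual=float(df),
    )


def paired_interaction_test(
    matrix: CountMatrix, cohort_a: Cohort, cohort_b: Cohort
) -> GlmResult:
    """Interaction contrast (caseA-baselineA) - (caseB-baselineB).

    Counts are TMM-normalized and log-CPM transformed; each subject is
    reduced to its within-pair log-ratio (exact subject blocking), and the
    cohorts compared per gene with the moderated two-sample statistic.
    """
    factors = tmm_factors(matrix)
    logc = log_cpm(matrix, factors)

    def ratios(cohort: Cohort) -> np.ndarray:
        cols = []
        for pair in cohort.subjects:
            i_case = matrix.sample_index(pair.case_sample)
            i_base = matrix.sample_index(pair.baseline_sample)
            cols.append(logc[:, i_case] - logc[:, i_base])
        return np.column_stack(cols)

    return _moderated_two_sample(
        "interaction", list(matrix.genes), ratios(cohort_a), ratios(cohort_b)
    )


def simple_contrast_test(
    matrix: CountMatrix, cohort_a: Cohort, cohort_b: Cohort
) -> GlmResult:
    """Simple contrast: case samples of cohort A vs case samples of cohort B."""
    factors = tmm_factors(matrix)
    logc = log_cpm(matrix, factors)

    def cases(cohort: Cohort) -> np.ndarray:
        idx = [matrix.sample_index(p.case_sample) for p in cohort.subjects]
        return logc[:, idx]

    return _moderated_two_sample(
        "simple", list(matrix.genes), cases(cohort_a), cases(cohort_b)
    )


def glm_egs(
    result: GlmResult,
    collection: GeneSetCollection,
    deg_q: float = 0.05,
    deg_lfc: float | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Gene-set enrichment of interaction DEGs (the GLM+EGS design).

    DEGs are genes with BH-adjusted p strictly below ``deg_q`` (and, in
    real-data mode, |log2FC| strictly above ``deg_lfc``).  Each gene set is
    tested for DEG overrepresentation with a two-sided Fisher exact test
    over the analysis universe (= genes in the result); set-level p-values
    are BH-adjusted across the collection.  An empty DEG list simply yields
    no enriched sets.
    """
    universe = set(result.genes)
    deg_genes = result.degs(deg_q, deg_lfc)
    rows = []
    for gene_set in collection:
        members = set(gene_set.genes) & universe
        g = len(deg_genes & members)
        table = ContingencyTable2x2(
            g, len(members) - g, len(deg_genes) - g,
            len(universe) - len(members) - (len(deg_genes) - g),
        )
        rows.append({"set_id": gene_set.set_id, "g": g, "set_size": len(members),
                     "fet_p": fisher_two_sided(table)})
    frame = pd.DataFrame(rows)
    frame["fet_q"] = bh_adjust(frame["fet_p"])
    frame["enriched"] = frame["fet_q"] < fdr_level
    return frame
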