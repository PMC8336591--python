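"""Simulation of paired tumor-normal cohorts with ground-truth enrichment.

The generator emulates the six-parameter benchmark design used to compare
cross-cohort pathway methods at very small sample sizes:

* baseline ("normal") expression per subject: negative-binomial counts with
  log-normally distributed gene means and a gene-wise dispersion that decays
  with the mean — a synthetic stand-in for sampling real normal tissue
  profiles;
* null log2 fold changes: drawn from an empirical pool built from
  same-condition replicate pairs, binned into deciles of baseline
  expression (bins containing zero baseline expression are merged), so
  tumor/normal noise inherits the mean-variance relationship of replicate
  data;
* differentially expressed genes: positive log2FCs drawn from a
  Gamma(shape=0.55, scale=6.06) distribution;
* gene sets: two enriched sets (default sizes 200 and 40, DEG proportion
  0.10 each) and two control sets (sizes 196 and 41) with disjoint
  memberships;
* subject coordination: each cohort-A subject shares the common DEG
  selection with probability ``prop_coordinated`` (Bernoulli), otherwise
  draws its own selection of the same size;
* cohort B receives no seeded DEGs at all, creating the
  responsive-vs-unresponsive interaction the benchmark scores.

Tumor counts are ``round(normal * 2**log2FC)``.  Everything is driven by a
single seed, so a dataset is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .io import CountMatrix, GeneSet, GeneSetCollection
from .preprocess import Cohort, PairedSample

__all__ = [
    "SimulationConfig",
    "NullFcPool",
    "SimulatedDataset",
    "synth_baseline",
    "build_null_pool",
    "sample_deg_lfc",
    "assign_truth",
    "generate_dataset",
    "generate_grid",
]

_MAX_SEED = 2**31 - 1


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator.

    Defaults reproduce the benchmark's reference condition: ~17k genes,
    two enriched sets (200 and 40 genes, 10% DEGs each), two control sets
    (196 and 41 genes), gamma log2FCs with shape 0.55 / scale 6.06, and a
    coordination proportion of 0.48.  Only ``cohort_size`` and
    ``prop_coordinated`` are varied across the benchmark grid.
    """

    n_genes: int = 17414
    cohort_size: int = 3
    prop_coordinated: float = 0.48
    gamma_shape: float = 0.55
    gamma_scale: float = 6.06
    enriched_sets: tuple[tuple[int, float], ...] = ((200, 0.10), (40, 0.10))
    control_sets: tuple[int, ...] = (196, 41)
    seed: int = 0
    # synthetic baseline model: log-normal gene means; NB dispersion follows
    # an isogenic-replicate trend (BCV ~ 0.1) with log-normal gene-wise
    # spread, as in standard RNA-seq count simulators
    baseline_mean_log: float = math.log(200.0)   # natural-log median gene mean
    baseline_sd_log: float = 1.5
    dispersion_intercept: float = 0.01           # trend: a + b / mean
    dispersion_slope: float = 1.0
    dispersion_sd_log: float = 0.5               # sd of log gene-wise spread
    n_replicate_pairs: int = 7

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be positive")
        if not (0.0 <= self.prop_coordinated <= 1.0):
            raise ValueError("prop_coordinated must be in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        for size, prop in self.enriched_sets:
            if not (0.0 < prop < 1.0):
                raise ValueError("DEG proportions must be in (0, 1)")
            if size < 1:
                raise ValueError("gene-set sizes must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["enriched_sets"] = [list(pair) for pair in self.enriched_sets]
        data["control_sets"] = list(self.control_sets)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "enriched_sets" in data:
            data["enriched_sets"] = tuple(
                (int(s), float(p)) for s, p in data["enriched_sets"]
            )
        if "control_sets" in data:
            data["control_sets"] = tuple(int(s) for s in data["control_sets"])
        return cls(**data)


@dataclass
class NullFcPool:
    """Empirical null log2FC pools keyed by baseline-expression bin.

    ``bin_of_gene[i]`` is the (merged) bin of gene i, assigned from the
    gene's baseline expression; ``pools[b]`` holds the replicate-pair
    log2FCs of all genes in bin b.
    """

    edges: np.ndarray                 # inner decile boundaries (len 9)
    bin_of_gene: np.ndarray           # per-gene merged-bin index
    pools: dict[int, np.ndarray]
    baseline: np.ndarray              # per-gene baseline expression used for binning

    def __post_init__(self) -> None:
        for b, pool in self.pools.items():
            if pool.size == 0:
                raise ValueError(f"empty null pool in bin {b}")

    def bin_for_value(self, value: float) -> int:
        raw = int(np.searchsorted(self.edges, value, side="right"))
        return self._merge_map.get(raw, raw) if hasattr(self, "_merge_map") else raw

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One null log2FC per gene, each drawn from its own bin's pool."""
        out = np.empty(self.bin_of_gene.size)
        for b, pool in self.pools.items():
            idx = np.flatnonzero(self.bin_of_gene == b)
            if idx.size:
                out[idx] = rng.choice(pool, size=idx.size, replace=True)
        return out


@dataclass
class SimulatedDataset:
    """Counts, cohorts, and ground-truth labels for one simulated study."""

    counts: CountMatrix
    cohort_a: Cohort
    cohort_b: Cohort
    collection: GeneSetCollection
    truth_sets: dict[str, bool]               # set_id -> differentially enriched
    truth_degs: dict[str, frozenset[str]]     # subject_id -> seeded DEG genes
    coordinated: dict[str, bool]              # cohort-A subject -> shared selection?
    config: SimulationConfig = field(repr=False, default=None)

    def all_pairs(self) -> list[PairedSample]:
        return list(self.cohort_a.subjects) + list(self.cohort_b.subjects)

    def truth_positive_sets(self) -> set[str]:
        return {s for s, v in self.truth_sets.items() if v}


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersions: np.ndarray,
    n_samples: int,
) -> np.ndarray:
    """Genes x samples negative-binomial draws (gamma-Poisson mixture)."""
    shape = 1.0 / dispersions
    lam = rng.gamma(shape[:, None], (means * dispersions)[:, None],
                    size=(means.size, n_samples))
    return rng.poisson(lam).astype(float)


def _gene_means_dispersions(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    means = rng.lognormal(config.baseline_mean_log, config.baseline_sd_log,
                          config.n_genes)
    trend = config.dispersion_intercept + config.dispersion_slope / np.maximum(
        means, 1.0
    )
    spread = rng.lognormal(0.0, config.dispersion_sd_log, config.n_genes)
    return means, trend * spread


def synth_baseline(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, list[tuple[str, str]]]:
    """Synthetic normal-tissue replicate samples plus same-condition pairs.

    Emits ``2 * n_replicate_pairs`` negative-binomial replicate columns that
    share gene means (so any two columns of a pair differ only by counting
    noise), and the list of sample-id pairs from which the empirical null
    log2FC pool is built.
    """
    if config.n_genes < 1000:
        raise ValueError("need at least 1000 genes for a stable null pool")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    means, disp = _gene_means_dispersions(config, rng)
    n_cols = 2 * config.n_replicate_pairs
    counts = _nb_counts(rng, means, disp, n_cols)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples = [f"rep{i:02d}" for i in range(n_cols)]
    pairs = [(samples[2 * i], samples[2 * i + 1])
             for i in range(config.n_replicate_pairs)]
    return CountMatrix(genes, samples, counts), pairs


def build_null_pool(
    normals: CountMatrix,
    replicate_pairs: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
) -> NullFcPool:
    """Decile-binned empirical null log2FC pool from replicate pairs.

    Genes are binned by baseline expression (mean over all replicate
    columns) into deciles; every bin whose expression range includes zero is
    merged into a single low-expression category.  Each gene's null draws
    then come from the bin holding that gene's baseline expression.
    """
    if len(replicate_pairs) < 1:
        raise ValueError("need at least one replicate pair")
    baseline = normals.counts.mean(axis=1)
    edges = np.quantile(baseline, np.linspace(0.1, 0.9, 9))
    raw_bin = np.searchsorted(edges, baseline, side="right")
    # merge every bin that contains a zero-expression gene into bin 0
    zero_bins = {int(b) for b in np.unique(raw_bin[baseline == 0])}
    merge_map = {b: 0 for b in zero_bins}
    bin_of_gene = np.array([merge_map.get(int(b), int(b)) for b in raw_bin])

    lfcs = []
    for a, b in replicate_pairs:
        ca = normals.column(a) + pseudocount
        cb = normals.column(b) + pseudocount
        lfcs.append(np.log2(ca) - np.log2(cb))
    lfc_matrix = np.column_stack(lfcs)  # genes x pairs

    pools: dict[int, np.ndarray] = {}
    for b in np.unique(bin_of_gene):
        pools[int(b)] = lfc_matrix[bin_of_gene == b, :].ravel()
    pool = NullFcPool(edges=edges, bin_of_gene=bin_of_gene, pools=pools,
                      baseline=baseline)
    pool._merge_map = merge_map
    return pool


def sample_deg_lfc(
    n: int, gamma_shape: float = 0.55, gamma_scale: float = 6.06,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Positive log2 fold changes for seeded DEGs: i.i.d. Gamma draws."""
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma parameters must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = rng.gamma(gamma_shape, gamma_scale, size=n)
    # a gamma draw of exactly 0.0 has measure zero but guard the contract
    return np.maximum(draws, np.finfo(float).tiny)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TruthAssignment:
    """Gene-set memberships and per-subject DEG selections for cohort A."""

    collection: GeneSetCollection
    enriched_ids: list[str]
    control_ids: list[str]
    shared_degs: dict[str, tuple[str, ...]]         # enriched set -> shared DEG genes
    subject_coordinated: np.ndarray                 # per cohort-A subject
    subject_degs: list[frozenset[str]]              # per cohort-A subject


def assign_truth(
    config: SimulationConfig,
    genes: Sequence[str],
    rng: np.random.Generator | None = None,
) -> TruthAssignment:
    """Draw gene-set memberships, the shared DEG selection, and coordination.

    Enriched and control sets receive disjoint random gene memberships.  Per
    enriched set the DEG count is round-half-up(proportion x size); one
    shared selection is drawn once, and each cohort-A subject is flagged
    coordinated with probability ``prop_coordinated`` — coordinated subjects
    reuse the shared selection, the rest draw their own of the same size.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(genes)
    sizes = [s for s, _ in config.enriched_sets] + list(config.control_sets)
    if sum(sizes) > len(genes):
        raise ValueError("gene sets do not fit into the gene universe")
    chosen = rng.choice(len(genes), size=sum(sizes), replace=False)
    sets: list[GeneSet] = []
    enriched_ids: list[str] = []
    control_ids: list[str] = []
    shared: dict[str, tuple[str, ...]] = {}
    offset = 0
    for size, prop in config.enriched_sets:
        members = tuple(genes[i] for i in chosen[offset:offset + size])
        offset += size
        set_id = f"enriched_{size}"
        sets.append(GeneSet(set_id, f"synthetic enriched set ({size} genes)", members))
        enriched_ids.append(set_id)
        n_deg = _round_half_up(prop * size)
        if n_deg < 1:
            raise ValueError(
                f"set {set_id}: proportion {prop} x size {size} rounds to 0 DEGs"
            )
        pick = rng.choice(size, size=n_deg, replace=False)
        shared[set_id] = tuple(members[i] for i in pick)
    for size in config.control_sets:
        members = tuple(genes[i] for i in chosen[offset:offset + size])
        offset += size
        set_id = f"control_{size}"
        sets.append(GeneSet(set_id, f"synthetic control set ({size} genes)", members))
        control_ids.append(set_id)

    coordinated = rng.random(config.cohort_size) < config.prop_coordinated
    subject_degs: list[frozenset[str]] = []
    for is_coord in coordinated:
        selection: set[str] = set()
        for (size, prop), set_id in zip(config.enriched_sets, enriched_ids):
            if is_coord:
                selection.update(shared[set_id])
            else:
                members = sets[enriched_ids.index(set_id)].genes
                n_deg = len(shared[set_id])
                pick = rng.choice(size, size=n_deg, replace=False)
                selection.update(members[i] for i in pick)
        subject_degs.append(frozenset(selection))

    return TruthAssignment(
        collection=GeneSetCollection(sets),
        enriched_ids=enriched_ids,
        control_ids=control_ids,
        shared_degs=shared,
        subject_coordinated=coordinated,
        subject_degs=subject_degs,
    )


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one two-cohort paired tumor-normal dataset with truth labels.

    Cohort A carries the seeded enrichment (per-subject DEGs with gamma
    log2FCs); cohort B is generated entirely from the null pool, so none of
    the four sets is enriched there.  Tumor counts are
    ``round(normal * 2**log2FC)``.
    """
    rng = np.random.default_rng(config.seed)
    means, disp = _gene_means_dispersions(config, rng)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    # replicate pool for the empirical null fold changes
    n_rep = 2 * config.n_replicate_pairs
    rep_counts = _nb_counts(rng, means, disp, n_rep)
    rep_samples = [f"rep{i:02d}" for i in range(n_rep)]
    rep_matrix = CountMatrix(genes, rep_samples, rep_counts)
    rep_pairs = [(rep_samples[2 * i], rep_samples[2 * i + 1])
                 for i in range(config.n_replicate_pairs)]
    pool = build_null_pool(rep_matrix, rep_pairs)

    truth = assign_truth(config, genes, rng)
    gene_index = {g: i for i, g in enumerate(genes)}

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    pairs_a: list[PairedSample] = []
    pairs_b: list[PairedSample] = []
    truth_degs: dict[str, frozenset[str]] = {}

    for label, pair_list in (("A", pairs_a), ("B", pairs_b)):
        for j in range(config.cohort_size):
            subject = f"{label}{j + 1:02d}"
            normal = _nb_counts(rng, means, disp, 1)[:, 0]
            lfc = pool.draw(rng)
            if label == "A":
                deg_genes = truth.subject_degs[j]
                idx = np.array([gene_index[g] for g in sorted(deg_genes)], dtype=int)
                lfc[idx] = sample_deg_lfc(
                    idx.size, config.gamma_shape, config.gamma_scale, rng
                )
                truth_degs[subject] = deg_genes
            else:
                truth_degs[subject] = frozenset()
            tumor = np.rint(normal * np.exp2(lfc))
            columns.extend([normal, tumor])
            sample_ids.extend([f"{subject}_normal", f"{subject}_tumor"])
            pair_list.append(
                PairedSample(subject, f"{subject}_normal", f"{subject}_tumor")
            )

    counts = CountMatrix(genes, sample_ids, np.column_stack(columns))
    truth_sets = {sid: sid in truth.enriched_ids
                  for sid in truth.collection.set_ids()}
    coordinated = {p.subject_id: bool(flag)
                   for p, flag in zip(pairs_a, truth.subject_coordinated)}
    return SimulatedDataset(
        counts=counts,
        cohort_a=Cohort("A", pairs_a),
        cohort_b=Cohort("B", pairs_b),
        collection=truth.collection,
        truth_sets=truth_sets,
        truth_degs=truth_degs,
        coordinated=coordinated,
        config=config,
    )


def grid_manifest(
    base_config: SimulationConfig,
    cohort_sizes: Sequence[int] = (2, 3, 7, 10, 30),
    props: Sequence[float] = (0.25, 0.48, 0.75),
    reps: int = 30,
    reps_by_size: dict[int, int] | None = None,
) -> list[dict]:
    """Deterministic (size, proportion, rep, seed) schedule for the grid.

    Seeds derive from the base config's seed through a spawn-key hash, so
    the same base seed always yields the same manifest and datasets.
    ``reps_by_size`` overrides the replicate count for individual cohort
    sizes (e.g. fewer replicates at the largest size).
    """
    manifest = []
    for ci, (size, prop) in enumerate(
        (s, p) for s in cohort_sizes for p in props
    ):
        n_reps = (reps_by_size or {}).get(size, reps)
        for rep in range(n_reps):
            seed = int(
                np.random.SeedSequence(base_config.seed, spawn_key=(ci, rep))
                .generate_state(1)[0] % _MAX_SEED
            )
            manifest.append(
                {"cohort_size": size, "prop_coordinated": prop, "rep": rep,
                 "seed": seed}
            )
    return manifest


def generate_grid(
    base_config: SimulationConfig,
    cohort_sizes: Sequence[int] = (2, 3, 7, 10, 30),
    props: Sequence[float] = (0.25, 0.48, 0.75),
    reps: int = 30,
    reps_by_size: dict[int, int] | None = None,
) -> tuple[list[dict], Iterator[tuple[dict, SimulatedDataset]]]:
    """Manifest plus a lazy iterator over (manifest entry, dataset) pairs."""
    manifest = grid_manifest(base_config, cohort_sizes, props, reps, reps_by_size)

    def _iterate() -> Iterator[tuple[dict, SimulatedDataset]]:
        for entry in manifest:
            config = replace(
                base_config,
                cohort_size=entry["cohort_size"],
                prop_coordinated=entry["prop_coordinated"],
                seed=entry["seed"],
            )
            yield entry, generate_dataset(config)

    return manifest, _iterate()
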