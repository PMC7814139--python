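"""Synthetic structured case-control cohorts with known ground truth.

The generator emulates the data layout a genotyping-array GWAS consumes:

* population structure via the Balding–Nichols model — subpopulation allele
  frequencies drawn ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral
  frequency ``p ~ Uniform(0.05, 0.5)``;
* linkage disequilibrium via founder-haplotype mosaics — within each block
  every haplotype is a copy of one of ``n_founders`` founder haplotypes,
  switching to a random founder with a fixed per-SNP probability, so
  adjacent-SNP r^2 decays geometrically with distance and vanishes between
  blocks;
* a logistic liability phenotype with additive per-allele log-odds effects
  on chosen causal SNPs, ascertained by rejection sampling to exact
  case/control counts;
* gene models tiling the LD blocks and gene sets partitioning the genes, so
  causal SNPs can be planted inside the genes of chosen sets.

QC pathologies (duplicates, relatives, differential missingness, batch
effects, Hardy–Weinberg violations) are injected separately by
:func:`implant_artifacts` so that every filter in the QC cascade has a
known-truth target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import (
    CASE,
    CONTROL,
    MISSING,
    GeneModel,
    GeneSetCollection,
    GenotypeDataset,
)

ARTIFACT_KINDS = (
    "duplicate_sample",
    "parent_child",
    "batch_missingness",
    "sample_missingness",
    "marker_missingness",
    "hwe_violation",
    "batch_association",
)


class SimulationError(RuntimeError):
    """Requested case/control counts unattainable within the draw cap."""


@dataclass
class SimConfig:
    """Study-design knobs for :func:`simulate_cohort`.

    Defaults describe a desk-scale analogue of an array-based case-control
    cohort: a 2000-SNP panel in 40 independent LD blocks of 50 SNPs, 480
    genes tiling the blocks, partitioned into 45 gene sets (the post-filter
    set count a curated neural gene-set collection yields), one homogeneous
    population, and no causal effects.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_pops: int = 1
    fst: float | Sequence[float] = 0.02
    pop_weights: Sequence[float] | None = None
    pop_counts: Sequence[int] | None = None
    n_blocks: int = 40
    block_size: int = 50
    n_founders: int = 20
    switch_rate: float = 0.02
    genes_per_block: int = 12
    n_sets: int = 45
    n_batches: int = 2
    causal_sets: list[tuple[str, int, float]] = field(default_factory=list)
    baseline_prevalence: float = 0.1
    snp_spacing_bp: int = 10_000
    block_gap_bp: int = 500_000
    seed: int = 0

    def fst_per_pop(self) -> np.ndarray:
        fst = np.broadcast_to(np.atleast_1d(self.fst), (self.n_pops,)).astype(float)
        if np.any((fst <= 0) | (fst >= 1)):
            raise ValueError("fst must lie in (0, 1)")
        return fst

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one case and one control")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0,1)")
        for _, n_causal, odds_ratio in self.causal_sets:
            if odds_ratio <= 0:
                raise ValueError("odds_ratio must be > 0")
            if n_causal < 1:
                raise ValueError("n_causal must be >= 1")
        self.fst_per_pop()
        if self.pop_counts is not None and len(self.pop_counts) != self.n_pops:
            raise ValueError("pop_counts length must equal n_pops")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    causal_effects: dict[str, float] = field(default_factory=dict)  # rsid -> beta
    enriched_set_names: list[str] = field(default_factory=list)
    pop_label: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    planted_artifacts: list[tuple[str, list]] = field(default_factory=list)
    seed: int | None = None

    @property
    def causal_rsids(self) -> list[str]:
        return list(self.causal_effects)


# ---------------------------------------------------------------------------
# genotype machinery
# ---------------------------------------------------------------------------
def _mosaic_haplotypes(
    founders: np.ndarray, n_hap: int, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Compose ``n_hap`` haplotypes as founder mosaics with geometric
    switch distances."""
    n_founders, n_snps = founders.shape
    draws = rng.integers(0, n_founders, size=(n_hap, n_snps))
    keep = rng.random((n_hap, n_snps)) < switch_rate
    keep[:, 0] = True
    cols = np.broadcast_to(np.arange(n_snps), (n_hap, n_snps))
    last = np.maximum.accumulate(np.where(keep, cols, -1), axis=1)
    founder_ids = np.take_along_axis(draws, last, axis=1)
    return founders[founder_ids, cols]


class _CohortSampler:
    """Draws genotype batches for a fixed frequency/founder landscape."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        fst = config.fst_per_pop()
        m = config.n_blocks * config.block_size
        self.ancestral = rng.uniform(0.05, 0.5, size=m)
        # subpop frequencies: Balding-Nichols Beta draw per (pop, snp)
        self.pop_freq = np.empty((config.n_pops, m))
        for k in range(config.n_pops):
            f = fst[k]
            a = self.ancestral * (1 - f) / f
            b = (1 - self.ancestral) * (1 - f) / f
            self.pop_freq[k] = rng.beta(a, b)
        # founder haplotypes per (pop, block)
        bs = config.block_size
        self.founders = [
            [
                (
                    rng.random((config.n_founders, bs))
                    < self.pop_freq[k, b * bs : (b + 1) * bs]
                ).astype(np.int8)
                for b in range(config.n_blocks)
            ]
            for k in range(config.n_pops)
        ]
        self.rng = rng

    def draw(self, pop_of_sample: np.ndarray) -> np.ndarray:
        """Genotypes for samples with the given per-sample population labels."""
        cfg = self.config
        n = pop_of_sample.size
        m = cfg.n_blocks * cfg.block_size
        g = np.empty((n, m), dtype=np.int8)
        for k in range(cfg.n_pops):
            rows = np.flatnonzero(pop_of_sample == k)
            if rows.size == 0:
                continue
            for b in range(cfg.n_blocks):
                sl = slice(b * cfg.block_size, (b + 1) * cfg.block_size)
                h1 = _mosaic_haplotypes(
                    self.founders[k][b], rows.size, cfg.switch_rate, self.rng
                )
                h2 = _mosaic_haplotypes(
                    self.founders[k][b], rows.size, cfg.switch_rate, self.rng
                )
                g[np.ix_(rows, range(sl.start, sl.stop))] = h1 + h2
        return g


def _variant_table(config: SimConfig) -> pd.DataFrame:
    m = config.n_blocks * config.block_size
    bp = np.empty(m, dtype=np.int64)
    block_span = config.block_size * config.snp_spacing_bp
    for b in range(config.n_blocks):
        base = 1 + b * (block_span + config.block_gap_bp)
        idx = np.arange(config.block_size)
        bp[b * config.block_size : (b + 1) * config.block_size] = (
            base + idx * config.snp_spacing_bp
        )
    return pd.DataFrame(
        {
            "chrom": "1",
            "rsid": [f"rs{j + 1:06d}" for j in range(m)],
            "bp": bp,
            "a1": "A",
            "a2": "C",
        }
    )


def _gene_models(config: SimConfig, variants: pd.DataFrame) -> list[GeneModel]:
    genes: list[GeneModel] = []
    gene_id = 0
    per_gene = config.block_size // config.genes_per_block
    if per_gene < 1:
        raise ValueError("genes_per_block exceeds block_size")
    bp = variants["bp"].to_numpy()
    for b in range(config.n_blocks):
        block_lo = b * config.block_size
        for gix in range(config.genes_per_block):
            lo = block_lo + gix * per_gene
            hi = lo + per_gene - 1
            if gix == config.genes_per_block - 1:
                hi = block_lo + config.block_size - 1
            gene_id += 1
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom="1",
                    start=int(bp[lo]),
                    end=int(bp[hi]),
                    symbol=f"G{gene_id}",
                )
            )
    return genes


def _partition_gene_sets(config: SimConfig, genes: list[GeneModel]) -> GeneSetCollection:
    """Interleave genes across sets so each set spans many LD blocks."""
    collection = GeneSetCollection()
    names = [f"set{k + 1:02d}" for k in range(config.n_sets)]
    members: dict[str, list[int]] = {n: [] for n in names}
    for i, gene in enumerate(genes):
        members[names[i % config.n_sets]].append(gene.gene_id)
    for n in names:
        collection.add(n, members[n], "simulated")
    return collection


def _choose_causal(
    config: SimConfig,
    collection: GeneSetCollection,
    genes: list[GeneModel],
    variants: pd.DataFrame,
    freq_for_power: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Pick causal SNPs inside genes of each enriched set, one per gene so
    that planted signals are LD-independent across blocks."""
    gene_by_id = {g.gene_id: g for g in genes}
    bp = variants["bp"].to_numpy()
    rsid = variants["rsid"].to_numpy()
    effects: dict[str, float] = {}
    for set_name, n_causal, odds_ratio in config.causal_sets:
        if set_name not in collection:
            raise ValueError(f"unknown causal set {set_name!r}")
        gene_ids = list(collection[set_name])
        if n_causal > len(gene_ids):
            raise ValueError(
                f"{set_name}: {n_causal} causal SNPs requested but only "
                f"{len(gene_ids)} genes in the set"
            )
        chosen = rng.choice(len(gene_ids), size=n_causal, replace=False)
        for ix in np.sort(chosen):
            gene = gene_by_id[gene_ids[ix]]
            in_gene = np.flatnonzero((bp >= gene.start) & (bp <= gene.end))
            # most-informative SNP in the gene: maximal p(1-p)
            het = freq_for_power[in_gene] * (1 - freq_for_power[in_gene])
            j = in_gene[int(np.argmax(het))]
            effects[rsid[j]] = float(np.log(odds_ratio))
    return effects


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypeDataset, list[GeneModel], GeneSetCollection, SimTruth]:
    """Simulate a structured case-control cohort with known truth.

    Returns the genotype dataset, the gene models tiling the SNP panel, the
    gene-set collection partitioning the genes, and the :class:`SimTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sampler = _CohortSampler(config, rng)
    variants = _variant_table(config)
    genes = _gene_models(config, variants)
    collection = _partition_gene_sets(config, genes)
    mean_freq = sampler.pop_freq.mean(axis=0)
    effects = _choose_causal(config, collection, genes, variants, mean_freq, rng)

    n_total = config.n_cases + config.n_controls
    if config.pop_weights is not None:
        weights = np.asarray(config.pop_weights, float)
        weights = weights / weights.sum()
    else:
        weights = np.full(config.n_pops, 1.0 / config.n_pops)

    causal_idx = (
        variants.set_index("rsid").index.get_indexer(list(effects))
        if effects
        else np.array([], dtype=int)
    )
    betas = np.array(list(effects.values()))
    alpha = float(np.log(config.baseline_prevalence / (1 - config.baseline_prevalence)))

    if not effects:
        # Phenotype independent of genotype: draw exactly n_total samples and
        # assign labels by permutation (exact, no rejection needed).
        if config.pop_counts is not None:
            counts = np.asarray(config.pop_counts, int)
            if counts.sum() != n_total:
                raise ValueError("pop_counts must sum to n_cases + n_controls")
            pops = np.repeat(np.arange(config.n_pops), counts)
        else:
            pops = rng.choice(config.n_pops, size=n_total, p=weights)
        g = sampler.draw(pops)
        pheno = np.zeros(n_total, dtype=np.int8)
        pheno[rng.permutation(n_total)[: config.n_cases]] = CASE
    else:
        if config.pop_counts is not None:
            raise ValueError("pop_counts only supported without causal effects")
        g_rows, pheno_rows, pop_rows = [], [], []
        n_case_kept = n_ctrl_kept = 0
        draws = 0
        cap = 500 * n_total
        batch = max(1024, n_total)
        while n_case_kept < config.n_cases or n_ctrl_kept < config.n_controls:
            if draws >= cap:
                raise SimulationError(
                    f"could not reach {config.n_cases}/{config.n_controls} "
                    f"cases/controls within {cap} draws"
                )
            pops = rng.choice(config.n_pops, size=batch, p=weights)
            gb = sampler.draw(pops)
            score = alpha + gb[:, causal_idx].astype(float) @ betas
            p_case = 1.0 / (1.0 + np.exp(-score))
            is_case = rng.random(batch) < p_case
            draws += batch
            for want_case, kept, quota in (
                (True, n_case_kept, config.n_cases),
                (False, n_ctrl_kept, config.n_controls),
            ):
                rows = np.flatnonzero(is_case == want_case)[: quota - kept]
                if rows.size:
                    g_rows.append(gb[rows])
                    pop_rows.append(pops[rows])
                    pheno_rows.append(
                        np.full(rows.size, CASE if want_case else CONTROL, np.int8)
                    )
                    if want_case:
                        n_case_kept += rows.size
                    else:
                        n_ctrl_kept += rows.size
        g = np.concatenate(g_rows)
        pheno = np.concatenate(pheno_rows)
        pops = np.concatenate(pop_rows)
        order = rng.permutation(n_total)
        g, pheno, pops = g[order], pheno[order], pops[order]

    batches = np.array(
        [f"B{k + 1}" for k in rng.integers(0, config.n_batches, size=n_total)]
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n_total)],
            "phenotype": pheno,
            "batch": batches,
            "sex": "unknown",
        }
    )
    dataset = GenotypeDataset(g, variants, samples)
    truth = SimTruth(
        causal_effects=effects,
        enriched_set_names=[name for name, _, _ in config.causal_sets],
        pop_label=pops,
        seed=config.seed,
    )
    return dataset, genes, collection, truth


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------
def make_null_set_landscape(
    genes: Sequence[GeneModel] | Sequence[int],
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
) -> GeneSetCollection:
    """Random gene sets over a gene universe, for type-I-error studies."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    universe = np.array(
        [g.gene_id if isinstance(g, GeneModel) else int(g) for g in genes]
    )
    lo, hi = size_range
    if hi > universe.size:
        raise ValueError(
            f"size_range upper bound {hi} exceeds gene universe ({universe.size})"
        )
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection.add(f"null{k + 1:02d}", members.tolist(), "null-landscape")
    return collection


def _pick_rsids(dataset, spec, rng, default_n=1):
    if "rsids" in spec:
        return list(spec["rsids"])
    n = int(spec.get("n_snps", default_n))
    idx = rng.choice(dataset.n_variants, size=n, replace=False)
    return dataset.variants["rsid"].to_numpy()[np.sort(idx)].tolist()


def implant_artifacts(
    dataset: GenotypeDataset, artifact_spec: Sequence[dict], seed: int = 0
) -> tuple[GenotypeDataset, SimTruth]:
    """Inject QC pathologies into a clean cohort.

    ``artifact_spec`` is a list of dicts, each with a ``kind`` key from
    :data:`ARTIFACT_KINDS` plus kind-specific parameters. Returns the
    modified dataset and a :class:`SimTruth` whose ``planted_artifacts``
    records ``(kind, affected ids)``.
    """
    rng = np.random.default_rng(seed)
    ds = dataset.copy()
    g = ds.genotypes
    samples = ds.samples
    freqs = ds.allele_frequencies()
    artifacts: list[tuple[str, list]] = []
    new_rows: list[np.ndarray] = []
    new_samples: list[dict] = []

    for spec in artifact_spec:
        kind = spec["kind"]
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        if kind == "duplicate_sample":
            sid = spec.get("source") or str(
                samples["sample_id"].iloc[int(rng.integers(len(samples)))]
            )
            src = int(np.flatnonzero(samples["sample_id"] == sid)[0])
            row = g[src].copy()
            eps = float(spec.get("flip_prob", 0.001))
            if eps > 0:
                flip = (rng.random(row.size) < eps) & (row != MISSING)
                row[flip] = np.where(row[flip] == 2, 0, row[flip] + 1)
            dup_id = f"dup_{sid}"
            new_rows.append(row)
            new_samples.append(
                dict(
                    sample_id=dup_id,
                    phenotype=int(samples["phenotype"].iloc[src]),
                    batch=samples["batch"].iloc[src],
                    sex=samples["sex"].iloc[src],
                )
            )
            artifacts.append((kind, [sid, dup_id]))
        elif kind == "parent_child":
            sid = spec.get("source") or str(
                samples["sample_id"].iloc[int(rng.integers(len(samples)))]
            )
            src = int(np.flatnonzero(samples["sample_id"] == sid)[0])
            parent = g[src]
            transmitted = (rng.random(parent.size) < parent / 2.0).astype(np.int8)
            other = (rng.random(parent.size) < np.nan_to_num(freqs)).astype(np.int8)
            child = np.where(parent == MISSING, MISSING, transmitted + other).astype(
                np.int8
            )
            child_id = f"child_{sid}"
            new_rows.append(child)
            new_samples.append(
                dict(
                    sample_id=child_id,
                    phenotype=int(samples["phenotype"].iloc[src]),
                    batch=samples["batch"].iloc[src],
                    sex="unknown",
                )
            )
            artifacts.append((kind, [sid, child_id]))
        elif kind == "batch_missingness":
            rsids = _pick_rsids(ds, spec, rng, default_n=10)
            cols = ds.variant_index(rsids)
            rows = np.ones(len(samples), dtype=bool)
            if "batch" in spec:
                rows &= (samples["batch"] == spec["batch"]).to_numpy()
            if "phenotype" in spec:
                code = CASE if spec["phenotype"] == "case" else CONTROL
                rows &= (samples["phenotype"] == code).to_numpy()
            inc = float(spec.get("increment", 0.05))
            rows = np.flatnonzero(rows)
            mask = rng.random((rows.size, cols.size)) < inc
            sub = g[np.ix_(rows, cols)]
            sub[mask] = MISSING
            g[np.ix_(rows, cols)] = sub
            artifacts.append((kind, rsids))
        elif kind == "sample_missingness":
            sid = spec.get("sample_id") or str(
                samples["sample_id"].iloc[int(rng.integers(len(samples)))]
            )
            src = int(np.flatnonzero(samples["sample_id"] == sid)[0])
            rate = float(spec.get("rate", 0.05))
            mask = rng.random(g.shape[1]) < rate
            g[src, mask] = MISSING
            artifacts.append((kind, [sid]))
        elif kind == "marker_missingness":
            rsids = _pick_rsids(ds, spec, rng, default_n=10)
            cols = ds.variant_index(rsids)
            rate = float(spec.get("rate", 0.05))
            mask = rng.random((g.shape[0], cols.size)) < rate
            sub = g[:, cols]
            sub[mask] = MISSING
            g[:, cols] = sub
            artifacts.append((kind, rsids))
        elif kind == "hwe_violation":
            rsids = _pick_rsids(ds, spec, rng, default_n=1)
            cols = ds.variant_index(rsids)
            het_prob = float(spec.get("het_prob", 0.95))
            for c in cols:
                p = freqs[c] if np.isfinite(freqs[c]) else 0.5
                draw = rng.random(g.shape[0])
                col = np.where(
                    draw < het_prob,
                    1,
                    np.where(rng.random(g.shape[0]) < p, 2, 0),
                ).astype(np.int8)
                g[:, c] = col
            artifacts.append((kind, rsids))
        elif kind == "batch_association":
            rsids = _pick_rsids(ds, spec, rng, default_n=10)
            cols = ds.variant_index(rsids)
            rows = np.ones(len(samples), dtype=bool)
            if "batch" in spec:
                rows &= (samples["batch"] == spec["batch"]).to_numpy()
            rows = np.flatnonzero(rows)
            delta = float(spec.get("delta", 0.3))
            for c in cols:
                p = freqs[c] if np.isfinite(freqs[c]) else 0.25
                p_new = float(np.clip(p + delta, 0.01, 0.99))
                col = (
                    (rng.random(rows.size) < p_new).astype(np.int8)
                    + (rng.random(rows.size) < p_new).astype(np.int8)
                )
                g[rows, c] = col
            artifacts.append((kind, rsids))

    if new_rows:
        g = np.vstack([g, np.array(new_rows, dtype=np.int8)])
        samples = pd.concat(
            [samples, pd.DataFrame(new_samples)], ignore_index=True
        )
        samples["phenotype"] = samples["phenotype"].astype(np.int8)
    out = GenotypeDataset(g, ds.variants, samples)
    truth = SimTruth(planted_artifacts=artifacts, seed=seed)
    return out, truth
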