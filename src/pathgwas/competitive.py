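"""Competitive gene-set analysis from LD-correlated SNP statistics.

A reconstruction of the regression-based competitive test: per-gene
association statistics are the mean of the member SNPs' 1-df chi-squares,
with a null approximated by a scaled chi-square whose variance accounts
for LD between the SNPs (Brown-style moment matching,
``Var[T] = (2k + 4 sum_{i<j} r^2_ij) / k^2``). Gene p-values are
probit-transformed to z-scores and regressed on set membership with
gene-level covariates (log SNP count, log gene length, mean pairwise
r^2); the one-sided test of a positive membership coefficient is the
competitive enrichment p. Family-wise correction permutes gene labels —
the competitive null is exchangeability of genes — with an adaptive stop
once every set has accumulated enough exceedances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, t as t_dist

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .assoc import impute_mean, score_test_chi2
from .datasets import CASE, GeneModel, GeneSetCollection, GenotypeDataset
from .sba import assign_snps_to_genes, _pearson_r2


@dataclass
class GeneStat:
    gene_id: int
    n_snps_param: int
    stat: float  # mean 1-df chi-square over the gene's SNPs
    z: float  # probit(1 - p)
    p: float


@dataclass
class CompetitiveResult:
    set_name: str
    n_genes_analyzed: int
    beta: float
    p: float
    p_corr: float | None = None
    n_perm_used: int | None = None
    flag: str | None = None


def _offdiag_r2(G: np.ndarray) -> tuple[np.ndarray, int]:
    """Pairwise r^2 with constant columns contributing zero correlation."""
    sd = G.std(axis=0)
    n_const = int((sd == 0).sum())
    r2 = _pearson_r2(G)
    if n_const:
        const = sd == 0
        r2[const, :] = 0.0
        r2[:, const] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2, n_const


def gene_statistic(
    snp_pvalues: np.ndarray | None,
    genotype_submatrix: np.ndarray,
    gene_id: int = 0,
    snp_chi2: np.ndarray | None = None,
) -> GeneStat:
    """Gene-level p from the mean of member-SNP 1-df chi-squares.

    Either the per-SNP p-values or the chi-square statistics themselves may
    be supplied. The null of the mean is moment-matched to a scaled
    chi-square: mean 1 and variance ``(2k + 4 sum_{i<j} r^2_ij) / k^2``
    with r the Pearson genotype correlation.
    """
    if snp_chi2 is None:
        if snp_pvalues is None:
            raise ValueError("need snp_pvalues or snp_chi2")
        snp_chi2 = chi2_dist.isf(np.asarray(snp_pvalues, float), 1)
    q = np.asarray(snp_chi2, dtype=float)
    k = q.size
    if k < 1:
        raise ValueError("gene has no SNPs")
    T = float(q.mean())
    if k == 1:
        var = 2.0
    else:
        r2, _ = _offdiag_r2(np.asarray(genotype_submatrix, float))
        sum_off = (r2.sum() - k) / 2.0
        var = (2.0 * k + 4.0 * sum_off) / k**2
    # scaled chi-square with E = 1, Var = var:  T ~ c * chi2_f
    c = var / 2.0
    f = 2.0 / var
    p = float(chi2_dist.sf(T / c, f))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GeneStat(gene_id=gene_id, n_snps_param=k, stat=T, z=float(norm.isf(p)), p=p)


def gene_covariates(gene: GeneModel, genotype_submatrix: np.ndarray) -> np.ndarray:
    """(log n_snps, log gene length in kb, mean pairwise r^2)."""
    k = genotype_submatrix.shape[1]
    if k < 1:
        raise ValueError("gene has no assigned SNPs")
    length_kb = (gene.end - gene.start + 1) / 1000.0
    if k == 1:
        mean_r2 = 0.0
    else:
        r2, _ = _offdiag_r2(np.asarray(genotype_submatrix, float))
        mean_r2 = float((r2.sum() - k) / (k * (k - 1)))
    return np.array([np.log(k), np.log(length_kb), mean_r2])


def _ols_onesided(
    z: np.ndarray, membership: np.ndarray, covariates: np.ndarray | None
):
    """One-sided (beta > 0) t-test of membership in z ~ 1 + s + C."""
    n = z.size
    cols = [np.ones(n), membership.astype(float)]
    if covariates is not None and covariates.size:
        cols.extend(np.atleast_2d(np.asarray(covariates, float).T))
    X = np.column_stack(cols)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z)
    resid = z - X @ beta
    df = n - X.shape[1]
    if df < 1:
        raise ValueError("not enough genes for the regression")
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    tstat = beta[1] / se if se > 0 else 0.0
    return float(beta[1]), float(t_dist.sf(tstat, df))


def competitive_set_test(
    gene_stats: np.ndarray | pd.DataFrame,
    membership: np.ndarray,
    covariates: np.ndarray | None = None,
    set_name: str = "",
) -> CompetitiveResult:
    """Competitive enrichment of one set over all analyzed genes.

    ``gene_stats`` is the vector of gene z-scores (or a frame with a ``z``
    column); ``membership`` the 0/1 indicator of set membership.
    """
    z = (
        gene_stats["z"].to_numpy()
        if isinstance(gene_stats, pd.DataFrame)
        else np.asarray(gene_stats, float)
    )
    s = np.asarray(membership).astype(float)
    n_in, n_out = int(s.sum()), int((1 - s).sum())
    if n_in == 0 or n_out == 0:
        return CompetitiveResult(set_name, z.size, np.nan, 1.0, flag="constant_membership")
    if n_in < 2 or n_out < 2:
        return CompetitiveResult(set_name, z.size, np.nan, 1.0, flag="too_few_genes")
    beta, p = _ols_onesided(z, s, covariates)
    return CompetitiveResult(set_name, z.size, beta, max(p, np.nextafter(0, 1)))


def adaptive_permutation_correction(
    gene_z: np.ndarray,
    memberships: dict[str, np.ndarray],
    covariates: np.ndarray | None,
    max_perm: int = 10_000,
    stop_exceedances: int = 10,
    seed: int = 0,
    batch: int = 500,
) -> tuple[dict[str, float], float, int]:
    """Family-wise permutation correction by gene-label permutation.

    Permutes the gene z-scores against gene labels, recomputes every set's
    one-sided nominal p per permutation, and corrects each set against the
    permutation distribution of the minimum nominal p across sets
    (``p_corr = (b+1)/(R+1)``). Stops early once every set has at least
    ``stop_exceedances`` exceedances. Returns ``(p_corr by set, the
    family-wise 0.05 nominal-p threshold, permutations used)``.
    """
    if max_perm < 100:
        raise ValueError("max_perm must be >= 100")
    names = list(memberships)
    if max_perm < len(names):
        import warnings

        warnings.warn("max_perm is smaller than the number of sets")
    z = np.asarray(gene_z, float)
    obs_p = np.array(
        [
            competitive_set_test(z, memberships[nm], covariates, nm).p
            for nm in names
        ]
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=int)
    min_ps: list[np.ndarray] = []
    used = 0
    while used < max_perm:
        b = min(batch, max_perm - used)
        Z = np.empty((z.size, b))
        for r in range(b):
            Z[:, r] = z[rng.permutation(z.size)]
        pmat = np.empty((len(names), b))
        for si, nm in enumerate(names):
            pmat[si] = _ols_onesided_batch(Z, memberships[nm], covariates)
        mp = pmat.min(axis=0)
        min_ps.append(mp)
        exceed += (mp[None, :] <= obs_p[:, None]).sum(axis=1)
        used += b
        if np.all(exceed >= stop_exceedances):
            break
    all_min = np.concatenate(min_ps)
    p_corr = {nm: (1 + int(exceed[i])) / (used + 1) for i, nm in enumerate(names)}
    fw_threshold = float(np.quantile(all_min, 0.05))
    return p_corr, fw_threshold, used


def _ols_onesided_batch(
    Z: np.ndarray, membership: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """One-sided membership p for every column of ``Z`` at once."""
    n, R = Z.shape
    cols = [np.ones(n), np.asarray(membership, float)]
    if covariates is not None and np.size(covariates):
        cols.extend(np.atleast_2d(np.asarray(covariates, float).T))
    X = np.column_stack(cols)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Z)  # k x R
    rss = np.einsum("ij,ij->j", Z, Z) - np.einsum("kj,kj->j", B, X.T @ Z)
    df = n - X.shape[1]
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(se > 0, B[1] / se, 0.0)
    return t_dist.sf(tstat, df)


class CompetitiveGeneSetAnalysis(BaseEstimator):
    """End-to-end competitive analysis over a genotype dataset.

    ``fit`` computes per-SNP score chi-squares (covariate-adjusted), gene
    statistics for every gene with at least one assigned SNP, gene-level
    covariates, one competitive regression per set, and the adaptive
    gene-label permutation correction. Results land in ``gene_stats_``
    (one row per analyzed gene) and ``set_results_`` (one row per set).
    """

    def __init__(
        self,
        window_kb: float = 10.0,
        max_perm: int = 10_000,
        stop_exceedances: int = 10,
        seed: int = 0,
    ):
        self.window_kb = window_kb
        self.max_perm = max_perm
        self.stop_exceedances = stop_exceedances
        self.seed = seed

    def fit(
        self,
        X: GenotypeDataset,
        y=None,
        *,
        collection: GeneSetCollection,
        genes: list[GeneModel],
        covariates: np.ndarray | None = None,
    ):
        gene_map = assign_snps_to_genes(X.variants, genes, self.window_kb)
        y_vec = (X.phenotype == CASE).astype(float)
        G = impute_mean(X)
        chi2_all = score_test_chi2(G, y_vec, covariates)
        pos = {rs: j for j, rs in enumerate(X.variants["rsid"])}

        gene_rows = []
        covar_rows = []
        analyzed: list[int] = []
        for gene in genes:
            idx = np.array([pos[rs] for rs in gene_map.get(gene.gene_id, ())], int)
            if idx.size == 0:
                continue
            sub = G[:, idx]
            gs = gene_statistic(None, sub, gene_id=gene.gene_id, snp_chi2=chi2_all[idx])
            covar_rows.append(gene_covariates(gene, sub))
            analyzed.append(gene.gene_id)
            gene_rows.append(
                dict(
                    gene_id=gene.gene_id, chrom=gene.chrom, start=gene.start,
                    end=gene.end, symbol=gene.symbol, n_snps=gs.n_snps_param,
                    stat=gs.stat, z=gs.z, p=gs.p,
                )
            )
        self.gene_stats_ = pd.DataFrame(gene_rows)
        self.gene_covariates_ = np.array(covar_rows)
        z = self.gene_stats_["z"].to_numpy()
        analyzed_set = {g: i for i, g in enumerate(analyzed)}

        memberships = {}
        nominal: dict[str, CompetitiveResult] = {}
        for name in collection.names():
            s = np.zeros(len(analyzed))
            for gid in collection[name]:
                if gid in analyzed_set:
                    s[analyzed_set[gid]] = 1.0
            memberships[name] = s
            nominal[name] = competitive_set_test(
                z, s, self.gene_covariates_, set_name=name
            )

        testable = {
            nm: m for nm, m in memberships.items() if nominal[nm].flag is None
        }
        if testable:
            p_corr, fw_thr, used = adaptive_permutation_correction(
                z, testable, self.gene_covariates_,
                max_perm=self.max_perm,
                stop_exceedances=self.stop_exceedances,
                seed=self.seed,
            )
        else:
            p_corr, fw_thr, used = {}, np.nan, 0
        self.fw_threshold_ = fw_thr
        self.n_perm_used_ = used
        rows = []
        for name, res in nominal.items():
            rows.append(
                dict(
                    SET=name,
                    GENES=int(memberships[name].sum()),
                    BETA=res.beta,
                    P=res.p,
                    P_CORR=p_corr.get(name, np.nan),
                    FLAG=res.flag,
                )
            )
        self.set_results_ = (
            pd.DataFrame(rows).sort_values("P", kind="stable").reset_index(drop=True)
        )
        return self
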