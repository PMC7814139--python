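"""Self-contained set-based association (SBA) by phenotype permutation.

The test assigns SNPs to genes by position (± a genomic window), pools each
gene set's SNPs, and scores a set by the mean association p-value of its
top LD-independent SNPs: SNPs below a nominal threshold are greedily
selected in order of increasing p, skipping any SNP whose r^2 with an
already-selected SNP reaches the independence threshold, up to a cap.
Case/control labels are then permuted — covariates stay attached to their
samples and the association is refit per permutation — and the empirical
p-value EMP1 is the (b+1)/(R+1)-corrected fraction of permutations whose
set statistic is at least as extreme (as small) as the observed one. A
max(T)-style family-wise empirical p compares each observed statistic to
the best statistic across all sets per permutation.

Association p-values inside the permutation loop (and for the observed
statistic, so the two are exchangeable) are 1-df efficient-score tests of
the additive genotype effect against the covariate-only logistic null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import chdtrc, chdtri

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .assoc import fit_logistic_snp, impute_mean, score_test_chi2
from .datasets import CASE, GeneModel, GeneSetCollection, GenotypeDataset

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class SbaParams:
    window_kb: float = 10.0
    set_p: float = 0.05
    set_r2: float = 0.5
    set_max: int = 5
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    statistic: str = "mean_p"  # or "mean_chisq"

    def validate(self) -> None:
        if self.window_kb < 0:
            raise ValueError("window_kb must be >= 0")
        if not 0 < self.set_p <= 1 or not 0 < self.set_r2 <= 1:
            raise ValueError("set_p and set_r2 must lie in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.statistic not in ("mean_p", "mean_chisq"):
            raise ValueError("statistic must be 'mean_p' or 'mean_chisq'")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------
def assign_snps_to_genes(
    variants: pd.DataFrame, genes: Sequence[GeneModel], window_kb: float = 10.0
) -> dict[int, list[str]]:
    """Map gene_id -> rsids with ``start - W <= bp <= end + W`` (inclusive)."""
    W = int(round(window_kb * 1000))
    out: dict[int, list[str]] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in variants.groupby("chrom", sort=False):
        order = np.argsort(sub["bp"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (
            sub["bp"].to_numpy()[order],
            sub["rsid"].to_numpy()[order],
        )
    for gene in genes:
        bp, rsid = by_chrom.get(str(gene.chrom), (np.array([]), np.array([])))
        lo = np.searchsorted(bp, gene.start - W, side="left")
        hi = np.searchsorted(bp, gene.end + W, side="right")
        out[gene.gene_id] = rsid[lo:hi].tolist()
    return out


def set_snp_index(
    gene_map: dict[int, list[str]], collection: GeneSetCollection
) -> dict[str, list[str]]:
    """Union of member genes' SNPs per set, deduplicated, order-stable.

    Sets whose genes carry no SNPs are retained with an empty list."""
    out: dict[str, list[str]] = {}
    for name in collection.names():
        seen: dict[str, None] = {}
        for gid in collection[name]:
            for rsid in gene_map.get(gid, ()):
                seen.setdefault(rsid, None)
        out[name] = list(seen)
    return out


# ---------------------------------------------------------------------------
# greedy LD-independent top-SNP selection
# ---------------------------------------------------------------------------
def _pearson_r2(G: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation between genotype columns."""
    z = G - G.mean(axis=0)
    sd = z.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = z / sd
    r = (z.T @ z) / G.shape[0]
    return np.clip(r**2, 0.0, 1.0)


def _greedy_select(
    order: np.ndarray, p: np.ndarray, r2: np.ndarray, set_p: float,
    set_r2: float, set_max: int,
) -> list[int]:
    """Greedy selection over pre-ordered candidate indices."""
    chosen: list[int] = []
    for i in order:
        if p[i] >= set_p:
            break  # order is ascending in p
        if all(r2[i, j] < set_r2 for j in chosen):
            chosen.append(int(i))
            if len(chosen) >= set_max:
                break
    return chosen


def select_independent_top(
    snps: Sequence[str],
    pvalues: np.ndarray,
    genotypes: np.ndarray,
    params: SbaParams,
    bp: np.ndarray | None = None,
) -> list[str]:
    """Ordered LD-independent top SNPs for one set.

    Sorts by ascending p (ties by ascending bp, then rsid), accepts a SNP
    iff ``p < set_p`` and its r^2 with every accepted SNP is below
    ``set_r2``, stopping at ``set_max``.
    """
    snps = list(snps)
    p = np.asarray(pvalues, dtype=float)
    if bp is None:
        bp = np.zeros(len(snps))
    r2 = _pearson_r2(np.asarray(genotypes, dtype=float))
    order = np.lexsort((np.asarray(snps), np.asarray(bp), p))
    chosen = _greedy_select(order, p, r2, params.set_p, params.set_r2, params.set_max)
    return [snps[i] for i in chosen]


def set_statistic(selected_pvalues: Sequence[float]) -> float | None:
    """Mean of the selected p-values; ``None`` when nothing was selected
    (treated as a statistic of 1 in permutation comparisons)."""
    vals = list(selected_pvalues)
    if not vals:
        return None
    return float(np.mean(vals))


def bonferroni_threshold(n_sets: int, alpha: float = 0.05) -> float:
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return alpha / n_sets


# ---------------------------------------------------------------------------
# permutation kernels
# ---------------------------------------------------------------------------
def _greedy_stat_one(p_row, r2, set_p, set_r2, set_max, mean_of=None):
    """Stat for one permutation of one set; pure-python reference kernel.

    Candidate columns are assumed pre-sorted by (bp, rsid) so a stable sort
    on p realizes the tie-break."""
    cand = np.flatnonzero(p_row < set_p)
    if cand.size == 0:
        return 1.0
    cand = cand[np.argsort(p_row[cand], kind="stable")]
    chosen = []
    for i in cand:
        ok = True
        for j in chosen:
            if r2[i, j] >= set_r2:
                ok = False
                break
        if ok:
            chosen.append(i)
            if len(chosen) >= set_max:
                break
    vals = mean_of if mean_of is not None else p_row
    total = 0.0
    for i in chosen:
        total += vals[i]
    return total / len(chosen)


def _set_stats_python(P, r2, set_p, set_r2, set_max, V=None):
    R = P.shape[0]
    out = np.empty(R)
    for r in range(R):
        out[r] = _greedy_stat_one(
            P[r], r2, set_p, set_r2, set_max, None if V is None else V[r]
        )
    return out


if _HAVE_NUMBA:

    @njit(cache=True)
    def _set_stats_numba(P, r2, set_p, set_r2, set_max, V, use_v):  # pragma: no cover
        R, k = P.shape
        out = np.empty(R)
        cand = np.empty(k, dtype=np.int64)
        chosen = np.empty(set_max, dtype=np.int64)
        for r in range(R):
            nc = 0
            for i in range(k):
                if P[r, i] < set_p:
                    cand[nc] = i
                    nc += 1
            if nc == 0:
                out[r] = 1.0
                continue
            # stable insertion sort of cand[:nc] by P[r, .]
            for a in range(1, nc):
                key = cand[a]
                kv = P[r, key]
                b = a - 1
                while b >= 0 and P[r, cand[b]] > kv:
                    cand[b + 1] = cand[b]
                    b -= 1
                cand[b + 1] = key
            nch = 0
            for a in range(nc):
                i = cand[a]
                ok = True
                for b in range(nch):
                    if r2[i, chosen[b]] >= set_r2:
                        ok = False
                        break
                if ok:
                    chosen[nch] = i
                    nch += 1
                    if nch >= set_max:
                        break
            total = 0.0
            for b in range(nch):
                total += V[r, chosen[b]] if use_v else P[r, chosen[b]]
            out[r] = total / nch
        return out


def _set_stats(P, r2, set_p, set_r2, set_max, V=None):
    """Per-permutation set statistics (mean selected p, or mean of ``V``)."""
    P = np.ascontiguousarray(P, dtype=np.float64)
    r2 = np.ascontiguousarray(r2, dtype=np.float64)
    if _HAVE_NUMBA:
        Vv = P if V is None else np.ascontiguousarray(V, dtype=np.float64)
        return _set_stats_numba(
            P, r2, float(set_p), float(set_r2), int(set_max), Vv, V is not None
        )
    return _set_stats_python(P, r2, set_p, set_r2, set_max, V)


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------
@dataclass
class SetAssocResult:
    set_name: str
    n_snps: int
    nsig: int
    isig: int
    stat: float | None
    emp1: float
    emp2: float | None = None
    top_snps: pd.DataFrame | None = None


def _permutation_matrix(y, n_perm, rng):
    n = y.size
    Y = np.tile(np.asarray(y, dtype=np.float64), (n_perm, 1))
    return rng.permuted(Y, axis=1).T


def _exhaustive_matrix(y):
    n = y.size
    n_case = int(y.sum())
    n_assign = math.comb(n, n_case)
    if n_assign > 500_000:
        raise ValueError(f"{n_assign} assignments is too many to enumerate")
    Y = np.zeros((n, n_assign), dtype=np.float64)
    for r, rows in enumerate(combinations(range(n), n_case)):
        Y[list(rows), r] = 1.0
    return Y


def _sparse_pvalues(S: np.ndarray, p_floor: float | None) -> np.ndarray:
    """Chi-square(1) upper-tail p per entry of ``S``.

    When ``p_floor`` is given, entries whose p-value provably exceeds it are
    set to exactly 1.0 instead of being evaluated; callers that only read
    p-values below ``p_floor`` (the greedy selection) get identical results
    at a fraction of the cost.
    """
    if p_floor is None or p_floor >= 1.0:
        return chdtrc(1, S)
    # slight inflation of the cutover p guards against round-trip error in
    # chdtri/chdtrc near the boundary
    thresh = chdtri(1, min(1.0, p_floor * (1.0 + 1e-7)))
    P = np.ones(S.shape)
    mask = S > thresh
    if mask.any():
        P[mask] = chdtrc(1, S[mask])
    return P


def _score_p_matrix(G, Y, covariates, p_floor=None):
    """p-values and chi-squares (each R x m) for every phenotype column of
    ``Y``; p-values that provably exceed ``p_floor`` may be reported as 1.0."""
    n, m = G.shape
    R = Y.shape[1]
    if covariates is None:
        # case/control counts are identical across label permutations, so the
        # intercept-only null is shared and everything collapses to one GEMM
        mu = Y[:, 0].mean()
        w = mu * (1 - mu)
        Gc = G - G.mean(axis=0)
        V = w * np.einsum("ij,ij->j", Gc, Gc)
        # float32 only pays off on large ensembles; small ones keep float64 so
        # the exhaustive path agrees with the observed pass to full precision
        dt = np.float32 if R * m > 200_000 else np.float64
        U = Gc.T.astype(dt) @ (Y - mu).astype(dt)
        Vsafe = np.where(V > 0, V, np.inf).astype(dt)
        stat = ((U * U) / Vsafe[:, None]).T.astype(np.float64)
        return _sparse_pvalues(stat, p_floor), stat
    S = np.empty((R, m))
    for r in range(R):
        S[r] = score_test_chi2(G, Y[:, r], covariates)
    return _sparse_pvalues(S, p_floor), S


class SetBasedAssociation(BaseEstimator):
    """Self-contained permutation set test, estimator-style.

    Parameters mirror :class:`SbaParams`; ``fit`` takes the QC'd dataset,
    the gene-set collection and the gene models (or a precomputed
    SNP-to-gene map), plus optional per-sample covariates (typically
    leading principal components). After fitting, ``results_`` holds one
    row per set sorted by EMP1, and ``set_results_`` the full
    :class:`SetAssocResult` objects keyed by set name.
    """

    def __init__(self, params: SbaParams | None = None, maxt: bool = False,
                 perm: str = "label", top_tables: bool = True):
        self.params = params
        self.maxt = maxt
        self.perm = perm  # "label" or "exhaustive"
        self.top_tables = top_tables  # refit per-SNP logistic tables per set

    # -- core ----------------------------------------------------------------
    def fit(
        self,
        X: GenotypeDataset,
        y=None,
        *,
        collection: GeneSetCollection,
        genes: Sequence[GeneModel] | None = None,
        gene_map: dict[int, list[str]] | None = None,
        covariates: np.ndarray | None = None,
    ):
        params = self.params or SbaParams()
        params.validate()
        if gene_map is None:
            if genes is None:
                raise ValueError("provide either genes or gene_map")
            gene_map = assign_snps_to_genes(X.variants, genes, params.window_kb)
        set_map = set_snp_index(gene_map, collection)

        n_sets = max(len(collection), 1)
        if 1.0 / (params.n_perm + 1) > bonferroni_threshold(n_sets, params.alpha):
            min_perm = int(np.ceil(n_sets / params.alpha))
            warnings.warn(
                f"n_perm={params.n_perm} cannot reach the Bonferroni level "
                f"{params.alpha}/{n_sets}; at least ~{min_perm} permutations "
                f"are required (e.g. 45 sets need >= 1000)"
            )

        y_vec = (X.phenotype == CASE).astype(np.float64)
        rsid_all = X.variants["rsid"].to_numpy()
        bp_all = X.variants["bp"].to_numpy()

        # union sub-panel of SNPs appearing in any set, pre-sorted (bp, rsid)
        union: dict[str, None] = {}
        for name in set_map:
            for rs in set_map[name]:
                union.setdefault(rs, None)
        union_rsids = np.array(list(union))
        if union_rsids.size:
            cols = X.variant_index(union_rsids)
            order = np.lexsort((rsid_all[cols], bp_all[cols]))
            cols = cols[order]
            union_rsids = rsid_all[cols]
        else:
            cols = np.array([], dtype=int)
        sub_pos = {rs: i for i, rs in enumerate(union_rsids)}
        G = impute_mean(X)[:, cols] if cols.size else np.empty((X.n_samples, 0))

        # observed per-SNP score p-values
        obs_stat = score_test_chi2(G, y_vec, covariates) if cols.size else np.array([])
        obs_p = chdtrc(1, obs_stat) if cols.size else np.array([])

        # per-set structures
        set_cols = {
            name: np.array(sorted(sub_pos[rs] for rs in set_map[name]), dtype=int)
            for name in set_map
        }
        set_r2 = {
            name: _pearson_r2(G[:, idx]) if idx.size else np.empty((0, 0))
            for name, idx in set_cols.items()
        }
        use_chisq = params.statistic == "mean_chisq"

        obs_stats: dict[str, float | None] = {}
        obs_nsig: dict[str, int] = {}
        obs_sel: dict[str, list[int]] = {}
        for name, idx in set_cols.items():
            if idx.size == 0:
                obs_stats[name], obs_nsig[name], obs_sel[name] = None, 0, []
                continue
            p_set = obs_p[idx]
            cand = np.flatnonzero(p_set < params.set_p)
            obs_nsig[name] = int(cand.size)
            order = cand[np.argsort(p_set[cand], kind="stable")]
            chosen = _greedy_select(
                np.concatenate([order, np.flatnonzero(p_set >= params.set_p)]),
                p_set, set_r2[name], params.set_p, params.set_r2, params.set_max,
            )
            obs_sel[name] = [int(idx[i]) for i in chosen]
            if not chosen:
                obs_stats[name] = None
            elif use_chisq:
                obs_stats[name] = float(np.mean(obs_stat[idx][chosen]))
            else:
                obs_stats[name] = float(np.mean(p_set[chosen]))

        # permutation ensemble
        rng = np.random.default_rng(params.seed)
        if self.perm == "exhaustive":
            Y = _exhaustive_matrix(y_vec)
        else:
            Y = _permutation_matrix(y_vec, params.n_perm, rng)
        R = Y.shape[1]
        if cols.size:
            P, S = _score_p_matrix(G, Y, covariates, p_floor=params.set_p)
        else:
            P = S = np.empty((R, 0))

        perm_stats = np.empty((len(set_cols), R))
        names = list(set_cols)
        for si, name in enumerate(names):
            idx = set_cols[name]
            if idx.size == 0:
                perm_stats[si] = 1.0
                continue
            Pset = P[:, idx]
            if use_chisq:
                # more extreme = larger mean chi-square; negate so that
                # "smaller is more extreme" holds uniformly downstream
                perm_stats[si] = -_set_stats(
                    Pset, set_r2[name], params.set_p, params.set_r2,
                    params.set_max, V=S[:, idx],
                )
            else:
                perm_stats[si] = _set_stats(
                    Pset, set_r2[name], params.set_p, params.set_r2, params.set_max
                )

        best_per_perm = perm_stats.min(axis=0)

        results: dict[str, SetAssocResult] = {}
        rows = []
        for si, name in enumerate(names):
            stat = obs_stats[name]
            cmp_obs = 1.0 if stat is None else (-stat if use_chisq else stat)
            if use_chisq and stat is not None:
                b = int(np.sum(perm_stats[si] <= -stat))
            else:
                b = int(np.sum(perm_stats[si] <= cmp_obs))
            if self.perm == "exhaustive":
                emp1 = b / R
                emp2 = float(np.sum(best_per_perm <= cmp_obs)) / R
            else:
                emp1 = (1 + b) / (R + 1)
                emp2 = (1 + int(np.sum(best_per_perm <= cmp_obs))) / (R + 1)
            top = (
                self._top_table(X, union_rsids, obs_sel[name], obs_p, covariates)
                if self.top_tables
                else None
            )
            results[name] = SetAssocResult(
                set_name=name,
                n_snps=int(set_cols[name].size),
                nsig=obs_nsig[name],
                isig=len(obs_sel[name]),
                stat=stat,
                emp1=emp1,
                emp2=emp2 if self.maxt else None,
                top_snps=top,
            )
            rows.append(
                dict(
                    SET=name, SNPS=int(set_cols[name].size), NSIG=obs_nsig[name],
                    ISIG=len(obs_sel[name]),
                    STAT=np.nan if stat is None else stat, EMP1=emp1,
                    **({"EMP2": emp2} if self.maxt else {}),
                )
            )
        self.set_results_ = results
        self.results_ = (
            pd.DataFrame(rows).sort_values("EMP1", kind="stable").reset_index(drop=True)
        )
        # permutation ensemble diagnostics: one row per set (order perm_stat_sets_),
        # one column per permutation; "smaller = more extreme" orientation
        self.perm_stats_ = perm_stats
        self.perm_stat_sets_ = names
        self.obs_cmp_ = {
            name: (1.0 if obs_stats[name] is None
                   else (-obs_stats[name] if use_chisq else obs_stats[name]))
            for name in names
        }
        self.n_perm_used_ = R
        self.gene_map_ = gene_map
        self.set_map_ = set_map
        return self

    def _top_table(self, X, union_rsids, sel, obs_p, covariates):
        if not sel:
            return pd.DataFrame(
                columns=["SNP", "CHR", "BP", "A1", "A2", "F_A", "F_U", "P", "OR"]
            )
        rows = []
        vars_by_rsid = X.variants.set_index("rsid")
        pheno = X.phenotype
        for i in sel:
            rs = union_rsids[i]
            j = int(X.variant_index([rs])[0])
            res = fit_logistic_snp(X.genotypes[:, j], pheno, covariates, rsid=rs)
            v = vars_by_rsid.loc[rs]
            rows.append(
                dict(
                    SNP=rs, CHR=v["chrom"], BP=int(v["bp"]), A1=v["a1"], A2=v["a2"],
                    F_A=res.f_a, F_U=res.f_u, P=float(obs_p[i]), OR=res.or_,
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def sba_test(
    dataset: GenotypeDataset,
    collection: GeneSetCollection,
    gene_map: dict[int, list[str]] | None = None,
    covariates: np.ndarray | None = None,
    params: SbaParams | None = None,
    genes: Sequence[GeneModel] | None = None,
    perm: str = "label",
    maxt: bool = False,
) -> dict[str, SetAssocResult]:
    est = SetBasedAssociation(params=params, maxt=maxt, perm=perm)
    est.fit(
        dataset, collection=collection, genes=genes, gene_map=gene_map,
        covariates=covariates,
    )
    return est.set_results_


def sba_maxt(
    dataset, collection, gene_map=None, covariates=None, params=None, genes=None,
    perm="label",
) -> dict[str, SetAssocResult]:
    return sba_test(
        dataset, collection, gene_map, covariates, params, genes, perm, maxt=True
    )


def leave_out_retest(
    dataset: GenotypeDataset,
    collection: GeneSetCollection,
    set_name: str,
    drop_genes: Sequence[int] | None = None,
    drop_snps: Sequence[str] | None = None,
    gene_map: dict[int, list[str]] | None = None,
    covariates: np.ndarray | None = None,
    params: SbaParams | None = None,
    genes: Sequence[GeneModel] | None = None,
) -> SetAssocResult:
    """Re-test one set after dropping genes and/or SNPs from it, with the
    same permutation seed, returning the modified set's result."""
    if set_name not in collection:
        raise KeyError(set_name)
    members = list(collection[set_name])
    drop_genes = set(drop_genes or [])
    unknown = drop_genes - set(members)
    if unknown:
        raise ValueError(f"genes {sorted(unknown)} are not in set {set_name!r}")
    kept = [g for g in members if g not in drop_genes]
    single = GeneSetCollection({set_name: kept})
    params = params or SbaParams()
    if gene_map is None:
        if genes is None:
            raise ValueError("provide either genes or gene_map")
        gene_map = assign_snps_to_genes(dataset.variants, genes, params.window_kb)
    if drop_snps:
        drop = set(drop_snps)
        gene_map = {
            gid: [rs for rs in rsids if rs not in drop]
            for gid, rsids in gene_map.items()
        }
    res = sba_test(
        dataset, single, gene_map=gene_map, covariates=covariates, params=params
    )
    return res[set_name]
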