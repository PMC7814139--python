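"""Covariate-adjusted single-marker association.

Per-SNP effects come from an additive logistic model
``logit P(case) = b0 + b_g * g + Gamma' * covariates`` fitted by
iteratively reweighted least squares, reported as Wald statistics together
with the per-status minor-allele frequencies and the raw allelic odds
ratio. A vectorized score test against the covariate-only null model is
exposed separately; it is algebraically the Cochran-Armitage trend test
when no covariates are present and is what the permutation machinery uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import chdtrc
from scipy.stats import norm

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .datasets import MISSING, GenotypeDataset


@dataclass
class AssocResult:
    rsid: str
    beta: float
    se: float
    p: float
    or_: float
    f_a: float
    f_u: float
    n_used: int
    flag: str | None = None


class LogisticFitError(RuntimeError):
    pass


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-9):
    """Newton/IRLS logistic fit; returns (beta, cov, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12))
    cov = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        XtWX = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            try:
                cov = np.linalg.inv((X * w[:, None]).T @ X)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, cov, False


def allele_freq_by_status(
    genotype_column: np.ndarray, phenotype: np.ndarray
) -> tuple[float, float]:
    """(f_a, f_u): A1 frequency among called cases and called controls."""
    g = np.asarray(genotype_column)
    f = []
    for status in (1, 0):
        rows = (phenotype == status) & (g != MISSING)
        if rows.sum() == 0:
            f.append(np.nan)
        else:
            f.append(float(g[rows].sum() / (2.0 * rows.sum())))
    return f[0], f[1]


def allelic_odds_ratio(f_a: float, f_u: float) -> float:
    """Allelic OR = (f_a/(1-f_a)) / (f_u/(1-f_u)); inf/0 at the boundaries."""
    if not (0 < f_a < 1) or not (0 < f_u < 1):
        if f_a in (0.0, 1.0) or f_u in (0.0, 1.0):
            odds_a = np.inf if f_a == 1.0 else f_a / (1 - f_a)
            odds_u = np.inf if f_u == 1.0 else f_u / (1 - f_u)
            with np.errstate(divide="ignore", invalid="ignore"):
                return float(odds_a / odds_u) if odds_u != 0 else np.inf
        raise ValueError("frequencies must lie in [0, 1]")
    return float((f_a / (1 - f_a)) / (f_u / (1 - f_u)))


def fit_logistic_snp(
    genotype_column: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    rsid: str = "",
) -> AssocResult:
    """Wald test of the additive genotype effect in a logistic model.

    Samples with a missing genotype are dropped for this SNP. Degenerate
    fits (monomorphic genotype, separation, collinearity, non-convergence)
    are flagged with ``p = 1`` rather than raised.
    """
    g = np.asarray(genotype_column, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = (g != MISSING) & ((y == 0) | (y == 1))
    g, y = g[keep], y[keep]
    C = covariates[keep] if covariates is not None else None
    f_a, f_u = allele_freq_by_status(
        np.asarray(genotype_column), np.asarray(phenotype)
    )
    n_used = int(keep.sum())

    def flagged(reason: str) -> AssocResult:
        return AssocResult(rsid, np.nan, np.nan, 1.0, np.nan, f_a, f_u, n_used, reason)

    if n_used == 0 or y.min() == y.max():
        return flagged("degenerate_phenotype")
    if g.min() == g.max():
        return flagged("monomorphic")
    cols = [np.ones(n_used), g]
    if C is not None:
        cols.extend(np.atleast_2d(C.T))
    X = np.column_stack(cols)
    beta, cov, converged = _irls_logistic(X, y)
    if cov is None:
        return flagged("collinear")
    if not converged or abs(beta[1]) > 15:
        return flagged("nonconvergence_or_separation")
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se
    p = float(2 * norm.sf(abs(z)))
    return AssocResult(
        rsid, float(beta[1]), se, max(p, np.nextafter(0, 1)), float(np.exp(beta[1])),
        f_a, f_u, n_used, None,
    )


def gwas_scan(
    dataset: GenotypeDataset, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-SNP logistic association over the whole panel.

    Output columns mirror a standard association table: CHR, SNP, BP, A1,
    F_A, F_U, A2, P, OR, plus BETA, SE, N and a FLAG column for degenerate
    fits.
    """
    pheno = dataset.phenotype
    rows = []
    for j in range(dataset.n_variants):
        v = dataset.variants.iloc[j]
        res = fit_logistic_snp(
            dataset.genotypes[:, j], pheno, covariates, rsid=v["rsid"]
        )
        rows.append(
            dict(
                CHR=v["chrom"], SNP=v["rsid"], BP=v["bp"], A1=v["a1"],
                F_A=res.f_a, F_U=res.f_u, A2=v["a2"], P=res.p, OR=res.or_,
                BETA=res.beta, SE=res.se, N=res.n_used, FLAG=res.flag,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score-test fast path (used by the permutation set test)
# ---------------------------------------------------------------------------
def score_test_chi2(
    G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """1-df efficient-score chi-square per SNP column of ``G``.

    The null logistic model (intercept + covariates) is fitted once; each
    SNP's score statistic is ``U^2 / V`` with the covariate-adjusted
    variance. Missing genotypes must already be imputed in ``G``. With no
    covariates this equals the Cochran-Armitage trend statistic.
    """
    y = np.asarray(y, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
        mu = np.full(n, y.mean())
    else:
        X = np.column_stack([np.ones(n), covariates])
        beta, _, converged = _irls_logistic(X, y)
        if not converged:
            raise LogisticFitError("null model did not converge")
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1 - mu)
    resid = y - mu
    U = G.T @ resid
    WG = G * w[:, None]
    A = X.T @ WG  # k x m
    XtWX = (X * w[:, None]).T @ X
    sol = np.linalg.solve(XtWX, A)
    V = np.einsum("ij,ij->i", G.T, WG.T) - np.einsum("ki,ki->i", A, sol)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(V > 0, U**2 / V, 0.0)
    return stat


def score_test_pvalues(
    G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    return chdtrc(1, score_test_chi2(G, y, covariates))


def impute_mean(dataset: GenotypeDataset, dtype=np.float64) -> np.ndarray:
    """Genotype matrix with missing calls replaced by the marker mean."""
    g = dataset.genotypes.astype(dtype)
    missing = dataset.genotypes == MISSING
    if missing.any():
        called = ~missing
        denom = np.maximum(called.sum(axis=0), 1)
        mean = np.where(called, g, 0).sum(axis=0) / denom
        g = np.where(missing, mean[None, :], g)
    return g


class LogisticGWAS(BaseEstimator):
    """Estimator wrapper: ``fit(dataset, covariates=...)`` then ``results_``."""

    def __init__(self, use_covariates: bool = True):
        self.use_covariates = use_covariates

    def fit(self, X: GenotypeDataset, y=None, covariates: np.ndarray | None = None):
        cov = covariates if self.use_covariates else None
        self.results_ = gwas_scan(X, cov)
        return self
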