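"""Ancestry PCA with Patterson normalization and Tracy-Widom selection.

Markers are standardized as ``(g - 2p) / sqrt(2 p̂ (1 - p̂))`` with the
posterior allele-frequency estimate ``p̂ = (count + 0.5) / (2n + 1)``;
missing calls are mean-imputed per marker and monomorphic markers dropped.
The number of statistically meaningful components is chosen with the
Tracy-Widom test on the leading eigenvalues, and ancestry outliers are
removed by iterated PCA at a standard-deviation limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .datasets import MISSING, GenotypeDataset

#: Tracy-Widom (TW1) critical values, Patterson's tabulation.
TW_CRITICAL = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


@dataclass
class PCAResult:
    scores: np.ndarray  # n x K
    eigenvalues: np.ndarray  # length K, non-increasing
    loadings: np.ndarray  # m_used x K (for projection)
    used_variants: np.ndarray  # boolean mask over input variants
    col_center: np.ndarray  # per-used-marker centering constants
    col_scale: np.ndarray  # per-used-marker scaling constants
    n_markers_effective: float = np.nan
    tw_stats: np.ndarray | None = None
    n_significant: int | None = None


def _standardize(dataset: GenotypeDataset):
    g = dataset.genotypes.astype(np.float64)
    called = dataset.genotypes != MISSING
    n_called = called.sum(axis=0)
    counts = np.where(called, g, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_freq = counts / (2.0 * n_called)
    poly = (n_called > 0) & (raw_freq > 0) & (raw_freq < 1)
    g = g[:, poly]
    called = called[:, poly]
    center = 2.0 * raw_freq[poly]
    posterior = (counts[poly] + 0.5) / (2.0 * n_called[poly] + 1.0)
    scale = np.sqrt(2.0 * posterior * (1.0 - posterior))
    g = np.where(called, g, center)
    z = (g - center) / scale
    return z, poly, center, scale


def pca_patterson(dataset: GenotypeDataset, K: int | None = None) -> PCAResult:
    """Principal components of the Patterson-normalized genotype matrix.

    ``scores`` are left singular vectors scaled by singular values;
    ``eigenvalues`` are eigenvalues of the marker-averaged covariance
    ``Z Z' / m`` so their sum equals its trace.
    """
    if dataset.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    z, poly, center, scale = _standardize(dataset)
    m_used = z.shape[1]
    if m_used == 0:
        raise ValueError("no polymorphic markers for PCA")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if K is None:
        K = s.size
    K = min(K, s.size)
    eigenvalues = (s**2) / m_used
    return PCAResult(
        scores=u[:, :K] * s[:K],
        eigenvalues=eigenvalues[:K],
        loadings=vt[:K].T,
        used_variants=poly,
        col_center=center,
        col_scale=scale,
    )


def tracy_widom_significant(
    eigenvalues: np.ndarray,
    n: int,
    m: int,
    alpha: float = 0.05,
    return_stats: bool = False,
):
    """Count leading eigenvalues significant under the Tracy-Widom test.

    Follows Patterson's procedure: for each leading eigenvalue the
    effective marker count is re-estimated from the moments of the
    remaining eigenvalues, the normalized top eigenvalue is centered and
    scaled with the (n_eff, m') constants, and components are counted
    significant until the first statistic falls below the critical value.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    crit = TW_CRITICAL.get(alpha)
    if crit is None:
        raise ValueError(f"no tabulated critical value for alpha={alpha}")
    stats = np.full(lam.size, -np.inf)
    n_sig = 0
    stopped = False
    for i in range(lam.size - 1):
        tail = lam[i:]
        mp = tail.size
        s1, s2 = tail.sum(), (tail**2).sum()
        denom = (mp - 1) * s2 - s1**2 / 1.0
        # effective number of markers from eigenvalue moments
        if denom <= 0 or s1 <= 0:
            break
        n_eff = (mp + 1) * s1**2 / denom
        if n_eff <= 1:
            break
        ell = mp * tail[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_m = np.sqrt(mp)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        stats[i] = (ell - mu) / sigma
        if not stopped and stats[i] > crit:
            n_sig += 1
        else:
            stopped = True
    if return_stats:
        return n_sig, stats
    return n_sig


def pca_outlier_removal(
    dataset: GenotypeDataset,
    sd_limit: float = 6.0,
    n_pcs: int = 10,
    max_rounds: int = 5,
) -> tuple[GenotypeDataset, list[str]]:
    """Iteratively remove samples beyond ``sd_limit`` SDs on any leading PC.

    PCA is recomputed after every removal round; stops when a round removes
    nobody or ``max_rounds`` is reached.
    """
    if sd_limit <= 0:
        raise ValueError("sd_limit must be > 0")
    ds = dataset
    removed: list[str] = []
    for _ in range(max_rounds):
        if ds.n_samples < 3:
            raise RuntimeError("outlier removal would leave fewer than 3 samples")
        k = min(n_pcs, ds.n_samples - 1)
        res = pca_patterson(ds, K=k)
        scores = res.scores
        sd = scores.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = np.abs((scores - scores.mean(axis=0)) / sd)
        out = (z > sd_limit).any(axis=1)
        if not out.any():
            break
        if (~out).sum() < 3:
            raise RuntimeError("outlier removal would leave fewer than 3 samples")
        ids = ds.samples["sample_id"].to_numpy()
        removed += sorted(ids[out])
        ds = ds.take_samples(~out)
    return ds, removed


class PattersonPCA(BaseEstimator):
    """sklearn-style ancestry PCA over :class:`GenotypeDataset` inputs.

    After ``fit``, exposes ``scores_`` (n x K), ``eigenvalues_``,
    ``tw_stats_`` and ``n_significant_``; ``transform`` projects a dataset
    with the same variant panel onto the fitted axes.
    """

    def __init__(self, n_components: int | None = 10, alpha: float = 0.05):
        self.n_components = n_components
        self.alpha = alpha

    def fit(self, X: GenotypeDataset, y=None):
        full = pca_patterson(X, K=None)
        K = full.eigenvalues.size if self.n_components is None else self.n_components
        K = min(K, full.eigenvalues.size)
        n_sig, stats = tracy_widom_significant(
            full.eigenvalues,
            X.n_samples,
            int(full.used_variants.sum()),
            alpha=self.alpha,
            return_stats=True,
        )
        self.result_ = full
        self.scores_ = full.scores[:, :K]
        self.eigenvalues_ = full.eigenvalues[:K]
        self.tw_stats_ = stats[:K]
        self.n_significant_ = n_sig
        return self

    def transform(self, X: GenotypeDataset) -> np.ndarray:
        res = self.result_
        g = X.genotypes.astype(np.float64)[:, res.used_variants]
        called = X.genotypes[:, res.used_variants] != MISSING
        g = np.where(called, g, res.col_center)
        z = (g - res.col_center) / res.col_scale
        K = self.scores_.shape[1]
        return z @ res.loadings[:, :K]

    def fit_transform(self, X: GenotypeDataset, y=None) -> np.ndarray:
        return self.fit(X).scores_
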