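"""Sample and marker quality control for case-control genotype panels.

The cascade mirrors standard array-GWAS practice: per-batch sample filters
(call rate, inbreeding), per-batch marker filters (call rate, case-control
differential missingness, Hardy-Weinberg), pairwise batch-effect scans
within phenotype strata, then post-merge ancestry-outlier removal and
identity-by-descent pruning of cryptic relatives.

All thresholds live in :class:`QCThresholds`; the defaults are the values a
stringent array QC uses (0.98 call rates, |F| <= 0.2, 0.02 differential
missingness, HWE 1e-6 in controls / 1e-10 in cases, 1e-6 batch scans,
PI_HAT 0.1875, 6-SD ancestry outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.special import chdtrc

try:  # sklearn-style estimator base; optional at import time
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .datasets import CASE, CONTROL, MISSING, GenotypeDataset


@dataclass
class QCThresholds:
    sample_call_rate: float = 0.98
    inbreeding_abs_max: float = 0.2
    marker_call_rate: float = 0.98
    diff_missingness_max: float = 0.02
    hwe_p_controls: float = 1e-6
    hwe_p_cases: float = 1e-10
    batch_p_max: float = 1e-6
    pihat_max: float = 0.1875
    pca_outlier_sd: float = 6.0
    pca_outlier_pcs: int = 10

    def validate(self) -> None:
        for name in (
            "sample_call_rate",
            "marker_call_rate",
            "diff_missingness_max",
            "hwe_p_controls",
            "hwe_p_cases",
            "batch_p_max",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.pca_outlier_sd <= 0:
            raise ValueError("pca_outlier_sd must be > 0")


@dataclass
class QCReport:
    """Removals with reasons, plus per-stage before/after counts."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    stage_counts: list[dict] = field(default_factory=list)

    def record_stage(self, stage, samples_before, samples_after, markers_before, markers_after):
        self.stage_counts.append(
            dict(
                stage=stage,
                samples_before=samples_before,
                samples_after=samples_after,
                markers_before=markers_before,
                markers_after=markers_after,
            )
        )

    def sample_reasons(self) -> dict[str, str]:
        return dict(self.removed_samples)

    def marker_reasons(self) -> dict[str, str]:
        return dict(self.removed_markers)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(self.removed_samples, columns=["sample_id", "reason"]),
            pd.DataFrame(self.removed_markers, columns=["rsid", "reason"]),
            pd.DataFrame(self.stage_counts),
        )


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------
def sample_call_rates(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotype calls per sample."""
    if dataset.n_variants < 1:
        raise ValueError("need at least one variant")
    return dataset.called.mean(axis=1)


def marker_call_rates(dataset: GenotypeDataset) -> np.ndarray:
    return dataset.called.mean(axis=0)


def inbreeding_coefficient(dataset: GenotypeDataset) -> np.ndarray:
    """Method-of-moments inbreeding F per sample.

    ``F = (O_hom - E_hom) / (L - E_hom)`` where the expected homozygosity
    uses the sample-size-corrected expected heterozygosity
    ``2 p (1-p) * 2n_j / (2n_j - 1)`` per marker; monomorphic markers are
    excluded. NaN where undefined.
    """
    g = dataset.genotypes
    called = g != MISSING
    n_j = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_j > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * n_j), np.nan)
    poly = (n_j > 1) & (p > 0) & (p < 1)
    if not poly.any():
        return np.full(dataset.n_samples, np.nan)
    e_het = 2.0 * p[poly] * (1 - p[poly]) * (2.0 * n_j[poly]) / (2.0 * n_j[poly] - 1)
    e_hom = 1.0 - e_het
    calledp = called[:, poly]
    L = calledp.sum(axis=1).astype(float)
    O_hom = (calledp & ((g[:, poly] == 0) | (g[:, poly] == 2))).sum(axis=1)
    E_hom = calledp @ e_hom
    denom = L - E_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, (O_hom - E_hom) / denom, np.nan)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the minor-allele count; the p-value sums the conditional
    probability of every heterozygote count no more likely than the one
    observed.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    valid = hom_major >= 0
    hs, hom_minor, hom_major = hs[valid], hom_minor[valid], hom_major[valid]
    logp = (
        hs * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hs == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(dataset: GenotypeDataset, mask: np.ndarray | None = None) -> np.ndarray:
    """HWE exact p per marker over the given sample mask (default: all)."""
    g = dataset.genotypes if mask is None else dataset.genotypes[mask]
    out = np.ones(g.shape[1])
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    for j in range(g.shape[1]):
        if n0[j] + n1[j] + n2[j] >= 1:
            out[j] = hwe_exact_test(int(n2[j]), int(n1[j]), int(n0[j]))
    return out


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-square p for 2x2 tables [[a,b],[c,d]]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat = np.where(np.isfinite(stat), stat, 0.0)
    return chdtrc(1, stat)


def differential_missingness_test(
    dataset: GenotypeDataset, rsid: str | None = None
) -> pd.DataFrame:
    """Case-control missingness-rate difference and 2x2 chi-square p.

    The rate difference is the primary filter quantity; the chi-square p is
    reported alongside. Returns one row per marker (or the single requested
    rsid) with columns ``rsid, miss_case, miss_control, diff, p``.
    """
    cases, controls = dataset.is_case, dataset.is_control
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("both phenotype classes must be present")
    missing = ~dataset.called
    miss_case = missing[cases].sum(axis=0)
    miss_ctrl = missing[controls].sum(axis=0)
    n_case, n_ctrl = int(cases.sum()), int(controls.sum())
    rate_case = miss_case / n_case
    rate_ctrl = miss_ctrl / n_ctrl
    p = _chi2_2x2(miss_case, n_case - miss_case, miss_ctrl, n_ctrl - miss_ctrl)
    out = pd.DataFrame(
        {
            "rsid": dataset.variants["rsid"],
            "miss_case": rate_case,
            "miss_control": rate_ctrl,
            "diff": np.abs(rate_case - rate_ctrl),
            "p": p,
        }
    )
    if rsid is not None:
        out = out[out["rsid"] == rsid].reset_index(drop=True)
    return out


def _allelic_chi2(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Allelic (2x2 allele count) chi-square p per marker between two
    genotype submatrices."""
    def counts(g):
        called = g != MISSING
        a1 = np.where(called, g, 0).sum(axis=0)
        tot = 2.0 * called.sum(axis=0)
        return a1, tot - a1

    a, b = counts(g1)
    c, d = counts(g2)
    return _chi2_2x2(a, b, c, d)


def _missingness_chi2(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    m1 = (g1 == MISSING).sum(axis=0)
    m2 = (g2 == MISSING).sum(axis=0)
    return _chi2_2x2(m1, g1.shape[0] - m1, m2, g2.shape[0] - m2)


def batch_effect_scan(dataset: GenotypeDataset) -> np.ndarray:
    """Per-marker minimum p over pairwise between-batch association and
    missingness tests, run separately in the case-only and control-only
    strata. Returns all-ones with a warning when only one batch exists."""
    batches = dataset.samples["batch"].to_numpy()
    labels = pd.unique(batches)
    min_p = np.ones(dataset.n_variants)
    if len(labels) < 2:
        warnings.warn("batch_effect_scan: single batch, nothing to compare")
        return min_p
    pheno = dataset.phenotype
    for stratum in (CASE, CONTROL):
        in_stratum = pheno == stratum
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                r1 = in_stratum & (batches == labels[i])
                r2 = in_stratum & (batches == labels[j])
                if r1.sum() < 2 or r2.sum() < 2:
                    continue
                g1, g2 = dataset.genotypes[r1], dataset.genotypes[r2]
                min_p = np.minimum(min_p, _allelic_chi2(g1, g2))
                min_p = np.minimum(min_p, _missingness_chi2(g1, g2))
    return min_p


# ---------------------------------------------------------------------------
# identity by descent
# ---------------------------------------------------------------------------
def _ibs_expectations(freq: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-marker P(IBS=s | IBD=k) under random mating at frequency p."""
    p = freq
    q = 1 - p
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = 1 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = 1 - e1_ibd1
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def _pihat_from_moments(N0, N1, N2, S0_0, S1_0, S2_0, S1_1, S2_1, L):
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(S0_0 > 0, N0 / S0_0, 0.0)
        p1 = np.where(S1_1 > 0, (N1 - p0 * S1_0) / S1_1, 0.0)
        p2 = np.where(L > 0, (N2 - p0 * S2_0 - p1 * S2_1) / L, 0.0)
    p0, p1, p2 = (np.clip(x, 0.0, 1.0) for x in (p0, p1, p2))
    total = p0 + p1 + p2
    total = np.where(total > 0, total, 1.0)
    p1, p2 = p1 / total, p2 / total
    return np.clip(p2 + 0.5 * p1, 0.0, 1.0)


def ibd_pihat(dataset: GenotypeDataset, pair: tuple[str, str]) -> float:
    """Method-of-moments PI_HAT for one sample pair from IBS sharing.

    Allele frequencies are estimated from the whole dataset; markers missing
    in either sample are skipped. Warns when fewer than 50 markers overlap.
    """
    ids = dataset.samples["sample_id"].to_numpy()
    i = int(np.flatnonzero(ids == pair[0])[0])
    k = int(np.flatnonzero(ids == pair[1])[0])
    gi, gk = dataset.genotypes[i], dataset.genotypes[k]
    freq = dataset.allele_frequencies()
    ok = (gi != MISSING) & (gk != MISSING) & np.isfinite(freq)
    ok &= (freq > 0) & (freq < 1)
    if ok.sum() < 50:
        warnings.warn(f"ibd_pihat: only {int(ok.sum())} overlapping markers; unreliable")
    gi, gk, freq = gi[ok], gk[ok], freq[ok]
    ibs = 2 - np.abs(gi.astype(int) - gk.astype(int))
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(freq)
    return float(
        _pihat_from_moments(
            np.sum(ibs == 0),
            np.sum(ibs == 1),
            np.sum(ibs == 2),
            e0_0.sum(),
            e1_0.sum(),
            e2_0.sum(),
            e1_1.sum(),
            e2_1.sum(),
            float(ibs.size),
        )
    )


def ibd_pihat_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """All-pairs PI_HAT via indicator matrix products (n x n, symmetric)."""
    g = dataset.genotypes
    freq = dataset.allele_frequencies()
    poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
    g = g[:, poly]
    freq = freq[poly]
    A0 = (g == 0).astype(np.float32)
    A1 = (g == 1).astype(np.float32)
    A2 = (g == 2).astype(np.float32)
    C = (g != MISSING).astype(np.float32)
    N_ibs0 = A0 @ A2.T + A2 @ A0.T
    N_ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    L = C @ C.T
    N_ibs1 = L - N_ibs0 - N_ibs2
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(freq)
    S = {}
    for key, e in (("0_0", e0_0), ("1_0", e1_0), ("2_0", e2_0), ("1_1", e1_1), ("2_1", e2_1)):
        S[key] = (C * e.astype(np.float32)) @ C.T
    pihat = _pihat_from_moments(
        N_ibs0, N_ibs1, N_ibs2, S["0_0"], S["1_0"], S["2_0"], S["1_1"], S["2_1"], L
    )
    np.fill_diagonal(pihat, 1.0)
    return pihat


# ---------------------------------------------------------------------------
# LD pruning (for IBD)
# ---------------------------------------------------------------------------
def ld_prune(
    dataset: GenotypeDataset, r2_max: float = 0.2, window: int = 50, step: int = 25
) -> np.ndarray:
    """Greedy LD pruning: keep mask over variants, scanning ``window``-SNP
    windows advanced by ``step`` and dropping any SNP with r^2 >= r2_max
    against a kept SNP earlier in the window."""
    g = dataset.genotypes.astype(np.float64)
    g[dataset.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    col_mean = np.nan_to_num(col_mean)
    filled = np.where(np.isnan(g), col_mean, g)
    filled -= filled.mean(axis=0)
    sd = filled.std(axis=0)
    keep = np.ones(dataset.n_variants, dtype=bool)
    keep[sd == 0] = False
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = filled / sd_safe
    n = z.shape[0]
    m = dataset.n_variants
    start = 0
    while start < m:
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        if idx.size > 1:
            corr = (z[:, idx].T @ z[:, idx]) / n
            r2 = corr**2
            local_keep = np.ones(idx.size, dtype=bool)
            for a in range(1, idx.size):
                if np.any(r2[a, :a][local_keep[:a]] >= r2_max):
                    local_keep[a] = False
            keep[idx[~local_keep]] = False
        start += step
    return keep


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------
_REASONS = (
    "sample_call_rate",
    "inbreeding",
    "marker_call_rate",
    "differential_missingness",
    "hwe",
    "batch_effect",
    "pca_outlier",
    "relatedness",
)


def run_qc(
    dataset: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    *,
    skip_pca_outliers: bool = False,
    skip_ibd: bool = False,
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC cascade and return the cleaned dataset plus report.

    Stage order: sample call rate -> |F| inbreeding -> per-batch marker call
    rate -> per-batch differential missingness -> per-batch HWE (controls
    then cases at their own thresholds) -> pairwise batch-effect scan ->
    PCA ancestry outliers -> IBD relatedness pruning.
    """
    th = thresholds or QCThresholds()
    th.validate()
    report = QCReport()
    ds = dataset

    def record(stage, before_s, before_m):
        report.record_stage(stage, before_s, ds.n_samples, before_m, ds.n_variants)

    # -- samples: call rate
    ns, nm = ds.n_samples, ds.n_variants
    cr = sample_call_rates(ds)
    bad = cr < th.sample_call_rate
    ids = ds.samples["sample_id"].to_numpy()
    report.removed_samples += [(s, "sample_call_rate") for s in ids[bad]]
    ds = ds.take_samples(~bad)
    record("sample_call_rate", ns, nm)
    if ds.n_samples == 0:
        raise RuntimeError("QC removed every sample at the call-rate stage")

    # -- samples: inbreeding
    ns, nm = ds.n_samples, ds.n_variants
    F = inbreeding_coefficient(ds)
    bad = np.abs(np.nan_to_num(F)) > th.inbreeding_abs_max
    ids = ds.samples["sample_id"].to_numpy()
    report.removed_samples += [(s, "inbreeding") for s in ids[bad]]
    ds = ds.take_samples(~bad)
    record("inbreeding", ns, nm)

    batches = pd.unique(ds.samples["batch"])

    def per_batch_masks():
        for b in batches:
            yield (ds.samples["batch"] == b).to_numpy()

    # -- markers: call rate (within any batch)
    ns, nm = ds.n_samples, ds.n_variants
    bad_m = np.zeros(ds.n_variants, dtype=bool)
    for rows in per_batch_masks():
        if rows.sum() == 0:
            continue
        bad_m |= (ds.genotypes[rows] != MISSING).mean(axis=0) < th.marker_call_rate
    rsids = ds.variants["rsid"].to_numpy()
    report.removed_markers += [(r, "marker_call_rate") for r in rsids[bad_m]]
    ds = ds.take_variants(~bad_m)
    record("marker_call_rate", ns, nm)

    # -- markers: case-control differential missingness (within batch)
    ns, nm = ds.n_samples, ds.n_variants
    bad_m = np.zeros(ds.n_variants, dtype=bool)
    for rows in per_batch_masks():
        sub = ds.take_samples(rows)
        if sub.is_case.sum() == 0 or sub.is_control.sum() == 0:
            continue
        dm = differential_missingness_test(sub)
        bad_m |= dm["diff"].to_numpy() > th.diff_missingness_max
    rsids = ds.variants["rsid"].to_numpy()
    report.removed_markers += [(r, "differential_missingness") for r in rsids[bad_m]]
    ds = ds.take_variants(~bad_m)
    record("differential_missingness", ns, nm)

    # -- markers: HWE in controls (1e-6) and cases (1e-10), per batch
    ns, nm = ds.n_samples, ds.n_variants
    bad_m = np.zeros(ds.n_variants, dtype=bool)
    for rows in per_batch_masks():
        ctrl = rows & ds.is_control
        case = rows & ds.is_case
        if ctrl.sum() > 1:
            bad_m |= hwe_pvalues(ds, ctrl) < th.hwe_p_controls
        if case.sum() > 1:
            bad_m |= hwe_pvalues(ds, case) < th.hwe_p_cases
    rsids = ds.variants["rsid"].to_numpy()
    report.removed_markers += [(r, "hwe") for r in rsids[bad_m]]
    ds = ds.take_variants(~bad_m)
    record("hwe", ns, nm)

    # -- markers: pairwise batch-effect scan
    ns, nm = ds.n_samples, ds.n_variants
    if len(batches) > 1:
        minp = batch_effect_scan(ds)
        bad_m = minp <= th.batch_p_max
        rsids = ds.variants["rsid"].to_numpy()
        report.removed_markers += [(r, "batch_effect") for r in rsids[bad_m]]
        ds = ds.take_variants(~bad_m)
    record("batch_effect", ns, nm)

    # -- samples: PCA ancestry outliers
    ns, nm = ds.n_samples, ds.n_variants
    if not skip_pca_outliers:
        from .structure import pca_outlier_removal

        ds, removed = pca_outlier_removal(
            ds, sd_limit=th.pca_outlier_sd, n_pcs=th.pca_outlier_pcs
        )
        report.removed_samples += [(s, "pca_outlier") for s in removed]
    record("pca_outlier", ns, nm)

    # -- samples: relatedness
    ns, nm = ds.n_samples, ds.n_variants
    if not skip_ibd and ds.n_samples > 1:
        keep_ld = ld_prune(ds)
        pruned = ds.take_variants(keep_ld) if keep_ld.sum() >= 50 else ds
        pihat = ibd_pihat_matrix(pruned)
        cr = sample_call_rates(ds)
        ids = ds.samples["sample_id"].to_numpy()
        iu = np.triu_indices(ds.n_samples, k=1)
        flagged = pihat[iu] > th.pihat_max
        to_remove: set[str] = set()
        order = np.argsort(-pihat[iu][flagged])  # worst pairs first
        pairs = list(zip(iu[0][flagged][order], iu[1][flagged][order]))
        for i, k in pairs:
            si, sk = ids[i], ids[k]
            if si in to_remove or sk in to_remove:
                continue
            if cr[i] < cr[k]:
                to_remove.add(si)
            elif cr[k] < cr[i]:
                to_remove.add(sk)
            else:  # exact tie: lexicographically larger id goes
                to_remove.add(max(si, sk))
        report.removed_samples += [(s, "relatedness") for s in sorted(to_remove)]
        ds = ds.drop_samples(to_remove)
    record("relatedness", ns, nm)

    return ds, report


class GenotypeQC(BaseEstimator):
    """Estimator-style wrapper over :func:`run_qc`.

    ``fit_transform(dataset)`` returns the cleaned dataset; the removal
    report is available as ``report_`` afterwards.
    """

    def __init__(
        self,
        thresholds: QCThresholds | None = None,
        skip_pca_outliers: bool = False,
        skip_ibd: bool = False,
    ):
        self.thresholds = thresholds
        self.skip_pca_outliers = skip_pca_outliers
        self.skip_ibd = skip_ibd

    def fit(self, X: GenotypeDataset, y=None):
        cleaned, report = run_qc(
            X,
            self.thresholds,
            skip_pca_outliers=self.skip_pca_outliers,
            skip_ibd=self.skip_ibd,
        )
        self.cleaned_ = cleaned
        self.report_ = report
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        if not hasattr(self, "report_"):
            raise RuntimeError("GenotypeQC must be fitted before transform")
        return X.drop_samples(
            [s for s, _ in self.report_.removed_samples]
        ).drop_variants([r for r, _ in self.report_.removed_markers])

    def fit_transform(self, X: GenotypeDataset, y=None) -> GenotypeDataset:
        return self.fit(X).cleaned_
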