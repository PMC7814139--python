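"""QC statistics against independent oracles, plus cascade behavior."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pathgwas.datasets import CASE, CONTROL, MISSING
from pathgwas.qc import (
    QCThresholds,
    batch_effect_scan,
    differential_missingness_test,
    hwe_exact_test,
    hwe_pvalues,
    ibd_pihat,
    ibd_pihat_matrix,
    inbreeding_coefficient,
    ld_prune,
    marker_call_rates,
    run_qc,
    sample_call_rates,
)
from pathgwas.synth import SimConfig, implant_artifacts, simulate_cohort

from conftest import make_dataset


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------
def hwe_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact-rational enumeration of the conditional heterozygote
    distribution, independent of the package's log-gamma implementation."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        # unnormalized weight 2^h / (hom_minor! h! hom_major!) via integers
        w = Fraction(2**h * comb(n, h) * comb(n - h, hom_minor), 1)
        probs[h] = w
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return float(sum(w for w in probs.values() if w / total <= p_obs) / total)


def test_hwe_small_examples():
    # 1 AA, 0 Aa, 1 aa: conditional dist on h in {0,2} is (1/3, 2/3)
    assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
    assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)
    # monomorphic marker: p = 1 by convention
    assert hwe_exact_test(5, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


def test_hwe_matches_rational_oracle_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 80))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = n - a - b
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_oracle(a, b, c), rel=1e-10
        )


def test_hwe_invalid_inputs():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_pvalues_vector(small_cohort):
    ds = small_cohort[0]
    p = hwe_pvalues(ds)
    g = ds.genotypes
    for j in (0, 7, 33):
        expect = hwe_exact_test(
            int((g[:, j] == 2).sum()), int((g[:, j] == 1).sum()),
            int((g[:, j] == 0).sum()),
        )
        assert p[j] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# call rates, inbreeding
# ---------------------------------------------------------------------------
def test_call_rates_hand_computed():
    g = np.array([[0, 1, MISSING, 2], [MISSING, MISSING, 1, 0]])
    ds = make_dataset(g)
    assert sample_call_rates(ds).tolist() == [0.75, 0.5]
    assert marker_call_rates(ds).tolist() == [0.5, 0.5, 0.5, 1.0]


def test_inbreeding_limits():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.2, 0.8, 300)
    # HWE draws: F near 0
    g_hwe = (rng.random((80, 300)) < p).astype(np.int8) + (
        rng.random((80, 300)) < p
    ).astype(np.int8)
    ds = make_dataset(g_hwe)
    F = inbreeding_coefficient(ds)
    assert np.abs(np.nanmean(F)) < 0.05
    # a fully homozygous sample: F near 1
    g2 = g_hwe.copy()
    g2[0] = np.where(rng.random(300) < p, 2, 0)
    F2 = inbreeding_coefficient(make_dataset(g2))
    assert F2[0] > 0.8


# ---------------------------------------------------------------------------
# differential missingness + batch scan
# ---------------------------------------------------------------------------
def test_differential_missingness_vs_scipy():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(120, 20)).astype(np.int8)
    miss = rng.random(g.shape) < np.where(np.arange(20) < 10, 0.15, 0.02)
    # make cases miss more on the first SNP
    pheno = np.array([1] * 60 + [0] * 60)
    miss[:60, 0] |= rng.random(60) < 0.3
    g[miss] = MISSING
    ds = make_dataset(g, phenotype=pheno)
    out = differential_missingness_test(ds)
    cases, controls = ds.is_case, ds.is_control
    for j in (0, 3, 11):
        mc = int((g[cases, j] == MISSING).sum())
        mu = int((g[controls, j] == MISSING).sum())
        table = [[mc, 60 - mc], [mu, 60 - mu]]
        assert out["diff"].iloc[j] == pytest.approx(abs(mc - mu) / 60)
        if mc + mu > 0:
            expect = chi2_contingency(table, correction=False).pvalue
            assert out["p"].iloc[j] == pytest.approx(expect, rel=1e-9)
    assert out["diff"].iloc[0] > 0.1


def test_batch_effect_scan_flags_shifted_marker(small_cohort):
    ds = small_cohort[0]
    rs = ds.variants["rsid"].iloc[2]
    out, _ = implant_artifacts(
        ds,
        [{"kind": "batch_association", "rsids": [rs], "batch": "B1", "delta": 0.45}],
        seed=5,
    )
    minp = batch_effect_scan(out)
    j = int(out.variant_index([rs])[0])
    assert minp[j] <= 1e-6
    assert np.median(minp) > 1e-3


def test_batch_effect_scan_single_batch_warns():
    ds = make_dataset(np.zeros((6, 4)), batch=["B1"] * 6)
    with pytest.warns(UserWarning, match="single batch"):
        minp = batch_effect_scan(ds)
    assert np.all(minp == 1.0)


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------
def test_pihat_duplicate_parent_child_unrelated(small_cohort):
    ds = small_cohort[0]
    sid = ds.samples["sample_id"].iloc[0]
    out, _ = implant_artifacts(
        ds,
        [
            {"kind": "duplicate_sample", "source": sid, "flip_prob": 0.0},
            {"kind": "parent_child", "source": sid},
        ],
        seed=6,
    )
    dup = ibd_pihat(out, (sid, f"dup_{sid}"))
    child = ibd_pihat(out, (sid, f"child_{sid}"))
    other = ds.samples["sample_id"].iloc[50]
    unrel = ibd_pihat(out, (sid, other))
    assert dup > 0.95
    assert 0.35 < child < 0.65
    assert unrel < 0.15


def test_pihat_matrix_matches_pairwise(small_cohort):
    ds = small_cohort[0].take_samples(np.arange(12))
    M = ibd_pihat_matrix(ds)
    ids = ds.samples["sample_id"].tolist()
    for i, k in [(0, 1), (2, 9), (4, 11)]:
        assert M[i, k] == pytest.approx(ibd_pihat(ds, (ids[i], ids[k])), abs=5e-3)
    assert np.allclose(M, M.T, atol=1e-6)


def test_ld_prune_caps_pairwise_r2(small_cohort):
    ds = small_cohort[0]
    keep = ld_prune(ds, r2_max=0.2)
    assert 0 < keep.sum() < ds.n_variants
    pruned = ds.take_variants(keep)
    g = pruned.genotypes.astype(float)
    # adjacent surviving SNPs in the same window must be below the threshold
    r = np.corrcoef(g.T)
    band = np.diag(r, k=1) ** 2
    assert np.nanmax(band) < 0.2 + 1e-9


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------
def test_thresholds_validate():
    with pytest.raises(ValueError):
        QCThresholds(sample_call_rate=0.0).validate()
    with pytest.raises(ValueError):
        QCThresholds(pca_outlier_sd=-1).validate()


def test_run_qc_clean_cohort_mostly_untouched(default_cohort):
    """On a clean default-size panel only the relatedness filter may fire:
    the founder pool gives every pair a background kinship (~0.05) whose
    estimation noise can occasionally cross the 0.1875 threshold."""
    ds = default_cohort[0]
    cleaned, report = run_qc(ds)
    assert not report.removed_markers
    reasons = set(r for _, r in report.removed_samples)
    assert reasons <= {"relatedness"}
    assert cleaned.n_samples >= 0.8 * ds.n_samples


def test_run_qc_without_ibd_is_idempotent(default_cohort):
    ds = default_cohort[0]
    cleaned, rep1 = run_qc(ds, skip_ibd=True)
    assert not rep1.removed_samples and not rep1.removed_markers
    again, rep2 = run_qc(cleaned, skip_ibd=True)
    assert not rep2.removed_samples and not rep2.removed_markers
    assert again.equals(cleaned)


def test_run_qc_reason_codes(default_cohort):
    ds = default_cohort[0]
    sid = ds.samples["sample_id"].iloc[4]
    rs = ds.variants["rsid"].iloc[17]
    out, _ = implant_artifacts(
        ds,
        [
            {"kind": "duplicate_sample", "source": sid, "flip_prob": 0.0},
            {"kind": "sample_missingness", "sample_id": sid, "rate": 0.10},
            {"kind": "marker_missingness", "rsids": [rs], "rate": 0.10},
        ],
        seed=7,
    )
    cleaned, report = run_qc(out)
    sreasons = report.sample_reasons()
    mreasons = report.marker_reasons()
    assert sreasons.get(sid) == "sample_call_rate"
    assert mreasons.get(rs) == "marker_call_rate"
    # the duplicate itself has full call rate and survives to the IBD stage;
    # its source was already dropped for call rate, so the pair is broken
    # and the duplicate either stays or goes via relatedness only
    assert sreasons.get(f"dup_{sid}") in (None, "relatedness")
    assert f"dup_{sid}" in cleaned.samples["sample_id"].tolist() or \
        sreasons.get(f"dup_{sid}") == "relatedness"


def test_run_qc_relatedness_removes_duplicate(default_cohort):
    """With the PCA stage disabled (a twin pair can register as its own
    principal axis on a small panel), the duplicate must fall to the IBD
    filter: equal call rates, so the lexicographically larger id goes."""
    ds = default_cohort[0]
    sid = ds.samples["sample_id"].iloc[8]
    out, _ = implant_artifacts(
        ds, [{"kind": "duplicate_sample", "source": sid, "flip_prob": 0.0}], seed=8
    )
    cleaned, report = run_qc(out, skip_pca_outliers=True)
    assert report.sample_reasons().get(f"dup_{sid}") == "relatedness"
    assert sid in cleaned.samples["sample_id"].tolist()


def test_run_qc_stage_counts_monotone(default_cohort):
    ds = default_cohort[0]
    _, report = run_qc(ds)
    for row in report.stage_counts:
        assert row["samples_after"] <= row["samples_before"]
        assert row["markers_after"] <= row["markers_before"]
    frames = report.to_frames()
    assert list(frames[2]["stage"])[0] == "sample_call_rate"
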