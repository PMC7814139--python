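"""Set-based association: annotation, greedy selection, permutation EMP1."""

import numpy as np
import pandas as pd
import pytest

from pathgwas.datasets import GeneModel, GeneSetCollection
from pathgwas.sba import (
    SbaParams,
    SetBasedAssociation,
    _exhaustive_matrix,
    _pearson_r2,
    _set_stats,
    _set_stats_python,
    assign_snps_to_genes,
    bonferroni_threshold,
    leave_out_retest,
    sba_maxt,
    sba_test,
    select_independent_top,
    set_snp_index,
    set_statistic,
)


def _variants(bps, chrom="1"):
    return pd.DataFrame(
        dict(
            chrom=[chrom] * len(bps),
            rsid=[f"rs{i:03d}" for i in range(len(bps))],
            bp=list(bps),
            a1=["A"] * len(bps),
            a2=["G"] * len(bps),
        )
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------
def test_window_boundary_inclusive():
    v = _variants([90_000, 100_000, 150_000, 160_000, 170_001])
    gene = GeneModel(1, "1", 100_000, 160_000, "G1")
    got = assign_snps_to_genes(v, [gene], window_kb=10.0)
    # start-10kb = 90_000 included; end+10kb = 170_000, so 170_001 excluded
    assert got[1] == ["rs000", "rs001", "rs002", "rs003"]
    zero = assign_snps_to_genes(v, [gene], window_kb=0.0)
    assert zero[1] == ["rs001", "rs002", "rs003"]


def test_assignment_respects_chromosome():
    v = _variants([100_000])
    gene = GeneModel(1, "2", 90_000, 110_000, "G1")
    assert assign_snps_to_genes(v, [gene])[1] == []


def test_set_snp_index_union_dedup():
    gene_map = {1: ["rsA", "rsB"], 2: ["rsB", "rsC"], 3: []}
    coll = GeneSetCollection()
    coll.add("s1", [1, 2])
    coll.add("s2", [3])
    idx = set_snp_index(gene_map, coll)
    assert idx["s1"] == ["rsA", "rsB", "rsC"]
    assert idx["s2"] == []


# ---------------------------------------------------------------------------
# greedy selection against a brute-force oracle
# ---------------------------------------------------------------------------
def greedy_oracle(snps, p, g, bp, set_p, set_r2, set_max):
    """Direct restatement of the selection rule with plain python."""
    r2 = np.corrcoef(g.T) ** 2
    order = sorted(range(len(snps)), key=lambda i: (p[i], bp[i], snps[i]))
    chosen = []
    for i in order:
        if p[i] >= set_p:
            continue
        if all(r2[i, j] < set_r2 for j in chosen):
            chosen.append(i)
        if len(chosen) == set_max:
            break
    return [snps[i] for i in chosen]


def test_greedy_selection_matches_oracle_random():
    rng = np.random.default_rng(31)
    params = SbaParams(set_p=0.3, set_r2=0.5, set_max=3)
    for _ in range(40):
        k = int(rng.integers(2, 11))
        g = rng.integers(0, 3, size=(60, k)).astype(float)
        # inject some near-duplicate columns to exercise the r^2 veto
        if k >= 4:
            g[:, 1] = g[:, 0]
            g[:, 3] = 2 - g[:, 2]
        g += rng.normal(0, 1e-6, g.shape)  # break exact monomorphism
        p = np.round(rng.random(k), 2)  # rounded to force ties
        bp = rng.integers(1, 1_000_000, k)
        snps = [f"rs{i}" for i in range(k)]
        got = select_independent_top(snps, p, g, params, bp=bp)
        want = greedy_oracle(snps, p, g, bp, params.set_p, params.set_r2,
                             params.set_max)
        assert got == want


def test_greedy_cap_and_threshold():
    params = SbaParams(set_p=0.05, set_max=2)
    rng = np.random.default_rng(32)
    g = rng.integers(0, 3, size=(50, 5)).astype(float) + rng.normal(0, 1e-6, (50, 5))
    p = np.array([0.01, 0.02, 0.03, 0.2, 0.9])
    got = select_independent_top([f"r{i}" for i in range(5)], p, g, params)
    assert got == ["r0", "r1"]  # capped at set_max, sub-threshold only
    none = select_independent_top(
        [f"r{i}" for i in range(5)], np.full(5, 0.5), g, params
    )
    assert none == []


def test_set_statistic_and_bonferroni():
    assert set_statistic([]) is None
    assert set_statistic([0.01, 0.03]) == pytest.approx(0.02)
    assert bonferroni_threshold(45) == pytest.approx(0.05 / 45)
    assert bonferroni_threshold(45) == pytest.approx(1.1e-3, rel=0.02)
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


# ---------------------------------------------------------------------------
# permutation kernels
# ---------------------------------------------------------------------------
def test_kernel_python_vs_dispatch():
    rng = np.random.default_rng(33)
    k = 7
    a = rng.random((k, k))
    r2 = np.clip((a + a.T) / 2, 0, 1)
    np.fill_diagonal(r2, 1.0)
    P = rng.random((50, k))
    V = rng.random((50, k))
    for Vv in (None, V):
        ref = _set_stats_python(P, r2, 0.3, 0.5, 3, Vv)
        got = _set_stats(P, r2, 0.3, 0.5, 3, Vv)
        assert got == pytest.approx(ref, rel=1e-12)
    # no candidate below threshold -> sentinel statistic 1.0
    assert _set_stats(np.full((3, k), 0.9), r2, 0.05, 0.5, 3)[0] == 1.0


def test_exhaustive_matrix_properties():
    y = np.array([1.0, 1, 0, 0, 0])
    Y = _exhaustive_matrix(y)
    assert Y.shape == (5, 10)
    assert np.all(Y.sum(axis=0) == 2)
    assert len({tuple(col) for col in Y.T}) == 10
    with pytest.raises(ValueError, match="too many"):
        _exhaustive_matrix(np.repeat([1.0, 0.0], 15))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def sba_fit(small_cohort):
    ds, genes, coll, _ = small_cohort
    params = SbaParams(n_perm=200, seed=5)
    est = SetBasedAssociation(params=params, maxt=True)
    est.fit(ds, collection=coll, genes=genes)
    return est


def test_results_table_shape_and_bounds(sba_fit, small_cohort):
    coll = small_cohort[2]
    tab = sba_fit.results_
    assert set(tab["SET"]) == set(coll.names())
    assert ((tab["EMP1"] > 0) & (tab["EMP1"] <= 1)).all()
    assert (tab["ISIG"] <= tab["NSIG"]).all()
    assert (tab["ISIG"] <= 5).all()
    assert tab["EMP1"].is_monotonic_increasing


def test_emp1_recomputed_from_perm_stats(sba_fit):
    R = sba_fit.n_perm_used_
    for si, name in enumerate(sba_fit.perm_stat_sets_):
        b = int(np.sum(sba_fit.perm_stats_[si] <= sba_fit.obs_cmp_[name]))
        assert sba_fit.set_results_[name].emp1 == pytest.approx((1 + b) / (R + 1))


def test_maxt_dominates_emp1(sba_fit):
    for res in sba_fit.set_results_.values():
        assert res.emp2 >= res.emp1


def test_maxt_single_set_reduces_to_emp1(small_cohort):
    ds, genes, coll, _ = small_cohort
    name = coll.names()[0]
    single = GeneSetCollection({name: list(coll[name])})
    res = sba_maxt(ds, single, genes=genes, params=SbaParams(n_perm=150, seed=6))
    assert res[name].emp2 == pytest.approx(res[name].emp1)


def test_deterministic_given_seed(small_cohort):
    ds, genes, coll, _ = small_cohort
    p = SbaParams(n_perm=150, seed=9)
    a = sba_test(ds, coll, genes=genes, params=p)
    b = sba_test(ds, coll, genes=genes, params=p)
    for name in a:
        assert a[name].emp1 == b[name].emp1 and a[name].stat == b[name].stat


def test_top_table_columns(sba_fit):
    for res in sba_fit.set_results_.values():
        assert list(res.top_snps.columns) == [
            "SNP", "CHR", "BP", "A1", "A2", "F_A", "F_U", "P", "OR",
        ]
        assert len(res.top_snps) == res.isig


def test_empty_set_sentinel(small_cohort):
    ds, genes, coll, _ = small_cohort
    coll2 = GeneSetCollection({"real": list(coll[coll.names()[0]]),
                               "ghost": [999_999]})
    res = sba_test(ds, coll2, genes=genes, params=SbaParams(n_perm=150, seed=2))
    ghost = res["ghost"]
    assert ghost.n_snps == 0 and ghost.stat is None and ghost.isig == 0
    assert ghost.emp1 == 1.0


def test_n_perm_warning(small_cohort):
    ds, genes, coll, _ = small_cohort
    with pytest.warns(UserWarning, match="Bonferroni"):
        sba_test(ds, coll, genes=genes, params=SbaParams(n_perm=50, seed=1))


def test_params_validate():
    with pytest.raises(ValueError):
        SbaParams(window_kb=-1).validate()
    with pytest.raises(ValueError):
        SbaParams(set_p=0.0).validate()
    with pytest.raises(ValueError):
        SbaParams(n_perm=0).validate()
    with pytest.raises(ValueError):
        SbaParams(statistic="median_p").validate()


def test_mean_chisq_mode(small_cohort):
    ds, genes, coll, _ = small_cohort
    res = sba_test(ds, coll, genes=genes,
                   params=SbaParams(n_perm=150, seed=3, statistic="mean_chisq"))
    for r in res.values():
        assert 0 < r.emp1 <= 1


# ---------------------------------------------------------------------------
# leave-out retest
# ---------------------------------------------------------------------------
def test_leave_out_nothing_reproduces_fit(small_cohort):
    ds, genes, coll, _ = small_cohort
    name = coll.names()[1]
    p = SbaParams(n_perm=150, seed=4)
    full = sba_test(ds, GeneSetCollection({name: list(coll[name])}),
                    genes=genes, params=p)[name]
    again = leave_out_retest(ds, coll, name, genes=genes, params=p)
    assert again.emp1 == full.emp1 and again.stat == full.stat


def test_leave_out_drop_snp_changes_selection(small_cohort, sba_fit):
    ds, genes, coll, _ = small_cohort
    # pick a set that actually selected SNPs (selection is permutation-free)
    name = next(n for n, r in sba_fit.set_results_.items() if r.isig > 0)
    p = SbaParams(n_perm=150, seed=4)
    base = leave_out_retest(ds, coll, name, genes=genes, params=p)
    assert base.isig > 0
    top = base.top_snps["SNP"].iloc[0]
    dropped = leave_out_retest(ds, coll, name, drop_snps=[top], genes=genes,
                               params=p)
    assert top not in set(dropped.top_snps["SNP"])
    assert dropped.n_snps == base.n_snps - 1


def test_leave_out_errors(small_cohort):
    ds, genes, coll, _ = small_cohort
    with pytest.raises(KeyError):
        leave_out_retest(ds, coll, "no_such_set", genes=genes)
    with pytest.raises(ValueError, match="not in set"):
        leave_out_retest(ds, coll, coll.names()[0], drop_genes=[10**9],
                         genes=genes)


# ---------------------------------------------------------------------------
# exhaustive mode on a tiny cohort
# ---------------------------------------------------------------------------
def test_exhaustive_mode_emp1_includes_observed(small_cohort):
    genes = small_cohort[1]
    full = small_cohort[0]
    rows = np.concatenate([np.flatnonzero(full.is_case)[:4],
                           np.flatnonzero(full.is_control)[:4]])
    ds = full.take_samples(rows)
    coll = GeneSetCollection({"s": [genes[0].gene_id, genes[1].gene_id]})
    res = sba_test(ds, coll, genes=genes, params=SbaParams(n_perm=1, seed=0),
                   perm="exhaustive")["s"]
    # the observed assignment is one of the 70 enumerated ones, so b >= 1
    # whenever a statistic exists, and EMP1 = b/70 is a multiple of 1/70
    assert res.emp1 * 70 == pytest.approx(round(res.emp1 * 70))
    if res.stat is not None:
        assert res.emp1 >= 1 / 70
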