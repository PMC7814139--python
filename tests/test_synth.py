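"""Generator properties: determinism, structure, truth bookkeeping, artifacts."""

import numpy as np
import pytest

from pathgwas.datasets import CASE, CONTROL, MISSING
from pathgwas.synth import (
    SimConfig,
    implant_artifacts,
    make_null_set_landscape,
    simulate_cohort,
)


SMALL = dict(n_cases=80, n_controls=80, n_blocks=6, block_size=20,
             genes_per_block=4, n_sets=6)


def test_determinism_same_seed():
    a = simulate_cohort(SimConfig(**SMALL, seed=3))
    b = simulate_cohort(SimConfig(**SMALL, seed=3))
    assert a[0].equals(b[0])
    assert a[3].causal_effects == b[3].causal_effects


def test_different_seed_differs():
    a = simulate_cohort(SimConfig(**SMALL, seed=3))
    b = simulate_cohort(SimConfig(**SMALL, seed=4))
    assert not a[0].equals(b[0])


def test_shapes_and_partition():
    cfg = SimConfig(**SMALL, seed=5)
    ds, genes, coll, truth = simulate_cohort(cfg)
    assert ds.n_samples == 160
    assert ds.n_variants == cfg.n_blocks * cfg.block_size
    assert len(genes) == cfg.n_blocks * cfg.genes_per_block
    # sets partition the gene universe: disjoint and covering
    seen = []
    for name in coll.names():
        seen.extend(coll[name])
    assert len(seen) == len(set(seen)) == len(genes)
    assert int(ds.is_case.sum()) == 80 and int(ds.is_control.sum()) == 80


def test_null_cohort_label_independence():
    """With no causal effects the labels are a pure permutation."""
    ds, *_ = simulate_cohort(SimConfig(**SMALL, seed=6))
    assert set(ds.phenotype.tolist()) == {CASE, CONTROL}
    f = ds.allele_frequencies()
    ok = np.isfinite(f)
    assert np.all((f[ok] >= 0) & (f[ok] <= 1))


def test_ld_within_blocks_exceeds_between():
    """Founder-mosaic LD: adjacent same-block r^2 beats cross-block r^2 on
    average (the amplitude scales like 1/n_founders, so pool many pairs)."""
    cfg = SimConfig(n_cases=250, n_controls=250, n_blocks=6, block_size=20,
                    genes_per_block=4, n_sets=6, seed=7)
    ds, *_ = simulate_cohort(cfg)
    g = ds.genotypes.astype(float)
    bs = cfg.block_size
    within, between = [], []
    for b in range(cfg.n_blocks - 1):
        for k in range(bs - 1):
            j = b * bs + k
            if g[:, [j, j + 1, j + bs]].std(axis=0).min() == 0:
                continue  # monomorphic column: correlation undefined
            within.append(np.corrcoef(g[:, j], g[:, j + 1])[0, 1] ** 2)
            between.append(np.corrcoef(g[:, j], g[:, j + bs])[0, 1] ** 2)
    assert len(within) > 30
    assert np.mean(within) > 5 * np.mean(between)
    assert np.mean(between) < 0.02


def test_causal_snps_live_in_enriched_set_genes():
    cfg = SimConfig(**SMALL, seed=8, causal_sets=[("set03", 2, 1.6)])
    ds, genes, coll, truth = simulate_cohort(cfg)
    assert truth.enriched_set_names == ["set03"]
    assert len(truth.causal_effects) == 2
    assert all(b == pytest.approx(np.log(1.6)) for b in truth.causal_effects.values())
    members = set(coll["set03"])
    vi = ds.variants.set_index("rsid")
    for rs in truth.causal_rsids:
        bp = int(vi.loc[rs, "bp"])
        hits = [g.gene_id for g in genes
                if g.gene_id in members and g.start <= bp <= g.end]
        assert hits, f"causal SNP {rs} not inside any set03 gene body"


def test_causal_cohort_exact_counts():
    cfg = SimConfig(**SMALL, seed=9, causal_sets=[("set01", 1, 1.5)])
    ds, *_ = simulate_cohort(cfg)
    assert int(ds.is_case.sum()) == 80 and int(ds.is_control.sum()) == 80


def test_pop_counts_respected():
    cfg = SimConfig(**SMALL, seed=10, n_pops=2, pop_counts=[100, 60])
    ds, _, _, truth = simulate_cohort(cfg)
    assert np.bincount(truth.pop_label).tolist() == [100, 60]


def test_validate_errors():
    with pytest.raises(ValueError):
        SimConfig(n_cases=0).validate()
    with pytest.raises(ValueError):
        SimConfig(baseline_prevalence=0.0).validate()
    with pytest.raises(ValueError):
        SimConfig(causal_sets=[("s", 1, -2.0)]).validate()
    with pytest.raises(ValueError):
        SimConfig(fst=1.5).validate()


def test_make_null_set_landscape():
    coll = make_null_set_landscape(list(range(100)), n_sets=7,
                                   size_range=(5, 12), seed=1)
    assert len(coll) == 7
    for name in coll.names():
        assert 5 <= len(coll[name]) <= 12
        assert len(set(coll[name])) == len(coll[name])
    with pytest.raises(ValueError):
        make_null_set_landscape(list(range(10)), 2, (5, 20), seed=1)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------
def test_empty_artifact_spec_is_identity(small_cohort):
    ds = small_cohort[0]
    out, truth = implant_artifacts(ds, [], seed=0)
    assert out.equals(ds)
    assert truth.planted_artifacts == []


def test_unknown_artifact_kind(small_cohort):
    with pytest.raises(ValueError, match="unknown artifact kind"):
        implant_artifacts(small_cohort[0], [{"kind": "nope"}], seed=0)


def test_duplicate_sample_artifact(small_cohort):
    ds = small_cohort[0]
    sid = ds.samples["sample_id"].iloc[0]
    out, truth = implant_artifacts(
        ds, [{"kind": "duplicate_sample", "source": sid, "flip_prob": 0.0}], seed=1
    )
    assert out.n_samples == ds.n_samples + 1
    assert truth.planted_artifacts == [("duplicate_sample", [sid, f"dup_{sid}"])]
    assert np.array_equal(out.genotypes[-1], ds.genotypes[0])


def test_marker_missingness_artifact(small_cohort):
    ds = small_cohort[0]
    rs = ds.variants["rsid"].iloc[5]
    out, truth = implant_artifacts(
        ds, [{"kind": "marker_missingness", "rsids": [rs], "rate": 0.5}], seed=2
    )
    j = int(out.variant_index([rs])[0])
    before = (ds.genotypes[:, j] == MISSING).mean()
    after = (out.genotypes[:, j] == MISSING).mean()
    assert after > before + 0.2


def test_hwe_violation_artifact(small_cohort):
    ds = small_cohort[0]
    rs = ds.variants["rsid"].iloc[3]
    out, _ = implant_artifacts(
        ds, [{"kind": "hwe_violation", "rsids": [rs], "het_prob": 0.95}], seed=3
    )
    j = int(out.variant_index([rs])[0])
    assert (out.genotypes[:, j] == 1).mean() > 0.8


def test_batch_association_artifact(small_cohort):
    ds = small_cohort[0]
    rs = ds.variants["rsid"].iloc[10]
    out, _ = implant_artifacts(
        ds,
        [{"kind": "batch_association", "rsids": [rs], "batch": "B1", "delta": 0.4}],
        seed=4,
    )
    j = int(out.variant_index([rs])[0])
    b1 = (out.samples["batch"] == "B1").to_numpy()
    g = out.genotypes[:, j].astype(float)

    def freq(rows):
        v = g[rows]
        v = v[v != MISSING]
        return v.mean() / 2

    assert freq(b1) > freq(~b1) + 0.15
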