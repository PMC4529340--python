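"""Cluster discovery and cross-cohort validation against planted truth,
plus exact-enumeration checks of the hypergeometric enrichment tail."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from transcohort import GeneSet, TranscohortError
from transcohort.clusters import (
    ClusterValidation,
    CorrelatedCluster,
    bidirectional_conservation,
    conservation_summary,
    discover_clusters,
    hypergeometric_enrichment,
    validate_cluster,
)
from transcohort.preprocess import iqr_filter

from conftest import make_dataset


def planted_two_modules(seed=0, n=120):
    """2 modules of 15 genes (loading 0.95) + 10 independent genes."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(2):
        f = rng.standard_normal(n)
        rows.append(0.95 * f[None, :] + 0.3 * rng.standard_normal((15, n)))
    rows.append(rng.standard_normal((10, n)))
    return make_dataset(np.vstack(rows))


def test_discovery_recovers_planted_modules_exactly():
    ds = planted_two_modules()
    clusters = discover_clusters(ds, corr_cut=0.6, min_size=10)
    assert len(clusters) == 2
    expect = [
        frozenset(f"g{i}" for i in range(15)),
        frozenset(f"g{i}" for i in range(15, 30)),
    ]
    assert {c.members for c in clusters} == set(expect)
    # deterministic naming by size then smallest member
    assert [c.id for c in clusters] == ["C1", "C2"]


def test_duplicate_rows_always_co_cluster():
    rng = np.random.default_rng(1)
    base = rng.standard_normal(50)
    X = np.vstack([base, base, rng.standard_normal((10, 50))])
    ds = make_dataset(X)
    clusters = discover_clusters(ds, corr_cut=0.99, min_size=2)
    pair = frozenset({"g0", "g1"})
    assert any(pair <= c.members for c in clusters)


def test_independent_features_yield_no_clusters():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.standard_normal((100, 80)))
    assert discover_clusters(ds, corr_cut=0.6, min_size=10) == []


def test_constant_feature_raises():
    X = np.vstack([np.ones(30), np.random.default_rng(0).standard_normal((3, 30))])
    with pytest.raises(TranscohortError, match="g0"):
        discover_clusters(make_dataset(X), 0.6, 2)


def test_corr_cut_bounds():
    ds = planted_two_modules()
    with pytest.raises(TranscohortError):
        discover_clusters(ds, corr_cut=1.5, min_size=10)


def test_self_validation_confirms_all_members():
    ds = planted_two_modules()
    clusters = discover_clusters(ds, 0.6, 10)
    for c in clusters:
        v = validate_cluster(c, ds)
        assert v.n_confirmed == len(c.members)
        assert v.validated


def test_validation_fails_on_independent_data():
    ds = planted_two_modules(seed=3)
    clusters = discover_clusters(ds, 0.6, 10)
    rng = np.random.default_rng(4)
    noise = make_dataset(rng.standard_normal(ds.values.shape))
    v = validate_cluster(clusters[0], noise)
    assert v.n_confirmed < 3
    assert not v.validated


def test_spurious_validation_rate_under_null():
    """Random 10-member clusters validate in independent data <=5% of the time."""
    rng = np.random.default_rng(5)
    n, n_feat = 100, 1000
    ds_b = make_dataset(rng.standard_normal((n_feat, n)))
    feats = np.array(ds_b.feature_ids)
    spurious = 0
    reps = 200
    for i in range(reps):
        members = frozenset(rng.choice(feats, size=10, replace=False))
        c = CorrelatedCluster(f"N{i}", members, "null", 0.6, 10)
        if validate_cluster(c, ds_b).validated:
            spurious += 1
    assert spurious / reps <= 0.05


def test_conservation_summary_perfect_and_degenerate():
    clusters = [
        CorrelatedCluster(f"C{i}", frozenset(f"g{j}" for j in range(10 + i)),
                          "A", 0.6, 10)
        for i in range(4)
    ]
    pairs = [(c, ClusterValidation(c.id, len(c.members), 3)) for c in clusters]
    s = conservation_summary(pairs)
    assert s["fraction"] == 1.0
    assert s["size_pearson_r"] == pytest.approx(1.0)
    with pytest.raises(TranscohortError):
        conservation_summary([])
    # <3 validated pairs: correlation undefined
    s2 = conservation_summary(pairs[:2])
    assert np.isnan(s2["size_pearson_r"])


def test_shared_modules_validate_across_cohorts(sim_pair):
    """10 shared + 2 private planted modules: fraction >= 10/12 - slack."""
    cfg, ds_a, ds_b, truth = sim_pair
    fa = iqr_filter(ds_a, 0.4)
    fb = ds_b.subset_features(fa.feature_ids)
    clusters = discover_clusters(fa, 0.6, 10)
    pairs = [(c, validate_cluster(c, fb)) for c in clusters]
    s = conservation_summary(pairs)
    assert s["fraction"] >= 10 / 12 - 0.1
    # every shared planted module of size >= 10 is recovered and validated
    shared_mods = [m for m in truth.shared_modules if cfg.modules[m].size >= 10]
    recovered = 0
    for m in shared_mods:
        genes = frozenset(g for g, mm in truth.module_membership.items() if mm == m)
        hit = [
            (c, v) for (c, v) in pairs
            if len(c.members & genes) / len(c.members | genes) >= 0.9
        ]
        if hit and hit[0][1].validated:
            recovered += 1
    assert recovered >= 0.9 * len(shared_mods)


def test_bidirectional_identical_datasets(sim_pair):
    _, ds_a, _, _ = sim_pair
    fa = iqr_filter(ds_a.subset_features(ds_a.feature_ids[:600]), 0.4)
    report = bidirectional_conservation(fa, fa, 0.6, 10)
    assert report["A_to_B"]["fraction"] == 1.0
    assert report["B_to_A"]["fraction"] == 1.0


def hypergeom_tail_enumeration(N, K, n, k):
    """Independent oracle: exact upper-tail sum of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(n, K) + 1)) / total


def test_hypergeometric_matches_enumeration_small_universes():
    for N in range(4, 13):
        universe = [f"u{i}" for i in range(N)]
        for K in (1, N // 3, N // 2):
            if K == 0:
                continue
            gs = GeneSet("S", "", frozenset(universe[:K]))
            for n in (1, N // 2, N - 1):
                members = universe[N - n:]
                k = len(set(members) & gs.members)
                res = hypergeometric_enrichment(members, gs, universe)
                assert res.p == pytest.approx(
                    hypergeom_tail_enumeration(N, K, n, k), abs=1e-12)


def test_hypergeometric_worked_example():
    universe = [f"u{i}" for i in range(20)]
    gs = GeneSet("S", "", frozenset(universe[:5]))
    members = universe[:4] + universe[10:12]  # n=6, k=4
    res = hypergeometric_enrichment(members, gs, universe)
    assert res.p == pytest.approx(0.013931888544891, rel=1e-9)


def test_hypergeometric_boundaries():
    universe = [f"u{i}" for i in range(12)]
    gs = GeneSet("S", "", frozenset(universe[:4]))
    # zero overlap: upper tail from 0 includes all mass
    res = hypergeometric_enrichment(universe[6:10], gs, universe)
    assert res.p == pytest.approx(
        hypergeom_tail_enumeration(12, 4, 4, res.overlap), abs=1e-12)
    with pytest.raises(TranscohortError):
        hypergeometric_enrichment(["a"], gs, [])


def test_within_cluster_merges_below_cut_height():
    """Every within-cluster pair joins the tree at height <= 1 - corr_cut."""
    from scipy.cluster.hierarchy import linkage, cophenet
    from scipy.spatial.distance import pdist

    ds = planted_two_modules(seed=6)
    cut = 0.6
    clusters = discover_clusters(ds, cut, 10)
    d = pdist(ds.values.to_numpy(), metric="correlation")
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    idx = {f: i for i, f in enumerate(ds.feature_ids)}
    m = len(ds.feature_ids)

    def cophenetic(i, j):
        a, b = sorted((i, j))
        return coph[m * a + b - ((a + 2) * (a + 1)) // 2]

    for c in clusters:
        for f1, f2 in combinations(sorted(c.members), 2):
            assert cophenetic(idx[f1], idx[f2]) <= 1 - cut + 1e-12
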