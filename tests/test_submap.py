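"""Subclass mapping: SNR ranking, weighted-KS enrichment calibration, and
association matrices on planted, identity and permuted-label data."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from transcohort import TranscohortError
from transcohort.submap import enrichment_pvalue, snr_marker_ranking, submap

from conftest import make_dataset


def labeled_dataset(seed=0, n_per=20, n_feat=600, shift=2.0):
    """Four groups; first 10 features mark each group in turn."""
    rng = np.random.default_rng(seed)
    labels = {}
    X = rng.standard_normal((n_feat, 4 * n_per))
    for g in range(4):
        cols = slice(g * n_per, (g + 1) * n_per)
        X[g * 10:(g + 1) * 10, cols] += shift
        for j in range(g * n_per, (g + 1) * n_per):
            labels[f"s{j}"] = f"G{g}"
    return make_dataset(X), labels


def test_snr_zero_for_equal_groups():
    """Features with identical in/out means and sds score exactly zero."""
    vals = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 2))
    ds = make_dataset(vals)
    labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(ds.sample_ids)}
    r = snr_marker_ranking(ds, labels, "A")
    assert np.allclose(r.to_numpy(), 0.0)


def test_snr_planted_marker_ranks_top_decile():
    ds, labels = labeled_dataset(seed=1)
    r = snr_marker_ranking(ds, labels, "G0")
    top = set(r.index[: len(r) // 10])
    planted = {f"g{i}" for i in range(10)}
    assert len(planted & top) >= 9


def test_snr_feature_order_invariance():
    ds, labels = labeled_dataset(seed=2)
    r1 = snr_marker_ranking(ds, labels, "G1")
    rng = np.random.default_rng(3)
    perm = list(rng.permutation(ds.feature_ids))
    ds2 = ds.subset_features(perm)
    r2 = snr_marker_ranking(ds2, labels, "G1")
    assert r1.sort_index().round(12).equals(r2.sort_index().round(12))


def test_snr_rejects_tiny_class():
    ds, labels = labeled_dataset()
    labels = dict(labels)
    small = {s: ("T" if i < 2 else "rest") for i, s in enumerate(ds.sample_ids)}
    with pytest.raises(TranscohortError):
        snr_marker_ranking(ds, small, "T")


def test_enrichment_maximal_when_markers_top():
    rng = np.random.default_rng(4)
    scores = np.sort(rng.uniform(0.1, 3.0, 200))[::-1]
    ranked = pd.Series(scores, index=[f"g{i}" for i in range(200)])
    p = enrichment_pvalue(ranked, [f"g{i}" for i in range(10)], n_perm=200, seed=0)
    assert p <= 2 / 201


def test_enrichment_null_calibration():
    """Random marker sets reject at ~alpha under the gene-permutation null."""
    rng = np.random.default_rng(5)
    ranked = pd.Series(np.sort(rng.uniform(0.1, 3.0, 300))[::-1],
                       index=[f"g{i}" for i in range(300)])
    rejections = 0
    draws = 200
    for i in range(draws):
        markers = list(rng.choice(ranked.index, size=15, replace=False))
        if enrichment_pvalue(ranked, markers, n_perm=100, seed=i) < 0.05:
            rejections += 1
    rate = rejections / draws
    ci = 3 * np.sqrt(0.05 * 0.95 / draws)
    assert abs(rate - 0.05) <= ci + 0.01


def test_enrichment_small_instance_matches_enumeration():
    """8 features, 2 markers: permutation p converges to the exact placement p."""
    weights = np.array([8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    ranked = pd.Series(weights, index=[f"g{i}" for i in range(8)])
    markers = ["g0", "g2"]

    def es(positions):
        pos = np.sort(np.array(positions))
        w = weights[pos]
        cum = np.cumsum(w) / w.sum()
        dev = cum - (pos - np.arange(2)) / 6
        return dev.max()

    obs = es([0, 2])
    exact = sum(1 for c in combinations(range(8), 2) if es(list(c)) >= obs) / comb(8, 2)
    p_hat = enrichment_pvalue(ranked, markers, n_perm=20000, seed=1)
    assert p_hat == pytest.approx(exact, abs=0.02)


def test_enrichment_rejects_empty_or_missing():
    ranked = pd.Series([2.0, 1.0], index=["a", "b"])
    with pytest.raises(TranscohortError):
        enrichment_pvalue(ranked, [], 100, 0)
    with pytest.raises(TranscohortError):
        enrichment_pvalue(ranked, ["zzz"], 100, 0)


def test_submap_identity_diagonal_significant(subtype_only_pair):
    _, ds_a, _, truth = subtype_only_pair
    la = truth.subtype_labels["A"]
    am = submap(ds_a, la, ds_a, la, n_perm=500, seed=0)
    M = am.fdr.to_numpy()
    assert np.diag(M).max() < 0.05
    assert M[~np.eye(M.shape[0], dtype=bool)].min() > 0.05


def test_submap_deterministic(subtype_only_pair):
    _, ds_a, ds_b, truth = subtype_only_pair
    la, lb = truth.subtype_labels["A"], truth.subtype_labels["B"]
    m1 = submap(ds_a, la, ds_b, lb, n_perm=200, seed=3)
    m2 = submap(ds_a, la, ds_b, lb, n_perm=200, seed=3)
    pd.testing.assert_frame_equal(m1.fdr, m2.fdr)


def test_submap_cross_cohort_diagonal(subtype_only_pair):
    _, ds_a, ds_b, truth = subtype_only_pair
    la, lb = truth.subtype_labels["A"], truth.subtype_labels["B"]
    am = submap(ds_a, la, ds_b, lb, n_perm=500, seed=0)
    assert np.diag(am.fdr.to_numpy()).max() < 0.05


def test_submap_null_labels_rarely_significant(subtype_only_pair):
    """Permuted labels: no significant cell in >=95% of replicates."""
    _, ds_a, ds_b, truth = subtype_only_pair
    la, lb = truth.subtype_labels["A"], truth.subtype_labels["B"]
    keys, vals = list(lb.keys()), list(lb.values())
    hits = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        perm = {k: v for k, v in zip(keys, rng.permutation(vals))}
        am = submap(ds_a, la, ds_b, perm, n_perm=300, seed=rep)
        hits += am.fdr.to_numpy().min() < 0.05
    assert hits / reps <= 0.05


def test_submap_single_subclass_degenerate():
    rng = np.random.default_rng(6)
    ds = make_dataset(rng.standard_normal((600, 12)))
    labels = {s: "only" for s in ds.sample_ids}
    with pytest.raises(TranscohortError):
        # one subclass means no out-of-class samples for the SNR ranking
        submap(ds, labels, ds, labels, n_perm=100, seed=0)


def test_submap_transpose_decision_symmetry(subtype_only_pair):
    _, ds_a, ds_b, truth = subtype_only_pair
    la, lb = truth.subtype_labels["A"], truth.subtype_labels["B"]
    ab = submap(ds_a, la, ds_b, lb, n_perm=500, seed=1)
    ba = submap(ds_b, lb, ds_a, la, n_perm=500, seed=1)
    agree = ((ab.fdr < 0.05) == (ba.fdr.T < 0.05)).to_numpy()
    # approximate symmetry: at most one borderline cell may flip
    assert agree.sum() >= agree.size - 1


def test_submap_monotone_in_separation():
    """Greater planted separation never worsens the worst diagonal FDR."""
    from transcohort.synthetic import SimulationConfig, generate_cohort_pair

    worst = []
    for sep in (1.0, 2.0, 4.0):
        cfg = SimulationConfig(seed=21, subtype_separation=sep,
                               ecm3_block=(25, 25, 0.0), ecm1_block=(20, 20, 0.0))
        a, b, truth = generate_cohort_pair(cfg)
        am = submap(a, truth.subtype_labels["A"], b, truth.subtype_labels["B"],
                    n_perm=300, seed=2)
        worst.append(np.diag(am.fdr.to_numpy()).max())
    assert worst[0] >= worst[1] >= worst[2] or worst[1] <= 0.05
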