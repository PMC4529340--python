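"""Marker thresholding against analytic mixture minima, intrinsic-subtype
assignment against planted labels, IHC rules, and table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from transcohort import ExpressionDataset, TranscohortError
from transcohort.subtypes import (
    NonBimodalError,
    assign_claudin_low,
    assign_intrinsic_subtypes,
    bimodal_threshold,
    classify_marker_status,
    frequency_table,
    ihc_subtype,
    pca_group_separation,
    round_half_up_pct,
)

from conftest import make_dataset


def mixture_sample(rng, n, w=0.5, mu2=6.0):
    n1 = int(round(w * n))
    return np.concatenate([rng.normal(0, 1, n1), rng.normal(mu2, 1, n - n1)])


def test_threshold_symmetric_mixture_near_midpoint():
    rng = np.random.default_rng(0)
    x = mixture_sample(rng, 400)
    th = bimodal_threshold(x)
    assert 2.5 <= th.threshold <= 3.5


def test_threshold_weighted_mixture_vs_analytic_minimum():
    """Threshold within +/-0.5 of the true 0.7/0.3 mixture density minimum."""
    w, mu2 = 0.7, 6.0
    grid = np.linspace(1.0, 5.0, 20001)
    dens = w * norm.pdf(grid, 0, 1) + (1 - w) * norm.pdf(grid, mu2, 1)
    true_min = grid[np.argmin(dens)]
    rng = np.random.default_rng(1)
    x = mixture_sample(rng, 400, w=w, mu2=mu2)
    th = bimodal_threshold(x)
    assert abs(th.threshold - true_min) <= 0.5


def test_unimodal_raises_non_bimodal():
    rng = np.random.default_rng(2)
    with pytest.raises(NonBimodalError):
        bimodal_threshold(rng.normal(0, 1, 400), gene="X")


def test_threshold_needs_enough_values():
    with pytest.raises(TranscohortError):
        bimodal_threshold(np.arange(10.0))


def test_marker_calls_match_planted_status(sim_pair):
    _, ds_a, _, truth = sim_pair
    er = classify_marker_status(ds_a, "ESR1")
    truth_er = pd.Series(truth.er_status["A"])
    acc = (er == truth_er[er.index]).mean()
    assert acc >= 0.95
    erbb2 = classify_marker_status(ds_a, "ERBB2")
    truth_h = pd.Series({s: lab == "ERBB2"
                         for s, lab in truth.subtype_labels["A"].items()})
    assert (erbb2 == truth_h[erbb2.index]).mean() >= 0.95


def test_threshold_translation_equivariance(sim_pair):
    _, ds_a, _, _ = sim_pair
    x = ds_a.values.loc["ESR1"].to_numpy()
    t0 = bimodal_threshold(x).threshold
    t5 = bimodal_threshold(x + 5.0).threshold
    assert t5 == pytest.approx(t0 + 5.0, abs=1e-6)
    calls0 = x > t0
    calls5 = (x + 5.0) > t5
    assert (calls0 == calls5).all()


def test_intrinsic_assignment_recovers_planted_subtypes(sim_pair):
    _, ds_a, _, truth = sim_pair
    calls = assign_intrinsic_subtypes(ds_a)
    lab = {c.sample_id: c.intrinsic for c in calls}
    t = truth.subtype_labels["A"]
    agreement = np.mean([lab[s] == t[s] for s in t])
    assert agreement >= 0.95


def test_intrinsic_assignment_sample_order_invariance(sim_pair):
    _, ds_a, _, _ = sim_pair
    calls = assign_intrinsic_subtypes(ds_a)
    lab = {c.sample_id: c.intrinsic for c in calls}
    rng = np.random.default_rng(3)
    perm = list(rng.permutation(ds_a.sample_ids))
    shuffled = ds_a.subset_samples(perm)
    calls2 = assign_intrinsic_subtypes(shuffled)
    lab2 = {c.sample_id: c.intrinsic for c in calls2}
    assert lab == lab2


def test_intrinsic_assignment_shift_invariance(sim_pair):
    _, ds_a, _, _ = sim_pair
    calls = assign_intrinsic_subtypes(ds_a)
    shifted = ExpressionDataset(ds_a.values + 7.0, cohort=ds_a.cohort)
    calls2 = assign_intrinsic_subtypes(shifted)
    assert [c.intrinsic for c in calls] == [c.intrinsic for c in calls2]


def test_intrinsic_panel_coverage_floor(sim_pair):
    from transcohort.panels import PAM50_USABLE

    _, ds_a, _, _ = sim_pair
    dropped = set(PAM50_USABLE[:30])
    crippled = ds_a.subset_features(
        [g for g in ds_a.feature_ids if g not in dropped])
    with pytest.raises(TranscohortError, match="coverage"):
        assign_intrinsic_subtypes(crippled)


def test_claudin_low_rescues_planted_candidates(sim_pair):
    _, ds_a, _, truth = sim_pair
    planted = truth.claudin_low["A"]
    assert planted  # generator plants at least one
    high_claudin = [s for s in ds_a.sample_ids if s not in planted][:5]
    rescued = assign_claudin_low(ds_a, candidates=planted + high_claudin)
    assert set(rescued) == set(planted)
    assert assign_claudin_low(ds_a, candidates=[]) == []


def test_claudin_low_requires_panel_genes(sim_pair):
    _, ds_a, _, _ = sim_pair
    noclaudin = ds_a.subset_features(ds_a.feature_ids[-100:])
    with pytest.raises(TranscohortError):
        assign_claudin_low(noclaudin, candidates=ds_a.sample_ids[:3])


@pytest.mark.parametrize("er,pr,her2,expected", [
    (True, False, False, "LumHER2neg"),
    (True, True, False, "LumHER2neg"),
    (False, True, False, "LumHER2neg"),
    (True, False, True, "LumHER2pos"),
    (False, True, True, "LumHER2pos"),
    (True, True, True, "LumHER2pos"),
    (False, False, True, "HER2posERneg"),
    (False, False, False, "TripleNeg"),
])
def test_ihc_rules_total_and_exclusive(er, pr, her2, expected):
    assert ihc_subtype(er, pr, her2) == expected


def test_ihc_missing_status_gives_missing_class():
    assert ihc_subtype(True, None, False) is None


def test_frequency_table_reproduces_published_ratios():
    """Shanghai 21/23 of 78 -> 27%/29%, ratio 0.93; Singapore 25/38 -> 0.66."""
    def build(counts, n, cohort):
        calls, labels = {}, {}
        i = 0
        for lab, c in counts.items():
            for _ in range(c):
                s = f"{cohort}{i}"
                calls[s] = lab
                labels[s] = cohort
                i += 1
        for _ in range(n - i):
            s = f"{cohort}{i}"
            calls[s] = "Unclassified"
            labels[s] = cohort
            i += 1
        return calls, labels

    sh_calls, sh_lab = build(
        {"LumA": 21, "LumB": 23, "Basal": 10, "ERBB2": 17}, 78, "SH")
    tbl = frequency_table(sh_calls, sh_lab)
    assert tbl.loc["SH", "LumA_pct"] == 27
    assert tbl.loc["SH", "LumB_pct"] == 29
    assert tbl.loc["SH", "luminal_ratio"] == pytest.approx(0.93)

    sg_calls, sg_lab = build(
        {"LumA": 25, "LumB": 38, "Basal": 8, "ERBB2": 17}, 100, "SG")
    assert frequency_table(sg_calls, sg_lab).loc["SG", "luminal_ratio"] == \
        pytest.approx(0.66)

    tw_calls, tw_lab = build(
        {"LumA": 15, "LumB": 35, "Basal": 8, "ERBB2": 15}, 81, "TW")
    assert frequency_table(tw_calls, tw_lab).loc["TW", "luminal_ratio"] == \
        pytest.approx(0.44)


def test_frequency_table_counts_and_percentage_slack():
    calls = {f"s{i}": lab for i, lab in
             enumerate(["LumA"] * 3 + ["LumB"] * 3 + ["Basal"] * 1)}
    labels = {s: "X" for s in calls}
    tbl = frequency_table(calls, labels)
    count_cols = [c for c in tbl.columns if c.endswith("_count")]
    assert tbl.loc["X", count_cols].sum() == 7
    pct_cols = [c for c in tbl.columns if c.endswith("_pct")]
    assert abs(tbl.loc["X", pct_cols].sum() - 100) <= len(pct_cols)
    assert tbl.loc["X", "luminal_ratio"] == 1.0


def test_round_half_up():
    assert round_half_up_pct(15, 81) == 19   # 18.52 -> 19
    assert round_half_up_pct(5, 200) == 3    # 2.5 -> 3 (half-up)
    assert round_half_up_pct(663, 1057) == 63


def test_pca_silhouette_orders_subtype_above_cohort(subtype_only_pair):
    """Batch-free miRNA profiles: subtype labels separate better than cohort."""
    from transcohort.synthetic import generate_mirna_pair

    cfg, _, _, truth = subtype_only_pair
    mir_a, mir_b, _ = generate_mirna_pair(cfg, subtype_labels=truth.subtype_labels)
    merged = ExpressionDataset(pd.concat([mir_a.values, mir_b.values], axis=1))
    subtype = {**truth.subtype_labels["A"], **truth.subtype_labels["B"]}
    cohort = {s: s[0] for s in merged.sample_ids}
    _, sil_subtype, sil_cohort = pca_group_separation(merged, subtype, cohort)
    assert sil_subtype > sil_cohort


def test_pca_silhouette_extremes():
    rng = np.random.default_rng(4)
    X = np.vstack([
        np.concatenate([rng.normal(0, 0.05, 10), rng.normal(8, 0.05, 10)]),
        np.concatenate([rng.normal(0, 0.05, 10), rng.normal(8, 0.05, 10)]),
        rng.normal(0, 0.05, 20),
    ])
    ds = make_dataset(X)
    two_group = {s: ("L" if i < 10 else "R") for i, s in enumerate(ds.sample_ids)}
    random_lab = {s: ("L" if i % 2 == 0 else "R")
                  for i, s in enumerate(ds.sample_ids)}
    _, sil_good, sil_rand = pca_group_separation(ds, two_group, random_lab)
    assert sil_good > 0.9
    assert abs(sil_rand) < 0.3


def test_pca_degenerate_rank_errors():
    X = np.outer(np.arange(5.0), np.ones(6))
    with pytest.raises(TranscohortError):
        pca_group_separation(make_dataset(X),
                             {f"s{j}": "a" for j in range(6)},
                             {f"s{j}": "b" for j in range(6)})
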