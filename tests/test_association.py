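"""Blocked Wilcoxon, effect sizes, FDR, meta-analysis and progression calls.

Independent oracles live in this module: an exhaustive-permutation rank-sum
test, brute-force AUROC pair counting, and a direct Benjamini-Hochberg
step-up implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nafld_meta import (auroc_effect, bh_fdr, blocked_wilcoxon,
                        generalized_fold_change, make_blocks, partial_spearman,
                        progression_consistent, run_meta_analysis,
                        run_progression)
from nafld_meta.association import AssociationError


# ---------------------------------------------------------------------------
# Oracles


def oracle_blocked_exact_p(values, in_case, blocks):
    """Exhaustively enumerate within-block case assignments; two-sided p."""
    values = np.asarray(values, float)
    in_case = np.asarray(in_case, bool)
    blocks = np.asarray(blocks)
    per_block = []
    for b in pd.unique(blocks):
        sel = blocks == b
        cases = in_case[sel]
        if sel.sum() < 2 or cases.all() or not cases.any():
            continue
        ranks = stats.rankdata(values[sel])
        n, n1 = sel.sum(), cases.sum()
        obs = ranks[cases].sum() - n1 * (n + 1) / 2
        dist = [ranks[list(c)].sum() - n1 * (n + 1) / 2
                for c in itertools.combinations(range(n), n1)]
        per_block.append((obs, dist))
    t_obs = sum(o for o, _ in per_block)
    totals = [0.0]
    for _, dist in per_block:
        totals = [t + d for t in totals for d in dist]
    hits = sum(abs(t) >= abs(t_obs) - 1e-9 for t in totals)
    return t_obs, hits / len(totals)


def oracle_auroc(case, control):
    wins = sum((c > k) + 0.5 * (c == k) for c in case for k in control)
    return wins / (len(case) * len(control))


def oracle_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


# ---------------------------------------------------------------------------
# blocked_wilcoxon


def test_single_block_complete_separation_exact_p():
    """Groups {1,2,3} vs {4,5,6}: 2 extreme assignments of C(6,3)=20."""
    z, p = blocked_wilcoxon([1, 2, 3, 4, 5, 6],
                            [True, True, True, False, False, False],
                            np.zeros(6), mode="exact")
    assert p == pytest.approx(0.1)
    assert z < 0  # cases hold the low ranks


def test_identical_groups_give_null_statistic():
    values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0] * 2
    in_case = [True] * 3 + [False] * 3 + [True] * 3 + [False] * 3
    blocks = [0] * 6 + [1] * 6
    z, p = blocked_wilcoxon(values, in_case, blocks, mode="normal")
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_two_consistent_blocks_beat_either_alone():
    """Evidence accumulates: two separated blocks give smaller exact p."""
    one_block = blocked_wilcoxon([1, 2, 5, 6], [1, 1, 0, 0], [0] * 4,
                                 mode="exact")[1]
    two_blocks = blocked_wilcoxon([1, 2, 5, 6] * 2, [1, 1, 0, 0] * 2,
                                  [0] * 4 + [1] * 4, mode="exact")[1]
    assert two_blocks < one_block


@pytest.mark.parametrize("seed", range(12))
def test_exact_p_matches_enumeration_oracle(seed):
    """Random small instances (<=10 samples, 1-3 blocks, ties included)."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 11)
    values = rng.integers(0, 5, n).astype(float)  # coarse grid forces ties
    blocks = rng.integers(0, rng.integers(1, 4), n)
    in_case = rng.random(n) < 0.5
    # ensure at least one informative block
    for b in np.unique(blocks):
        sel = blocks == b
        if sel.sum() >= 2:
            idx = np.flatnonzero(sel)
            in_case[idx[0]], in_case[idx[1]] = True, False
            break
    z, p = blocked_wilcoxon(values, in_case, blocks, mode="exact")
    t_oracle, p_oracle = oracle_blocked_exact_p(values, in_case, blocks)
    assert p == pytest.approx(p_oracle)


def test_single_block_normal_mode_matches_tie_corrected_mann_whitney():
    rng = np.random.default_rng(3)
    values = rng.integers(0, 8, 40).astype(float)
    in_case = rng.random(40) < 0.5
    _, p = blocked_wilcoxon(values, in_case, np.zeros(40), mode="normal")
    ref = stats.mannwhitneyu(values[in_case], values[~in_case],
                             alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_no_informative_block_is_an_error():
    with pytest.raises(AssociationError, match="no within-block"):
        blocked_wilcoxon([1, 2, 3, 4], [True, True, False, False],
                         [0, 0, 1, 1])


# ---------------------------------------------------------------------------
# Effect sizes and FDR


def test_auroc_hand_example_and_brute_force(rng):
    auc, lo, hi = auroc_effect([3, 5], [1, 4])
    assert auc == pytest.approx(0.75)
    for _ in range(20):
        case = rng.normal(0.5, 1, rng.integers(2, 25))
        control = rng.normal(0, 1, rng.integers(2, 25))
        auc, lo, hi = auroc_effect(case, control)
        assert auc == pytest.approx(oracle_auroc(case, control))
        assert lo <= auc <= hi


def test_auroc_degenerate_cases():
    assert auroc_effect([5, 6], [1, 2])[0] == 1.0
    assert auroc_effect([1, 2, 3], [1, 2, 3])[0] == pytest.approx(0.5)
    with pytest.raises(AssociationError):
        auroc_effect([], [1.0])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
@settings(deadline=None, max_examples=60)
def test_bh_matches_step_up_oracle(pvals):
    np.testing.assert_allclose(bh_fdr(pvals), oracle_bh(pvals), atol=1e-12)


def test_bh_hand_example_and_degenerate_inputs():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    with pytest.raises(AssociationError):
        bh_fdr([0.5, 1.5])


def test_gfc_location_properties(rng):
    case = rng.normal(0, 1, 30)
    control = rng.normal(0, 1, 25)
    g0 = generalized_fold_change(case, control)
    assert generalized_fold_change(case, case) == pytest.approx(0.0)
    assert generalized_fold_change(case + 1.7, control + 1.7) == pytest.approx(g0)
    assert generalized_fold_change(case + 0.9, control) == pytest.approx(g0 + 0.9)
    assert generalized_fold_change(control, case) == pytest.approx(-g0)


# ---------------------------------------------------------------------------
# Blocks


def test_make_blocks_degenerate_modes(small_cohort):
    _, metadata, _ = small_cohort
    study_only = make_blocks(metadata, n_bmi_bins=1, include_study=True)
    assert set(study_only.str.split("|").str[0]) == set(metadata["study"])
    assert study_only.nunique() == metadata["study"].nunique()
    single = make_blocks(metadata, n_bmi_bins=1, include_study=False)
    assert single.nunique() == 1


def test_make_blocks_study_by_tertile_counts(small_cohort):
    _, metadata, _ = small_cohort
    blocks = make_blocks(metadata, n_bmi_bins=3)
    assert blocks.nunique() <= 9
    assert blocks.groupby(blocks).size().min() >= 1
    with pytest.raises(AssociationError):
        make_blocks(metadata, n_bmi_bins=0)


# ---------------------------------------------------------------------------
# Meta-analysis driver and progression


def test_meta_analysis_recovers_spiked_features(small_norm):
    norm, metadata, truth = small_norm
    assoc = run_meta_analysis(norm, metadata, contrasts=("meta",))
    merged = assoc.merge(truth.rename(columns={"direction": "true_dir"}),
                        on="feature_id")
    uniform = merged[merged["class"] == "stage_uniform"]
    hits = (uniform["q_value"] < 0.05) & \
           (np.sign(uniform["gfc"]) == uniform["true_dir"])
    assert hits.mean() >= 0.8
    # negatively spiked features are reported as control-enriched
    down = uniform[(uniform["true_dir"] < 0) & (uniform["q_value"] < 0.05)]
    assert (down["direction"] == "enriched_control").all()


def test_meta_analysis_null_cohort_controls_discoveries(null_cohort):
    from nafld_meta import fit_snm, log_cpm, to_cpm
    profile, metadata, _ = null_cohort
    norm = fit_snm(log_cpm(to_cpm(profile)), metadata)
    assoc = run_meta_analysis(norm, metadata, contrasts=("meta",))
    assert (assoc["q_value"] < 0.05).mean() <= 0.05


def test_meta_analysis_q_values_monotone_in_sorted_p(small_norm):
    norm, metadata, _ = small_norm
    assoc = run_meta_analysis(norm, metadata, contrasts=("meta", "NASH"))
    for _, grp in assoc.groupby("contrast"):
        g = grp.sort_values("p_value")
        assert (np.diff(g["q_value"]) >= -1e-12).all()
        assert (g["q_value"] <= 1).all()
    # AUROC direction consistency away from 0.5
    strong = assoc[np.abs(assoc["auroc"] - 0.5) > 0.05]
    assert (np.sign(strong["gfc"]) == np.sign(strong["auroc"] - 0.5)).all()


def test_partial_spearman_perfect_monotone_without_confounding():
    rho, p = partial_spearman([1, 2, 3, 4, 5], [0, 1, 2, 3, 4],
                              [25, 25, 25, 25, 25])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(0.0, abs=1e-9)


def test_partial_spearman_constant_feature_flagged():
    rho, p = partial_spearman([2, 2, 2, 2, 2], [0, 1, 2, 3, 4],
                              [22, 24, 26, 28, 30])
    assert rho == 0.0 and p == 1.0


def test_progression_calls_match_monotone_truth(small_norm):
    norm, metadata, truth = small_norm
    prog = run_progression(norm, metadata)
    merged = prog.merge(truth, on="feature_id")
    mono = merged[merged["class"] == "stage_monotone"]
    expected = np.where(mono["direction"] > 0, "correlated", "anti-correlated")
    assert (mono["call"] == expected).mean() >= 0.7
    # calls respect their definition
    assert (prog.loc[prog["call"] == "correlated", "rho_partial"] > 0).all()
    assert (prog.loc[prog["call"] == "correlated", "q_value"] < 0.05).all()


def test_progression_consistent_rules():
    rows = []
    for fid, qs, gs in [("both_up", (0.01, 0.01, 0.01), (1, 1, 1)),
                        ("nash_only", (0.01, 0.5, 0.5), (1, 1, 1)),
                        ("discordant", (0.01, 0.01, 0.01), (1, 1, -1))]:
        for stage, q, g in zip(("NASH", "fibrosis", "cirrhosis"), qs, gs):
            rows.append((fid, stage, q, g))
    assoc = pd.DataFrame(rows, columns=["feature_id", "contrast", "q_value", "gfc"])
    out = progression_consistent(assoc)
    assert list(out["feature_id"]) == ["both_up"]
    assert {"gfc_NASH", "gfc_fibrosis", "gfc_cirrhosis"} <= set(out.columns)
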