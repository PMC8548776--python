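"""log-cpm transform, SNM batch correction and rank-based confounder ANOVA."""

import numpy as np
import pandas as pd
import pytest

from nafld_meta import (STAGES, NormalizedMatrix, SynthConfig, confounder_anova,
                        fit_snm, generate_cohort, log_cpm, to_cpm)
from nafld_meta.normalization import NormalizationError, SNMNormalizer
from nafld_meta.profiles import ProfileTable


def test_log_cpm_closed_form_values():
    values = pd.DataFrame({"s1": [0.0, 3.0, 999997.0]}, index=list("abc"))
    out = log_cpm(ProfileTable(values, unit="cpm"))
    assert out.values.loc["a", "s1"] == 0.0       # log2(0 + 1)
    assert out.values.loc["b", "s1"] == 2.0       # log2(3 + 1)
    assert out.unit == "log_cpm"


def test_log_cpm_monotone_in_input(rng):
    x = np.sort(rng.uniform(0, 1e6, 50))
    values = pd.DataFrame({"s1": x}, index=[f"f{i}" for i in range(50)])
    out = log_cpm(ProfileTable(values, unit="cpm")).values["s1"].to_numpy()
    assert (np.diff(out) > 0).all()


def test_log_cpm_invariant_to_library_size(rng):
    props = rng.dirichlet(np.ones(20))
    a = ProfileTable(pd.DataFrame({"s": props * 1e3},
                                  index=[f"f{i}" for i in range(20)]))
    b = ProfileTable(pd.DataFrame({"s": props * 1e7},
                                  index=[f"f{i}" for i in range(20)]))
    pd.testing.assert_frame_equal(log_cpm(to_cpm(a)).values,
                                  log_cpm(to_cpm(b)).values)


def test_log_cpm_rejects_nonpositive_pseudocount(small_cohort):
    with pytest.raises(NormalizationError):
        log_cpm(to_cpm(small_cohort[0]), pseudocount=0.0)


# ---------------------------------------------------------------------------
# SNM


def batch_free_matrix(seed=31, n_features=60, per_stage=10):
    cfg = SynthConfig(n_features=n_features,
                      samples_per_study_per_stage={s: per_stage for s in STAGES},
                      batch_sd_log2=0.0, frac_bmi_linked=0.0, seed=seed)
    profile, metadata, truth = generate_cohort(cfg)
    return log_cpm(to_cpm(profile)), metadata, truth


def test_snm_without_batch_effect_only_recentres_per_study():
    """No batch signal: the correction reduces to a per-study/per-feature
    recentring of noise-level magnitude, never a per-sample rewrite."""
    matrix, metadata, _ = batch_free_matrix()
    out = fit_snm(matrix, metadata)
    delta = out.values - matrix.values
    within_study_var = delta.T.groupby(metadata["study"]).var()
    assert within_study_var.to_numpy().max() < 1e-12  # constant within study
    assert np.abs(delta.to_numpy()).mean() < 0.3      # and small overall


def test_snm_recovers_known_per_study_shifts():
    """Per-study +2/0/-2 shifts vanish: post-SNM study means agree within 0.1."""
    matrix, metadata, _ = batch_free_matrix(seed=5)
    shift = metadata["study"].map({"study1": 2.0, "study2": 0.0,
                                   "study3": -2.0}).to_numpy()
    shifted = NormalizedMatrix(matrix.values + shift[None, :], unit="log_cpm")
    out = fit_snm(shifted, metadata)
    by_study = out.values.T.groupby(metadata["study"]).mean()  # study x feature
    spread = by_study.max(axis=0) - by_study.min(axis=0)
    assert spread.mean() < 0.1


def test_snm_preserves_spiked_stage_signal():
    """Case-control mean difference of spiked features survives correction."""
    cfg = SynthConfig(n_features=80,
                      samples_per_study_per_stage={s: 12 for s in STAGES},
                      effect_size_log2=2.0, batch_sd_log2=1.0,
                      frac_stage_monotone_diff=0.0, frac_bmi_linked=0.0,
                      dispersion=0.1, seed=41)
    profile, metadata, truth = generate_cohort(cfg)
    out = fit_snm(log_cpm(to_cpm(profile)), metadata)
    is_case = (metadata["stage"] != "HC").to_numpy()
    spiked = truth.loc[truth["class"] == "stage_uniform"]
    diffs = []
    for _, row in spiked.iterrows():
        x = out.values.loc[row["feature_id"]].to_numpy()
        diffs.append((x[is_case].mean() - x[~is_case].mean()) * row["direction"])
    assert abs(np.mean(diffs) - 2.0) < 0.25


def test_snm_requires_log_scale_and_enough_samples(small_cohort):
    profile, metadata, _ = small_cohort
    with pytest.raises(NormalizationError, match="log_cpm"):
        fit_snm(NormalizedMatrix(to_cpm(profile).values.pipe(np.log1p),
                                 unit="normalized"), metadata)


def test_snm_warns_on_confounded_design(rng):
    """A study holding a single stage triggers the singularity warning path."""
    n = 30
    X = rng.normal(0, 1, (n, 5))
    stage = np.r_[["HC"] * 10, ["NASH"] * 10, ["cirrhosis"] * 10]
    study = np.r_[["s1"] * 10, ["s1"] * 10, ["s2"] * 10]  # s2 = cirrhosis only
    with pytest.warns(UserWarning, match="confounded"):
        SNMNormalizer().fit(X, biological=stage, adjustment=study)


def test_snm_transformer_round_trip_orientation(small_cohort):
    """Estimator API: samples x features in, same shape out, finite values."""
    profile, metadata, _ = small_cohort
    matrix = log_cpm(to_cpm(profile))
    est = SNMNormalizer()
    out = est.fit_transform(matrix.values.to_numpy().T,
                            biological=metadata["stage"],
                            adjustment=metadata["study"])
    assert out.shape == matrix.values.T.shape
    assert np.isfinite(out).all()
    assert est.n_iter_ >= 1 and est.weights_.shape == (profile.shape[0],)


# ---------------------------------------------------------------------------
# Confounder ANOVA


def make_norm(frame):
    return NormalizedMatrix(frame, unit="normalized")


def meta_frame(n, rng, stage_levels=5):
    stages = np.array(STAGES)[np.arange(n) % stage_levels]
    return pd.DataFrame({
        "study": np.array(["study1", "study2", "study3"])[np.arange(n) % 3],
        "stage": pd.Categorical(stages, categories=list(STAGES), ordered=True),
        "bmi": rng.normal(27, 3, n),
        "age": rng.normal(50, 10, n),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
    }, index=[f"s{i}" for i in range(n)])


def test_stage_deterministic_feature_attributes_to_stage(rng):
    meta = meta_frame(100, rng)
    stage_rank = meta["stage"].cat.codes.to_numpy(float)
    frame = pd.DataFrame([stage_rank * 2.0], index=["f0"], columns=meta.index)
    out = confounder_anova(make_norm(frame), meta)
    # type-II: stage fraction is 1 - R^2 of the chance overlap with the
    # other covariates, so just under 1 for a saturated stage effect
    assert out.loc["f0", "stage"] >= 0.95
    assert out.loc["f0", ["bmi", "age", "sex", "study"]].max() < 0.01


def test_noise_features_have_small_stage_fractions(rng):
    meta = meta_frame(90, rng)
    frame = pd.DataFrame(rng.normal(0, 1, (200, 90)),
                         index=[f"f{i}" for i in range(200)], columns=meta.index)
    out = confounder_anova(make_norm(frame), meta)
    assert out["stage"].mean() < 0.05


def test_bmi_feature_under_stage_correlated_bmi_attributes_to_bmi(rng):
    """Type-II adjustment: a pure-BMI feature loads on BMI, not stage."""
    n = 120
    meta = meta_frame(n, rng)
    stage_rank = meta["stage"].cat.codes.to_numpy(float)
    meta["bmi"] = 24 + 2 * stage_rank + rng.normal(0, 1.5, n)
    frame = pd.DataFrame([meta["bmi"].to_numpy()], index=["f0"],
                         columns=meta.index)
    out = confounder_anova(make_norm(frame), meta)
    assert out.loc["f0", "bmi"] > out.loc["f0", "stage"]


def test_constant_feature_flagged_with_zero_fractions(rng):
    meta = meta_frame(40, rng)
    frame = pd.DataFrame([np.ones(40)], index=["f0"], columns=meta.index)
    out = confounder_anova(make_norm(frame), meta)
    assert bool(out.loc["f0", "constant"])
    assert out.loc["f0", ["stage", "bmi", "age", "sex", "study"]].sum() == 0


def test_fractions_invariant_to_monotone_transform(rng):
    """Rank basis: x -> exp(x) leaves every variance fraction unchanged."""
    meta = meta_frame(80, rng)
    base = rng.normal(0, 1, (5, 80)) + meta["stage"].cat.codes.to_numpy(float)
    frame = pd.DataFrame(base, index=[f"f{i}" for i in range(5)],
                         columns=meta.index)
    out1 = confounder_anova(make_norm(frame), meta)
    out2 = confounder_anova(make_norm(np.exp(frame)), meta)
    pd.testing.assert_frame_equal(out1, out2)


def test_fractions_match_statsmodels_type_ii_anova(rng):
    """Independent oracle: statsmodels anova_lm(typ=2) on ranks, one feature."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    meta = meta_frame(60, rng)
    y = rng.normal(0, 1, 60) + 0.5 * meta["stage"].cat.codes.to_numpy(float)
    frame = pd.DataFrame([y], index=["f0"], columns=meta.index)
    ours = confounder_anova(make_norm(frame), meta)

    data = meta.copy()
    data["r"] = sps.rankdata(y)
    data["stage"] = data["stage"].astype(str)
    model = smf.ols("r ~ C(stage) + bmi + age + C(sex) + C(study)", data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    total = ((data["r"] - data["r"].mean()) ** 2).sum()
    expect = {"stage": anova.loc["C(stage)", "sum_sq"] / total,
              "bmi": anova.loc["bmi", "sum_sq"] / total,
              "study": anova.loc["C(study)", "sum_sq"] / total}
    for cov, val in expect.items():
        assert ours.loc["f0", cov] == pytest.approx(val, abs=1e-8)
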