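"""Self-contained recovery and calibration experiments on synthetic cohorts.

Each function sets up a simulation with known ground truth, runs the relevant
pipeline stages, and returns summary numbers.  They are the package's own
verification battery: confounder control of the blocked test, batch-shift
removal by SNM, differential-abundance recovery against the truth table,
generalized-fold-change calibration, partial-Spearman behaviour, and the
transfer-matrix response to shared versus disjoint stage signatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import (blocked_wilcoxon, generalized_fold_change,
                          make_blocks, partial_spearman, run_meta_analysis)
from .ml import TrainConfig, stage_vs_control_matrix
from .normalization import NormalizedMatrix, confounder_anova, fit_snm, log_cpm
from .profiles import STAGES, to_cpm
from .synthetic import SynthConfig, generate_cohort


def confounded_null_rates(n_features: int = 1000, n_per_group: int = 100,
                          slope: float = 0.05, bmi_shift: float = 3.0,
                          bmi_sd: float = 3.0, alpha: float = 0.05,
                          n_bmi_bins: int = 3, seed: int = 0) -> dict:
    """Rejection rates of the naive vs BMI-blocked test under a confounded null.

    Each simulated feature depends on BMI only (slope per BMI unit), while
    cases carry a one-standard-deviation BMI shift; the disease has no direct
    effect, so every rejection is a false positive.  Returns the naive
    (single-block) and BMI-tertile-blocked rejection rates at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    naive = blocked = 0
    in_case = np.r_[np.zeros(n_per_group, bool), np.ones(n_per_group, bool)]
    single_block = np.zeros(2 * n_per_group, int)
    for _ in range(n_features):
        bmi = np.concatenate([rng.normal(25.0, bmi_sd, n_per_group),
                              rng.normal(25.0 + bmi_shift, bmi_sd, n_per_group)])
        y = slope * bmi + rng.normal(0.0, 1.0, 2 * n_per_group)
        edges = np.quantile(bmi, np.linspace(0, 1, n_bmi_bins + 1))[1:-1]
        bins = np.searchsorted(edges, bmi, side="right")
        _, p_naive = blocked_wilcoxon(y, in_case, single_block, mode="normal")
        _, p_block = blocked_wilcoxon(y, in_case, bins, mode="normal")
        naive += p_naive < alpha
        blocked += p_block < alpha
    return {"naive_rate": naive / n_features,
            "blocked_rate": blocked / n_features,
            "n": n_features}


def batch_recovery(seed: int = 0, n_features: int = 200,
                   samples_per_stage: int = 15,
                   shifts=(2.0, 0.0, -2.0)) -> dict:
    """SNM recovery of known per-study shifts, against a batch-free oracle.

    A cohort is generated with zero random batch effect; deterministic
    per-study log2 shifts are then added to every feature, SNM is fitted on
    the shifted matrix, and the result is compared with the untouched
    (batch-free) matrix from the very same draw: residual study-explained
    rank variance, and the change in spiked-feature AUROC (patients vs
    controls) caused by batch injection + correction.
    """
    cfg = SynthConfig(
        n_features=n_features,
        samples_per_study_per_stage={s: samples_per_stage for s in STAGES},
        frac_bmi_linked=0.0, batch_sd_log2=0.0, seed=seed)
    profile, metadata, truth = generate_cohort(cfg)
    clean = log_cpm(to_cpm(profile))
    shift_per_sample = metadata["study"].map(
        {f"study{i + 1}": s for i, s in enumerate(shifts)}).to_numpy(float)
    shifted = NormalizedMatrix(clean.values + shift_per_sample[None, :],
                               unit="log_cpm")
    corrected = fit_snm(shifted, metadata)

    anova_pre = confounder_anova(shifted, metadata)
    anova_post = confounder_anova(corrected, metadata)

    spiked = truth.loc[truth["class"] == "stage_uniform", "feature_id"]
    is_case = (metadata["stage"] != "HC").to_numpy()

    def mean_auroc(matrix: NormalizedMatrix) -> float:
        arr = matrix.values.loc[spiked].to_numpy()
        aucs = [stats.rankdata(row)[is_case].sum() for row in arr]
        n1, n0 = is_case.sum(), (~is_case).sum()
        aucs = [(a - n1 * (n1 + 1) / 2) / (n1 * n0) for a in aucs]
        # fold below-0.5 (depleted) features so direction does not cancel
        return float(np.mean([max(a, 1 - a) for a in aucs]))

    return {
        "study_variance_pre": float(anova_pre["study"].mean()),
        "study_variance_post": float(anova_post["study"].mean()),
        "auroc_batch_free": mean_auroc(clean),
        "auroc_post_snm": mean_auroc(corrected),
        "auroc_delta": abs(mean_auroc(corrected) - mean_auroc(clean)),
        "n": n_features,
    }


def da_recovery(seeds=range(10), n_features: int = 200,
                controls_per_study: int = 40, cases_per_study: int = 40,
                fdr: float = 0.05) -> dict:
    """Differential-abundance recovery against the generator's truth table.

    For each seed: a three-study cohort (40 controls and 40 patients per
    study, effect 2 log2 units, random batch effects) goes through the full
    cpm -> log-cpm -> SNM -> blocked meta-analysis path.  Sensitivity is the
    fraction of stage-uniform truth features reaching meta q < ``fdr`` with
    the correct direction; the false-discovery proportion counts truth-null
    features among all discoveries.
    """
    per_stage = cases_per_study // 4
    sens, fdps = [], []
    for seed in seeds:
        cfg = SynthConfig(
            n_features=n_features,
            samples_per_study_per_stage={
                "HC": controls_per_study, "NAFL": per_stage, "NASH": per_stage,
                "fibrosis": per_stage, "cirrhosis": per_stage},
            frac_bmi_linked=0.0, seed=seed)
        profile, metadata, truth = generate_cohort(cfg)
        norm = fit_snm(log_cpm(to_cpm(profile)), metadata)
        assoc = run_meta_analysis(norm, metadata, contrasts=("meta",), fdr=fdr)
        merged = assoc.merge(
            truth.rename(columns={"direction": "true_direction"}),
            on="feature_id")
        uniform = merged[merged["class"] == "stage_uniform"]
        hit = (uniform["q_value"] < fdr) & \
              (np.sign(uniform["gfc"]) == uniform["true_direction"])
        sens.append(hit.mean())
        flagged = merged[merged["q_value"] < fdr]
        fdps.append((flagged["class"] == "null").mean() if len(flagged) else 0.0)
    return {"sensitivity": float(np.mean(sens)),
            "fdp": float(np.mean(fdps)),
            "n": len(list(seeds)) * n_features}


def gfc_calibration(deltas=(0.5, 1.0, 2.0), n_per_arm: int = 100,
                    n_replicates: int = 200, log_sd: float = 0.5,
                    seed: int = 0) -> dict:
    """Mean absolute error of the generalized fold change at known shifts.

    Case and control values are normal on the log scale (location-shifted
    log-normal abundances, within-group log-sd 0.5); for each shift delta
    the mean |gFC - delta| over replicates is reported.
    """
    rng = np.random.default_rng(seed)
    errors = {}
    for delta in deltas:
        errs = []
        for _ in range(n_replicates):
            control = rng.normal(0.0, log_sd, n_per_arm)
            case = rng.normal(delta, log_sd, n_per_arm)
            errs.append(abs(generalized_fold_change(case, control) - delta))
        errors[delta] = float(np.mean(errs))
    return {"mean_abs_error": errors,
            "max_mean_abs_error": float(max(errors.values())),
            "n": n_replicates * len(tuple(deltas))}


def psrc_calibration(n_null: int = 1000, n_samples: int = 150,
                     n_confounded: int = 50, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Type-I error and confounding removal of the partial Spearman test.

    Null arm: features independent of both stage and BMI (BMI itself is
    stage-correlated); rejections at ``alpha`` estimate the type-I rate.
    Confounded arm: the feature tracks BMI only; |rho_partial| should be
    near zero because the BMI effect is partialled out.
    """
    rng = np.random.default_rng(seed)
    stage_rank = np.tile(np.arange(5), n_samples // 5 + 1)[:n_samples]
    rejections = 0
    for _ in range(n_null):
        bmi = 24.0 + 2.0 * stage_rank + rng.normal(0, 2.0, n_samples)
        y = rng.normal(0, 1.0, n_samples)
        _, p = partial_spearman(y, stage_rank, bmi)
        rejections += p < alpha
    rhos = []
    for _ in range(n_confounded):
        bmi = 24.0 + 2.0 * stage_rank + rng.normal(0, 2.0, n_samples)
        y = bmi + rng.normal(0, 0.5, n_samples)
        rho, _ = partial_spearman(y, stage_rank, bmi)
        rhos.append(abs(rho))
    return {"type1_rate": rejections / n_null,
            "confounded_mean_abs_rho": float(np.mean(rhos)),
            "n": n_null}


def transfer_experiment(kind: str = "shared", seed: int = 0,
                        n_features: int = 300, samples_per_stage: int = 20
                        ) -> dict:
    """Stage-to-stage transfer AUROC under shared vs disjoint signatures.

    ``kind="shared"``: every patient stage carries the same stage-uniform
    signature, so models trained on one stage should transfer (off-diagonal
    AUROC close to the diagonal).  ``kind="disjoint"``: each stage has its
    own private feature set, so transfer should collapse (large
    diagonal-minus-off-diagonal gap).
    """
    if kind == "shared":
        cfg = SynthConfig(n_features=n_features,
                          samples_per_study_per_stage={s: samples_per_stage
                                                       for s in STAGES},
                          frac_stage_uniform_diff=0.15,
                          frac_stage_monotone_diff=0.0,
                          frac_bmi_linked=0.0, seed=seed)
    elif kind == "disjoint":
        cfg = SynthConfig(n_features=n_features,
                          samples_per_study_per_stage={s: samples_per_stage
                                                       for s in STAGES},
                          frac_stage_uniform_diff=0.0,
                          frac_stage_monotone_diff=0.0,
                          frac_bmi_linked=0.0,
                          frac_stage_specific_diff=0.2, seed=seed)
    else:
        raise ValueError("kind must be 'shared' or 'disjoint'")
    profile, metadata, _ = generate_cohort(cfg)
    norm = fit_snm(log_cpm(to_cpm(profile)), metadata)
    result = stage_vs_control_matrix(norm, metadata, TrainConfig(seed=seed))
    auroc = result.auroc
    diag = np.diag(auroc.to_numpy())
    off_mask = ~np.eye(len(auroc), dtype=bool)
    off = auroc.to_numpy()[off_mask]
    row_gaps = np.abs(auroc.to_numpy() - diag[:, None])[off_mask]
    return {"auroc": auroc,
            "mean_diagonal": float(diag.mean()),
            "mean_off_diagonal": float(off.mean()),
            "max_row_gap": float(row_gaps.max()),
            "diag_minus_offdiag": float(diag.mean() - off.mean()),
            "n": auroc.size}
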