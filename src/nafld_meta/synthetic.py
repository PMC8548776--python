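"""Synthetic multi-study metagenomic cohorts with known ground truth.

The generator emulates a merged shotgun-metagenomics case-control design:
several studies, five ordered disease stages (HC, NAFL, NASH, fibrosis,
cirrhosis), per-study batch effects on every feature, a BMI distribution that
shifts with stage (the classic obesity confounder of fatty-liver cohorts),
and overdispersed sequencing counts with variable library sizes.

Differentially abundant features come in two flavours: *stage-uniform*
features shifted by the same amount in every patient stage (a shared
dysbiosis signature) and *stage-monotone* features whose shift grows linearly
with progression rank.  A third class is linked to BMI rather than disease,
which is what makes confounder-aware testing demonstrably necessary.  Every
feature's class, direction and effect size is returned in a truth table so
downstream recovery is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import PATIENT_STAGES, STAGE_RANK, STAGES, ProfileTable, stage_categorical


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _per_study_counts(spec, n_studies: int) -> np.ndarray:
    """Normalize an int or per-study sequence into an array of length n_studies."""
    if np.isscalar(spec):
        if spec < 1:
            raise ConfigError("sample counts must be >= 1")
        return np.full(n_studies, int(spec))
    arr = np.asarray(list(spec), dtype=int)
    if arr.size != n_studies or (arr < 1).any():
        raise ConfigError("per-study sample counts must list >=1 samples for each study")
    return arr


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Attributes
    ----------
    n_studies : int
        Number of independent studies merged into the cohort.
    samples_per_study_per_stage : mapping
        Stage -> samples per study (an int, or a per-study sequence for
        unbalanced designs).  Must cover exactly the five stages.
    n_features : int
        Number of microbial features (species-level taxa).
    frac_stage_uniform_diff, frac_stage_monotone_diff, frac_bmi_linked : float
        Fractions of features assigned to each non-null truth class; their
        sum (with ``frac_stage_specific_diff``) must not exceed 1.
    frac_stage_specific_diff : float
        Fraction of features carrying a *disjoint* signature: split evenly
        over the four patient stages, each such feature is shifted in its
        designated stage only.  Used to emulate stage-heterogeneous
        dysbiosis, the opposite of the shared-signature classes above.
    effect_size_log2 : float
        log2 abundance shift applied to affected features in cases
        (full shift for the uniform class; the monotone class reaches it at
        cirrhosis, scaling linearly with stage rank / 4).
    batch_sd_log2 : float
        Standard deviation of the per-study, per-feature log2 batch shift.
    bmi_confounding_slope : float
        log2 shift per BMI unit (relative to healthy-control mean BMI) for
        BMI-linked features.
    bmi_stage_means : mapping
        Stage -> mean BMI (kg/m^2); defaults rise with progression so that
        BMI is stage-correlated, as in real NAFLD cohorts.
    bmi_sd : float
        Within-stage BMI standard deviation.
    library_size_log_mean, library_size_log_sd : float
        Natural-log parameters of the log-normal library-size distribution.
    dispersion : float
        Gamma-Poisson overdispersion: Var = mu + dispersion * mu^2.
    seed : int
        Seed for the single random generator; identical seeds give
        bit-identical cohorts.
    """

    n_studies: int = 3
    samples_per_study_per_stage: Mapping[str, object] = field(
        default_factory=lambda: {s: 20 for s in STAGES})
    n_features: int = 300
    frac_stage_uniform_diff: float = 0.10
    frac_stage_monotone_diff: float = 0.10
    frac_bmi_linked: float = 0.10
    frac_stage_specific_diff: float = 0.0
    effect_size_log2: float = 2.0
    batch_sd_log2: float = 1.0
    bmi_confounding_slope: float = 0.15
    bmi_stage_means: Mapping[str, float] = field(default_factory=lambda: {
        "HC": 24.0, "NAFL": 28.0, "NASH": 30.0, "fibrosis": 31.0, "cirrhosis": 32.0})
    bmi_sd: float = 3.0
    library_size_log_mean: float = 14.5
    library_size_log_sd: float = 0.35
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1 or self.n_features < 1:
            raise ConfigError("n_studies and n_features must be >= 1")
        if set(self.samples_per_study_per_stage) != set(STAGES):
            raise ConfigError(f"samples_per_study_per_stage must cover exactly {STAGES}")
        for stage, spec in self.samples_per_study_per_stage.items():
            _per_study_counts(spec, self.n_studies)
        fracs = (self.frac_stage_uniform_diff, self.frac_stage_monotone_diff,
                 self.frac_bmi_linked, self.frac_stage_specific_diff)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ConfigError("truth-class fractions must lie in [0,1] and sum to <= 1")
        if self.effect_size_log2 < 0 or self.batch_sd_log2 < 0:
            raise ConfigError("effect_size_log2 and batch_sd_log2 must be nonnegative")
        if self.bmi_sd <= 0 or self.dispersion <= 0:
            raise ConfigError("bmi_sd and dispersion must be positive")
        if set(self.bmi_stage_means) != set(STAGES):
            raise ConfigError(f"bmi_stage_means must cover exactly {STAGES}")


def _assign_classes(cfg: SynthConfig, rng: np.random.Generator,
                    eligible: np.ndarray) -> pd.DataFrame:
    """Assign truth classes, spiking only ``eligible`` (non-dominant) features.

    Restricting differential features to the lower half of baseline abundance
    mirrors real case-control cohorts (disease-associated taxa are rarely the
    community's dominant members) and keeps the truth labels compositionally
    coherent: spiking a dominant taxon would shift every other feature's
    relative abundance through closure, silently turning nulls into
    differential features.
    """
    n = cfg.n_features
    n_uniform = int(round(cfg.frac_stage_uniform_diff * n))
    n_monotone = int(round(cfg.frac_stage_monotone_diff * n))
    n_bmi = int(round(cfg.frac_bmi_linked * n))
    n_specific = int(round(cfg.frac_stage_specific_diff * n))
    n_affected = n_uniform + n_monotone + n_bmi + n_specific
    if n_affected > n:
        raise ConfigError("truth-class fractions allocate more features than exist")
    pool = np.flatnonzero(eligible)
    if n_affected > pool.size:  # fractions too large for the eligible half
        pool = np.arange(n)
    order = np.concatenate([rng.permutation(pool),
                            rng.permutation(np.setdiff1d(np.arange(n), pool))])
    classes = np.array(["null"] * n, dtype=object)
    bounds = np.cumsum([0, n_uniform, n_monotone, n_bmi, n_specific])
    for label, lo, hi in zip(
            ("stage_uniform", "stage_monotone", "bmi_linked", "stage_specific"),
            bounds[:-1], bounds[1:]):
        classes[order[lo:hi]] = label
    specific_stage = np.array([""] * n, dtype=object)
    specific_stage[order[bounds[3]:bounds[4]]] = [
        PATIENT_STAGES[i % len(PATIENT_STAGES)] for i in range(n_specific)]
    direction = np.where(rng.random(n) < 0.5, 1, -1)
    direction[classes == "null"] = 1
    effect = np.zeros(n)
    effect[np.isin(classes, ["stage_uniform", "stage_monotone",
                             "stage_specific"])] = cfg.effect_size_log2
    effect[classes == "bmi_linked"] = cfg.bmi_confounding_slope
    return pd.DataFrame({"class": classes, "direction": direction,
                         "true_effect_log2": effect * direction,
                         "specific_stage": specific_stage})


def generate_cohort(config: SynthConfig) -> tuple[ProfileTable, pd.DataFrame, pd.DataFrame]:
    """Generate a merged multi-study cohort.

    Returns
    -------
    profile : ProfileTable
        Integer counts, features x samples.
    metadata : pandas.DataFrame
        Indexed by sample ID with columns study, stage, bmi, age, sex.
    truth : pandas.DataFrame
        One row per feature: class, direction, true_effect_log2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    feature_ids = [f"sp_{i:04d}" for i in range(config.n_features)]
    # Baseline log2 relative abundance: wide spread gives realistic sparsity
    # (rare features drop below detection in shallow samples).
    baseline = rng.normal(0.0, 2.5, config.n_features)
    truth = _assign_classes(config, rng, eligible=baseline <= np.median(baseline))
    truth.index = pd.Index(feature_ids, name="feature_id")
    batch = rng.normal(0.0, config.batch_sd_log2,
                       (config.n_studies, config.n_features))

    rows = []
    sample_ids, studies, stages, bmis, ages, sexes = [], [], [], [], [], []
    hc_bmi = config.bmi_stage_means["HC"]
    cls = truth["class"].to_numpy()
    direction = truth["direction"].to_numpy().astype(float)
    is_stage_affected = np.isin(cls, ["stage_uniform", "stage_monotone"])
    monotone = cls == "stage_monotone"
    bmi_linked = cls == "bmi_linked"
    specific = cls == "stage_specific"
    specific_stage = truth["specific_stage"].to_numpy()

    for study_idx in range(config.n_studies):
        study = f"study{study_idx + 1}"
        for stage in STAGES:
            n_samples = int(_per_study_counts(
                config.samples_per_study_per_stage[stage], config.n_studies)[study_idx])
            rank = STAGE_RANK[stage]
            for i in range(n_samples):
                bmi = rng.normal(config.bmi_stage_means[stage], config.bmi_sd)
                bmi = max(bmi, 15.0)
                age = rng.normal(48.0, 12.0)
                sex = "F" if rng.random() < 0.5 else "M"

                log2_mu = baseline + batch[study_idx]
                if rank > 0:
                    scale = np.where(monotone, rank / 4.0, 1.0)
                    affected = is_stage_affected | (specific & (specific_stage == stage))
                    log2_mu = log2_mu + np.where(
                        affected,
                        direction * config.effect_size_log2 * scale, 0.0)
                log2_mu = log2_mu + np.where(
                    bmi_linked,
                    direction * config.bmi_confounding_slope * (bmi - hc_bmi), 0.0)

                rel = np.exp2(log2_mu)
                rel = rel / rel.sum()
                lib = rng.lognormal(config.library_size_log_mean,
                                    config.library_size_log_sd)
                mu = rel * lib
                lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
                counts = rng.poisson(lam)

                rows.append(counts)
                sample_ids.append(f"{study}_{stage}_{i:03d}")
                studies.append(study)
                stages.append(stage)
                bmis.append(round(bmi, 2))
                ages.append(round(max(age, 18.0), 1))
                sexes.append(sex)

    values = pd.DataFrame(np.asarray(rows, dtype=float).T,
                          index=pd.Index(feature_ids, name="feature_id"),
                          columns=sample_ids)
    metadata = pd.DataFrame({
        "study": studies,
        "stage": stage_categorical(stages),
        "bmi": bmis,
        "age": ages,
        "sex": sexes,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return ProfileTable(values, unit="counts"), metadata, truth.reset_index()


def degrade_to_relative(profile: ProfileTable) -> ProfileTable:
    """Rescale each sample to percent relative abundances (columns sum to 100).

    Emulates profilers that report relative abundances instead of counts;
    all-zero samples are left at zero.
    """
    arr = profile.values.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("relative-abundance conversion requires nonnegative input")
    totals = arr.sum(axis=0)
    scaled = np.divide(arr * 100.0, totals, out=np.zeros_like(arr),
                       where=totals > 0)
    return ProfileTable(pd.DataFrame(scaled, index=profile.values.index,
                                     columns=profile.values.columns),
                        unit="relative")


def balanced_preset(seed: int = 0, n_features: int = 300,
                    samples_per_stage: int = 20) -> SynthConfig:
    """Three balanced studies; the default playground for pipeline runs."""
    return SynthConfig(
        samples_per_study_per_stage={s: samples_per_stage for s in STAGES},
        n_features=n_features, seed=seed)


def unbalanced_preset(seed: int = 0, n_features: int = 300) -> SynthConfig:
    """Stage totals 120/39/39/15/14 (HC through cirrhosis) over three studies.

    Mirrors the skew of real merged NAFLD cohorts, where controls outnumber
    advanced-stage patients by an order of magnitude.
    """
    return SynthConfig(
        samples_per_study_per_stage={
            "HC": (40, 40, 40),
            "NAFL": (13, 13, 13),
            "NASH": (13, 13, 13),
            "fibrosis": (5, 5, 5),
            "cirrhosis": (5, 5, 4),
        },
        n_features=n_features, seed=seed)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
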