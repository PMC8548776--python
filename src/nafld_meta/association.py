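"""Univariate meta-analysis: blocked rank tests, effect sizes, FDR, progression.

The central test is a stratified (van Elteren-style) Wilcoxon rank-sum test:
samples are partitioned into blocks — here study x BMI-bin, so that both the
cohort of origin and the BMI confounder are held fixed within each stratum —
ranks are computed within blocks, and the standardized within-block rank-sum
deviations are summed across blocks into one Z statistic.  Effect sizes are
the generalized fold change (mean quantile difference on the log scale) and
the rank-based AUROC with a DeLong confidence interval.  Progression is
assessed by partial Spearman correlation between abundance and stage rank
with BMI partialled out.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedMatrix
from .profiles import PATIENT_STAGES, STAGE_RANK, STAGES

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

#: Contrast name -> (case stages, control stages).
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "meta": (PATIENT_STAGES, ("HC",)),
    "NAFL": (("NAFL",), ("HC",)),
    "NASH": (("NASH",), ("HC",)),
    "fibrosis": (("fibrosis",), ("HC",)),
    "cirrhosis": (("cirrhosis",), ("HC",)),
    "progressive": (("NASH", "fibrosis", "cirrhosis"), ("HC", "NAFL")),
}


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Blocking


def make_blocks(metadata: pd.DataFrame, n_bmi_bins: int = 3,
                include_study: bool = True, missing: str = "own_block"
                ) -> pd.Series:
    """Assign each sample to a block = study x BMI quantile bin.

    BMI bins are global quantile (e.g. tertile) cuts over all non-missing
    values.  ``missing`` controls samples without BMI: "own_block" groups
    them into a dedicated bin, "drop" raises if any are present.
    """
    if n_bmi_bins < 1:
        raise AssociationError("n_bmi_bins must be >= 1")
    bmi = pd.to_numeric(metadata.get("bmi"), errors="coerce")
    if bmi.isna().any() and missing == "drop":
        raise AssociationError("samples with missing BMI present")
    if n_bmi_bins == 1:
        bins = pd.Series("bin0", index=metadata.index)
    else:
        edges = np.unique(np.quantile(bmi.dropna(), np.linspace(0, 1, n_bmi_bins + 1)))
        cut = np.clip(np.searchsorted(edges[1:-1], bmi, side="right"), 0,
                      len(edges) - 2)
        bins = pd.Series([f"bin{b}" for b in cut], index=metadata.index)
        bins[bmi.isna()] = "bin_missing"
    if include_study:
        return metadata["study"].astype(str) + "|" + bins
    return bins


# ---------------------------------------------------------------------------
# Blocked (van Elteren) Wilcoxon rank-sum test


def _block_moments(values: np.ndarray, in_case: np.ndarray):
    """Rank-sum of the case group, its null mean and tie-corrected variance."""
    n = values.size
    n1 = int(in_case.sum())
    n2 = n - n1
    ranks = stats.rankdata(values)
    w = ranks[in_case].sum()
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    return w, mean, var


def _exact_block_distributions(block_values, block_cases, max_size: int):
    """Per-block distributions of (rank-sum - mean); None if too large."""
    total = 1
    dists = []
    for values, in_case in zip(block_values, block_cases):
        n, n1 = values.size, int(in_case.sum())
        total *= math.comb(n, n1)
        if total > max_size:
            return None
        ranks = stats.rankdata(values)
        mean = n1 * (n + 1) / 2.0
        dists.append(np.array([ranks[list(combo)].sum() - mean
                               for combo in itertools.combinations(range(n), n1)]))
    return dists


def blocked_wilcoxon(values, in_case, blocks, mode: str = "auto",
                     max_exact: int = 100_000) -> tuple[float, float]:
    """Stratified two-sample Wilcoxon rank-sum test.

    Parameters
    ----------
    values : array-like
        Observations (one feature across samples).
    in_case : boolean array-like
        Group membership (True = case).
    blocks : array-like
        Block label per sample; ranks are computed within blocks only.
    mode : {"auto", "normal", "exact"}
        "normal" uses the standardized-sum normal approximation with tie
        correction; "exact" enumerates all within-block group assignments
        (permutation null); "auto" uses the exact test when the number of
        arrangements is at most ``max_exact``.

    Returns
    -------
    z, p : float
        Standardized statistic (sum over informative blocks of rank-sum
        deviations, divided by the root of the summed null variances) and
        the two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    in_case = np.asarray(in_case, dtype=bool)
    blocks = np.asarray(blocks)
    if values.shape != in_case.shape or values.shape != blocks.shape:
        raise AssociationError("values, in_case and blocks must align")

    block_values, block_cases = [], []
    for b in pd.unique(blocks):
        sel = blocks == b
        if sel.sum() < 2:
            continue
        cases = in_case[sel]
        if cases.all() or not cases.any():
            continue  # non-informative: a single group represented
        block_values.append(values[sel])
        block_cases.append(cases)
    if not block_values:
        raise AssociationError("no within-block contrast: every block "
                               "contains a single group")

    num = 0.0
    var = 0.0
    for v, c in zip(block_values, block_cases):
        w, mean, v_b = _block_moments(v, c)
        num += w - mean
        var += v_b

    if var <= 0:  # complete ties everywhere
        return 0.0, 1.0
    z = num / math.sqrt(var)

    dists = None
    if mode in ("auto", "exact"):
        limit = max_exact if mode == "auto" else 10 ** 9
        dists = _exact_block_distributions(block_values, block_cases, limit)
        if mode == "exact" and dists is None:
            raise AssociationError("exact test too large; raise max_exact or "
                                   "use mode='normal'")
    if dists is not None:
        totals = dists[0]
        for d in dists[1:]:
            totals = np.add.outer(totals, d).ravel()
        p = float(np.mean(np.abs(totals) >= abs(num) - 1e-9))
        return z, p
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Effect sizes


def generalized_fold_change(case_values, control_values,
                            quantiles=DEFAULT_QUANTILES) -> float:
    """Mean difference of case and control quantiles (log-scale inputs).

    A robust location-shift estimate for sparse abundance data: the
    difference case - control is taken at each quantile of a fixed grid
    (default 0.1 to 0.9 in steps of 0.1) and averaged.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise AssociationError("generalized fold change needs >= 2 values per group")
    qs = np.asarray(quantiles, dtype=float)
    return float(np.mean(np.quantile(case, qs) - np.quantile(control, qs)))


def auroc_effect(case_values, control_values, ci: float = 0.95
                 ) -> tuple[float, float, float]:
    """Rank-based AUROC = P(case > control) + P(tie)/2, with a DeLong CI.

    The point estimate is the midrank Mann-Whitney statistic; the confidence
    interval uses the DeLong placement-value variance, clipped to [0, 1].
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n0 = case.size, control.size
    if n1 == 0 or n0 == 0:
        raise AssociationError("auroc_effect needs >= 1 value per group")
    ranks = stats.rankdata(np.concatenate([case, control]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # DeLong placements: per case, fraction of controls it beats (ties half).
    v10 = np.array([(np.sum(control < x) + 0.5 * np.sum(control == x)) / n0
                    for x in case])
    v01 = np.array([(np.sum(case > y) + 0.5 * np.sum(case == y)) / n1
                    for y in control])
    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01, ddof=1) / n0
    half = stats.norm.ppf(0.5 + ci / 2.0) * math.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Meta-analysis driver


def run_meta_analysis(norm: NormalizedMatrix, metadata: pd.DataFrame,
                      blocks: pd.Series | None = None,
                      contrasts=tuple(CONTRASTS),
                      fdr: float = 0.05, core_fdr: float = 1e-3,
                      n_bmi_bins: int = 3, mode: str = "normal",
                      quantiles=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Blocked differential-abundance analysis over a set of stage contrasts.

    For each contrast (all-patients vs HC, each stage vs HC, and progressive
    stages vs the rest) and each feature: blocked Wilcoxon p-value, BH
    q-value within the contrast family, generalized fold change, AUROC with
    95% CI, and direction.  The core flag marks features whose all-patients
    ("meta") q-value falls below ``core_fdr``.

    Returns a tidy DataFrame with one row per (feature, contrast).
    """
    meta = metadata.loc[norm.sample_ids]
    if blocks is None:
        blocks = make_blocks(meta, n_bmi_bins=n_bmi_bins)
    blocks = blocks.loc[meta.index]
    mat = norm.values
    records = []
    for contrast in contrasts:
        case_stages, control_stages = CONTRASTS[contrast]
        is_case = meta["stage"].isin(case_stages).to_numpy()
        is_control = meta["stage"].isin(control_stages).to_numpy()
        keep = is_case | is_control
        if not is_case.any() or not is_control.any():
            continue  # empty arm: skip contrast
        sub = mat.loc[:, keep].to_numpy()
        sub_case = is_case[keep]
        sub_blocks = blocks.to_numpy()[keep]
        for i, fid in enumerate(mat.index):
            row = sub[i]
            _, p = blocked_wilcoxon(row, sub_case, sub_blocks, mode=mode)
            gfc = generalized_fold_change(row[sub_case], row[~sub_case],
                                          quantiles=quantiles)
            auc, lo, hi = auroc_effect(row[sub_case], row[~sub_case])
            records.append((fid, contrast, p, gfc, auc, lo, hi))
    table = pd.DataFrame(records, columns=[
        "feature_id", "contrast", "p_value", "gfc", "auroc",
        "auroc_ci_low", "auroc_ci_high"])
    table["q_value"] = np.nan
    for contrast, idx in table.groupby("contrast").groups.items():
        table.loc[idx, "q_value"] = bh_fdr(table.loc[idx, "p_value"])
    table["direction"] = np.where(table["gfc"] > 0, "enriched_case",
                                  "enriched_control")
    table["significant"] = table["q_value"] < fdr
    core = table.loc[table["contrast"] == "meta"]
    core_set = set(core.loc[core["q_value"] < core_fdr, "feature_id"])
    table["core_flag"] = table["feature_id"].isin(core_set)
    return table


# ---------------------------------------------------------------------------
# Progression correlation (partial Spearman) and consistency calls


def partial_spearman(values, stage_rank, covariate_bmi
                     ) -> tuple[float, float]:
    """Partial Spearman correlation of abundance with stage rank, given BMI.

    Midranks of the abundance and of the stage rank are each regressed on
    midranks of BMI; the Pearson correlation of the residuals is the partial
    rank correlation, with a t-approximation p-value on n - 3 degrees of
    freedom.
    """
    x = np.asarray(values, dtype=float)
    s = np.asarray(stage_rank, dtype=float)
    b = np.asarray(covariate_bmi, dtype=float)
    n = x.size
    if n < 4:
        raise AssociationError("partial Spearman needs >= 4 samples")
    if np.ptp(x) == 0 or np.ptp(s) == 0:
        return 0.0, 1.0
    rx, rs, rb = (stats.rankdata(v) for v in (x, s, b))
    design = np.column_stack([np.ones(n), rb])

    def resid(y):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return y - design @ beta

    ex, es = resid(rx), resid(rs)
    denom = math.sqrt((ex ** 2).sum() * (es ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float(np.clip((ex * es).sum() / denom, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, min(p, 1.0)


def run_progression(norm: NormalizedMatrix, metadata: pd.DataFrame,
                    fdr: float = 0.05, include_hc: bool = True) -> pd.DataFrame:
    """Per-feature progression correlation (pSRC) with BMI partialled out.

    Stage coding includes HC at rank 0 by default; with
    ``include_hc=False`` only patients (ranks 1-4) enter.
    Calls are "correlated" / "anti-correlated" at q < ``fdr``.
    """
    meta = metadata.loc[norm.sample_ids]
    keep = np.ones(len(meta), dtype=bool) if include_hc else \
        (meta["stage"] != "HC").to_numpy()
    ranks = meta["stage"].map(STAGE_RANK).to_numpy(dtype=float)[keep]
    bmi = pd.to_numeric(meta["bmi"]).to_numpy(dtype=float)[keep]
    sub = norm.values.to_numpy()[:, keep]
    rows = []
    for i, fid in enumerate(norm.values.index):
        rho, p = partial_spearman(sub[i], ranks, bmi)
        rows.append((fid, rho, p))
    out = pd.DataFrame(rows, columns=["feature_id", "rho_partial", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"])
    out["call"] = "none"
    out.loc[(out["q_value"] < fdr) & (out["rho_partial"] > 0), "call"] = "correlated"
    out.loc[(out["q_value"] < fdr) & (out["rho_partial"] < 0), "call"] = "anti-correlated"
    return out


def progression_consistent(assoc: pd.DataFrame,
                           stages=("NASH", "fibrosis", "cirrhosis"),
                           fdr: float = 0.05) -> pd.DataFrame:
    """Features significant with a consistent direction in all late stages.

    A feature qualifies when its stage-vs-HC q-value is below ``fdr`` in
    every listed stage and its generalized fold change carries the same sign
    throughout.  Returns the qualifying features with their per-stage gfc.
    """
    sub = assoc[assoc["contrast"].isin(stages)]
    missing = set(stages) - set(sub["contrast"])
    if missing:
        raise AssociationError(f"association table lacks contrasts: {sorted(missing)}")
    wide_q = sub.pivot(index="feature_id", columns="contrast", values="q_value")
    wide_g = sub.pivot(index="feature_id", columns="contrast", values="gfc")
    sig = (wide_q[list(stages)] < fdr).all(axis=1)
    signs = np.sign(wide_g[list(stages)])
    consistent = (signs.eq(signs.iloc[:, 0], axis=0)).all(axis=1) & (signs != 0).all(axis=1)
    keep = wide_g.loc[sig & consistent, list(stages)]
    keep.columns = [f"gfc_{s}" for s in stages]
    return keep.reset_index()
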