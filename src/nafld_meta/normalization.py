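"""Normalization: log-cpm transform, supervised batch correction, confounder ANOVA.

The batch-correction step follows the supervised-normalization idea: fit, per
feature, a linear model containing both the biological variables whose effect
must be preserved (disease stage) and the adjustment variables whose effect
must be removed (study), then subtract only the fitted adjustment component.
Features are iteratively reweighted by their evidence of biological
association so that genuine disease signal is not absorbed into the batch
estimate when the design is partially confounded.

The confounder ANOVA quantifies, per feature, the fraction of abundance
variance attributable to disease stage versus nuisance covariates (BMI, age,
sex, study).  Because microbiome abundances are heavily non-Gaussian it is
computed on midranks, with type-II sums of squares so each covariate is
adjusted for all others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileTable, align_metadata, to_cpm


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """A real-valued feature-by-sample matrix on a log or batch-corrected scale."""

    values: pd.DataFrame
    unit: str  # "log_cpm" or "normalized"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise NormalizationError("normalized matrix contains non-finite entries")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def log_cpm(profile: ProfileTable, pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(cpm + pseudocount) transform.

    Converts counts (or relative abundances) to cpm first; the default
    pseudocount of 1 maps absent features to exactly zero.
    """
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    cpm = profile if profile.unit == "cpm" else to_cpm(profile)
    values = np.log2(cpm.values + pseudocount)
    return NormalizedMatrix(values, unit="log_cpm",
                            provenance={"pseudocount": pseudocount})


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Drop-first dummy coding, returning the design block and level names."""
    d = pd.get_dummies(pd.Series(labels).astype(str), drop_first=True, dtype=float)
    return d.to_numpy(), list(d.columns)


class SNMNormalizer(BaseEstimator, TransformerMixin):
    """Supervised-normalization batch correction for log-scale abundance data.

    Removes the adjustment-variable (study) component of each feature while
    preserving the biological-variable (stage) component, via iteratively
    reweighted per-feature least squares.

    Parameters
    ----------
    max_iter : int, default 5
        Maximum reweighting iterations.
    tol : float, default 1e-4
        Convergence threshold on the maximum change of any adjustment
        coefficient between iterations.
    binary_disease : bool, default False
        Collapse the biological factor to control-vs-case instead of the full
        five-level stage coding.

    Attributes
    ----------
    adj_coef_ : ndarray of shape (n_adj_levels - 1, n_features)
        Fitted adjustment (batch) coefficients.
    weights_ : ndarray of shape (n_features,)
        Final per-feature biological-association weights in [0, 1].
    n_iter_ : int
        Iterations actually run.

    Notes
    -----
    ``fit`` expects ``X`` with shape (n_samples, n_features) per sklearn
    convention, with the biological and adjustment labels passed as keyword
    arguments.  Each iteration (a) regresses the batch-cleaned data on the
    biological design, (b) converts the per-feature biological F statistics
    into association weights through Benjamini-Hochberg-adjusted tail
    probabilities of the F null, and (c) re-estimates the adjustment
    coefficients from the data minus the *weighted* biological fit, so null
    features contribute their full profile to the batch estimate while
    strongly associated features contribute only their non-biological part.
    """

    def __init__(self, max_iter: int = 5, tol: float = 1e-4,
                 binary_disease: bool = False):
        self.max_iter = max_iter
        self.tol = tol
        self.binary_disease = binary_disease

    def _designs(self, biological, adjustment):
        bio = pd.Series(biological).astype(str)
        if self.binary_disease:
            bio = pd.Series(np.where(bio == "HC", "HC", "case"))
        B, bio_names = _dummies(bio)
        A, adj_names = _dummies(pd.Series(adjustment).astype(str))
        return B, bio_names, A, adj_names

    def fit(self, X, y=None, *, biological, adjustment):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        bio = pd.Series(biological).reset_index(drop=True)
        adj = pd.Series(adjustment).reset_index(drop=True)
        if len(bio) != n or len(adj) != n:
            raise NormalizationError("label length does not match n_samples")
        if adj.groupby(adj, observed=True).size().min() < 2:
            raise NormalizationError("each adjustment level (study) needs >= 2 samples")

        B, bio_names, A, adj_names = self._designs(bio, adj)
        ones = np.ones((n, 1))
        XB = np.hstack([ones, B])
        XA = np.hstack([ones, A])
        full = np.hstack([ones, B, A])
        rank = np.linalg.matrix_rank(full)
        single_stage = (bio.groupby(adj.to_numpy(), observed=True)
                        .nunique() == 1)
        if rank < full.shape[1]:
            if single_stage.any():
                warnings.warn(
                    "study/stage design is confounded (some study contains a "
                    "single stage); falling back to estimable contrasts",
                    stacklevel=2)
            else:
                raise NormalizationError("rank-deficient stage+study design")

        A_centred = A - A.mean(axis=0)
        B_centred = B - B.mean(axis=0)
        df_bio = B.shape[1]
        df_resid = n - XB.shape[1]

        adj_coef = np.zeros((A.shape[1], p))
        weights = np.ones(p)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # (a) biological fit on batch-cleaned data
            cleaned = X - A_centred @ adj_coef
            beta_b, *_ = np.linalg.lstsq(XB, cleaned, rcond=None)
            resid = cleaned - XB @ beta_b
            rss1 = (resid ** 2).sum(axis=0)
            rss0 = ((cleaned - cleaned.mean(axis=0)) ** 2).sum(axis=0)
            # (b) evidence of biological association -> weights
            with np.errstate(divide="ignore", invalid="ignore"):
                fstat = ((rss0 - rss1) / df_bio) / (rss1 / max(df_resid, 1))
            fstat = np.nan_to_num(fstat, nan=0.0, posinf=np.inf)
            pvals = stats.f.sf(np.clip(fstat, 0, None), df_bio, max(df_resid, 1))
            weights = 1.0 - multipletests(pvals, method="fdr_bh")[1]
            # (c) adjustment fit on data minus weighted biological component
            bio_component = B_centred @ beta_b[1:, :]
            beta_a, *_ = np.linalg.lstsq(XA, X - weights * bio_component,
                                         rcond=None)
            new_adj = beta_a[1:, :]
            delta = np.max(np.abs(new_adj - adj_coef)) if adj_coef.size else 0.0
            adj_coef = new_adj
            if delta < self.tol:
                break

        self.adj_coef_ = adj_coef
        self.weights_ = weights
        self.n_iter_ = n_iter
        self.adj_levels_ = adj_names
        self.adj_mean_ = A.mean(axis=0)
        self._adj_template = pd.Series(adj).astype(str)
        return self

    def transform(self, X, adjustment=None):
        if adjustment is None:
            adjustment = self._adj_template
        A = pd.get_dummies(pd.Series(adjustment).astype(str), dtype=float)
        A = A.reindex(columns=[c for c in self.adj_levels_], fill_value=0.0)
        A_centred = A.to_numpy() - self.adj_mean_
        return np.asarray(X, dtype=float) - A_centred @ self.adj_coef_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def fit_snm(matrix: NormalizedMatrix, metadata: pd.DataFrame,
            biological: str = "stage", adjustment: str = "study",
            max_iter: int = 5, tol: float = 1e-4,
            binary_disease: bool = False) -> NormalizedMatrix:
    """Batch-correct a log-cpm matrix, preserving the stage signal.

    Thin functional wrapper around :class:`SNMNormalizer` operating on the
    feature-by-sample orientation used throughout the pipeline.
    """
    if matrix.unit != "log_cpm":
        raise NormalizationError("fit_snm expects a log_cpm matrix")
    meta = metadata.loc[matrix.sample_ids]
    est = SNMNormalizer(max_iter=max_iter, tol=tol, binary_disease=binary_disease)
    corrected = est.fit_transform(matrix.values.to_numpy().T,
                                  biological=meta[biological],
                                  adjustment=meta[adjustment])
    values = pd.DataFrame(corrected.T, index=matrix.values.index,
                          columns=matrix.values.columns)
    prov = dict(matrix.provenance)
    prov.update({"snm": {"biological": biological, "adjustment": adjustment,
                         "max_iter": max_iter, "tol": tol,
                         "n_iter": est.n_iter_,
                         "binary_disease": binary_disease}})
    return NormalizedMatrix(values, unit="normalized", provenance=prov)


# ---------------------------------------------------------------------------
# Confounder ANOVA on ranks


def _covariate_block(metadata: pd.DataFrame, cov: str) -> np.ndarray:
    col = metadata[cov]
    if cov in ("bmi", "age") or pd.api.types.is_numeric_dtype(col):
        x = pd.to_numeric(col).to_numpy(dtype=float)
        return (x - x.mean())[:, None]
    block, _ = _dummies(col.astype(str))
    return block - block.mean(axis=0)


def confounder_anova(matrix: NormalizedMatrix, metadata: pd.DataFrame,
                     covariates=("stage", "bmi", "age", "sex", "study")
                     ) -> pd.DataFrame:
    """Per-feature fraction of rank variance explained by each covariate.

    Abundances are replaced by midranks across samples; a linear model with
    all covariates is fitted and type-II sums of squares (each covariate's
    increment over the model containing all others) are divided by the total
    rank sum of squares.  Continuous covariates (BMI, age) enter linearly;
    categorical ones as factors.

    Returns a DataFrame indexed by feature with one fraction column per
    covariate plus a ``constant`` flag for features with no rank variance.
    """
    meta = metadata.loc[matrix.sample_ids]
    covariates = [c for c in covariates if c in meta.columns]
    blocks = {c: _covariate_block(meta, c) for c in covariates}
    n = len(meta)
    ones = np.ones((n, 1))

    Y = np.apply_along_axis(stats.rankdata, 1, matrix.values.to_numpy()).T  # samples x features
    ss_total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    constant = ss_total <= 1e-12

    def rss(design: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
        r = Y - design @ beta
        return (r ** 2).sum(axis=0)

    full_design = np.hstack([ones] + [blocks[c] for c in covariates])
    rss_full = rss(full_design)

    out = {}
    for cov in covariates:
        reduced = np.hstack([ones] + [blocks[c] for c in covariates if c != cov])
        ss_cov = np.clip(rss(reduced) - rss_full, 0.0, None)
        frac = np.divide(ss_cov, ss_total, out=np.zeros_like(ss_cov),
                         where=~constant)
        out[cov] = frac
    result = pd.DataFrame(out, index=matrix.values.index)
    result["constant"] = constant
    return result
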