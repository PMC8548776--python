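"""Alpha diversity, Bray-Curtis dissimilarity, PCoA and PCA sample views."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .association import blocked_wilcoxon
from .normalization import NormalizedMatrix
from .profiles import STAGES, ProfileTable


class DiversityError(ValueError):
    pass


@dataclass
class OrdinationResult:
    """Sample coordinates with per-axis eigenvalues and variance fractions."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int = 0


def simpson_diversity(sample_abundances) -> float:
    """Gini-Simpson index 1 - sum(p_i^2) of one sample's abundance vector.

    The probability that two randomly drawn reads belong to different taxa;
    0 for a single-species sample, approaching 1 for many evenly abundant
    species.
    """
    x = np.asarray(sample_abundances, dtype=float)
    if np.any(x < 0):
        raise DiversityError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise DiversityError("zero-sum sample has undefined diversity")
    p = x / total
    return float(1.0 - (p ** 2).sum())


def sample_diversities(profile: ProfileTable) -> pd.Series:
    """Gini-Simpson index for every sample of a profile."""
    return pd.Series({s: simpson_diversity(profile.values[s].to_numpy())
                      for s in profile.sample_ids}, name="simpson")


def inverse_simpson(sample_abundances) -> float:
    """Inverse Simpson index 1 / sum(p_i^2)."""
    x = np.asarray(sample_abundances, dtype=float)
    total = x.sum()
    if total <= 0:
        raise DiversityError("zero-sum sample has undefined diversity")
    p = x / total
    return float(1.0 / (p ** 2).sum())


def stage_diversity_tests(diversities: pd.Series, stages: pd.Series
                          ) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum p-values between stage groups.

    Unstratified (single-block) tests on the per-sample diversity values;
    stage pairs where either group has fewer than two samples are reported
    as NaN.
    """
    stages = stages.loc[diversities.index]
    present = [s for s in STAGES if (stages == s).sum() > 0]
    out = pd.DataFrame(np.nan, index=present, columns=present)
    block = np.zeros(len(diversities), dtype=int)
    for i, a in enumerate(present):
        out.loc[a, a] = 1.0
        for b in present[i + 1:]:
            sel = stages.isin([a, b]).to_numpy()
            if (stages == a).sum() < 2 or (stages == b).sum() < 2:
                continue
            _, p = blocked_wilcoxon(diversities.to_numpy()[sel],
                                    (stages == a).to_numpy()[sel],
                                    block[sel], mode="auto")
            out.loc[a, b] = out.loc[b, a] = p
    return out


def bray_curtis(profile: ProfileTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix on per-sample relative abundances.

    d(x, y) = 1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y) after scaling each
    sample to proportions, making the distance library-size invariant.
    """
    arr = profile.values.to_numpy(dtype=float).T  # samples x features
    if np.any(arr < 0):
        raise DiversityError("abundances must be nonnegative")
    totals = arr.sum(axis=1)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(profile.sample_ids, totals) if t <= 0]
        raise DiversityError(f"zero-sum samples: {bad}")
    rel = arr / totals[:, None]
    dist = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(dist, index=profile.sample_ids, columns=profile.sample_ids)


def pcoa(dist: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centred Gower matrix; axes with
    negative eigenvalues (non-Euclidean distances) are dropped without
    correction and excluded from the proportion-explained denominator,
    their count being reported instead.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise DiversityError("distance matrix must be square and symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0)
    n_negative = int((eigvals < -1e-10 * max(abs(eigvals[0]), 1.0)).sum())
    k = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    denom = eigvals[positive].sum()
    prop = eigvals[:k] / denom if denom > 0 else np.zeros(k)
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=index,
                         columns=[f"PCo{i + 1}" for i in range(k)])
    if k < n_axes:  # degenerate input: pad with zero axes for a stable shape
        for i in range(k, n_axes):
            frame[f"PCo{i + 1}"] = 0.0
        eigvals_out = np.concatenate([eigvals[:k], np.zeros(n_axes - k)])
        prop = np.concatenate([prop, np.zeros(n_axes - k)])
    else:
        eigvals_out = eigvals[:n_axes]
    return OrdinationResult(frame, eigvals_out, np.asarray(prop),
                            n_negative_eigenvalues=n_negative)


def pca_view(norm: NormalizedMatrix, n_components: int = 2) -> OrdinationResult:
    """Feature-centred PCA of the samples of a normalized matrix.

    The standard view for judging batch structure: samples cluster by study
    before batch correction and mix afterwards.
    """
    X = norm.values.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < n_components:
        raise DiversityError("fewer samples than requested components")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    frame = pd.DataFrame(scores, index=norm.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    eigvals = model.explained_variance_ * (X.shape[0] - 1)
    return OrdinationResult(frame, eigvals, model.explained_variance_ratio_)
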