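"""Profile and metadata tables: reading, writing, cpm conversion, feature filtering.

Abundance profiles are feature-by-sample matrices (species, genus, pathway or
gene-family level).  Feature identifiers may be plain names or MetaPhlAn-style
pipe-delimited taxonomy strings (``k__...|p__...|...|s__...``); the reader can
restrict such tables to a single taxonomic rank.  Metadata carries, per sample,
the study of origin, the ordered disease stage (HC < NAFL < NASH < fibrosis <
cirrhosis), BMI, age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Ordered disease-stage labels: healthy controls, then the four patient stages
#: in order of progression.
STAGES = ("HC", "NAFL", "NASH", "fibrosis", "cirrhosis")

#: Integer progression rank per stage (HC = 0 ... cirrhosis = 4).
STAGE_RANK = {stage: rank for rank, stage in enumerate(STAGES)}

PATIENT_STAGES = STAGES[1:]

VALID_UNITS = ("counts", "relative", "cpm", "log_cpm", "normalized")

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}


class ProfileError(ValueError):
    """Malformed profile or metadata input."""


@dataclass
class ProfileTable:
    """A feature-by-sample abundance matrix with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Features as rows (index = feature IDs), samples as columns.
    unit : str
        One of ``counts``, ``relative``, ``cpm``, ``log_cpm``, ``normalized``.
        Values must be nonnegative except for the two log-scale units.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ProfileError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx, cols = self.values.index, self.values.columns
        for name, labels in (("feature", idx), ("sample", cols)):
            if labels.duplicated().any():
                dups = labels[labels.duplicated()].unique().tolist()
                raise ProfileError(f"duplicate {name} IDs: {dups}")
        if self.unit not in ("log_cpm", "normalized"):
            arr = self.values.to_numpy()
            if np.any(arr < 0):
                bad = self.values.index[(arr < 0).any(axis=1)].tolist()
                raise ProfileError(f"negative abundances in features: {bad[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids) -> "ProfileTable":
        return replace(self, values=self.values.loc[list(feature_ids)])

    def subset_samples(self, sample_ids) -> "ProfileTable":
        return replace(self, values=self.values[list(sample_ids)])


def stage_categorical(labels) -> pd.Categorical:
    """Encode stage labels as an ordered categorical over the five stages."""
    labels = pd.Series(labels, dtype=object)
    unknown = set(labels.dropna()) - set(STAGES)
    if unknown:
        raise ProfileError(f"unknown stage labels: {sorted(unknown)}")
    return pd.Categorical(labels, categories=list(STAGES), ordered=True)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate per-sample metadata and coerce the stage column.

    Expects the index to hold sample IDs and at least the columns
    ``study``/``stage``; ``bmi``, ``age`` and ``sex`` are carried through
    when present.  BMI, when present, must be positive.
    """
    if metadata.index.duplicated().any():
        raise ProfileError("duplicate sample IDs in metadata")
    for col in ("study", "stage"):
        if col not in metadata.columns:
            raise ProfileError(f"metadata missing required column {col!r}")
    out = metadata.copy()
    out["stage"] = stage_categorical(out["stage"])
    if "bmi" in out.columns:
        bmi = pd.to_numeric(out["bmi"], errors="coerce")
        if (bmi.dropna() <= 0).any():
            bad = out.index[bmi <= 0].tolist()
            raise ProfileError(f"nonpositive BMI for samples: {bad}")
        out["bmi"] = bmi
    return out


def align_metadata(profile: ProfileTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Strict one-to-one join of metadata rows onto profile samples.

    Any sample present in one table but not the other is an error (silent
    dropping would desynchronize labels from columns downstream).
    """
    metadata = validate_metadata(metadata)
    missing = set(profile.sample_ids) - set(metadata.index)
    extra = set(metadata.index) - set(profile.sample_ids)
    if missing:
        raise ProfileError(f"samples without metadata: {sorted(missing)[:5]}")
    if extra:
        raise ProfileError(f"metadata rows without samples: {sorted(extra)[:5]}")
    return metadata.loc[profile.sample_ids]


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path) -> pd.DataFrame:
    # pandas silently renames duplicate header columns; check them verbatim
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")[1:]
            dups = {h for h in header if header.count(h) > 1}
            if dups:
                raise ProfileError(f"duplicate sample columns: {sorted(dups)}")
            break
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ProfileError(f"cannot parse {path}: {exc}") from exc


def taxonomy_rank(feature_id: str) -> str | None:
    """Deepest taxonomic rank of a MetaPhlAn-style pipe-delimited ID."""
    last = feature_id.rsplit("|", 1)[-1]
    for rank, prefix in _RANK_PREFIX.items():
        if last.startswith(prefix):
            return rank
    return None


def read_profile(path, unit: str = "counts", taxonomy_dialect: str | None = None,
                 rank: str = "species") -> ProfileTable:
    """Read a feature-by-sample TSV profile.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with feature IDs in the first column and sample IDs
        in the header; ``#``-prefixed lines are ignored.
    unit : str
        Unit to declare on the returned table.
    taxonomy_dialect : {None, "metaphlan"}
        With ``"metaphlan"``, rows are restricted to the requested taxonomic
        ``rank`` by inspecting the deepest pipe-delimited rank prefix.
    rank : str
        Rank kept under the MetaPhlAn dialect (``species`` or ``genus`` in
        typical use).
    """
    frame = _read_tsv(path)
    if taxonomy_dialect == "metaphlan":
        if rank not in _RANK_PREFIX:
            raise ProfileError(f"unknown taxonomic rank {rank!r}")
        keep = [fid for fid in frame.index if taxonomy_rank(str(fid)) == rank]
        frame = frame.loc[keep]
    elif taxonomy_dialect is not None:
        raise ProfileError(f"unknown taxonomy dialect {taxonomy_dialect!r}")
    return ProfileTable(frame.astype(float), unit=unit)


def write_profile(profile: ProfileTable, path) -> None:
    profile.values.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(_read_tsv(path))


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Unit conversion and filtering


def to_cpm(profile: ProfileTable) -> ProfileTable:
    """Rescale every sample to counts-per-million (column sums of 1e6).

    Accepts raw counts or relative abundances; idempotent on cpm input.
    Library size is thereby divided out, so samples of different sequencing
    depth become comparable.
    """
    if profile.unit not in ("counts", "relative", "cpm"):
        raise ProfileError(f"to_cpm expects counts/relative input, got {profile.unit!r}")
    totals = profile.values.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ProfileError(f"all-zero samples cannot be scaled to cpm: {zero}")
    values = profile.values.div(totals, axis=1) * 1e6
    return ProfileTable(values, unit="cpm")


def prevalence_filter(profile: ProfileTable, min_cpm: float = 1.0,
                      min_samples: int = 3, strict: bool = True) -> ProfileTable:
    """Drop features not exceeding ``min_cpm`` in at least ``min_samples`` samples.

    The boundary is strict by default: a feature must have cpm *greater than*
    ``min_cpm`` (not equal) in enough samples to be kept.
    """
    if profile.unit != "cpm":
        raise ProfileError("prevalence_filter expects a cpm table; call to_cpm first")
    arr = profile.values.to_numpy()
    hits = (arr > min_cpm) if strict else (arr >= min_cpm)
    keep = hits.sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return ProfileTable(profile.values.loc[keep], unit="cpm")


def consistent_features(profile: ProfileTable, metadata: pd.DataFrame,
                        min_cpm: float = 1.0, min_samples: int = 3,
                        strict: bool = True) -> list[str]:
    """Features passing the prevalence filter within *every* study separately.

    This is the cross-study consistency rule: a feature merely detected in the
    pooled table is not enough, it must be reliably present in each cohort.
    """
    metadata = align_metadata(profile, metadata)
    studies = metadata["study"].unique()
    kept: set[str] | None = None
    for study in studies:
        samples = metadata.index[metadata["study"] == study]
        sub = profile.subset_samples(samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            passed = set(prevalence_filter(sub, min_cpm, min_samples, strict).feature_ids)
        kept = passed if kept is None else kept & passed
    if kept is None:
        raise ProfileError("no studies in metadata")
    return [fid for fid in profile.feature_ids if fid in kept]
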