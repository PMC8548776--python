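"""End-to-end orchestration: filter -> normalize -> associate -> diversity ->
network -> machine learning, from a single config, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (make_blocks, progression_consistent,
                          run_meta_analysis, run_progression)
from .diversity import bray_curtis, pca_view, pcoa, sample_diversities, stage_diversity_tests
from .ml import TrainConfig, one_vs_rest_models, stage_vs_control_matrix
from .network import build_network, spearman_matrix, write_network
from .normalization import confounder_anova, fit_snm, log_cpm
from .profiles import (ProfileTable, align_metadata, consistent_features,
                       prevalence_filter, read_metadata, read_profile, to_cpm)
from .synthetic import balanced_preset, generate_cohort

log = logging.getLogger("nafld_meta")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``profile_path``/``metadata_path`` unset, the bundled balanced
    synthetic preset is generated instead (useful for smoke runs and demos).
    """

    out_dir: str = "nafld_meta_run"
    profile_path: str | None = None
    metadata_path: str | None = None
    rank: str = "species"
    taxonomy_dialect: str | None = None
    unit: str = "counts"
    min_cpm: float = 1.0
    min_samples: int = 3
    per_study: bool = True
    pseudocount: float = 1.0
    snm_max_iter: int = 5
    snm_tol: float = 1e-4
    n_bmi_bins: int = 3
    fdr: float = 0.05
    core_fdr: float = 1e-3
    network_rho: float = 0.8
    ml: TrainConfig = field(default_factory=TrainConfig)
    run_ml: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name, value in (("fdr", self.fdr), ("core_fdr", self.core_fdr),
                            ("network_rho", self.network_rho)):
            if not 0 < value <= 1:
                raise PipelineError(f"{name} must lie in (0, 1], got {value}")
        self.ml.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ml = TrainConfig(**raw.pop("ml", {}))
        cfg = cls(ml=ml, **raw)
        cfg.validate()
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_all(config: RunConfig) -> dict:
    """Execute every analysis stage and return the run manifest.

    Writes, under ``config.out_dir``: the filtered profile, the normalized
    matrix, the variance partition, the association and progression tables,
    the progression-consistent feature list, diversity values and pairwise
    stage tests, the Bray-Curtis matrix with PCoA coordinates, PCA views
    before and after batch correction, the co-occurrence network, and (when
    ``run_ml``) the transfer and one-vs-rest evaluation matrices.  The
    manifest records the config, row counts per stage and a sha256 checksum
    of every output, so that reruns are verifiably identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _config_dict(config),
                      "counts": {}, "outputs": {}}
    stage = "load"
    try:
        if config.profile_path is None:
            synth = balanced_preset(seed=config.seed)
            profile, metadata, truth = generate_cohort(synth)
            _write(truth, out / "truth.tsv", index=False)
        else:
            profile = read_profile(config.profile_path, unit=config.unit,
                                   taxonomy_dialect=config.taxonomy_dialect,
                                   rank=config.rank)
            metadata = read_metadata(config.metadata_path)
        metadata = align_metadata(profile, metadata)
        manifest["counts"]["input"] = dict(zip(("features", "samples"), profile.shape))

        stage = "filter"
        cpm = to_cpm(profile)
        filtered = prevalence_filter(cpm, config.min_cpm, config.min_samples)
        manifest["counts"]["prevalence_filtered"] = filtered.shape[0]
        if config.per_study:
            features = consistent_features(cpm, metadata, config.min_cpm,
                                           config.min_samples)
        else:
            features = filtered.feature_ids
        manifest["counts"]["consistent"] = len(features)
        log.info("%d features pass filtering (%d consistent across studies)",
                 filtered.shape[0], len(features))
        cpm = cpm.subset_features(features)
        _write(cpm.values, out / "filtered_cpm.tsv", index_label="feature_id")

        stage = "normalize"
        logged = log_cpm(cpm, pseudocount=config.pseudocount)
        pca_pre = pca_view(logged)
        norm = fit_snm(logged, metadata, max_iter=config.snm_max_iter,
                       tol=config.snm_tol)
        pca_post = pca_view(norm)
        _write(norm.values, out / "normalized.tsv", index_label="feature_id")
        _write(pca_pre.coordinates, out / "pca_log_cpm.tsv", index_label="sample_id")
        _write(pca_post.coordinates, out / "pca_snm.tsv", index_label="sample_id")

        stage = "confounder_anova"
        variance = confounder_anova(norm, metadata)
        _write(variance, out / "variance_partition.tsv", index_label="feature_id")

        stage = "associations"
        blocks = make_blocks(metadata, n_bmi_bins=config.n_bmi_bins)
        assoc = run_meta_analysis(norm, metadata, blocks=blocks,
                                  fdr=config.fdr, core_fdr=config.core_fdr)
        _write(assoc, out / "associations.tsv", index=False)
        meta_rows = assoc[assoc["contrast"] == "meta"]
        manifest["counts"]["meta_significant"] = int(meta_rows["significant"].sum())
        manifest["counts"]["core_set"] = int(meta_rows["core_flag"].sum())
        progression = run_progression(norm, metadata, fdr=config.fdr)
        _write(progression, out / "progression.tsv", index=False)
        consistent = progression_consistent(assoc, fdr=config.fdr)
        _write(consistent, out / "progression_consistent.tsv", index=False)

        stage = "diversity"
        diversities = sample_diversities(cpm)
        div = diversities.to_frame()
        div["stage"] = metadata["stage"].astype(str)
        _write(div, out / "alpha_diversity.tsv", index_label="sample_id")
        _write(stage_diversity_tests(diversities, metadata["stage"]),
               out / "alpha_diversity_tests.tsv", index_label="stage")
        dist = bray_curtis(cpm)
        _write(dist, out / "bray_curtis.tsv", index_label="sample_id")
        ordination = pcoa(dist)
        _write(ordination.coordinates, out / "pcoa.tsv", index_label="sample_id")

        stage = "network"
        core_ids = sorted(set(meta_rows.loc[meta_rows["core_flag"], "feature_id"]))
        manifest["counts"]["network_nodes"] = len(core_ids)
        if len(core_ids) >= 2:
            rho = spearman_matrix(norm.values.loc[core_ids])
            graph = build_network(rho, threshold=config.network_rho)
            write_network(graph, edge_path=out / "network_edges.tsv",
                          graphml_path=out / "network.graphml")
            manifest["counts"]["network_edges"] = graph.number_of_edges()

        if config.run_ml:
            stage = "ml_transfer"
            transfer = stage_vs_control_matrix(norm, metadata, config.ml)
            _write(transfer.auroc, out / "transfer_auroc.tsv", index_label="train_stage")
            _write(transfer.aupr, out / "transfer_aupr.tsv", index_label="train_stage")
            for s, imp in transfer.importance.items():
                _write(imp.to_frame("relative_influence"),
                       out / f"importance_{s}_vs_HC.tsv", index_label="feature_id")
            stage = "ml_one_vs_rest"
            ovr = one_vs_rest_models(norm, metadata, config.ml)
            _write(ovr.auroc.join(ovr.aupr, lsuffix="_auroc", rsuffix="_aupr"),
                   out / "one_vs_rest.tsv", index_label="stage")
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.glob("*")):
        if path.is_file():
            manifest["outputs"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["ml"]["interaction_depth"] = list(d["ml"]["interaction_depth"])
    d["ml"]["n_trees"] = list(d["ml"]["n_trees"])
    return d
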