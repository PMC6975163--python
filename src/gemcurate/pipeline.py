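"""End-to-end pipeline orchestration with a run manifest.

Stages: gap-fill ensemble generation → ensemble essentiality simulation →
clustering/classification analysis → optional evaluation against an
experimental essentiality table and subsystem meta-analysis.  A manifest
(JSON) records parameters, seeds, per-stage wall time, and outputs so a
run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .curation import (
    cluster_members,
    collapse_correlated_genes,
    compute_curation_metrics,
    curation_targets,
    pcoa_hamming,
)
from .ensemble import (
    Ensemble,
    ensemble_essentiality,
    subsample_curve,
)
from .errors import GemcurateError
from .evaluation import compare_cluster_performance, precision_recall, subsystem_stats
from .fixtures import read_experimental_essentiality
from .gapfill import (
    DEFAULT_ACTIVATION_CUTOFF,
    DEFAULT_BIOMASS_FLOOR,
    generate_ensemble,
)
from .fba import DEFAULT_ESSENTIALITY_THRESHOLD
from .model import (
    read_media,
    read_model,
    read_subsystem_annotation,
    read_universal,
)

logger = logging.getLogger("gemcurate")


@dataclass
class RunConfig:
    """Declarative pipeline configuration; defaults match the method's
    published operating point."""

    model_path: str
    universal_path: str
    media_path: str
    output_dir: str
    essentiality_path: str | None = None
    annotation_path: str | None = None
    n_members: int = 1000
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR
    activation_cutoff: float = DEFAULT_ACTIVATION_CUTOFF
    essentiality_threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD
    seed: int = 0
    subsample_step: int = 20
    subsample_draws: int = 1000
    min_unique_members: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; write artifacts and a manifest; return outdir.

    Any stage error halts the run with the stage name; artifacts written
    by completed stages are kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": [],
    }
    stage_name = "load-inputs"
    try:
        t0 = time.perf_counter()
        model = read_model(config.model_path)
        universal = read_universal(config.universal_path)
        media = read_media(config.media_path)
        _record(manifest, stage_name, t0)

        stage_name = "gapfill-ensemble"
        t0 = time.perf_counter()
        ensemble = generate_ensemble(
            model, universal, media,
            n=config.n_members,
            seed=config.seed,
            biomass_floor=config.biomass_floor,
            activation_cutoff=config.activation_cutoff,
            min_unique=config.min_unique_members,
        )
        ensemble.write(out / "ensemble")
        _record(manifest, stage_name, t0,
                n_members=ensemble.n_members,
                n_variable_reactions=len(ensemble.variable_reactions))

        stage_name = "simulate-essentiality"
        t0 = time.perf_counter()
        matrix = ensemble_essentiality(
            ensemble, threshold=config.essentiality_threshold
        )
        matrix.to_tsv(out / "essentiality.tsv")
        if ensemble.n_members >= config.subsample_step:
            for stat, data in (
                ("variable_reactions", ensemble.feature_matrix),
                ("non_consensus_genes", matrix.values),
            ):
                curve = subsample_curve(
                    data, stat,
                    step=config.subsample_step,
                    draws=config.subsample_draws,
                    seed=config.seed,
                )
                curve.to_tsv(out / f"subsample_{stat}.tsv")
        _record(manifest, stage_name, t0,
                n_genes=len(matrix.genes),
                n_non_consensus=len(matrix.non_consensus_genes()))

        stage_name = "analyze"
        t0 = time.perf_counter()
        reduced, reps, groups = collapse_correlated_genes(matrix)
        assignment = cluster_members(
            reduced, matrix.member_ids, k=2, seed=config.seed,
            collapsed_groups=groups,
        )
        _write_tsv_labels(assignment.labels, out / "clusters.tsv")
        pcoa = pcoa_hamming(matrix)
        pcoa.to_frame().to_csv(out / "pcoa.tsv", sep="\t")
        metrics = compute_curation_metrics(ensemble, assignment, seed=config.seed)
        metrics.to_tsv(out / "metrics.tsv")
        targets = curation_targets(metrics)
        targets.to_csv(out / "curation_targets.tsv", sep="\t", index=False)
        plot_data = metrics.table[["cluster_ratio", "fractional_importance"]]
        plot_data.to_csv(out / "curation_plot.tsv", sep="\t")
        _record(manifest, stage_name, t0, oob_accuracy=metrics.oob_accuracy)

        stage_name = "evaluate"
        t0 = time.perf_counter()
        if config.essentiality_path:
            experimental = read_experimental_essentiality(config.essentiality_path)
            report = precision_recall(matrix, experimental, assignment.labels)
            report.to_csv(out / "performance.tsv", sep="\t")
            tests = compare_cluster_performance(report)
            tests.to_csv(out / "cluster_tests.tsv", sep="\t", index=False)
            _record(manifest, stage_name, t0, n_shared_genes=int(
                len([g for g in matrix.genes if g in experimental])))
        else:
            _record(manifest, stage_name, t0, skipped=True)

        stage_name = "meta"
        t0 = time.perf_counter()
        if config.annotation_path:
            annotation = read_subsystem_annotation(config.annotation_path)
            try:
                stats = subsystem_stats(
                    metrics.table.rename(columns={
                        "fractional_importance": "mean_fractional_importance"
                    }),
                    annotation,
                )
                stats["summary"].to_csv(out / "subsystem_summary.tsv", sep="\t")
                stats["pairwise"].to_csv(
                    out / "subsystem_pairwise.tsv", sep="\t", index=False
                )
                _record(manifest, stage_name, t0,
                        omnibus_p=stats["p_value"])
            except GemcurateError as exc:
                _record(manifest, stage_name, t0, skipped=True, reason=str(exc))
        else:
            _record(manifest, stage_name, t0, skipped=True)
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=_json_default)
            + "\n"
        )
    logger.info("pipeline complete: %s", out)
    return out


def _record(manifest: dict, stage: str, t0: float, **extra) -> None:
    manifest["stages"].append(
        {"stage": stage, "wall_time_s": round(time.perf_counter() - t0, 4), **extra}
    )
    logger.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)


def _write_tsv_labels(labels: dict[str, int], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(labels.items()), columns=["member", "cluster"]
    ).to_csv(path, sep="\t", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
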