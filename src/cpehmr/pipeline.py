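"""End-to-end pipeline: files in, per-group report tables out.

Stages: load promoters and groups -> build transcribed regions -> load
and normalize peak tracks -> assemble per-group HMR matrices -> attach
expression -> cluster statistics -> regression battery (best subset,
CV, LMG, random forest, void split) -> frequency and correlation
tables. Each stage logs record counts in/out, so the study's filters
are visible as count deltas; any stage error aborts the run naming the
stage and offending records. A manifest records the config hash, seeds
and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cpe_classifier import (
    assign_groups,
    promoters_from_annotation,
    read_promoter_annotation,
)
from .expression import aggregate_fpkm, attach_expression, correlate
from .genomic_model import (
    CPE_GROUPS,
    FEATURE_LABELS,
    CorePromoter,
    Mark,
    PeakTrack,
    Stage,
    build_transcribed_region,
    read_bed,
    read_expression_table,
    read_fasta,
    read_transcript_bed,
)
from .hmr_engine import HmrMatrix, build_matrix
from .pattern_stats import cluster_null_test, frequency_table, hierarchical_order, kmeans_partition
from .regression_suite import (
    DEFAULT_VOID_WINDOWS,
    cross_validate,
    exhaustive_subset_search,
    lmg_importance,
    rf_regress,
    select_final_model,
    split_void,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_study", "build_group_matrices"]

logger = logging.getLogger("cpehmr.pipeline")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and algorithm parameters of one run."""

    annotation: str
    transcripts_bed: str
    peaks_dir: str
    expression_tsv: str
    output_dir: str
    promoters_fasta: str | None = None  # enables sequence-scan classification
    tss_index: int = 60

    alpha: float = 0.05
    folds: int = 10
    mtry: int = 2
    ntree: int = 500
    cluster_k: int = 3
    cluster_n_iter: int = 100_000
    kmeans_k: int = 5
    kmeans_restarts: int = 1000
    frequency_threshold: float = 0.5
    transform_rule: str = "min_positive"
    void_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOID_WINDOWS)
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict) and key in ("inputs", "params", "output"):
                flat.update(value)
            else:
                flat[key] = value
        if "void_windows" in flat:
            flat["void_windows"] = {
                g: tuple(w) for g, w in flat["void_windows"].items()
            }
        return cls(**flat)

    def validate_paths(self) -> None:
        for label, p in (
            ("annotation", self.annotation),
            ("transcripts_bed", self.transcripts_bed),
            ("peaks_dir", self.peaks_dir),
            ("expression_tsv", self.expression_tsv),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p} does not exist")
        if self.promoters_fasta is not None and not Path(self.promoters_fasta).exists():
            raise FileNotFoundError(f"promoters_fasta: {self.promoters_fasta} does not exist")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_peak_tracks(peaks_dir: str | Path, stages=tuple(Stage)) -> dict[tuple[Mark, Stage], PeakTrack]:
    """Load every (mark, stage) BED; a missing file is a hard error."""
    peaks_dir = Path(peaks_dir)
    tracks: dict[tuple[Mark, Stage], PeakTrack] = {}
    missing = []
    for mark in Mark:
        for stage in stages:
            path = peaks_dir / f"{mark.value}_{stage.name}.bed"
            if not path.exists():
                missing.append((mark.value, stage.name))
                continue
            tracks[(mark, stage)] = PeakTrack.from_intervals(mark, stage, read_bed(path))
    if missing:
        raise FileNotFoundError(f"missing peak BED files for (mark, stage): {missing}")
    return tracks


def load_study(config: PipelineConfig):
    """Load and label promoters, transcripts, tracks and expression."""
    annotation = read_promoter_annotation(config.annotation)
    promoters = promoters_from_annotation(annotation)
    sequences = read_fasta(config.promoters_fasta) if config.promoters_fasta else None
    if sequences is not None:
        # sequence route: groups come from motif scanning, annotation
        # supplies coordinates only
        bare = [p.with_group("Unassigned") for p in promoters]
        promoters, counts, excluded = assign_groups(
            bare, annotation=None, sequences=sequences, tss_index=config.tss_index
        )
    else:
        promoters, counts, excluded = assign_groups(promoters, annotation=annotation)
    logger.info("promoters labelled: %s (excluded %d)", counts, len(excluded))
    transcripts = read_transcript_bed(config.transcripts_bed)
    tracks = load_peak_tracks(config.peaks_dir)
    expression = read_expression_table(config.expression_tsv)
    return promoters, transcripts, tracks, expression


def build_group_matrices(
    promoters: list[CorePromoter],
    transcripts,
    tracks,
    expression: pd.DataFrame,
    *,
    transform_rule: str = "min_positive",
    stages=tuple(Stage),
) -> dict[str, HmrMatrix]:
    """Per-group HMR matrices with expression attached."""
    by_tss: dict[tuple[str, int], list] = {}
    for tx in transcripts:
        by_tss.setdefault((tx.chrom, tx.tss), []).append(tx)
    matrices: dict[str, HmrMatrix] = {}
    for group in CPE_GROUPS:
        members = [p for p in promoters if p.group == group]
        if not members:
            continue
        t_regions = {}
        missing = []
        for p in members:
            txs = by_tss.get((p.region.chrom, p.tss))
            if not txs:
                missing.append(p.promoter_id)
                continue
            t_regions[p.promoter_id] = build_transcribed_region(p.tss, txs)
        if missing:
            raise ValueError(f"{group}: promoters without transcripts at their TSS: {missing}")
        matrix = build_matrix(members, t_regions, tracks, stages, group=group)
        fpkm = aggregate_fpkm(members, transcripts, expression, stages)
        matrices[group] = attach_expression(matrix, fpkm, rule=transform_rule)
        logger.info("group %s: %d promoters x %d stages = %d observations",
                    group, len(members), len(stages), len(matrices[group]))
    return matrices


def _analyse_group(group: str, matrix: HmrMatrix, config: PipelineConfig) -> dict:
    out: dict = {"n_obs": len(matrix)}
    winners = exhaustive_subset_search(matrix)
    model = select_final_model(winners, alpha=config.alpha)
    report = cross_validate(model.features, matrix, folds=config.folds, seed=config.seed)
    lmg = lmg_importance(model.features, matrix)
    rf = rf_regress(
        matrix, mtry=config.mtry, ntree=config.ntree, seed=config.seed
    )
    out.update(
        model=model,
        cv=report,
        lmg=lmg,
        rf=rf,
        correlations=correlate(matrix),
    )
    if group in config.void_windows:
        # the split is a prediction task: the full six-feature model avoids
        # selection-induced omitted-variable shifts of the void predictions
        window = tuple(config.void_windows[group])
        cv_full = cross_validate(
            FEATURE_LABELS, matrix, folds=config.folds, seed=config.seed
        )
        out["cv_full"] = cv_full
        out["void_linear"] = split_void(matrix, cv_full.cv_predictions, window)
        out["void_rf"] = split_void(matrix, rf.predictions, window)
    points = matrix.features
    out["heat_order"] = hierarchical_order(points)
    if group in ("Inr", "DPE"):
        km = kmeans_partition(
            points, k=config.cluster_k, n_restarts=config.kmeans_restarts,
            seed=config.seed, feature_names=FEATURE_LABELS,
        )
        out["cluster_test"] = cluster_null_test(
            points, km.centers, n_iter=config.cluster_n_iter, seed=config.seed
        )
    out["kmeans"] = kmeans_partition(
        points, k=config.kmeans_k, n_restarts=config.kmeans_restarts,
        seed=config.seed, feature_names=FEATURE_LABELS,
    )
    return out


def _write_group_outputs(group: str, res: dict, matrix: HmrMatrix, outdir: Path) -> None:
    gdir = outdir / group
    gdir.mkdir(parents=True, exist_ok=True)
    wide = matrix.data.copy()
    wide["stage"] = wide["stage"].map(lambda s: s.name)
    wide.to_csv(gdir / "hmr_matrix.tsv", sep="\t", index=False, float_format="%.6g")
    matrix.to_long().assign(stage=lambda d: d["stage"].map(lambda s: s.name)).to_csv(
        gdir / "hmr_long.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame({"row_order": res["heat_order"]}).to_csv(
        gdir / "heatmap_row_order.tsv", sep="\t", index=False
    )
    model = res["model"]
    pd.DataFrame(
        [
            {"feature": f, "coefficient": model.coefficients[f], "p_value": model.coef_p[f]}
            for f in model.features
        ]
        + [{"feature": "(intercept)", "coefficient": model.intercept, "p_value": float("nan")}]
    ).to_csv(gdir / "selected_model.tsv", sep="\t", index=False, float_format="%.6g")
    cv = res["cv"]
    scatter = matrix.data[["promoter_id"]].copy()
    scatter["stage"] = matrix.data["stage"].map(lambda s: s.name)
    scatter["measured"] = matrix.data["log_fpkm"]
    scatter["predicted"] = cv.cv_predictions
    scatter["fold"] = cv.fold_assignment
    scatter.to_csv(gdir / "cv_scatter.tsv", sep="\t", index=False, float_format="%.6g")
    pd.Series(res["lmg"].weights, name="lmg").rename_axis("feature").to_csv(
        gdir / "importance_lmg.tsv", sep="\t", float_format="%.6g"
    )
    pd.Series(res["rf"].importance.weights, name="node_impurity").rename_axis("feature").to_csv(
        gdir / "importance_rf.tsv", sep="\t", float_format="%.6g"
    )
    res["correlations"].rename_axis("feature").to_csv(
        gdir / "correlations.tsv", sep="\t", float_format="%.6g"
    )
    if "cluster_test" in res:
        ct = res["cluster_test"]
        pd.Series(asdict(ct)).rename_axis("key").to_csv(
            gdir / "cluster_test.tsv", sep="\t", header=["value"]
        )
    res["kmeans"].summaries.to_csv(
        gdir / "kmeans_clusters.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for key, fname in (("void_linear", "void_split_linear.tsv"), ("void_rf", "void_split_rf.tsv")):
        if key in res:
            split = res[key]
            membership = np.full(len(matrix), "p")
            membership[split.n_index] = "n"
            pd.DataFrame(
                {
                    "promoter_id": matrix.data["promoter_id"],
                    "stage": matrix.data["stage"].map(lambda s: s.name),
                    "subset": membership,
                }
            ).to_csv(gdir / fname, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the per-group report bundle.

    Returns the in-memory results: {"matrices": ..., "groups": {group:
    {model, cv, lmg, rf, cluster_test, ...}}, "frequency": ...}.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load_inputs"
    try:
        promoters, transcripts, tracks, expression = load_study(config)
        stage = "build_matrices"
        matrices = build_group_matrices(
            promoters, transcripts, tracks, expression,
            transform_rule=config.transform_rule,
        )
        stage = "group_analyses"
        results = {g: _analyse_group(g, m, config) for g, m in matrices.items()}
        stage = "frequency_table"
        freq = frequency_table(matrices, threshold=config.frequency_threshold)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for group, res in results.items():
        _write_group_outputs(group, res, matrices[group], outdir)
    freq.data.to_csv(outdir / "frequency_table.tsv", sep="\t", float_format="%.6g")

    manifest = {
        "cpehmr_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "group_sizes": {g: int(len(m) // 11) if len(m) % 11 == 0 else None for g, m in matrices.items()},
        "n_observations": {g: int(len(m)) for g, m in matrices.items()},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"matrices": matrices, "groups": results, "frequency": freq, "manifest": manifest}
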