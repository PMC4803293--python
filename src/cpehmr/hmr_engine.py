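"""Histone modification ratio (HMR) computation.

The HMR of a region under a peak track is the fraction of the region's
bases covered by called peaks — a number in [0, 1]. Tracks are merged
before overlap computation, so stacked peak calls can never push the
ratio above 1. Computed for each promoter at each stage over two regions
(core promoter, transcribed region) and three marks, the HMRs form the
six-feature observation matrix that all downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_model import (
    FEATURE_LABELS,
    FEATURES,
    CorePromoter,
    FeatureId,
    GenomicInterval,
    Mark,
    PeakTrack,
    RegionKind,
    Stage,
)

__all__ = ["compute_hmr", "HmrObservation", "HmrMatrix", "build_matrix"]


def compute_hmr(
    region: GenomicInterval, track: PeakTrack, *, chrom_harmonize: bool = False
) -> float:
    """Coverage fraction of ``region`` under a normalized peak track.

    ``chrom_harmonize`` relaxes chromosome matching to tolerate a "chr"
    prefix mismatch between the region and the track.
    """
    if chrom_harmonize:
        chroms = {region.chrom, f"chr{region.chrom}", region.chrom.removeprefix("chr")}
        overlap = 0
        for chrom in chroms:
            probe = GenomicInterval(chrom, region.start, region.end, region.strand)
            overlap = max(overlap, track.overlap_length(probe))
    else:
        overlap = track.overlap_length(region)
    return overlap / region.length


@dataclass(frozen=True)
class HmrObservation:
    """One promoter at one stage: the regression row."""

    promoter_id: str
    stage: Stage
    hmr: dict[str, float]  # feature label -> ratio in [0, 1]
    fpkm: float = float("nan")
    log_fpkm: float = float("nan")


@dataclass
class HmrMatrix:
    """Per-group observation matrix: one row per promoter x stage.

    ``data`` columns: promoter_id, stage (Stage), the six feature labels,
    and — once the expression module has run — fpkm and log_fpkm.
    """

    group: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(FEATURE_LABELS) - set(self.data.columns)
        if missing:
            raise ValueError(f"HMR matrix missing feature columns {sorted(missing)}")
        vals = self.data[list(FEATURE_LABELS)].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("HMR values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> np.ndarray:
        return self.data[list(FEATURE_LABELS)].to_numpy(dtype=float)

    def observations(self) -> Iterator[HmrObservation]:
        has_expr = "log_fpkm" in self.data.columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield HmrObservation(
                promoter_id=d["promoter_id"],
                stage=d["stage"],
                hmr={lab: d[lab] for lab in FEATURE_LABELS},
                fpkm=d.get("fpkm", float("nan")) if has_expr else float("nan"),
                log_fpkm=d.get("log_fpkm", float("nan")) if has_expr else float("nan"),
            )

    def to_long(self) -> pd.DataFrame:
        """Long format (promoter_id, stage, feature, hmr) for export."""
        return self.data.melt(
            id_vars=["promoter_id", "stage"],
            value_vars=list(FEATURE_LABELS),
            var_name="feature",
            value_name="hmr",
        )


def build_matrix(
    promoters: Sequence[CorePromoter],
    transcribed_regions: Mapping[str, GenomicInterval],
    tracks: Mapping[tuple[Mark, Stage], PeakTrack],
    stages: Sequence[Stage] = tuple(Stage),
    *,
    group: str | None = None,
    chrom_harmonize: bool = False,
) -> HmrMatrix:
    """Assemble the complete six-feature HMR matrix for one CPE group.

    Every promoter needs a transcribed region and every (mark, stage)
    pair needs a track: missing entries are hard errors, never silent
    zeros.
    """
    if not promoters:
        raise ValueError("no promoters supplied")
    groups = {p.group for p in promoters}
    if group is None:
        if len(groups) > 1:
            raise ValueError(f"promoters span multiple groups {sorted(groups)}; pass group=")
        group = next(iter(groups))
    no_region = [p.promoter_id for p in promoters if p.promoter_id not in transcribed_regions]
    if no_region:
        raise ValueError(f"promoters without a transcribed region: {no_region}")
    missing_tracks = [
        (mark.value, stage.name)
        for stage in stages
        for mark in Mark
        if (mark, stage) not in tracks
    ]
    if missing_tracks:
        raise ValueError(f"missing peak tracks for (mark, stage): {missing_tracks}")

    rows = []
    for prom in promoters:
        regions = {
            RegionKind.CP: prom.region,
            RegionKind.T: transcribed_regions[prom.promoter_id],
        }
        for stage in stages:
            row: dict[str, object] = {"promoter_id": prom.promoter_id, "stage": stage}
            for feat in FEATURES:
                track = tracks[(feat.mark, stage)]
                row[feat.label] = compute_hmr(
                    regions[feat.region_kind], track, chrom_harmonize=chrom_harmonize
                )
            rows.append(row)
    data = pd.DataFrame(rows, columns=["promoter_id", "stage", *FEATURE_LABELS])
    return HmrMatrix(group=group, data=data)
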