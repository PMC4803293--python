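"""Genomic primitives: intervals, stage/mark vocabularies, and text-format IO.

All coordinates are 0-based, half-open (BED convention). One-based inputs
must be converted at the reader boundary; nothing downstream ever sees a
1-based coordinate.

The fixed vocabularies mirror the study design this package analyses:
eleven developmental stages of *D. melanogaster* (six 4-hour embryo
windows, three larval stages, pupae, adult males) and three assayed
histone marks (H3K4me3 and H3K27ac as active marks, H3K27me3 as the
inactive mark), each quantified over two region kinds — the core promoter
(CP) and the transcribed region (T) — yielding six features per
promoter-stage observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Stage",
    "Mark",
    "RegionKind",
    "FeatureId",
    "FEATURES",
    "FEATURE_LABELS",
    "CorePromoter",
    "CPE_GROUPS",
    "TranscriptModel",
    "PeakTrack",
    "normalize_track",
    "build_transcribed_region",
    "read_bed",
    "write_bed",
    "read_transcript_bed",
    "read_fasta",
    "read_expression_table",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"negative start in interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Stage(Enum):
    """The eleven developmental stages, in temporal order.

    A plain Enum (not IntEnum) so pandas keeps Stage objects intact in
    object columns instead of silently coercing them to integers.
    """

    def __lt__(self, other):
        if isinstance(other, Stage):
            return self.value < other.value
        return NotImplemented

    E0h = 0
    E4h = 1
    E8h = 2
    E12h = 3
    E16h = 4
    E20h = 5
    L1 = 6
    L2 = 7
    L3 = 8
    Pupae = 9
    AdultMale = 10


STAGES: tuple[Stage, ...] = tuple(Stage)


class Mark(Enum):
    """Assayed histone marks; polarity records the canonical association."""

    H3K4me3 = "H3K4me3"
    H3K27ac = "H3K27ac"
    H3K27me3 = "H3K27me3"

    @property
    def polarity(self) -> str:
        return "inactive" if self is Mark.H3K27me3 else "active"


class RegionKind(Enum):
    CP = "CP"  # core promoter region
    T = "T"  # transcribed region (TSS to farthest TES)


@dataclass(frozen=True)
class FeatureId:
    """One of the six (mark, region kind) histone-modification-ratio features."""

    mark: Mark
    region_kind: RegionKind

    @property
    def label(self) -> str:
        return f"{self.mark.value}_{self.region_kind.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


#: Canonical feature order, used for tie-breaks and column layout.
FEATURES: tuple[FeatureId, ...] = tuple(
    FeatureId(mark, kind) for kind in (RegionKind.CP, RegionKind.T) for mark in Mark
)
FEATURE_LABELS: tuple[str, ...] = tuple(f.label for f in FEATURES)

CPE_GROUPS: tuple[str, ...] = ("Inr", "TATA", "DPE", "TATA_DPE")


@dataclass(frozen=True)
class CorePromoter:
    """A core promoter region with its +1 position and CPE group label."""

    promoter_id: str
    gene_id: str
    region: GenomicInterval
    tss: int
    group: str = "Unassigned"

    def __post_init__(self) -> None:
        if not (self.region.start <= self.tss < self.region.end):
            raise ValueError(
                f"TSS {self.tss} of promoter {self.promoter_id} outside its "
                f"region {self.region.chrom}:{self.region.start}-{self.region.end}"
            )
        if self.group not in CPE_GROUPS + ("Unassigned",):
            raise ValueError(f"unknown CPE group {self.group!r}")

    def with_group(self, group: str) -> "CorePromoter":
        return replace(self, group=group)


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript reduced to its TSS/TES pair."""

    transcript_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValueError(f"transcript {self.transcript_id} has TSS == TES ({self.tss})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}")


def normalize_track(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge intervals (overlapping *or* abutting) per chromosome.

    Total covered base count is preserved; the result is the minimal sorted
    representation of the covered set, on which coverage fractions are
    well defined. Idempotent.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"expected GenomicInterval, got {type(iv).__name__}: {iv!r}")
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass
class PeakTrack:
    """Normalized peak intervals for one (mark, stage).

    ``intervals`` is guaranteed sorted, merged and non-adjacent per
    chromosome when built through :meth:`from_intervals`.
    """

    mark: Mark
    stage: Stage
    intervals: tuple[GenomicInterval, ...]
    _index: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @classmethod
    def from_intervals(
        cls, mark: Mark, stage: Stage, intervals: Iterable[GenomicInterval]
    ) -> "PeakTrack":
        return cls(mark, stage, tuple(normalize_track(intervals)))

    def _chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._index:
            starts = np.array([iv.start for iv in self.intervals if iv.chrom == chrom])
            ends = np.array([iv.end for iv in self.intervals if iv.chrom == chrom])
            self._index[chrom] = (starts, ends)
        return self._index[chrom]

    def covered_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def overlap_length(self, region: GenomicInterval) -> int:
        """Covered bases of ``region`` ∩ this track (exact, via clipping)."""
        starts, ends = self._chrom_arrays(region.chrom)
        if starts.size == 0:
            return 0
        clipped = np.minimum(ends, region.end) - np.maximum(starts, region.start)
        return int(np.clip(clipped, 0, None).sum())


def build_transcribed_region(
    tss: int, transcripts: Sequence[TranscriptModel]
) -> GenomicInterval:
    """Span from the TSS to the farthest TES among transcripts sharing it.

    The interval is stored unoriented (start < end); strand is kept as
    metadata only, since coverage fractions are orientation-free.
    """
    if not transcripts:
        raise ValueError(f"no transcripts supplied for TSS {tss}")
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise ValueError(
            f"transcripts for TSS {tss} span multiple chromosomes: {sorted(chroms)}"
        )
    mismatched = [t.transcript_id for t in transcripts if t.tss != tss]
    if mismatched:
        raise ValueError(f"transcripts not sharing TSS {tss}: {mismatched}")
    far = max(transcripts, key=lambda t: abs(t.tes - t.tss))
    lo, hi = min(tss, far.tes), max(tss, far.tes)
    return GenomicInterval(far.chrom, lo, hi, far.strand)


# ---------------------------------------------------------------------------
# Readers / writers (BED3/BED6, FASTA, expression TSV)
# ---------------------------------------------------------------------------


def _parse_bed_fields(path: Path, lineno: int, line: str) -> tuple[str, int, int, list[str]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric BED coordinates") from exc
    return chrom, start, end, fields[3:]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; strand is taken from column 6 when present."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, rest = _parse_bed_fields(path, lineno, line)
            strand = rest[2] if len(rest) >= 3 and rest[2] in _STRANDS else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    path = Path(path)
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must align with intervals")
    with path.open("w") as fh:
        for i, iv in enumerate(intervals):
            if names is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_transcript_bed(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from BED6; TSS/TES are assigned by strand.

    For '+' (and unstranded) records the TSS is the interval start and the
    TES its end boundary; for '-' records the roles are swapped, so the
    TSS is the end boundary and the TES the start.
    """
    path = Path(path)
    out: list[TranscriptModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, rest = _parse_bed_fields(path, lineno, line)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: degenerate transcript interval")
            name = rest[0] if rest else f"tx_{lineno}"
            strand = rest[2] if len(rest) >= 3 and rest[2] in _STRANDS else "."
            if strand == "-":
                tss, tes = end, start
            else:
                tss, tes = start, end
            out.append(TranscriptModel(name, chrom, tss, tes, strand))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping.

    Duplicate record ids are rejected (naming the offending record index)
    since promoter ids must be unique keys downstream.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for recno, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if record.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r} at record {recno}")
        out[record.id] = str(record.seq).upper()
    return out


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a (transcript_id, stage, fpkm) TSV; validates stages and FPKM.

    Returns a DataFrame with columns transcript_id (str), stage (Stage),
    fpkm (float >= 0).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "stage", "fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    stage_names = {s.name for s in Stage}
    bad = df.loc[~df["stage"].isin(stage_names)]
    if not bad.empty:
        raise ValueError(
            f"{path}: unknown stage names at rows {list(bad.index[:5] + 2)}: "
            f"{sorted(bad['stage'].unique())}"
        )
    fpkm = pd.to_numeric(df["fpkm"], errors="coerce")
    nonnum = df.index[fpkm.isna()]
    if len(nonnum):
        raise ValueError(f"{path}: non-numeric fpkm at line {nonnum[0] + 2}")
    if (fpkm < 0).any():
        raise ValueError(f"{path}: negative FPKM values present")
    out = df.copy()
    out["fpkm"] = fpkm.astype(float)
    out["stage"] = out["stage"].map(lambda s: Stage[s])
    return out
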