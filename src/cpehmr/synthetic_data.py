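"""Synthetic study generator.

Emits a complete file-backed study with known ground truth: promoter
sequences with planted CPE motifs at their canonical offsets, core
promoter and transcript BED files, per-(mark, stage) peak BED files
whose coverage of each region realizes planted HMR targets, and an
expression table whose log FPKM follows a planted linear model on the
realized HMR features plus Gaussian noise.

Promoters belong to one of three chromatin archetypes:

* ``active``   — high active-mark HMRs (H3K4me3, H3K27ac), near-zero
  H3K27me3;
* ``inactive`` — high H3K27me3, low active marks;
* ``void``     — no modifications at all (HMR exactly 0).

TATA-less promoters hold their archetype statically across stages (with
small jitter); TATA-containing non-void promoters toggle their whole
modification state on/off per stage (Bernoulli), emulating the dynamic
behaviour of those groups. Void promoters in TATA-containing groups are
the "void but expressed" archetype: their measured log FPKM is drawn
uniformly on intercept +/- ``void_log_fpkm_halfwidth``, decoupled from
the (absent) chromatin features and centered on the planted intercept
so the void subpopulation does not displace the fitted intercept —
which is exactly what makes their *predicted* log FPKM land in the void
removal window.

All randomness flows from one root seed through named substreams
(sequences, targets, expression, geometry), so the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cpe_classifier import DEFAULT_SPECS, IUPAC_CODES, MotifSpec, offset_to_index, scan_promoter
from .genomic_model import (
    CPE_GROUPS,
    FEATURE_LABELS,
    FEATURES,
    GenomicInterval,
    Mark,
    Stage,
    normalize_track,
    write_bed,
)

__all__ = [
    "ARCHETYPES",
    "PlantedModel",
    "SyntheticConfig",
    "SyntheticTruth",
    "plant_motifs",
    "sample_group_matrix",
    "generate_study",
]

ARCHETYPES: tuple[str, ...] = ("active", "inactive", "void")

_ACTIVE_LABELS = tuple(f.label for f in FEATURES if f.mark.polarity == "active")
_INACTIVE_LABELS = tuple(f.label for f in FEATURES if f.mark.polarity == "inactive")


@dataclass(frozen=True)
class PlantedModel:
    """Linear model generating log FPKM from HMR features."""

    intercept: float
    slopes: dict[str, float]

    def response(self, features: pd.DataFrame) -> np.ndarray:
        y = np.full(len(features), self.intercept, dtype=float)
        for label, slope in self.slopes.items():
            y += slope * features[label].to_numpy(dtype=float)
        return y


def _default_group_sizes() -> dict[str, int]:
    return {"Inr": 24, "TATA": 33, "DPE": 25, "TATA_DPE": 14}


def _default_archetype_mix() -> dict[str, dict[str, float]]:
    return {
        "Inr": {"active": 0.42, "inactive": 0.33, "void": 0.25},
        "DPE": {"active": 0.40, "inactive": 0.36, "void": 0.24},
        "TATA": {"active": 0.34, "inactive": 0.21, "void": 0.45},
        "TATA_DPE": {"active": 0.30, "inactive": 0.20, "void": 0.50},
    }


def _default_archetype_ranges() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-archetype uniform ranges for each HMR feature.

    Each feature draws independently within its archetype range, so the
    same mark's CP and T coverages are correlated through the archetype
    but retain feature-specific variation — peak breadth and position
    differ between the promoter-proximal window and the gene body, so
    the two region kinds are far from redundant. The ranges were chosen
    so that the planted regression slopes are identifiable from one
    group (the within-archetype spread is what separates a feature from
    its same-polarity partners).
    """
    return {
        "active": {
            "H3K4me3_CP": (0.45, 1.0),
            "H3K27ac_CP": (0.15, 0.65),
            "H3K27me3_CP": (0.0, 0.35),
            "H3K4me3_T": (0.1, 0.6),
            "H3K27ac_T": (0.45, 0.97),
            "H3K27me3_T": (0.0, 0.2),
        },
        "inactive": {
            "H3K4me3_CP": (0.0, 0.45),
            "H3K27ac_CP": (0.0, 0.35),
            "H3K27me3_CP": (0.2, 1.0),
            "H3K4me3_T": (0.0, 0.3),
            "H3K27ac_T": (0.0, 0.4),
            "H3K27me3_T": (0.0, 0.45),
        },
        "void": {lab: (0.0, 0.0) for lab in FEATURE_LABELS},
    }


def _default_planted_models() -> dict[str, PlantedModel]:
    return {
        "Inr": PlantedModel(
            0.82, {"H3K27ac_T": 2.98, "H3K4me3_CP": 1.61, "H3K27me3_CP": -0.80}
        ),
        "DPE": PlantedModel(0.89, {"H3K4me3_T": 3.38, "H3K27ac_T": 1.66}),
        "TATA": PlantedModel(
            0.86, {"H3K27ac_T": 3.13, "H3K4me3_CP": 1.62, "H3K27me3_CP": -1.19}
        ),
        "TATA_DPE": PlantedModel(0.71, {"H3K27ac_T": 3.54, "H3K4me3_CP": 3.26}),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults reproduce the analysed study's structure: 24/33/25/14
    promoters in the Inr/TATA/DPE/TATA_DPE groups, eleven stages, and
    per-group planted linear models whose coefficients are the published
    regression equations, with unit Gaussian noise on log FPKM.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    stages: tuple[Stage, ...] = tuple(Stage)
    archetype_mix: dict[str, dict[str, float]] = field(default_factory=_default_archetype_mix)
    archetype_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_archetype_ranges
    )
    feature_distribution: str = "archetypes"  # or "iid_uniform" (calibration mode)
    planted_models: dict[str, PlantedModel] = field(default_factory=_default_planted_models)
    noise_sd: float = 1.0
    void_log_fpkm_halfwidth: float = 1.0
    on_probability: float = 0.5  # per-stage on-state, TATA-containing non-void
    stage_jitter: float = 0.015  # per-stage HMR wobble for static archetypes
    cp_length: int = 100
    transcribed_length_range: tuple[int, int] = (3000, 20000)
    slot: int = 30_000  # genomic spacing per promoter; keeps regions disjoint
    chrom: str = "chr2L"
    sequence_length: int = 120
    tss_index: int = 60
    fpkm_floor: float = 0.01  # emitted FPKM below this is reported as 0
    seed: int = 0

    def __post_init__(self) -> None:
        for group, mix in self.archetype_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"archetype mix for {group} does not sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"negative archetype proportion for {group}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("negative group size")


@dataclass
class SyntheticTruth:
    """Ground truth for every emitted promoter, for recovery tests."""

    promoters: pd.DataFrame  # promoter_id, group, archetype, strand, tss, transcribed_length
    hmr: pd.DataFrame  # promoter_id, stage, feature, hmr (realized target)
    expression: pd.DataFrame  # promoter_id, stage, log_fpkm (planted), is_void
    config: SyntheticConfig
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

_REQUIRED_BY_GROUP: dict[str, tuple[str, ...]] = {
    "Inr": ("Inr",),
    "TATA": ("Inr", "TATA"),
    "DPE": ("Inr", "DPE"),
    "TATA_DPE": ("Inr", "TATA", "DPE"),
}


def _concretize(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_CODES[c])[rng.integers(len(IUPAC_CODES[c]))] for c in consensus.upper()
    )


def plant_motifs(
    rng: np.random.Generator,
    group: str,
    specs: Sequence[MotifSpec] = DEFAULT_SPECS,
    *,
    length: int = 120,
    tss_index: int = 60,
    max_retries: int = 50,
) -> str:
    """Generate a promoter sequence carrying exactly the group's motifs.

    Required consensi are concretized (random choice among each IUPAC
    code's bases) and pasted at a randomly chosen allowed anchor offset;
    the draw is retried until no excluded motif accidentally matches at
    any of its anchored windows.
    """
    if group not in _REQUIRED_BY_GROUP:
        raise ValueError(f"unknown CPE group {group!r}")
    required = set(_REQUIRED_BY_GROUP[group])
    by_name = {s.name: s for s in specs}
    unknown = required - set(by_name)
    if unknown:
        raise ValueError(f"specs missing required motifs {sorted(unknown)}")
    for _ in range(max_retries):
        seq = rng.choice(list("ACGT"), size=length)
        for name in sorted(required):
            spec = by_name[name]
            offset = spec.anchor_offsets[rng.integers(len(spec.anchor_offsets))]
            start = offset_to_index(offset, tss_index) - spec.anchor_base
            if start < 0 or start + len(spec.consensus) > length:
                raise ValueError(
                    f"sequence of length {length} cannot host {name} at offset {offset}"
                )
            seq[start : start + len(spec.consensus)] = list(_concretize(spec.consensus, rng))
        s = "".join(seq)
        call = scan_promoter(s, tss_index, specs)
        flags = {"Inr": call.has_inr, "TATA": call.has_tata, "DPE": call.has_dpe}
        if all(flags.get(n, False) for n in required) and not any(
            flags[n] for n in flags if n in by_name and n not in required
        ):
            return s
    raise RuntimeError(
        f"failed to scrub accidental motif matches after {max_retries} draws"
    )


# ---------------------------------------------------------------------------
# HMR target drawing
# ---------------------------------------------------------------------------


def _archetype_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n promoters across archetypes."""
    quotas = {a: n * mix.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    return counts


def _draw_state(
    archetype: str,
    ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One fully 'on' realization of an archetype's six HMR values."""
    if archetype not in ranges:
        raise ValueError(f"unknown archetype {archetype!r}")
    out: dict[str, float] = {}
    for lab in FEATURE_LABELS:
        lo, hi = ranges[archetype][lab]
        out[lab] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return out


def _draw_group_targets(
    config: SyntheticConfig, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Target HMRs per (promoter, stage) with archetype annotations.

    TATA-less groups: one per-promoter state, held static across stages
    up to +/- ``stage_jitter``. TATA-containing groups: per-stage
    Bernoulli on/off for non-void promoters; off stages have all-zero
    HMRs but still follow the planted expression model.
    """
    n = config.group_sizes.get(group, 0)
    if config.feature_distribution == "iid_uniform":
        # calibration mode: every feature varies independently over its
        # full range, giving a neutral fully identifiable design
        rows = []
        for j in range(n):
            pid = f"{group}_{j:03d}"
            for stage in config.stages:
                state = {lab: float(rng.uniform(0.0, 1.0)) for lab in FEATURE_LABELS}
                rows.append(
                    {
                        "promoter_id": pid,
                        "stage": stage,
                        "archetype": "iid",
                        "is_void": False,
                        **state,
                    }
                )
        return pd.DataFrame(
            rows, columns=["promoter_id", "stage", "archetype", "is_void", *FEATURE_LABELS]
        )
    if config.feature_distribution != "archetypes":
        raise ValueError(f"unknown feature distribution {config.feature_distribution!r}")
    counts = _archetype_counts(n, config.archetype_mix[group])
    archetypes = [a for a in ARCHETYPES for _ in range(counts[a])]
    rng.shuffle(archetypes)
    ranges = config.archetype_ranges
    dynamic = group in ("TATA", "TATA_DPE")
    rows = []
    for j, archetype in enumerate(archetypes):
        pid = f"{group}_{j:03d}"
        base = None if dynamic else _draw_state(archetype, ranges, rng)
        for stage in config.stages:
            if dynamic:
                if archetype == "void" or rng.random() >= config.on_probability:
                    state = {lab: 0.0 for lab in FEATURE_LABELS}
                else:
                    state = _draw_state(archetype, ranges, rng)
            else:
                assert base is not None
                if archetype == "void":
                    state = dict(base)
                else:
                    state = {
                        lab: float(np.clip(v + rng.uniform(-config.stage_jitter, config.stage_jitter), 0.0, 1.0))
                        for lab, v in base.items()
                    }
            rows.append(
                {
                    "promoter_id": pid,
                    "stage": stage,
                    "archetype": archetype,
                    "is_void": archetype == "void",
                    **state,
                }
            )
    return pd.DataFrame(rows, columns=["promoter_id", "stage", "archetype", "is_void", *FEATURE_LABELS])


def _planted_response(
    config: SyntheticConfig,
    group: str,
    features: pd.DataFrame,
    is_void: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Planted log FPKM: linear model + noise, or the void-archetype draw."""
    model = config.planted_models[group]
    y = model.response(features) + rng.normal(0.0, config.noise_sd, size=len(features))
    if group in ("TATA", "TATA_DPE") and is_void.any():
        hw = config.void_log_fpkm_halfwidth
        y[is_void] = model.intercept + rng.uniform(-hw, hw, size=int(is_void.sum()))
    return y


def sample_group_matrix(
    config: SyntheticConfig, group: str, seed: int | None = None
) -> pd.DataFrame:
    """In-memory study matrix for one group (no file round trip).

    Returns one row per promoter x stage with the six HMR features, the
    planted ``log_fpkm``, and archetype annotations — the observation
    matrix the regression battery consumes, at planted (unquantized)
    HMR values.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    df = _draw_group_targets(config, group, rng)
    df["log_fpkm"] = _planted_response(
        config, group, df[list(FEATURE_LABELS)], df["is_void"].to_numpy(), rng
    )
    return df


# ---------------------------------------------------------------------------
# Full file-backed study
# ---------------------------------------------------------------------------


@dataclass
class _PromoterGeometry:
    promoter_id: str
    gene_id: str
    group: str
    archetype: str
    strand: str
    tss: int
    cp_region: GenomicInterval
    t_region: GenomicInterval
    t_length: int


def _lay_out_promoters(
    config: SyntheticConfig, truth_targets: Mapping[str, pd.DataFrame], rng: np.random.Generator
) -> list[_PromoterGeometry]:
    half_cp = config.cp_length // 2
    lo_t, hi_t = config.transcribed_length_range
    out: list[_PromoterGeometry] = []
    i = 0
    for group in CPE_GROUPS:
        targets = truth_targets[group]
        for pid, sub in targets.groupby("promoter_id", sort=True):
            archetype = sub["archetype"].iloc[0]
            strand = "+" if i % 2 == 0 else "-"
            base = 1000 + i * config.slot
            t_length = int(rng.integers(lo_t, hi_t + 1))
            if strand == "+":
                tss = base + config.cp_length
                t_region = GenomicInterval(config.chrom, tss, tss + t_length, strand)
            else:
                tss = base + config.cp_length + t_length
                t_region = GenomicInterval(config.chrom, tss - t_length, tss, strand)
            cp_region = GenomicInterval(
                config.chrom, tss - half_cp, tss - half_cp + config.cp_length, strand
            )
            out.append(
                _PromoterGeometry(
                    promoter_id=pid,
                    gene_id=f"gene_{pid}",
                    group=group,
                    archetype=archetype,
                    strand=strand,
                    tss=tss,
                    cp_region=cp_region,
                    t_region=t_region,
                    t_length=t_length,
                )
            )
            i += 1
    return out


def _realize_peaks(
    geom: _PromoterGeometry, cp_target: float, t_target: float, cp_length: int
) -> tuple[list[GenomicInterval], float, float]:
    """Peak intervals realizing the two targets over CP and T regions.

    The CP peak is anchored at the CP region start; the T top-up peak at
    the far (TES) end of the transcribed region, which by construction
    never overlaps the CP peak's contribution inside T. Returns
    (intervals, realized_cp, realized_t) with realized values exact at
    1 bp resolution.
    """
    intervals: list[GenomicInterval] = []
    n_cp = int(round(cp_target * cp_length))
    cp = geom.cp_region
    if n_cp > 0:
        intervals.append(GenomicInterval(cp.chrom, cp.start, cp.start + n_cp))
    t = geom.t_region
    if n_cp > 0:
        c = max(0, min(cp.start + n_cp, t.end) - max(cp.start, t.start))
    else:
        c = 0
    needed = int(round(t_target * t.length))
    extra = max(0, needed - c)
    # the top-up peak must stay clear of the core promoter's inner half,
    # or it would silently raise the realized CP coverage
    if extra > t.length - (cp_length // 2):
        raise ValueError(
            f"transcribed region of {geom.promoter_id} too short ({t.length} bp) "
            f"to realize HMR {t_target:.3f} without touching the core promoter"
        )
    if extra > 0:
        if geom.strand == "+":
            intervals.append(GenomicInterval(t.chrom, t.end - extra, t.end))
        else:
            intervals.append(GenomicInterval(t.chrom, t.start, t.start + extra))
    realized_cp = n_cp / cp_length
    realized_t = max(needed, c) / t.length
    if abs(realized_cp - cp_target) > 0.02 or abs(realized_t - t_target) > 0.02:
        raise ValueError(
            f"cannot realize HMR targets ({cp_target:.3f}, {t_target:.3f}) for "
            f"{geom.promoter_id}: region too short at 1 bp resolution"
        )
    return intervals, realized_cp, realized_t


def generate_study(config: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Write a complete synthetic study to ``outdir`` and return its truth.

    Emits promoters.bed / promoters.fasta / annotation.tsv /
    transcripts.bed / peaks/<mark>_<stage>.bed / expression.tsv plus
    truth tables (truth_promoters.tsv, truth_hmr.tsv,
    truth_expression.tsv). Fully reproducible under ``config.seed``.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    rng_seq, rng_targets, rng_expr, rng_geom = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    targets = {g: _draw_group_targets(config, g, rng_targets) for g in CPE_GROUPS}
    geoms = _lay_out_promoters(config, targets, rng_geom)
    geom_by_id = {g.promoter_id: g for g in geoms}

    # --- peaks: realize targets as intervals, record realized values ----
    peak_intervals: dict[tuple[Mark, Stage], list[GenomicInterval]] = {
        (mark, stage): [] for mark in Mark for stage in config.stages
    }
    realized_frames = []
    for group in CPE_GROUPS:
        df = targets[group].copy()
        for idx, row in df.iterrows():
            geom = geom_by_id[row["promoter_id"]]
            for mark in Mark:
                cp_lab = f"{mark.value}_CP"
                t_lab = f"{mark.value}_T"
                ivs, r_cp, r_t = _realize_peaks(
                    geom, float(row[cp_lab]), float(row[t_lab]), config.cp_length
                )
                peak_intervals[(mark, row["stage"])].extend(ivs)
                df.at[idx, cp_lab] = r_cp
                df.at[idx, t_lab] = r_t
        realized_frames.append(df.assign(group=group))

    # --- expression from realized HMRs --------------------------------
    expr_truth_frames = []
    for group, df in zip(CPE_GROUPS, realized_frames):
        y = _planted_response(
            config, group, df[list(FEATURE_LABELS)], df["is_void"].to_numpy(), rng_expr
        )
        expr_truth_frames.append(
            df[["promoter_id", "stage", "is_void"]].assign(log_fpkm=y, group=group)
        )
    expr_truth = pd.concat(expr_truth_frames, ignore_index=True)

    # --- transcripts + per-transcript FPKM -----------------------------
    tx_rows = []
    fpkm_rows = []
    for geom in geoms:
        n_tx = int(rng_expr.integers(1, 4))
        lengths = [geom.t_length] + [
            max(100, int(geom.t_length * rng_expr.uniform(0.2, 0.95)))
            for _ in range(n_tx - 1)
        ]
        weights = rng_expr.dirichlet(np.ones(n_tx))
        tx_ids = [f"tx_{geom.promoter_id}_{k}" for k in range(n_tx)]
        for tx_id, L in zip(tx_ids, lengths):
            if geom.strand == "+":
                start, end = geom.tss, geom.tss + L
            else:
                start, end = geom.tss - L, geom.tss
            tx_rows.append((geom.t_region.chrom, start, end, tx_id, 0, geom.strand))
        sub = expr_truth.loc[expr_truth["promoter_id"] == geom.promoter_id]
        for row in sub.itertuples(index=False):
            total = float(np.exp(row.log_fpkm))
            if total < config.fpkm_floor:
                total = 0.0
            for tx_id, w in zip(tx_ids, weights):
                fpkm_rows.append((tx_id, row.stage.name, total * w))

    # --- sequences ------------------------------------------------------
    sequences = {
        geom.promoter_id: plant_motifs(
            rng_seq,
            geom.group,
            length=config.sequence_length,
            tss_index=config.tss_index,
        )
        for geom in geoms
    }

    # --- write files ----------------------------------------------------
    paths: dict[str, Path] = {}

    paths["promoters_bed"] = outdir / "promoters.bed"
    with paths["promoters_bed"].open("w") as fh:
        for g in geoms:
            fh.write(
                f"{g.cp_region.chrom}\t{g.cp_region.start}\t{g.cp_region.end}\t"
                f"{g.promoter_id}\t0\t{g.strand}\n"
            )

    paths["promoters_fasta"] = outdir / "promoters.fasta"
    with paths["promoters_fasta"].open("w") as fh:
        for g in geoms:
            fh.write(f">{g.promoter_id}\n{sequences[g.promoter_id]}\n")

    paths["annotation"] = outdir / "annotation.tsv"
    ann = pd.DataFrame(
        [
            {
                "promoter_id": g.promoter_id,
                "gene_id": g.gene_id,
                "chrom": g.cp_region.chrom,
                "start": g.cp_region.start,
                "end": g.cp_region.end,
                "strand": g.strand,
                "tss": g.tss,
                "group": g.group,
            }
            for g in geoms
        ]
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)

    paths["transcripts_bed"] = outdir / "transcripts.bed"
    with paths["transcripts_bed"].open("w") as fh:
        for chrom, start, end, name, score, strand in tx_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")

    paths["peaks_dir"] = outdir / "peaks"
    for (mark, stage), ivs in peak_intervals.items():
        merged = normalize_track(ivs) if ivs else []
        write_bed(merged, outdir / "peaks" / f"{mark.value}_{stage.name}.bed")

    paths["expression"] = outdir / "expression.tsv"
    pd.DataFrame(fpkm_rows, columns=["transcript_id", "stage", "fpkm"]).to_csv(
        paths["expression"], sep="\t", index=False, float_format="%.6g"
    )

    realized = pd.concat(realized_frames, ignore_index=True)
    truth_prom = pd.DataFrame(
        [
            {
                "promoter_id": g.promoter_id,
                "group": g.group,
                "archetype": g.archetype,
                "strand": g.strand,
                "tss": g.tss,
                "transcribed_length": g.t_length,
            }
            for g in geoms
        ]
    )
    truth_hmr = realized.melt(
        id_vars=["promoter_id", "stage"],
        value_vars=list(FEATURE_LABELS),
        var_name="feature",
        value_name="hmr",
    )
    truth_hmr["stage"] = truth_hmr["stage"].map(lambda s: s.name)
    truth_expr_out = expr_truth.assign(stage=expr_truth["stage"].map(lambda s: s.name))

    paths["truth_promoters"] = outdir / "truth_promoters.tsv"
    truth_prom.to_csv(paths["truth_promoters"], sep="\t", index=False)
    paths["truth_hmr"] = outdir / "truth_hmr.tsv"
    truth_hmr.to_csv(paths["truth_hmr"], sep="\t", index=False, float_format="%.6g")
    paths["truth_expression"] = outdir / "truth_expression.tsv"
    truth_expr_out.to_csv(paths["truth_expression"], sep="\t", index=False, float_format="%.6g")

    return SyntheticTruth(
        promoters=truth_prom,
        hmr=realized,
        expression=expr_truth,
        config=config,
        paths=paths,
    )
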