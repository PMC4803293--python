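"""Expression aggregation and the group-wise log transform.

A core promoter's FPKM at a stage is the sum over all transcripts that
share its TSS. Before regression the values are log transformed with a
group-level pseudocount: log(FPKM + m), where m is by default the
group's minimum *positive* FPKM. (Adding the group's literal minimum
would be a no-op whenever any FPKM in the group is zero and would leave
log(0) undefined; the literal rule is still available via ``rule``.)
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_model import FEATURE_LABELS, CorePromoter, Stage, TranscriptModel
from .hmr_engine import HmrMatrix

__all__ = [
    "aggregate_fpkm",
    "log_transform_group",
    "attach_expression",
    "correlate",
]


def aggregate_fpkm(
    promoters: Sequence[CorePromoter],
    transcripts: Sequence[TranscriptModel],
    expression: pd.DataFrame,
    stages: Sequence[Stage] = tuple(Stage),
) -> pd.DataFrame:
    """Per-promoter, per-stage FPKM as the sum over TSS-sharing transcripts.

    ``expression`` has columns (transcript_id, stage, fpkm). A transcript
    absent from a stage's table contributes 0 with a warning; a promoter
    whose TSS has no transcripts at all is an error.

    Returns a DataFrame (promoter_id, stage, fpkm).
    """
    by_tss: dict[tuple[str, int], list[str]] = {}
    for tx in transcripts:
        by_tss.setdefault((tx.chrom, tx.tss), []).append(tx.transcript_id)

    orphans = [
        p.promoter_id for p in promoters if (p.region.chrom, p.tss) not in by_tss
    ]
    if orphans:
        raise ValueError(f"promoters whose TSS has no transcripts: {orphans}")

    fpkm_lookup: dict[tuple[str, Stage], float] = {
        (row.transcript_id, row.stage): row.fpkm
        for row in expression.itertuples(index=False)
    }

    rows = []
    missing: set[tuple[str, str]] = set()
    for prom in promoters:
        tx_ids = by_tss[(prom.region.chrom, prom.tss)]
        for stage in stages:
            total = 0.0
            for tx_id in tx_ids:
                key = (tx_id, stage)
                if key in fpkm_lookup:
                    total += fpkm_lookup[key]
                else:
                    missing.add((tx_id, stage.name))
            rows.append({"promoter_id": prom.promoter_id, "stage": stage, "fpkm": total})
    if missing:
        shown = sorted(missing)[:5]
        warnings.warn(
            f"{len(missing)} (transcript, stage) pairs missing from the expression "
            f"table, counted as FPKM 0; first few: {shown}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def log_transform_group(
    fpkms, *, rule: str = "min_positive", base: float | None = None
) -> np.ndarray:
    """Group-wise pseudocount log transform: log(fpkm + m).

    ``rule='min_positive'`` (default) uses the group's smallest positive
    FPKM as m; ``rule='literal'`` uses the group minimum, which fails on
    groups containing zeros. Natural log by default; ``base`` rescales,
    which is irrelevant to correlations.
    """
    x = np.asarray(fpkms, dtype=float)
    if x.size == 0:
        raise ValueError("empty FPKM group")
    if np.any(x < 0):
        raise ValueError("negative FPKM values")
    if rule == "min_positive":
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all-zero FPKM group: no positive minimum exists")
        m = positive.min()
    elif rule == "literal":
        m = x.min()
        if m == 0 and np.any(x == 0):
            raise ValueError(
                "literal minimum rule gives m=0 on a group containing zeros; "
                "log(0) is undefined (use rule='min_positive')"
            )
    else:
        raise ValueError(f"unknown transform rule {rule!r}")
    out = np.log(x + m)
    if base is not None:
        out = out / np.log(base)
    if not np.all(np.isfinite(out)):
        raise AssertionError("non-finite log FPKM after transform")
    return out


def attach_expression(
    matrix: HmrMatrix,
    fpkm: pd.DataFrame,
    *,
    rule: str = "min_positive",
    base: float | None = None,
) -> HmrMatrix:
    """Join per-(promoter, stage) FPKM onto an HMR matrix and log transform.

    The transform's pseudocount is computed over this matrix's group, as
    all rows of one :class:`HmrMatrix` belong to a single CPE group.
    """
    merged = matrix.data.merge(
        fpkm[["promoter_id", "stage", "fpkm"]], on=["promoter_id", "stage"], how="left"
    )
    if merged["fpkm"].isna().any():
        bad = merged.loc[merged["fpkm"].isna(), "promoter_id"].unique()[:5]
        raise ValueError(f"missing FPKM for promoters (first few): {list(bad)}")
    merged["log_fpkm"] = log_transform_group(merged["fpkm"].to_numpy(), rule=rule, base=base)
    return HmrMatrix(group=matrix.group, data=merged)


def correlate(matrix: HmrMatrix, response: str = "log_fpkm") -> pd.Series:
    """Pearson correlation of each HMR feature with log FPKM.

    Computed over all promoter x stage observations of the group.
    Constant features yield NaN (undefined, not 0) with a warning.
    """
    if response not in matrix.data.columns:
        raise ValueError(f"matrix has no {response!r} column; run attach_expression first")
    y = matrix.data[response].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(y) == 0:
        raise ValueError("constant expression vector")
    out = {}
    for lab in FEATURE_LABELS:
        x = matrix.data[lab].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {lab} is constant; correlation undefined", stacklevel=2)
            out[lab] = np.nan
        else:
            out[lab] = stats.pearsonr(x, y).statistic
    return pd.Series(out, name=f"r_vs_{response}")
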