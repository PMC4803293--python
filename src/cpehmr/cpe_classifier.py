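"""Core promoter element (CPE) classification.

Promoters are assigned to one of four groups — Inr only, TATA, DPE, or
TATA_DPE — either from a curated annotation table (the route a promoter
database provides) or by scanning the promoter sequence for the
*D. melanogaster* consensus motifs at their canonical positions:

* Inr   ``TCAGTYKNNNTYNR``  — encompasses the +1 TSS; the A of the
  leading TCA triplet is registered at +1, i.e. the match starts at -2.
* TATA  ``STATAWAAR``       — the upstream T (consensus position 2) sits
  at -31 or -30 relative to +1.
* DPE   ``CRWMGCGWKCGGTTS`` — located at +28..+33 relative to +1; by
  default the match window may *start* at any of those offsets.

Promoter positions use the biological convention without a position 0:
-1 immediately abuts +1. The single place where that discontinuity is
converted to string indices is :func:`offset_to_index`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .genomic_model import CPE_GROUPS, CorePromoter, GenomicInterval

__all__ = [
    "IUPAC_CODES",
    "MotifSpec",
    "CpeCall",
    "INR_SPEC",
    "TATA_SPEC",
    "DPE_SPEC",
    "DEFAULT_SPECS",
    "dpe_spec",
    "iupac_match",
    "offset_to_index",
    "scan_promoter",
    "derive_group",
    "assign_groups",
    "read_promoter_annotation",
]

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus anchored at fixed offsets relative to +1.

    ``anchor_base`` is the 0-based index within the consensus that is
    placed at each candidate offset; the match window therefore starts
    ``anchor_base`` positions upstream of the offset.
    """

    name: str
    consensus: str
    anchor_offsets: tuple[int, ...]
    anchor_base: int = 0

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes in consensus: {sorted(bad)}")
        if not self.anchor_offsets:
            raise ValueError(f"{self.name}: anchor_offsets must be non-empty")
        if any(o == 0 for o in self.anchor_offsets):
            raise ValueError(f"{self.name}: there is no position 0 (use -1 or +1)")
        if not (0 <= self.anchor_base < len(self.consensus)):
            raise ValueError(f"{self.name}: anchor_base outside consensus")


INR_SPEC = MotifSpec("Inr", "TCAGTYKNNNTYNR", (-2,), anchor_base=0)
TATA_SPEC = MotifSpec("TATA", "STATAWAAR", (-31, -30), anchor_base=1)
DPE_SPEC = MotifSpec("DPE", "CRWMGCGWKCGGTTS", tuple(range(28, 34)), anchor_base=0)
DEFAULT_SPECS: tuple[MotifSpec, ...] = (INR_SPEC, TATA_SPEC, DPE_SPEC)


def dpe_spec(mode: str = "window_start") -> MotifSpec:
    """DPE spec under either registration of the 15-nt consensus.

    ``window_start``: the match may start at any of +28..+33 (default).
    ``contained``: the match window must cover the whole +28..+33 span,
    i.e. it may start at +19..+28.
    """
    if mode == "window_start":
        return DPE_SPEC
    if mode == "contained":
        return replace(DPE_SPEC, anchor_offsets=tuple(range(19, 29)))
    raise ValueError(f"unknown DPE anchoring mode {mode!r}")


def iupac_match(consensus: str, window: str, *, strict: bool = True) -> bool:
    """True iff every base of ``window`` is allowed by the IUPAC consensus.

    ``strict`` controls non-ACGT bases in the window: reject (raise) when
    True, report no-match when False.
    """
    if len(consensus) != len(window):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)} vs window {len(window)}"
        )
    for code, base in zip(consensus.upper(), window.upper()):
        if base not in "ACGT":
            if strict:
                raise ValueError(f"non-ACGT base {base!r} in window")
            return False
        if base not in IUPAC_CODES[code]:
            return False
    return True


def offset_to_index(offset: int, tss_index: int) -> int:
    """Convert a promoter position (no 0; -1 abuts +1) to a string index.

    ``tss_index`` is the 0-based index of the +1 base within the sequence.
    """
    if offset == 0:
        raise ValueError("there is no position 0 in promoter coordinates")
    return tss_index + offset - 1 if offset > 0 else tss_index + offset


@dataclass(frozen=True)
class CpeCall:
    """Motif flags and the derived CPE group for one promoter."""

    promoter_id: str
    has_inr: bool
    has_tata: bool
    has_dpe: bool
    group: str
    not_evaluable: tuple[str, ...] = ()


def derive_group(
    has_inr: bool, has_tata: bool, has_dpe: bool, *, require_inr: bool = True
) -> str:
    """Map motif flags to the four-group label.

    The annotation route guarantees Inr presence, so only the TATA/DPE
    flags partition promoters; in sequence-scan mode a promoter without a
    detectable Inr is left Unassigned (``require_inr=True``).
    """
    if require_inr and not has_inr:
        return "Unassigned"
    if has_tata and has_dpe:
        return "TATA_DPE"
    if has_tata:
        return "TATA"
    if has_dpe:
        return "DPE"
    return "Inr"


def scan_promoter(
    sequence: str,
    tss_index: int,
    specs: Sequence[MotifSpec] = DEFAULT_SPECS,
    *,
    promoter_id: str = "",
    require_inr: bool = True,
) -> CpeCall:
    """Scan one promoter sequence for anchored CPE motifs.

    A motif is present iff its consensus matches at >= 1 allowed anchor
    offset. Motifs whose window would fall outside the sequence at every
    allowed offset are reported in ``not_evaluable`` (and treated as
    absent), with a log message.
    """
    sequence = sequence.upper()
    flags: dict[str, bool] = {}
    not_evaluable: list[str] = []
    for spec in specs:
        found = False
        evaluable = False
        for offset in spec.anchor_offsets:
            start = offset_to_index(offset, tss_index) - spec.anchor_base
            end = start + len(spec.consensus)
            if start < 0 or end > len(sequence):
                continue
            evaluable = True
            if iupac_match(spec.consensus, sequence[start:end], strict=False):
                found = True
                break
        if not evaluable:
            not_evaluable.append(spec.name)
            logger.warning(
                "motif %s not evaluable for promoter %s: sequence too short "
                "around the TSS", spec.name, promoter_id or "<unnamed>",
            )
        flags[spec.name] = found
    has_inr = flags.get("Inr", False)
    has_tata = flags.get("TATA", False)
    has_dpe = flags.get("DPE", False)
    return CpeCall(
        promoter_id=promoter_id,
        has_inr=has_inr,
        has_tata=has_tata,
        has_dpe=has_dpe,
        group=derive_group(has_inr, has_tata, has_dpe, require_inr=require_inr),
        not_evaluable=tuple(not_evaluable),
    )


ANNOTATION_COLUMNS = (
    "promoter_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "tss",
    "group",
)


def read_promoter_annotation(path) -> pd.DataFrame:
    """Read the promoter annotation TSV (curated-database route)."""
    df = pd.read_csv(path, sep="\t", dtype={"promoter_id": str, "gene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    bad = df.loc[~df["group"].isin(CPE_GROUPS)]
    if not bad.empty:
        raise ValueError(
            f"{path}: unknown CPE groups {sorted(bad['group'].unique())}"
        )
    return df


def promoters_from_annotation(annotation: pd.DataFrame) -> list[CorePromoter]:
    """Materialize :class:`CorePromoter` objects from an annotation table."""
    out = []
    for row in annotation.itertuples(index=False):
        out.append(
            CorePromoter(
                promoter_id=row.promoter_id,
                gene_id=row.gene_id,
                region=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                tss=int(row.tss),
                group=row.group,
            )
        )
    return out


def assign_groups(
    promoters: Sequence[CorePromoter],
    annotation: pd.DataFrame | None = None,
    sequences: Mapping[str, str] | None = None,
    tss_index: int | None = None,
    specs: Sequence[MotifSpec] = DEFAULT_SPECS,
) -> tuple[list[CorePromoter], dict[str, int], list[str]]:
    """Label promoters with CPE groups and apply the gene-consistency filter.

    Each promoter must be resolvable from exactly one source (annotation
    table keyed by promoter_id, or sequences + ``tss_index``). A promoter
    present in both sources with conflicting labels is an error. Genes
    whose promoters fall into different groups are excluded entirely, with
    a warning listing them.

    Returns (labelled promoters, per-group counts, excluded promoter ids).
    """
    ann_groups: dict[str, str] = {}
    if annotation is not None:
        ann_groups = dict(zip(annotation["promoter_id"], annotation["group"]))

    labelled: list[CorePromoter] = []
    conflicts: list[str] = []
    for prom in promoters:
        from_ann = ann_groups.get(prom.promoter_id)
        from_seq = None
        if sequences is not None and prom.promoter_id in sequences:
            if tss_index is None:
                raise ValueError("tss_index is required when classifying from sequences")
            from_seq = scan_promoter(
                sequences[prom.promoter_id],
                tss_index,
                specs,
                promoter_id=prom.promoter_id,
            ).group
        if from_ann is not None and from_seq is not None and from_ann != from_seq:
            conflicts.append(prom.promoter_id)
            continue
        group = from_ann if from_ann is not None else from_seq
        if group is None:
            raise ValueError(f"promoter {prom.promoter_id} found in no source")
        labelled.append(prom.with_group(group))
    if conflicts:
        raise ValueError(f"conflicting group labels between sources for: {conflicts}")

    # genes with promoters in several groups are dropped for simplicity
    by_gene: dict[str, set[str]] = {}
    for prom in labelled:
        if prom.group != "Unassigned":
            by_gene.setdefault(prom.gene_id, set()).add(prom.group)
    mixed_genes = {g for g, groups in by_gene.items() if len(groups) > 1}
    excluded = [p.promoter_id for p in labelled if p.gene_id in mixed_genes]
    if excluded:
        warnings.warn(
            f"excluding promoters of genes with inconsistent CPE groups: {excluded}",
            stacklevel=2,
        )
        labelled = [p for p in labelled if p.gene_id not in mixed_genes]

    counts = {g: 0 for g in CPE_GROUPS + ("Unassigned",)}
    for prom in labelled:
        counts[prom.group] += 1
    return labelled, counts, excluded
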