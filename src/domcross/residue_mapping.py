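"""Length filtering and SIFTS-based residue mapping of instances.

A Pfam-side instance arrives with UniProt boundaries and needs PDB
author numbering to locate its coordinates; a CATH-side instance
arrives with PDB numbering and needs UniProt positions (and accession)
to be comparable across databases.  Both directions use the affine
offset of the single SIFTS segment that fully covers the span.

Failures are statuses, never exceptions: instances from obsolete PDB
entries become OBSOLETE; spans not covered by exactly one segment of
one UniProt accession become INCONSISTENT with a human-readable reason,
so the list can be handed to database curators.
"""

from __future__ import annotations

import copy
import csv
import enum
from dataclasses import dataclass
from pathlib import Path

from .core_model import (
    SiftsSegment,
    SourceDB,
    StructuralInstance,
    instance_key,
    region_length,
)
from .db_io import SiftsIndex

__all__ = [
    "MappingStatus",
    "MappingOutcome",
    "filter_by_length",
    "map_instance",
    "map_instances",
    "write_unmapped_report",
]


class MappingStatus(str, enum.Enum):
    MAPPED = "MAPPED"
    OBSOLETE = "OBSOLETE"
    INCONSISTENT = "INCONSISTENT"
    LENGTH_FILTERED = "LENGTH_FILTERED"


@dataclass
class MappingOutcome:
    status: MappingStatus
    instance: StructuralInstance
    reason: str = ""


def filter_by_length(
    stis: list[StructuralInstance], min_length: int
) -> tuple[list[StructuralInstance], list[StructuralInstance]]:
    """Partition instances into (kept, too-short) by native span length.

    Very short assignments are removed up front: fragments of a few
    residues cannot be meaningfully superposed or scored.
    """
    kept: list[StructuralInstance] = []
    short: list[StructuralInstance] = []
    for sti in stis:
        if region_length(*sti.native_span) >= min_length:
            kept.append(sti)
        else:
            short.append(sti)
    return kept, short


def _covering_segments(
    segments: list[SiftsSegment], span: tuple[int, int], side: SourceDB
) -> list[SiftsSegment]:
    start, end = span
    out = []
    for seg in segments:
        if side is SourceDB.PFAM_SIDE:
            lo, hi = seg.sp_beg, seg.sp_end
        else:
            lo, hi = seg.pdb_beg, seg.pdb_end
        if lo <= start and end <= hi:
            out.append(seg)
    return out


def _overlapping_accessions(
    segments: list[SiftsSegment], span: tuple[int, int], side: SourceDB
) -> set[str]:
    start, end = span
    accs = set()
    for seg in segments:
        if side is SourceDB.PFAM_SIDE:
            lo, hi = seg.sp_beg, seg.sp_end
        else:
            lo, hi = seg.pdb_beg, seg.pdb_end
        if lo <= end and start <= hi:
            accs.add(seg.uniprot_id)
    return accs


def map_instance(
    sti: StructuralInstance, sifts_index: SiftsIndex, obsolete_ids: set[str]
) -> MappingOutcome:
    """Complete the dual numbering of one instance via SIFTS.

    The native span must fall entirely within ONE usable segment of ONE
    UniProt accession; the other numbering is then the affine shift
    ``target = target_beg + (pos - source_beg)``.  A span covered by no
    segment, crossing segments, or touching two accessions is
    INCONSISTENT.  Already-mapped instances are returned unchanged
    (mapping is idempotent).
    """
    if sti.pdb_id.upper() in obsolete_ids:
        return MappingOutcome(MappingStatus.OBSOLETE, sti, "PDB entry is obsolete")
    if sti.is_mapped:
        return MappingOutcome(MappingStatus.MAPPED, sti, "already mapped")

    chain = sifts_index.get(sti.pdb_id, sti.chain_id)
    if chain is None or (not chain.usable and not chain.unusable):
        return MappingOutcome(
            MappingStatus.INCONSISTENT, sti, "chain absent from SIFTS table"
        )
    span = sti.native_span
    covering = _covering_segments(chain.usable, span, sti.source_db)
    if not covering:
        overlapping = _overlapping_accessions(chain.usable, span, sti.source_db)
        if len(overlapping) > 1:
            return MappingOutcome(
                MappingStatus.INCONSISTENT,
                sti,
                "span maps to multiple UniProt accessions: "
                + ",".join(sorted(overlapping)),
            )
        if overlapping:
            return MappingOutcome(
                MappingStatus.INCONSISTENT,
                sti,
                "span crosses segment boundaries / not covered by a single segment",
            )
        if chain.unusable:
            return MappingOutcome(
                MappingStatus.INCONSISTENT,
                sti,
                "only unusable SIFTS segments overlap the chain: "
                + "; ".join(chain.unusable),
            )
        return MappingOutcome(
            MappingStatus.INCONSISTENT, sti, "no SIFTS segment covers the span"
        )
    accessions = {seg.uniprot_id for seg in covering}
    if len(accessions) > 1:
        return MappingOutcome(
            MappingStatus.INCONSISTENT,
            sti,
            "span covered by segments of multiple UniProt accessions: "
            + ",".join(sorted(accessions)),
        )
    # distinct offsets from redundant covering segments would be ambiguous
    mapped_spans = set()
    for seg in covering:
        if sti.source_db is SourceDB.PFAM_SIDE:
            offset = seg.pdb_beg - seg.sp_beg
        else:
            offset = seg.sp_beg - seg.pdb_beg
        mapped_spans.add((span[0] + offset, span[1] + offset))
    if len(mapped_spans) > 1:
        return MappingOutcome(
            MappingStatus.INCONSISTENT,
            sti,
            "covering segments disagree on the numbering offset",
        )
    (tgt_start, tgt_end), = mapped_spans
    accession = next(iter(accessions))
    if sti.uniprot_id is not None and sti.uniprot_id != accession:
        return MappingOutcome(
            MappingStatus.INCONSISTENT,
            sti,
            f"record accession {sti.uniprot_id} disagrees with SIFTS {accession}",
        )
    mapped = copy.copy(sti)
    if sti.source_db is SourceDB.PFAM_SIDE:
        mapped.pdb_start, mapped.pdb_end = tgt_start, tgt_end
    else:
        mapped.uniprot_start, mapped.uniprot_end = tgt_start, tgt_end
    mapped.uniprot_id = accession
    return MappingOutcome(MappingStatus.MAPPED, mapped, "")


def map_instances(
    stis: list[StructuralInstance], sifts_index: SiftsIndex, obsolete_ids: set[str]
) -> list[MappingOutcome]:
    """Map a list of post-filter instances, preserving order."""
    return [map_instance(sti, sifts_index, obsolete_ids) for sti in stis]


def write_unmapped_report(outcomes: list[MappingOutcome], path) -> None:
    """Write the curator-facing list of non-mapped instances.

    One row per OBSOLETE / INCONSISTENT / LENGTH_FILTERED instance:
    instance key, status, reason.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["instance_key", "status", "reason"])
        for out in outcomes:
            if out.status is not MappingStatus.MAPPED:
                writer.writerow([instance_key(out.instance), out.status.value, out.reason])
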