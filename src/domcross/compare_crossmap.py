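"""Set comparison of the two mapped instance lists and cross-mapping.

Comparison works on PDB id, chain id and UniProt boundaries: two
records denote the same domain instance when they sit on the same chain
of the same entry, agree on the UniProt accession (when both carry
one), and their start and end boundaries each differ by at most the
configured tolerance.  The two databases routinely disagree by a few
residues on where a domain begins, hence the tolerance (30 by default).

Instances unique to one database are *cross-mapped*: the full table of
the other database is queried by PDB id + chain, and boundary agreement
is checked in the target side's native numbering.  A hit names the
family of the other database that houses the instance; instances with
no hit remain un-mapped and are later judged structurally one by one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core_model import SourceDB, StructuralInstance, instance_key

__all__ = [
    "ComparisonResult",
    "CrossmapHit",
    "TargetIndex",
    "match_boundaries",
    "partition_instances",
    "crossmap_instance",
]


def match_boundaries(a: tuple[int, int], b: tuple[int, int], tolerance: int) -> bool:
    """True when both boundary differences are within the tolerance.

    ``|a.start - b.start| <= tolerance`` and ``|a.end - b.end| <=
    tolerance``, inclusive.  The two regions must be expressed in the
    same numbering system; this function cannot check that.
    """
    return abs(a[0] - b[0]) <= tolerance and abs(a[1] - b[1]) <= tolerance


def _boundary_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Max of start and end differences (the hit-quality metric)."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _total_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


@dataclass
class ComparisonResult:
    """Common pairs and per-side unique instances."""

    common_pairs: list[tuple[StructuralInstance, StructuralInstance]] = field(
        default_factory=list
    )
    unique_pfam: list[StructuralInstance] = field(default_factory=list)
    unique_cath: list[StructuralInstance] = field(default_factory=list)


def partition_instances(
    pfam_mapped: list[StructuralInstance],
    cath_mapped: list[StructuralInstance],
    tolerance: int,
) -> ComparisonResult:
    """Split the two mapped sets into common pairs and uniques.

    Candidate pairs require equal PDB id, chain id and (when both sides
    carry one) equal UniProt accession; boundary agreement is decided in
    UniProt numbering.  Pairing is greedy one-to-one in ascending order
    of total boundary distance, ties broken by the smaller instance
    keys, which makes the outcome deterministic and symmetric.
    """
    candidates = []
    for i, p in enumerate(pfam_mapped):
        for j, c in enumerate(cath_mapped):
            if p.pdb_id != c.pdb_id or p.chain_id != c.chain_id:
                continue
            if (
                p.uniprot_id is not None
                and c.uniprot_id is not None
                and p.uniprot_id != c.uniprot_id
            ):
                continue
            if match_boundaries(p.uniprot_span, c.uniprot_span, tolerance):
                dist = _total_distance(p.uniprot_span, c.uniprot_span)
                candidates.append((dist, instance_key(p), instance_key(c), i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_c: set[int] = set()
    result = ComparisonResult()
    for _, _, _, i, j in candidates:
        if i in used_p or j in used_c:
            continue
        used_p.add(i)
        used_c.add(j)
        result.common_pairs.append((pfam_mapped[i], cath_mapped[j]))
    result.unique_pfam = [p for i, p in enumerate(pfam_mapped) if i not in used_p]
    result.unique_cath = [c for j, c in enumerate(cath_mapped) if j not in used_c]
    return result


@dataclass
class CrossmapHit:
    """A unique instance located in a family of the other database."""

    source: StructuralInstance
    target_family: str
    target_span: tuple[int, int]
    distance: int
    novel: bool
    #: other in-tolerance candidate families, for the audit trail
    alternatives: list[tuple[str, int]] = field(default_factory=list)


class TargetIndex:
    """(pdb, chain) index over the FULL table of one database side."""

    def __init__(self, records: list[StructuralInstance], side: SourceDB) -> None:
        self.side = SourceDB(side)
        self._by_chain: dict[tuple[str, str], list[StructuralInstance]] = {}
        for rec in records:
            if rec.source_db is not self.side:
                raise ValueError(
                    f"record {instance_key(rec)} is not on the {self.side.value}"
                )
            self._by_chain.setdefault((rec.pdb_id, rec.chain_id), []).append(rec)

    def candidates(self, pdb_id: str, chain_id: str) -> list[StructuralInstance]:
        return self._by_chain.get((pdb_id, chain_id), [])


def crossmap_instance(
    sti: StructuralInstance,
    target_index: TargetIndex,
    tolerance: int,
    processed_families: set[str],
) -> Optional[CrossmapHit]:
    """Look up one database-unique instance in the other database.

    Boundary agreement is checked in the *target* side's native
    numbering (UniProt when the target is the Pfam side, PDB author
    numbering for the CATH side); the source instance is fully mapped,
    so both spans are available.  The best hit is the candidate with
    the smallest boundary distance (max of start/end differences), ties
    broken by the lexicographically smaller family id.  Hits into
    families already processed in earlier iterations are returned with
    ``novel=False``; they must not re-trigger those families.  Returns
    None when no candidate is within tolerance (un-mapped).
    """
    if target_index.side is SourceDB.PFAM_SIDE:
        source_span = sti.uniprot_span
    else:
        source_span = sti.pdb_span
    scored: list[tuple[int, str, StructuralInstance]] = []
    for cand in target_index.candidates(sti.pdb_id, sti.chain_id):
        span = cand.native_span
        if match_boundaries(source_span, span, tolerance):
            scored.append((_boundary_distance(source_span, span), cand.family_id, cand))
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1]))
    dist, family, best = scored[0]
    return CrossmapHit(
        source=sti,
        target_family=family,
        target_span=best.native_span,
        distance=dist,
        novel=family not in processed_families,
        alternatives=[(f, d) for d, f, _ in scored[1:] if f != family],
    )


def write_crossmap_report(hits: list[CrossmapHit], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source_key", "target_family", "distance", "novel"])
        for hit in hits:
            writer.writerow(
                [
                    instance_key(hit.source),
                    hit.target_family,
                    hit.distance,
                    "yes" if hit.novel else "no",
                ]
            )


def write_unmapped_instances(stis: list[StructuralInstance], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["instance_key"])
        for sti in stis:
            writer.writerow([instance_key(sti)])
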