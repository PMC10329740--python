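"""Shared domain types for cross-database protein-domain classification.

The central object is the *structural instance* (StI): the region of one
PDB chain covered by one domain-family assignment.  Sequence-family
databases (the "Pfam side") number domain boundaries in UniProt
coordinates, while structure-domain databases (the "CATH side") use PDB
author numbering; an StI therefore carries both numbering systems, with
the missing one filled in by residue mapping.

All residue ranges throughout the package are 1-based and inclusive at
both ends, matching PDB author numbering.  PDB insertion codes and
non-integer author numbers are deliberately not modeled; records that
would need them are routed to the INCONSISTENT category instead.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SourceDB",
    "Provenance",
    "Category",
    "FamilyStatus",
    "StructuralInstance",
    "SiftsSegment",
    "BackboneStructure",
    "AlignmentResult",
    "LedgerEntry",
    "FamilyEntry",
    "CategoryLedger",
    "RunConfig",
    "IterationState",
    "instance_key",
    "region_length",
    "region_overlap_fraction",
    "InvalidInstanceError",
    "InvalidRegionError",
    "BACKBONE_ATOMS",
]

#: Backbone atom names, in the storage order used by every coordinate array.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_PFAM_ACC_RE = re.compile(r"^PF\d{5}$")
_CATH_ACC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class InvalidInstanceError(ValueError):
    """A structural instance violates its structural invariants."""


class InvalidRegionError(ValueError):
    """A residue range with start > end or non-positive bounds."""


class SourceDB(str, enum.Enum):
    """Which database side an instance was retrieved from."""

    PFAM_SIDE = "PFAM_SIDE"
    CATH_SIDE = "CATH_SIDE"

    @property
    def other(self) -> "SourceDB":
        return SourceDB.CATH_SIDE if self is SourceDB.PFAM_SIDE else SourceDB.PFAM_SIDE


class Provenance(str, enum.Enum):
    EXPERIMENTAL = "EXPERIMENTAL"
    INSTANCE_AVERAGE = "INSTANCE_AVERAGE"
    FAMILY_AVERAGE = "FAMILY_AVERAGE"
    CORE_AVERAGE = "CORE_AVERAGE"


class Category(str, enum.Enum):
    """Final per-instance classification.

    CORE instances are the iteration-1 common set and are also counted
    among TRUE in all summary reporting.
    """

    CORE = "CORE"
    TRUE = "TRUE"
    DOMAIN_LIKE = "DOMAIN_LIKE"
    FAILED = "FAILED"
    OBSOLETE = "OBSOLETE"
    INCONSISTENT = "INCONSISTENT"
    LENGTH_FILTERED = "LENGTH_FILTERED"


class FamilyStatus(str, enum.Enum):
    STARTING = "STARTING"
    ACCEPTED = "ACCEPTED"
    FAILED = "FAILED"


# ---------------------------------------------------------------------------
# Regions


def region_length(start: int, end: int) -> int:
    """Number of residues in the inclusive range ``[start, end]``."""
    if start > end:
        raise InvalidRegionError(f"invalid region: start {start} > end {end}")
    return end - start + 1


def region_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two inclusive ranges as a fraction of the shorter one.

    Returns ``|a ∩ b| / min(|a|, |b|)``; 0.0 for disjoint ranges.
    """
    la = region_length(*a)
    lb = region_length(*b)
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / min(la, lb)


# ---------------------------------------------------------------------------
# Structural instance


@dataclass
class StructuralInstance:
    """One domain region on one PDB chain, with dual numbering.

    Before residue mapping exactly one numbering system is populated:
    UniProt boundaries for Pfam-side instances, PDB author boundaries
    for CATH-side instances.  After a successful mapping both are set
    and the two spans have equal length.
    """

    pdb_id: str
    chain_id: str
    domain_label: str
    family_id: str
    source_db: SourceDB
    pdb_start: Optional[int] = None
    pdb_end: Optional[int] = None
    uniprot_id: Optional[str] = None
    uniprot_start: Optional[int] = None
    uniprot_end: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise InvalidInstanceError(f"PDB id must be 4 characters: {self.pdb_id!r}")
        if not self.chain_id:
            raise InvalidInstanceError("empty chain id")
        self.source_db = SourceDB(self.source_db)
        if self.pdb_start is not None and self.pdb_end is not None:
            if self.pdb_start > self.pdb_end:
                raise InvalidInstanceError(
                    f"pdb_start {self.pdb_start} > pdb_end {self.pdb_end}"
                )
        if self.uniprot_start is not None and self.uniprot_end is not None:
            if self.uniprot_start > self.uniprot_end:
                raise InvalidInstanceError(
                    f"uniprot_start {self.uniprot_start} > uniprot_end {self.uniprot_end}"
                )
        acc_re = _PFAM_ACC_RE if self.source_db is SourceDB.PFAM_SIDE else _CATH_ACC_RE
        if not acc_re.match(self.family_id):
            raise InvalidInstanceError(
                f"family id {self.family_id!r} does not match the "
                f"{self.source_db.value} accession syntax"
            )

    # -- numbering helpers -------------------------------------------------

    @property
    def native_span(self) -> tuple[int, int]:
        """Boundaries in the instance's own database numbering."""
        if self.source_db is SourceDB.PFAM_SIDE:
            s, e = self.uniprot_start, self.uniprot_end
        else:
            s, e = self.pdb_start, self.pdb_end
        if s is None or e is None:
            raise InvalidInstanceError(
                f"native span not populated for {self.pdb_id}/{self.chain_id}"
            )
        return s, e

    @property
    def uniprot_span(self) -> tuple[int, int]:
        if self.uniprot_start is None or self.uniprot_end is None:
            raise InvalidInstanceError("UniProt span not populated")
        return self.uniprot_start, self.uniprot_end

    @property
    def pdb_span(self) -> tuple[int, int]:
        if self.pdb_start is None or self.pdb_end is None:
            raise InvalidInstanceError("PDB span not populated")
        return self.pdb_start, self.pdb_end

    @property
    def is_mapped(self) -> bool:
        return None not in (
            self.pdb_start,
            self.pdb_end,
            self.uniprot_start,
            self.uniprot_end,
        ) and self.uniprot_id is not None

    def key(self) -> str:
        return instance_key(self)


def instance_key(sti: StructuralInstance) -> str:
    """Canonical, run-stable identity of an instance.

    Built from the side's *native* numbering so the key is unchanged by
    residue mapping: ``pdb|chain|side|family|start|end``.
    """
    if not sti.pdb_id or not sti.chain_id:
        raise InvalidInstanceError("instance without pdb or chain id has no key")
    start, end = sti.native_span
    return "|".join(
        [sti.pdb_id, sti.chain_id, sti.source_db.value, sti.family_id, str(start), str(end)]
    )


# ---------------------------------------------------------------------------
# SIFTS segments


@dataclass(frozen=True)
class SiftsSegment:
    """One contiguous PDB↔UniProt correspondence segment of a chain."""

    pdb_id: str
    chain_id: str
    uniprot_id: str
    sp_beg: int
    sp_end: int
    pdb_beg: int
    pdb_end: int

    def __post_init__(self) -> None:
        if min(self.sp_beg, self.sp_end, self.pdb_beg, self.pdb_end) < 1:
            raise InvalidRegionError("SIFTS segment bounds must be positive")
        if self.sp_end - self.sp_beg != self.pdb_end - self.pdb_beg:
            raise InvalidRegionError(
                "SIFTS segment is not contiguous: UniProt and PDB spans differ in length"
            )


# ---------------------------------------------------------------------------
# Backbone coordinates


class BackboneStructure:
    """Ordered backbone (N, CA, C, O) coordinates of one chain region.

    Coordinates are stored as an ``(n_residues, 4, 3)`` float array in Å,
    atom order as in :data:`BACKBONE_ATOMS`.  Residue numbers are the
    author numbers of the source chain (or 1..k for computed averages)
    and must be strictly increasing.
    """

    def __init__(
        self,
        structure_id: str,
        residue_numbers,
        coords,
        provenance: Provenance = Provenance.EXPERIMENTAL,
    ) -> None:
        self.structure_id = str(structure_id)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.coords = np.asarray(coords, dtype=float)
        self.provenance = Provenance(provenance)
        if self.residue_numbers.ndim != 1 or len(self.residue_numbers) == 0:
            raise ValueError("a backbone structure needs at least one residue")
        if self.coords.shape != (len(self.residue_numbers), 4, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.residue_numbers)} residues x 4 backbone atoms x 3"
            )
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape ``(n_residues, 3)``."""
        return self.coords[:, BACKBONE_ATOMS.index("CA"), :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        new = self.coords.reshape(-1, 3) @ np.asarray(rotation).T + np.asarray(translation)
        return BackboneStructure(
            self.structure_id, self.residue_numbers.copy(), new.reshape(self.coords.shape), self.provenance
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BackboneStructure({self.structure_id!r}, {len(self)} residues, "
            f"{self.provenance.value})"
        )


# ---------------------------------------------------------------------------
# Alignment result


@dataclass
class AlignmentResult:
    """Outcome of aligning a query backbone against a reference."""

    query_id: str
    reference_id: str
    score: float
    rmsd: float
    n_matched: int
    offset: int
    passed: bool
    #: True when the query was longer than the reference and the offset
    #: therefore slides the reference along the query.
    flipped: bool = False
    #: Rigid transform taking query coordinates into the reference frame.
    transform: Optional["object"] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"alignment score {self.score} outside [0, 1]")
        if self.rmsd < 0 or not math.isfinite(self.rmsd):
            raise ValueError(f"invalid rmsd {self.rmsd}")

    def pair_indices(self, n_query: int, n_reference: int) -> tuple[np.ndarray, np.ndarray]:
        """Residue-index correspondence (query indices, reference indices)."""
        if not self.flipped:
            q = np.arange(n_query)
            return q, q + self.offset
        r = np.arange(n_reference)
        return r + self.offset, r


# ---------------------------------------------------------------------------
# Ledger


@dataclass
class LedgerEntry:
    key: str
    category: Category
    iteration: int
    score: Optional[float] = None
    reason: str = ""


@dataclass
class FamilyEntry:
    family_id: str
    side: SourceDB
    status: FamilyStatus
    score: Optional[float] = None
    iteration: int = 0


class CategoryLedger:
    """Final per-instance categories with per-step provenance.

    Every parsed instance key appears exactly once.  CORE entries are
    included in TRUE totals when counting, mirroring the convention that
    core instances are a subset of the true set.
    """

    def __init__(self) -> None:
        self.entries: dict[str, LedgerEntry] = {}
        self.families: list[FamilyEntry] = []

    def assign(
        self,
        key: str,
        category: Category,
        iteration: int,
        score: Optional[float] = None,
        reason: str = "",
    ) -> None:
        if key in self.entries:
            raise ValueError(
                f"instance {key} already categorized as {self.entries[key].category.value}"
            )
        self.entries[key] = LedgerEntry(key, Category(category), iteration, score, reason)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def add_family(self, entry: FamilyEntry) -> None:
        self.families.append(entry)

    def of_category(self, category: Category) -> list[LedgerEntry]:
        return [e for e in self.entries.values() if e.category is category]

    def counts(self) -> dict[str, int]:
        """Entry counts per category, with CORE also counted into TRUE."""
        out = {c.value: 0 for c in Category}
        for e in self.entries.values():
            out[e.category.value] += 1
        out["TRUE"] += out["CORE"]
        return out


# ---------------------------------------------------------------------------
# Run configuration and loop state


@dataclass
class RunConfig:
    """Parameters of one classification run.

    tolerance
        Maximum allowed difference (residues) between start and between
        end boundaries for two records to denote the same domain
        instance; used both for set comparison and for cross-mapping.
    score_threshold
        Minimum Gaussian alignment score against the core average for a
        family or instance to qualify for the domain type.
    min_length
        Instances shorter than this many residues are filtered out
        before mapping, to avoid scoring fragments.
    sigma
        Width (Å) of the Gaussian used in the similarity score.
    coverage_min
        Minimum fraction of members that must contribute a residue for
        an averaged position to be emitted.
    """

    pfam_table: str = ""
    cath_table: str = ""
    sifts_table: str = ""
    obsolete_list: str = ""
    pdb_dir: str = ""
    out_dir: str = "domcross_out"
    starting_families_pfam: list[str] = field(default_factory=list)
    starting_families_cath: list[str] = field(default_factory=list)
    tolerance: int = 30
    score_threshold: float = 0.6
    min_length: int = 30
    sigma: float = 2.0
    coverage_min: float = 0.5
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not (0.0 < self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 < self.coverage_min <= 1.0):
            raise ValueError("coverage_min must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationState:
    """Mutable state carried across workflow iterations."""

    iteration: int = 1
    families_pfam_side: list[str] = field(default_factory=list)
    families_cath_side: list[str] = field(default_factory=list)
    carried_instances: list[StructuralInstance] = field(default_factory=list)
    processed_families: set[str] = field(default_factory=set)
    core_average: Optional[BackboneStructure] = None
    ledger: CategoryLedger = field(default_factory=CategoryLedger)
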