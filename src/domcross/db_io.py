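"""Readers and writers for every file format the pipeline touches.

Five formats are handled:

* the *interchange table*: one tab-separated dialect carrying the rows
  of both domain databases (header ``#side pdb chain label family
  start end uniprot``), with start/end in each side's native numbering;
* the nine-field *unified record* printed for fully mapped instances
  (``PDB,chain,label,family,pdb_start,pdb_end,uniprot,up_start,up_end``);
* a SIFTS-style PDB↔UniProt segment table following the
  ``pdb_chain_uniprot`` column convention;
* the obsolete-PDB-ID list, one ID per line;
* PDB coordinate files, read and written backbone-only through gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import gemmi
import numpy as np

from .core_model import (
    BACKBONE_ATOMS,
    BackboneStructure,
    InvalidInstanceError,
    Provenance,
    SiftsSegment,
    SourceDB,
    StructuralInstance,
)

__all__ = [
    "ParseError",
    "read_database_table",
    "serialize_unified",
    "parse_unified",
    "SiftsIndex",
    "ChainSegments",
    "read_sifts_table",
    "read_backbone",
    "write_backbone",
    "read_obsolete_list",
]

PathLike = Union[str, Path]

_SIDE_TAGS = {"PFAM": SourceDB.PFAM_SIDE, "CATH": SourceDB.CATH_SIDE}
_TABLE_HEADER = "#side\tpdb\tchain\tlabel\tfamily\tstart\tend\tuniprot"


class ParseError(ValueError):
    """A malformed row; the message names the file and line number."""


# ---------------------------------------------------------------------------
# Interchange table


def read_database_table(path: PathLike, side: SourceDB) -> list[StructuralInstance]:
    """Read one side's domain-assignment table.

    Each row becomes a :class:`StructuralInstance` with only its native
    numbering populated (UniProt for the Pfam side, PDB author numbering
    for the CATH side).  Row order is preserved.
    """
    side = SourceDB(side)
    path = Path(path)
    instances: list[StructuralInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, got {len(fields)}"
                )
            tag, pdb_id, chain_id, label, family, start_s, end_s, uniprot = fields
            if tag not in _SIDE_TAGS:
                raise ParseError(f"{path}:{lineno}: unknown side tag {tag!r}")
            if _SIDE_TAGS[tag] is not side:
                raise ParseError(
                    f"{path}:{lineno}: row tagged {tag} in a {side.value} table"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer boundary") from exc
            uniprot_id = None if uniprot == "-" else uniprot
            try:
                if side is SourceDB.PFAM_SIDE:
                    sti = StructuralInstance(
                        pdb_id=pdb_id,
                        chain_id=chain_id,
                        domain_label=label,
                        family_id=family,
                        source_db=side,
                        uniprot_id=uniprot_id,
                        uniprot_start=start,
                        uniprot_end=end,
                    )
                else:
                    sti = StructuralInstance(
                        pdb_id=pdb_id,
                        chain_id=chain_id,
                        domain_label=label,
                        family_id=family,
                        source_db=side,
                        uniprot_id=uniprot_id,
                        pdb_start=start,
                        pdb_end=end,
                    )
            except InvalidInstanceError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            instances.append(sti)
    return instances


def write_database_table(instances: list[StructuralInstance], path: PathLike) -> None:
    """Write instances back out in the interchange dialect."""
    lines = [_TABLE_HEADER]
    for sti in instances:
        tag = "PFAM" if sti.source_db is SourceDB.PFAM_SIDE else "CATH"
        start, end = sti.native_span
        lines.append(
            "\t".join(
                [
                    tag,
                    sti.pdb_id,
                    sti.chain_id,
                    sti.domain_label,
                    sti.family_id,
                    str(start),
                    str(end),
                    sti.uniprot_id or "-",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Unified nine-field record


def serialize_unified(sti: StructuralInstance) -> str:
    """Render a fully mapped instance as the nine-field unified record.

    Example: ``1CVJ,G,RRM_1,PF00076,13,83,P11940,13,83``.
    """
    if not sti.is_mapped:
        raise InvalidInstanceError(
            f"cannot serialize unmapped instance {sti.pdb_id}/{sti.chain_id}"
        )
    return ",".join(
        [
            sti.pdb_id,
            sti.chain_id,
            sti.domain_label,
            sti.family_id,
            str(sti.pdb_start),
            str(sti.pdb_end),
            sti.uniprot_id,
            str(sti.uniprot_start),
            str(sti.uniprot_end),
        ]
    )


def parse_unified(line: str, side: SourceDB) -> StructuralInstance:
    """Inverse of :func:`serialize_unified` (the side is not encoded)."""
    fields = line.strip().split(",")
    if len(fields) != 9:
        raise ParseError(f"unified record needs 9 fields, got {len(fields)}: {line!r}")
    pdb_id, chain_id, label, family, ps, pe, up, us, ue = fields
    return StructuralInstance(
        pdb_id=pdb_id,
        chain_id=chain_id,
        domain_label=label,
        family_id=family,
        source_db=SourceDB(side),
        pdb_start=int(ps),
        pdb_end=int(pe),
        uniprot_id=up,
        uniprot_start=int(us),
        uniprot_end=int(ue),
    )


# ---------------------------------------------------------------------------
# SIFTS segment table


@dataclass
class ChainSegments:
    """Usable and flagged SIFTS segments of one (pdb, chain)."""

    pdb_id: str
    chain_id: str
    usable: list[SiftsSegment] = field(default_factory=list)
    unusable: list[str] = field(default_factory=list)  # reasons, one per bad row

    @property
    def accessions(self) -> set[str]:
        return {s.uniprot_id for s in self.usable}

    @property
    def multi_accession(self) -> bool:
        return len(self.accessions) > 1


class SiftsIndex:
    """Per-chain index over a SIFTS-style segment table."""

    def __init__(self) -> None:
        self._chains: dict[tuple[str, str], ChainSegments] = {}

    def get(self, pdb_id: str, chain_id: str) -> ChainSegments | None:
        return self._chains.get((pdb_id.upper(), chain_id))

    def add(self, pdb_id: str, chain_id: str) -> ChainSegments:
        key = (pdb_id.upper(), chain_id)
        if key not in self._chains:
            self._chains[key] = ChainSegments(key[0], chain_id)
        return self._chains[key]

    def __len__(self) -> int:
        return len(self._chains)


def read_sifts_table(path: PathLike) -> SiftsIndex:
    """Read a PDB↔UniProt segment table.

    Columns: ``PDB CHAIN SP_PRIMARY SP_BEG SP_END PDB_BEG PDB_END``
    (tab-separated; comment lines start with '#'; an optional literal
    header row is skipped).  Segments whose PDB bounds are not plain
    integers, or whose UniProt and PDB spans differ in length, are kept
    as flagged *unusable* rather than dropped, so the residue-mapping
    step can report them as inconsistent.
    """
    path = Path(path)
    index = SiftsIndex()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].upper() == "PDB":  # column-name header
                continue
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            pdb_id, chain_id, acc, sp_beg, sp_end, pdb_beg, pdb_end = fields
            chain = index.add(pdb_id, chain_id)
            try:
                seg = SiftsSegment(
                    pdb_id=pdb_id.upper(),
                    chain_id=chain_id,
                    uniprot_id=acc,
                    sp_beg=int(sp_beg),
                    sp_end=int(sp_end),
                    pdb_beg=int(pdb_beg),
                    pdb_end=int(pdb_end),
                )
            except ValueError as exc:
                chain.unusable.append(f"line {lineno}: {exc}")
                continue
            chain.usable.append(seg)
    for chain in index._chains.values():
        chain.usable.sort(key=lambda s: (s.sp_beg, s.uniprot_id))
    return index


# ---------------------------------------------------------------------------
# PDB backbone I/O


def read_backbone(
    path: PathLike, chain_id: str, start: int, end: int, structure_id: str | None = None
) -> BackboneStructure:
    """Extract N/CA/C/O coordinates of residues ``start..end`` of a chain.

    ``start``/``end`` are author residue numbers, inclusive.  Residues
    missing any of the four backbone atoms (or carrying an insertion
    code) are skipped with a warning.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FileNotFoundError(f"no models in {path}")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain {chain_id!r} not found in {path}")
    numbers: list[int] = []
    coords: list[np.ndarray] = []
    for res in chain:
        if res.seqid.num is None or not (start <= res.seqid.num <= end):
            continue
        if res.seqid.icode not in ("", " ", "\x00"):
            warnings.warn(
                f"{path}: skipping residue {res.seqid.num}{res.seqid.icode} "
                f"(insertion codes are not modeled)"
            )
            continue
        atom_pos = {}
        for atom in res:
            if atom.name in BACKBONE_ATOMS and atom.name not in atom_pos:
                atom_pos[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
        if len(atom_pos) < 4:
            missing = sorted(set(BACKBONE_ATOMS) - set(atom_pos))
            warnings.warn(
                f"{path}: skipping residue {res.seqid.num} of chain {chain_id} "
                f"(missing backbone atoms: {','.join(missing)})"
            )
            continue
        numbers.append(res.seqid.num)
        coords.append(np.array([atom_pos[a] for a in BACKBONE_ATOMS]))
    if not numbers:
        raise ValueError(
            f"{path}: no complete residues of chain {chain_id} in range {start}-{end}"
        )
    sid = structure_id or f"{path.stem}_{chain_id}_{start}_{end}"
    return BackboneStructure(sid, numbers, np.stack(coords), Provenance.EXPERIMENTAL)


def write_backbone(structure: BackboneStructure, path: PathLike, chain_id: str = "A") -> None:
    """Write a backbone as standard ATOM records (occ 1.00, B 0.00)."""
    st = gemmi.Structure()
    st.name = structure.structure_id[:78]
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for num, res_coords in zip(structure.residue_numbers, structure.coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        res.het_flag = "A"
        for atom_name, pos in zip(BACKBONE_ATOMS, res_coords):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*map(float, pos))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path), gemmi.PdbWriteOptions(minimal_file=True))


# ---------------------------------------------------------------------------
# Obsolete list


def read_obsolete_list(path: PathLike) -> set[str]:
    """Read one PDB ID per line ('#' comments allowed); stored uppercase."""
    ids: set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.add(line.upper())
    return ids
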