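"""Superposition, Gaussian similarity scoring and average structures.

The structural assessment needs three primitives:

* least-squares rigid-body superposition of paired points (Kabsch);
* a Gaussian overlap score of paired CA distances, normalized by the
  reference length — a stand-in for the M-score of multiple-structure
  aligners: 1.0 means every reference position is matched at zero
  distance, and the score decays smoothly with deviation instead of
  being dominated by outliers the way plain RMSD is;
* averaging of backbone coordinate sets after mutual superposition, at
  the UniProt-instance level, the family level ("average of
  averages"), and for the core prototype.

The built-in aligner is deliberately simple: a gapless offset scan of
the query CA trace along the reference, each offset superposed and
iteratively refined on the well-fitting pairs.  It is adequate for
single-domain regions of similar length — exactly what the pipeline
feeds it — and is fully deterministic.  An external gapped aligner can
be plugged in via :class:`ExternalAligner` without touching the rest of
the pipeline.

Averaged structures are alignment prototypes, not physical models:
locally averaged bond geometry may be distorted.
"""

from __future__ import annotations

import csv
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    AlignmentResult,
    BackboneStructure,
    Provenance,
    StructuralInstance,
    instance_key,
    region_overlap_fraction,
)

__all__ = [
    "Superposition",
    "ScoreParams",
    "DegenerateInputError",
    "kabsch_superpose",
    "gaussian_score",
    "align_to_reference",
    "average_structures",
    "group_instances",
    "instance_level_averages",
    "family_level_average",
    "ExternalAligner",
    "write_scores",
]


class DegenerateInputError(ValueError):
    """Fewer than three points, or a collinear configuration."""


@dataclass
class Superposition:
    """Rigid transform ``x -> R x + t`` plus its residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


@dataclass
class ScoreParams:
    """Knobs of the built-in aligner and averaging.

    sigma
        Gaussian width in Å (default 2.0: ~one CA-CA bond of slack).
    threshold
        Score at or above which an alignment counts as passed.
    refine_cutoff
        Pairs beyond ``refine_cutoff * sigma`` Å are dropped from the
        superposition during refinement.
    max_refine_rounds
        Upper bound on refinement re-superpositions per offset.
    coverage_min
        Fraction of members that must contribute for an averaged
        position to be emitted.
    """

    sigma: float = 2.0
    threshold: float = 0.6
    refine_cutoff: float = 2.0
    max_refine_rounds: int = 5
    coverage_min: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Solves for the proper rotation R and translation t minimizing
    ``sum_i |R m_i + t - f_i|^2`` via the SVD of the cross-covariance
    matrix, with the reflection corrected by the sign of its
    determinant.  Requires >= 3 non-collinear point pairs.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateInputError("superposition needs at least 3 point pairs")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    m0 = moving - cm
    f0 = fixed - cf
    # collinear points leave the rotation about the axis undetermined
    sv_m = np.linalg.svd(m0, compute_uv=False)
    if sv_m[1] <= 1e-9 * max(sv_m[0], 1.0):
        raise DegenerateInputError("point set is (near-)collinear")
    H = m0.T @ f0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cf - R @ cm
    diff = m0 @ R.T - f0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


# ---------------------------------------------------------------------------
# Gaussian similarity score


def gaussian_score(distances, sigma: float, n_norm: int) -> float:
    """Normalized Gaussian overlap of paired distances.

    ``score = (1/n_norm) * sum_i exp(-d_i^2 / (2 sigma^2))``.

    With ``n_norm`` set to the reference length, unpaired reference
    positions contribute zero, so truncated matches score in proportion
    to their coverage.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(list(distances), float)
    if n_norm < max(1, d.size):
        raise ValueError(f"n_norm {n_norm} smaller than number of distances {d.size}")
    if d.size == 0:
        return 0.0
    return float(np.exp(-(d**2) / (2.0 * sigma**2)).sum() / n_norm)


# ---------------------------------------------------------------------------
# Built-in aligner


def _refine_superposition(
    q: np.ndarray, r: np.ndarray, params: ScoreParams
) -> tuple[Superposition, np.ndarray]:
    """Superpose q onto r, iteratively re-fitting on close pairs.

    Returns the final transform and the boolean inclusion mask of the
    pairs it was fitted on.
    """
    sup = kabsch_superpose(q, r)
    include = np.ones(len(q), dtype=bool)
    cutoff = params.refine_cutoff * params.sigma
    for _ in range(params.max_refine_rounds):
        d = np.linalg.norm(sup.apply(q) - r, axis=1)
        new_include = d <= cutoff
        if new_include.sum() < 3 or np.array_equal(new_include, include):
            break
        include = new_include
        sup = kabsch_superpose(q[include], r[include])
    return sup, include


def align_to_reference(
    query: BackboneStructure, reference: BackboneStructure, params: ScoreParams
) -> AlignmentResult:
    """Gapless offset-scan alignment of query CA trace vs reference.

    For each shift of the shorter trace along the longer one, the
    paired CAs are superposed and refined; the offset with the highest
    Gaussian score (normalized by the reference length) wins, ties
    going to the smaller offset.  The returned transform maps query
    coordinates into the reference frame, which is what averaging
    needs.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("cannot align empty structures")
    q_ca = query.ca
    r_ca = reference.ca
    n, m = len(query), len(reference)
    flipped = n > m
    n_pairs = min(n, m)
    best: tuple[float, int, Superposition, np.ndarray] | None = None
    for offset in range(abs(m - n) + 1):
        if flipped:
            q_seg = q_ca[offset : offset + n_pairs]
            r_seg = r_ca
        else:
            q_seg = q_ca
            r_seg = r_ca[offset : offset + n_pairs]
        sup, include = _refine_superposition(q_seg, r_seg, params)
        d_all = np.linalg.norm(sup.apply(q_seg) - r_seg, axis=1)
        score = gaussian_score(d_all, params.sigma, m)
        if best is None or score > best[0]:
            best = (score, offset, sup, include)
    score, offset, sup, include = best
    if flipped:
        q_seg = q_ca[offset : offset + n_pairs]
        r_seg = r_ca
    else:
        q_seg = q_ca
        r_seg = r_ca[offset : offset + n_pairs]
    d_inc = np.linalg.norm(sup.apply(q_seg[include]) - r_seg[include], axis=1)
    rmsd = float(np.sqrt((d_inc**2).mean()))
    return AlignmentResult(
        query_id=query.structure_id,
        reference_id=reference.structure_id,
        score=min(score, 1.0),
        rmsd=rmsd,
        n_matched=int(include.sum()),
        offset=offset,
        passed=score >= params.threshold,
        flipped=flipped,
        transform=sup,
    )


# ---------------------------------------------------------------------------
# Averaging


def average_structures(
    members: list[BackboneStructure],
    params: ScoreParams,
    structure_id: str = "average",
    provenance: Provenance = Provenance.INSTANCE_AVERAGE,
) -> BackboneStructure:
    """Mean backbone of a set of structures after mutual superposition.

    The longest member (ties: smallest structure_id) serves as the
    reference frame; every other member is aligned onto it with the
    built-in aligner and its coordinates transformed accordingly.  A
    reference position is emitted when at least ``coverage_min`` of the
    members contribute an aligned residue there; the output is the
    arithmetic mean of the contributing N, CA, C, O coordinates,
    renumbered 1..k.
    """
    if not members:
        raise ValueError("cannot average an empty structure list")
    if len(members) == 1:
        only = members[0]
        return BackboneStructure(
            structure_id, np.arange(1, len(only) + 1), only.coords.copy(), provenance
        )
    order = sorted(range(len(members)), key=lambda i: (-len(members[i]), members[i].structure_id))
    ref = members[order[0]]
    m = len(ref)
    sums = np.zeros((m, 4, 3))
    counts = np.zeros(m, dtype=int)
    sums += ref.coords
    counts += 1
    for i in order[1:]:
        member = members[i]
        res = align_to_reference(member, ref, params)
        q_idx, r_idx = res.pair_indices(len(member), m)
        transformed = res.transform.apply(member.coords.reshape(-1, 3)).reshape(
            member.coords.shape
        )
        sums[r_idx] += transformed[q_idx]
        counts[r_idx] += 1
    keep = counts / len(members) >= params.coverage_min - 1e-12
    if not keep.any():
        raise ValueError("no reference position reaches the coverage threshold")
    mean = sums[keep] / counts[keep, None, None]
    return BackboneStructure(structure_id, np.arange(1, keep.sum() + 1), mean, provenance)


def group_instances(
    items: list[tuple[StructuralInstance, BackboneStructure]],
) -> list[tuple[str, list[int]]]:
    """Group instances per UniProt domain.

    Instances sharing a UniProt accession are clustered by single
    linkage on span overlap >= 0.5, so the several crystal forms of one
    domain fall into one group; instances without an accession form
    singleton groups keyed by their instance key.  The group key is
    ``accession:min_start-max_end`` (minimal covering span); groups are
    returned with their item indices, in sorted key order.
    """
    by_acc: dict[str, list[int]] = {}
    singletons: list[int] = []
    for idx, (sti, _) in enumerate(items):
        if sti.uniprot_id is None:
            singletons.append(idx)
        else:
            by_acc.setdefault(sti.uniprot_id, []).append(idx)

    groups: list[tuple[str, list[int]]] = []
    for acc in sorted(by_acc):
        idxs = by_acc[acc]
        # single-linkage on span overlap
        parent = list(range(len(idxs)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                sa = items[idxs[a]][0].uniprot_span
                sb = items[idxs[b]][0].uniprot_span
                if region_overlap_fraction(sa, sb) >= 0.5:
                    parent[find(a)] = find(b)
        clusters: dict[int, list[int]] = {}
        for a in range(len(idxs)):
            clusters.setdefault(find(a), []).append(idxs[a])
        for members in clusters.values():
            spans = [items[i][0].uniprot_span for i in members]
            lo = min(s for s, _ in spans)
            hi = max(e for _, e in spans)
            groups.append((f"{acc}:{lo}-{hi}", members))
    for idx in singletons:
        groups.append((instance_key(items[idx][0]), [idx]))
    groups.sort(key=lambda g: g[0])
    return groups


def instance_level_averages(
    items: list[tuple[StructuralInstance, BackboneStructure]],
    params: ScoreParams,
) -> list[tuple[str, BackboneStructure]]:
    """One average per UniProt domain (see :func:`group_instances`)."""
    out: list[tuple[str, BackboneStructure]] = []
    for key, member_idxs in group_instances(items):
        avg = average_structures(
            [items[i][1] for i in member_idxs],
            params,
            structure_id=key,
            provenance=Provenance.INSTANCE_AVERAGE,
        )
        out.append((key, avg))
    return out


def family_level_average(
    instance_averages: list[BackboneStructure],
    params: ScoreParams,
    structure_id: str = "family_average",
) -> BackboneStructure:
    """Average of the UniProt-instance-level averages.

    Each UniProt domain enters with weight one regardless of how many
    PDB depositions it has, so heavily crystallized proteins do not
    dominate the family prototype.
    """
    return average_structures(
        instance_averages, params, structure_id=structure_id, provenance=Provenance.FAMILY_AVERAGE
    )


# ---------------------------------------------------------------------------
# External-aligner adapter


class ExternalAligner:
    """Adapter running an external structural-alignment program.

    The command template receives ``{query}`` and ``{reference}`` PDB
    paths and must print (or write to ``{out}``) a CSV with a header
    containing at least ``score`` and optionally ``rmsd`` and
    ``n_matched`` columns; the first data row is used.  This lets a
    gapped production aligner replace the built-in scan without
    changing the pipeline.
    """

    def __init__(self, command_template: str) -> None:
        self.command_template = command_template

    def align(self, query_pdb: str, ref_pdb: str, threshold: float = 0.6) -> AlignmentResult:
        import tempfile

        with tempfile.NamedTemporaryFile(suffix=".csv", delete=False) as tmp:
            out_path = tmp.name
        cmd = self.command_template.format(query=query_pdb, reference=ref_pdb, out=out_path)
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True, check=True
        )
        text = Path(out_path).read_text() if Path(out_path).stat().st_size else proc.stdout
        rows = list(csv.DictReader(text.splitlines()))
        if not rows:
            raise RuntimeError(f"external aligner produced no CSV rows: {cmd}")
        row = rows[0]
        score = float(row["score"])
        return AlignmentResult(
            query_id=Path(query_pdb).stem,
            reference_id=Path(ref_pdb).stem,
            score=score,
            rmsd=float(row.get("rmsd", 0.0) or 0.0),
            n_matched=int(float(row.get("n_matched", 0) or 0)),
            offset=0,
            passed=score >= threshold,
        )


def write_scores(results: list[AlignmentResult], path) -> None:
    """Append-style score table: one row per alignment performed."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["query_id", "reference_id", "score", "rmsd", "n_matched", "offset", "passed"]
        )
        for r in results:
            writer.writerow(
                [
                    r.query_id,
                    r.reference_id,
                    f"{r.score:.6f}",
                    f"{r.rmsd:.4f}",
                    r.n_matched,
                    r.offset,
                    "yes" if r.passed else "no",
                ]
            )
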