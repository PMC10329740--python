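"""Iterative classification driver.

One iteration runs: retrieve instances of the current families from
both tables → length filter → residue mapping → set comparison →
(first iteration only) core average computation → cross-mapping of the
uniques → family-level assessment of newly found families → instance
level assessment of the un-mapped remainder.  Families whose average
structure aligns to the core above the threshold are queued for the
next iteration together with their cross-mapped instances, which are
recognized as TRUE when the next comparison re-finds them as common.
The loop stops when an iteration accepts no new family.

Category semantics:

==============  ======================================================
CORE            common to both starting families (iteration 1); also
                counted among TRUE in all reporting
TRUE            common to both databases at any iteration, including
                cross-mapped instances whose new family passed
DOMAIN_LIKE     unique, not cross-mappable, instance-level average
                aligns to the core above threshold
FAILED          below threshold, at family level or instance level
OBSOLETE        PDB entry withdrawn; cannot be mapped
INCONSISTENT    SIFTS cannot map the span unambiguously
LENGTH_FILTERED shorter than the minimum domain length
==============  ======================================================
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional

import yaml

from .compare_crossmap import (
    CrossmapHit,
    TargetIndex,
    crossmap_instance,
    partition_instances,
)
from .core_model import (
    AlignmentResult,
    BackboneStructure,
    Category,
    CategoryLedger,
    FamilyEntry,
    FamilyStatus,
    IterationState,
    Provenance,
    RunConfig,
    SourceDB,
    StructuralInstance,
    instance_key,
)
from .db_io import (
    read_backbone,
    read_database_table,
    read_obsolete_list,
    read_sifts_table,
    serialize_unified,
    write_backbone,
)
from .residue_mapping import (
    MappingOutcome,
    MappingStatus,
    filter_by_length,
    map_instances,
    write_unmapped_report,
)
from .structure_math import (
    ScoreParams,
    align_to_reference,
    average_structures,
    family_level_average,
    group_instances,
    instance_level_averages,
    write_scores,
)

__all__ = [
    "ConfigurationError",
    "FamilyAssessment",
    "IterationSummary",
    "StructureLoader",
    "WorkflowRunner",
    "compute_core_average",
    "assess_crossmapped_families",
    "assess_unmapped",
    "run_workflow",
    "load_config",
]


class ConfigurationError(RuntimeError):
    """The run cannot start or continue with the given inputs."""


@dataclass
class FamilyAssessment:
    """Verdict on one cross-mapped family."""

    family_id: str
    side: SourceDB  # side of the database the family belongs to
    members: list[StructuralInstance]
    average: BackboneStructure
    alignment: AlignmentResult
    verdict: FamilyStatus


@dataclass
class IterationSummary:
    """Per-iteration accounting, one row of the run summary table."""

    iteration: int
    retrieved_pfam: int = 0
    retrieved_cath: int = 0
    length_filtered_pfam: int = 0
    length_filtered_cath: int = 0
    obsolete_pfam: int = 0
    obsolete_cath: int = 0
    inconsistent_pfam: int = 0
    inconsistent_cath: int = 0
    mapped_pfam: int = 0
    mapped_cath: int = 0
    common_pairs: int = 0
    unique_pfam: int = 0
    unique_cath: int = 0
    crossmapped: int = 0
    unmapped: int = 0
    families_assessed: int = 0
    families_accepted: int = 0
    families_failed: int = 0
    carried_forward: int = 0
    failed_family_members: int = 0
    domain_like: int = 0
    failed_instance: int = 0
    new_families: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Structure access


class StructureLoader:
    """Cached backbone extraction from per-entry PDB files."""

    def __init__(self, pdb_dir) -> None:
        self.pdb_dir = Path(pdb_dir)
        self._cache: dict[str, BackboneStructure] = {}

    def path_for(self, pdb_id: str) -> Path:
        for name in (f"{pdb_id.upper()}.pdb", f"{pdb_id.lower()}.pdb"):
            p = self.pdb_dir / name
            if p.exists():
                return p
        raise FileNotFoundError(f"no PDB file for entry {pdb_id} under {self.pdb_dir}")

    def load(self, sti: StructuralInstance) -> BackboneStructure:
        key = instance_key(sti)
        if key not in self._cache:
            start, end = sti.pdb_span
            self._cache[key] = read_backbone(
                self.path_for(sti.pdb_id), sti.chain_id, start, end, structure_id=key
            )
        return self._cache[key]


# ---------------------------------------------------------------------------
# Assessment primitives


def compute_core_average(
    core_members: list[tuple[StructuralInstance, BackboneStructure]],
    params: ScoreParams,
) -> tuple[BackboneStructure, list[tuple[str, BackboneStructure]]]:
    """Core prototype: average of UniProt-instance-level averages.

    Computed once, from the Pfam-side members of the iteration-1 common
    pairs, and frozen for the remainder of the run.  Returns the core
    structure and the instance-level averages it was built from.
    """
    if not core_members:
        raise ConfigurationError(
            "no common instance between the starting families: at least one shared "
            "PDB structure is required to compute the core average"
        )
    inst = instance_level_averages(core_members, params)
    core = family_level_average([s for _, s in inst], params, structure_id="core")
    core = BackboneStructure(
        "core", core.residue_numbers, core.coords, Provenance.CORE_AVERAGE
    )
    return core, inst


def assess_crossmapped_families(
    hits_by_family: dict[str, list[tuple[StructuralInstance, BackboneStructure]]],
    family_sides: dict[str, SourceDB],
    core: BackboneStructure,
    params: ScoreParams,
) -> list[FamilyAssessment]:
    """Family-level structural test of each newly found family.

    The family average (average of its members' UniProt-instance-level
    averages) is aligned against the core; at or above the threshold
    the family is ACCEPTED, otherwise FAILED together with all its
    cross-mapped member instances.
    """
    out: list[FamilyAssessment] = []
    for family_id in sorted(hits_by_family):
        members = hits_by_family[family_id]
        inst = instance_level_averages(members, params)
        avg = family_level_average(
            [s for _, s in inst], params, structure_id=f"family_{family_id}"
        )
        res = align_to_reference(avg, core, params)
        verdict = FamilyStatus.ACCEPTED if res.passed else FamilyStatus.FAILED
        out.append(
            FamilyAssessment(
                family_id=family_id,
                side=family_sides[family_id],
                members=[sti for sti, _ in members],
                average=avg,
                alignment=res,
                verdict=verdict,
            )
        )
    return out


def assess_unmapped(
    items: list[tuple[StructuralInstance, BackboneStructure]],
    core: BackboneStructure,
    params: ScoreParams,
) -> list[tuple[str, BackboneStructure, AlignmentResult, list[StructuralInstance]]]:
    """Instance-level structural test of the un-mapped instances.

    Instances are grouped per UniProt domain; each group average is
    aligned against the core once and the verdict applies to every
    member (DOMAIN_LIKE at or above threshold, FAILED below).
    """
    if not items:
        return []
    out = []
    for key, member_idxs in group_instances(items):
        avg = average_structures(
            [items[i][1] for i in member_idxs],
            params,
            structure_id=key,
            provenance=Provenance.INSTANCE_AVERAGE,
        )
        res = align_to_reference(avg, core, params)
        out.append((key, avg, res, [items[i][0] for i in member_idxs]))
    return out


# ---------------------------------------------------------------------------
# Workflow runner


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name)


class WorkflowRunner:
    """Load inputs, iterate to convergence, write all outputs."""

    def __init__(self, config: RunConfig, structure_loader: Optional[StructureLoader] = None):
        self.config = config
        self.params = ScoreParams(
            sigma=config.sigma,
            threshold=config.score_threshold,
            coverage_min=config.coverage_min,
        )
        self.loader = structure_loader or StructureLoader(config.pdb_dir)
        self.pfam_records = read_database_table(config.pfam_table, SourceDB.PFAM_SIDE)
        self.cath_records = read_database_table(config.cath_table, SourceDB.CATH_SIDE)
        self.sifts = read_sifts_table(config.sifts_table)
        self.obsolete = read_obsolete_list(config.obsolete_list)
        self.pfam_index = TargetIndex(self.pfam_records, SourceDB.PFAM_SIDE)
        self.cath_index = TargetIndex(self.cath_records, SourceDB.CATH_SIDE)

        self.state = IterationState(
            families_pfam_side=list(config.starting_families_pfam),
            families_cath_side=list(config.starting_families_cath),
            processed_families=set(config.starting_families_pfam)
            | set(config.starting_families_cath),
        )
        for fam in config.starting_families_pfam:
            self.state.ledger.add_family(
                FamilyEntry(fam, SourceDB.PFAM_SIDE, FamilyStatus.STARTING, iteration=1)
            )
        for fam in config.starting_families_cath:
            self.state.ledger.add_family(
                FamilyEntry(fam, SourceDB.CATH_SIDE, FamilyStatus.STARTING, iteration=1)
            )

        self.summaries: list[IterationSummary] = []
        self.score_log: list[AlignmentResult] = []
        self.nonmapped: list[MappingOutcome] = []
        self.crossmap_rows: list[tuple[int, CrossmapHit]] = []
        self.unmapped_rows: list[tuple[int, str]] = []
        self.mapped_by_key: dict[str, StructuralInstance] = {}
        self.pair_partner_keys: set[str] = set()  # CATH-side members of common pairs
        self.averages: dict[str, BackboneStructure] = {}
        self.converged = False
        self.log_lines: list[str] = []

    # -- helpers -----------------------------------------------------------

    def _log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def _retrieve(self, families: list[str], side: SourceDB) -> list[StructuralInstance]:
        records = self.pfam_records if side is SourceDB.PFAM_SIDE else self.cath_records
        wanted = set(families)
        out = []
        for sti in records:
            if sti.family_id not in wanted:
                continue
            if instance_key(sti) in self.state.ledger:
                self._log(
                    f"warning: {instance_key(sti)} already categorized; not re-parsed"
                )
                continue
            out.append(sti)
        return out

    def _filter_and_map(
        self, retrieved: list[StructuralInstance], summary: IterationSummary, side: SourceDB
    ) -> list[StructuralInstance]:
        it = summary.iteration
        kept, short = filter_by_length(retrieved, self.config.min_length)
        for sti in short:
            self.state.ledger.assign(
                instance_key(sti),
                Category.LENGTH_FILTERED,
                it,
                reason=f"native span shorter than {self.config.min_length} residues",
            )
            self.nonmapped.append(
                MappingOutcome(MappingStatus.LENGTH_FILTERED, sti, "below minimum length")
            )
        outcomes = map_instances(kept, self.sifts, self.obsolete)
        mapped: list[StructuralInstance] = []
        for out in outcomes:
            if out.status is MappingStatus.MAPPED:
                mapped.append(out.instance)
                self.mapped_by_key[instance_key(out.instance)] = out.instance
            else:
                self.state.ledger.assign(
                    instance_key(out.instance),
                    Category(out.status.value),
                    it,
                    reason=out.reason,
                )
                self.nonmapped.append(out)
        n_obs = sum(1 for o in outcomes if o.status is MappingStatus.OBSOLETE)
        n_inc = sum(1 for o in outcomes if o.status is MappingStatus.INCONSISTENT)
        if side is SourceDB.PFAM_SIDE:
            summary.length_filtered_pfam += len(short)
            summary.obsolete_pfam += n_obs
            summary.inconsistent_pfam += n_inc
        else:
            summary.length_filtered_cath += len(short)
            summary.obsolete_cath += n_obs
            summary.inconsistent_cath += n_inc
        return mapped

    # -- one iteration -----------------------------------------------------

    def run_iteration(self) -> IterationSummary:
        state = self.state
        it = state.iteration
        summary = IterationSummary(iteration=it)
        self._log(
            f"iteration {it}: families pfam={state.families_pfam_side} "
            f"cath={state.families_cath_side} carried={len(state.carried_instances)}"
        )

        retrieved_p = self._retrieve(state.families_pfam_side, SourceDB.PFAM_SIDE)
        retrieved_c = self._retrieve(state.families_cath_side, SourceDB.CATH_SIDE)
        carried_p = [s for s in state.carried_instances if s.source_db is SourceDB.PFAM_SIDE]
        carried_c = [s for s in state.carried_instances if s.source_db is SourceDB.CATH_SIDE]
        summary.retrieved_pfam = len(retrieved_p) + len(carried_p)
        summary.retrieved_cath = len(retrieved_c) + len(carried_c)

        mapped_p = self._filter_and_map(retrieved_p, summary, SourceDB.PFAM_SIDE) + carried_p
        mapped_c = self._filter_and_map(retrieved_c, summary, SourceDB.CATH_SIDE) + carried_c
        summary.mapped_pfam = len(mapped_p)
        summary.mapped_cath = len(mapped_c)

        comparison = partition_instances(mapped_p, mapped_c, self.config.tolerance)
        summary.common_pairs = len(comparison.common_pairs)
        summary.unique_pfam = len(comparison.unique_pfam)
        summary.unique_cath = len(comparison.unique_cath)

        common_category = Category.CORE if it == 1 else Category.TRUE
        for p, c in comparison.common_pairs:
            self.state.ledger.assign(
                instance_key(p), common_category, it, reason="common to both databases"
            )
            self.state.ledger.assign(
                instance_key(c), common_category, it, reason="common to both databases"
            )
            self.pair_partner_keys.add(instance_key(c))
        for s in state.carried_instances:
            k = instance_key(s)
            if k not in self.state.ledger:
                self._log(
                    f"warning: carried instance {k} not re-found as common; "
                    "it re-enters the unique path this iteration"
                )

        if it == 1:
            core_members = [(p, self.loader.load(p)) for p, _ in comparison.common_pairs]
            core, inst_avgs = compute_core_average(core_members, self.params)
            state.core_average = core
            self.averages["core"] = core
            for key, avg in inst_avgs:
                self.averages[f"instance_{_sanitize(key)}"] = avg
        core = state.core_average

        # cross-mapping of uniques
        novel_by_family: dict[str, list[tuple[StructuralInstance, BackboneStructure]]] = {}
        family_sides: dict[str, SourceDB] = {}
        unmapped_items: list[tuple[StructuralInstance, BackboneStructure]] = []
        for sti, target in (
            [(s, self.cath_index) for s in comparison.unique_pfam]
            + [(s, self.pfam_index) for s in comparison.unique_cath]
        ):
            hit = crossmap_instance(
                sti, target, self.config.tolerance, state.processed_families
            )
            if hit is not None:
                self.crossmap_rows.append((it, hit))
            if hit is not None and hit.novel:
                novel_by_family.setdefault(hit.target_family, []).append(
                    (sti, self.loader.load(sti))
                )
                family_sides[hit.target_family] = target.side
            else:
                # no hit, or a hit into an already-processed family: the
                # instance is judged individually at the instance level
                unmapped_items.append((sti, self.loader.load(sti)))
                self.unmapped_rows.append((it, instance_key(sti)))
        summary.crossmapped = sum(len(v) for v in novel_by_family.values())
        summary.unmapped = len(unmapped_items)

        # family-level assessment
        assessments = assess_crossmapped_families(
            novel_by_family, family_sides, core, self.params
        )
        carried_next: list[StructuralInstance] = []
        for a in assessments:
            self.score_log.append(a.alignment)
            self.averages[f"family_{_sanitize(a.family_id)}"] = a.average
            state.processed_families.add(a.family_id)
            self.state.ledger.add_family(
                FamilyEntry(a.family_id, a.side, a.verdict, a.alignment.score, it)
            )
            if a.verdict is FamilyStatus.ACCEPTED:
                summary.families_accepted += 1
                summary.new_families.append(a.family_id)
                carried_next.extend(a.members)
                self._log(
                    f"iteration {it}: family {a.family_id} ACCEPTED "
                    f"(score {a.alignment.score:.3f}, {len(a.members)} instances carried)"
                )
            else:
                summary.families_failed += 1
                summary.failed_family_members += len(a.members)
                for sti in a.members:
                    self.state.ledger.assign(
                        instance_key(sti),
                        Category.FAILED,
                        it,
                        score=a.alignment.score,
                        reason=f"cross-mapped family {a.family_id} below threshold",
                    )
                self._log(
                    f"iteration {it}: family {a.family_id} FAILED "
                    f"(score {a.alignment.score:.3f})"
                )
        summary.families_assessed = len(assessments)
        summary.carried_forward = len(carried_next)

        # instance-level assessment of the un-mapped remainder
        for key, avg, res, members in assess_unmapped(unmapped_items, core, self.params):
            self.score_log.append(res)
            self.averages[f"instance_{_sanitize(key)}"] = avg
            category = Category.DOMAIN_LIKE if res.passed else Category.FAILED
            for sti in members:
                self.state.ledger.assign(
                    instance_key(sti),
                    category,
                    it,
                    score=res.score,
                    reason=f"instance-level group {key}",
                )
            if res.passed:
                summary.domain_like += len(members)
            else:
                summary.failed_instance += len(members)

        # queue next iteration: only the newly accepted families run again
        state.families_pfam_side = sorted(
            f for f in summary.new_families if family_sides[f] is SourceDB.PFAM_SIDE
        )
        state.families_cath_side = sorted(
            f for f in summary.new_families if family_sides[f] is SourceDB.CATH_SIDE
        )
        state.carried_instances = carried_next
        return summary

    # -- full run ----------------------------------------------------------

    def run(self) -> CategoryLedger:
        cfg = self.config
        self._log(f"seed={cfg.seed}")
        self._log(f"config: {json.dumps(asdict(cfg), sort_keys=True)}")
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        while True:
            summary = self.run_iteration()
            self.summaries.append(summary)
            self._write_params_file(out_dir)
            if not summary.new_families:
                self.converged = True
                break
            if self.state.iteration >= cfg.max_iterations:
                self._log(
                    f"warning: NOT_CONVERGED after {cfg.max_iterations} iterations"
                )
                for sti in self.state.carried_instances:
                    self.state.ledger.assign(
                        instance_key(sti),
                        Category.TRUE,
                        self.state.iteration,
                        reason="cross-mapped to an accepted family; run stopped at "
                        "max_iterations before re-comparison",
                    )
                break
            self.state.iteration += 1
        self._write_outputs(out_dir)
        return self.state.ledger

    # -- reporting ---------------------------------------------------------

    def category_counts(self) -> dict[str, int]:
        """Counts per category, counting each common pair once.

        A common domain instance is represented by two table rows (one
        per database); reporting counts it once.  CORE instances are
        also included in the TRUE total.
        """
        counts = {c.value: 0 for c in Category}
        for key, entry in self.state.ledger.entries.items():
            if key in self.pair_partner_keys:
                continue
            counts[entry.category.value] += 1
        counts["TRUE"] += counts["CORE"]
        return counts

    def _write_params_file(self, out_dir: Path) -> None:
        state = self.state
        payload = {
            "iteration_completed": state.iteration,
            "next_families": {
                "pfam": state.families_pfam_side,
                "cath": state.families_cath_side,
            },
            "carried_instances": [instance_key(s) for s in state.carried_instances],
            "core_average": "averages/core.pdb" if state.core_average is not None else None,
            "tolerance": self.config.tolerance,
            "score_threshold": self.config.score_threshold,
            "min_length": self.config.min_length,
            "sigma": self.config.sigma,
        }
        with open(out_dir / f"params_iter{state.iteration}.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def _write_category_csv(self, path: Path, categories: set[Category]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["instance_key", "unified", "iteration", "score", "reason"])
            for key in sorted(self.state.ledger.entries):
                entry = self.state.ledger.entries[key]
                if entry.category not in categories:
                    continue
                sti = self.mapped_by_key.get(key)
                unified = serialize_unified(sti) if sti is not None and sti.is_mapped else ""
                score = "" if entry.score is None else f"{entry.score:.6f}"
                writer.writerow([key, unified, entry.iteration, score, entry.reason])

    def _write_outputs(self, out_dir: Path) -> None:
        self._write_category_csv(out_dir / "core.csv", {Category.CORE})
        # CORE is a subset of TRUE: true.csv carries both
        self._write_category_csv(out_dir / "true.csv", {Category.CORE, Category.TRUE})
        self._write_category_csv(out_dir / "domain_like.csv", {Category.DOMAIN_LIKE})
        self._write_category_csv(out_dir / "failed.csv", {Category.FAILED})
        write_unmapped_report(self.nonmapped, out_dir / "obsolete_inconsistent.csv")

        with open(out_dir / "failed_families.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["family_id", "side", "score", "iteration"])
            for fam in self.state.ledger.families:
                if fam.status is FamilyStatus.FAILED:
                    score = "" if fam.score is None else f"{fam.score:.6f}"
                    writer.writerow([fam.family_id, fam.side.value, score, fam.iteration])

        with open(out_dir / "crossmapped.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["iteration", "source_key", "target_family", "distance", "novel"])
            for it, hit in self.crossmap_rows:
                writer.writerow(
                    [
                        it,
                        instance_key(hit.source),
                        hit.target_family,
                        hit.distance,
                        "yes" if hit.novel else "no",
                    ]
                )

        with open(out_dir / "unmapped.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["iteration", "instance_key"])
            for it, key in self.unmapped_rows:
                writer.writerow([it, key])

        write_scores(self.score_log, out_dir / "scores.csv")

        avg_dir = out_dir / "averages"
        avg_dir.mkdir(exist_ok=True)
        for name, structure in sorted(self.averages.items()):
            write_backbone(structure, avg_dir / f"{name}.pdb")

        summary = {
            "seed": self.config.seed,
            "converged": self.converged,
            "n_iterations": self.state.iteration,
            "iterations": [asdict(s) for s in self.summaries],
            "totals": self.category_counts(),
            "ledger_entries": len(self.state.ledger),
            "config": asdict(self.config),
        }
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

        (out_dir / "run.log").write_text("\n".join(self.log_lines) + "\n", encoding="utf-8")


def run_workflow(config: RunConfig) -> WorkflowRunner:
    """Run the full loop; returns the runner with ledger and summaries."""
    runner = WorkflowRunner(config)
    runner.run()
    return runner


# ---------------------------------------------------------------------------
# Config file


def load_config(path) -> RunConfig:
    """Load a YAML run configuration.

    Relative input/output paths are resolved against the directory
    containing the config file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def resolve(p: Optional[str]) -> str:
        if not p:
            return ""
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    inputs = raw.get("inputs", {})
    fams = raw.get("starting_families", {})
    return RunConfig(
        pfam_table=resolve(inputs.get("pfam_table")),
        cath_table=resolve(inputs.get("cath_table")),
        sifts_table=resolve(inputs.get("sifts_table")),
        obsolete_list=resolve(inputs.get("obsolete_list")),
        pdb_dir=resolve(inputs.get("pdb_dir")),
        out_dir=resolve(raw.get("output_dir", "domcross_out")),
        starting_families_pfam=list(fams.get("pfam", [])),
        starting_families_cath=list(fams.get("cath", [])),
        tolerance=int(raw.get("tolerance", 30)),
        score_threshold=float(raw.get("score_threshold", 0.6)),
        min_length=int(raw.get("min_length", 30)),
        sigma=float(raw.get("sigma", 2.0)),
        coverage_min=float(raw.get("coverage_min", 0.5)),
        max_iterations=int(raw.get("max_iterations", 10)),
        seed=int(raw.get("seed", 0)),
    )
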