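"""Synthetic input bundles with planted per-instance ground truth.

A bundle contains everything a run consumes — the two database tables,
a SIFTS-style segment table, an obsolete-ID list, per-entry PDB files
and a ready-to-run config — plus ``truth.csv`` giving the category
every planted instance must end up in.  Two fold templates are used:

* CORE_FOLD, an ideal α-helical backbone (1.5 Å rise, 100°/residue):
  every instance of the domain type;
* DECOY_FOLD, an extended strand (3.5 Å/residue): structures that must
  fail the alignment against the core.

These are geometric stand-ins, not realistic protein folds; what
matters for the pipeline is only that same-template pairs score above
the threshold and cross-template pairs below it, which the generator
verifies by actually scoring generated pairs before writing anything.

The planted classes and what they exercise:

=================  ====================================================
n_core             shared between the two starting families; become
                   CORE at iteration 1 and feed the core average
n_crossmap_true    unique to the CATH side, with a matching record in
                   one NEW Pfam-side family; the family is accepted at
                   iteration 1 and its instances become TRUE at
                   iteration 2 (the run converges in exactly 2)
n_domain_like      unique, no record in the other database, core fold
n_failed_fold      decoy folds: alternating un-mapped instances and
                   members of a decoy cross-mapped family
n_obsolete         listed in the obsolete-PDB file
n_inconsistent     chain split between two UniProt accessions in SIFTS
n_short            below the minimum domain length
=================  ====================================================
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_model import BackboneStructure, Category, Provenance, RunConfig
from .db_io import write_backbone
from .structure_math import ScoreParams, align_to_reference

__all__ = [
    "GenerationError",
    "ScenarioSpec",
    "SCENARIOS",
    "make_fold",
    "generate_scenario",
]

PFAM_START_FAMILY = "PF00076"
CATH_START_FAMILY = "3.30.70.330"
PFAM_NEW_FAMILY = "PF90001"
PFAM_DECOY_FAMILY = "PF90900"

CORE_FOLD = "CORE_FOLD"
DECOY_FOLD = "DECOY_FOLD"


class GenerationError(RuntimeError):
    """The requested scenario violates its own separation invariants."""


@dataclass
class ScenarioSpec:
    """Planted composition of one synthetic bundle."""

    n_core: int = 6
    n_crossmap_true: int = 4
    n_domain_like: int = 3
    n_failed_fold: int = 2
    n_obsolete: int = 2
    n_inconsistent: int = 1
    n_short: int = 3
    domain_length: int = 90
    noise: float = 0.3  # Å, per-coordinate Gaussian
    tolerance: int = 30
    score_threshold: float = 0.6
    min_length: int = 30
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_core",
            "n_crossmap_true",
            "n_domain_like",
            "n_failed_fold",
            "n_obsolete",
            "n_inconsistent",
            "n_short",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


#: Named presets for the CLI and the acceptance checks.
SCENARIOS: dict[str, dict] = {
    "core_only": dict(
        n_core=6, n_crossmap_true=0, n_domain_like=0, n_failed_fold=0,
        n_obsolete=0, n_inconsistent=0, n_short=0,
    ),
    "four_category": dict(
        n_core=6, n_crossmap_true=4, n_domain_like=3, n_failed_fold=2,
        n_obsolete=2, n_inconsistent=1, n_short=3,
    ),
    "bookkeeping": dict(
        n_core=4, n_crossmap_true=0, n_domain_like=0, n_failed_fold=0,
        n_obsolete=2, n_inconsistent=1, n_short=3,
    ),
}


# ---------------------------------------------------------------------------
# Fold templates


def make_fold(
    template: str, n_residues: int, noise: float, seed: int, structure_id: str = "fold"
) -> BackboneStructure:
    """Deterministic synthetic backbone of one of the two templates.

    CORE_FOLD is an ideal α-helix CA trace (radius 2.3 Å, rise 1.5 Å,
    100° per residue); DECOY_FOLD is a straight extended chain at
    3.5 Å per residue.  N and C are placed by interpolation along the
    trace and O offset from C, giving a chain-following (not
    physically exact) backbone.  Gaussian noise of the given amplitude
    is added to every coordinate.
    """
    if n_residues < 4:
        raise ValueError("a fold needs at least 4 residues")
    i = np.arange(n_residues)
    if template == CORE_FOLD:
        theta = np.deg2rad(100.0) * i
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
    elif template == DECOY_FOLD:
        ca = np.stack([3.5 * i, np.zeros(n_residues), np.zeros(n_residues)], axis=1)
    else:
        raise ValueError(f"unknown fold template {template!r}")
    prev = np.vstack([ca[0] - (ca[1] - ca[0]), ca[:-1]])
    nxt = np.vstack([ca[1:], ca[-1] + (ca[-1] - ca[-2])])
    n_atom = ca + 0.38 * (prev - ca)
    c_atom = ca + 0.40 * (nxt - ca)
    o_atom = c_atom + np.array([0.0, 0.0, 1.23])
    coords = np.stack([n_atom, ca, c_atom, o_atom], axis=1)
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(0.0, noise, coords.shape) if noise > 0 else coords
    return BackboneStructure(structure_id, i + 1, coords, Provenance.EXPERIMENTAL)


# ---------------------------------------------------------------------------
# Scenario generation


@dataclass
class _Planted:
    pdb_id: str
    accession: str
    pfam_row: tuple | None  # interchange fields minus the side tag
    cath_row: tuple | None
    fold: str | None  # template, None when no structure file is needed
    fold_seed: int = 0
    truth: list[tuple[str, str]] = field(default_factory=list)  # (key, category)
    split_sifts: bool = False
    obsolete: bool = False
    structure_len: int = 0


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def generate_scenario(spec: ScenarioSpec, out_dir) -> dict:
    """Write a complete input bundle; returns paths and planted truth.

    Regenerating with the same spec yields byte-identical files.  The
    generator fails fast — writing nothing — if the fold templates do
    not separate at the configured threshold, or if the boundary jitter
    could make a planted common pair ambiguous.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    params = ScoreParams(sigma=spec.sigma, threshold=spec.score_threshold)

    # -- self-check: fold separation under the configured noise ------------
    probe_a = make_fold(CORE_FOLD, spec.domain_length, spec.noise, _derive_seed(spec.seed, 9001), "probe_a")
    probe_b = make_fold(CORE_FOLD, spec.domain_length, spec.noise, _derive_seed(spec.seed, 9002), "probe_b")
    probe_d = make_fold(DECOY_FOLD, spec.domain_length, spec.noise, _derive_seed(spec.seed, 9003), "probe_d")
    same = align_to_reference(probe_a, probe_b, params).score
    cross = align_to_reference(probe_d, probe_a, params).score
    if same < spec.score_threshold:
        raise GenerationError(
            f"same-fold score {same:.3f} below threshold {spec.score_threshold}: "
            "noise too large for a usable scenario"
        )
    if cross >= spec.score_threshold:
        raise GenerationError(
            f"decoy-fold score {cross:.3f} not below threshold {spec.score_threshold}"
        )

    jitter_max = spec.tolerance // 2

    def jitter() -> int:
        return int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max > 0 else 0

    planted: list[_Planted] = []
    counter = 0

    def next_ids() -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"{counter:04d}", f"P{counter:05d}"

    # keep jittered boundaries >= 1 so they stay inside the SIFTS segment
    dom_start = jitter_max + 10
    dom_end = dom_start + spec.domain_length - 1
    chain = "A"

    def key(pdb, side, family, s, e):
        return f"{pdb}|{chain}|{side}|{family}|{s}|{e}"

    # core: one record in each starting family, boundaries within tolerance
    for _ in range(spec.n_core):
        pdb, acc = next_ids()
        cs, ce = dom_start + jitter(), dom_end + jitter()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=(pdb, chain, "RRM_1", PFAM_START_FAMILY, dom_start, dom_end, acc),
            cath_row=(pdb, chain, "01", CATH_START_FAMILY, cs, ce, "-"),
            fold=CORE_FOLD,
            fold_seed=_derive_seed(spec.seed, counter),
            structure_len=max(dom_end, ce) + 10,
        )
        p.truth = [
            (key(pdb, "PFAM_SIDE", PFAM_START_FAMILY, dom_start, dom_end), Category.CORE.value),
            (key(pdb, "CATH_SIDE", CATH_START_FAMILY, cs, ce), Category.CORE.value),
        ]
        planted.append(p)

    # crossmap-true: CATH record in the starting family, Pfam record in a
    # NEW family; both become TRUE (the Pfam twin is parsed at iteration 2)
    for _ in range(spec.n_crossmap_true):
        pdb, acc = next_ids()
        cs, ce = dom_start + jitter(), dom_end + jitter()
        ps, pe = dom_start + jitter(), dom_end + jitter()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=(pdb, chain, "RRM_new", PFAM_NEW_FAMILY, ps, pe, acc),
            cath_row=(pdb, chain, "01", CATH_START_FAMILY, cs, ce, "-"),
            fold=CORE_FOLD,
            fold_seed=_derive_seed(spec.seed, counter),
            structure_len=max(ce, pe) + 10,
        )
        p.truth = [
            (key(pdb, "CATH_SIDE", CATH_START_FAMILY, cs, ce), Category.TRUE.value),
            (key(pdb, "PFAM_SIDE", PFAM_NEW_FAMILY, ps, pe), Category.TRUE.value),
        ]
        planted.append(p)

    # domain-like: unique on alternating sides, no record in the other DB
    for i in range(spec.n_domain_like):
        pdb, acc = next_ids()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=None,
            cath_row=None,
            fold=CORE_FOLD,
            fold_seed=_derive_seed(spec.seed, counter),
            structure_len=dom_end + 10,
        )
        if i % 2 == 0:
            p.pfam_row = (pdb, chain, "RRM_1", PFAM_START_FAMILY, dom_start, dom_end, acc)
            p.truth = [
                (key(pdb, "PFAM_SIDE", PFAM_START_FAMILY, dom_start, dom_end),
                 Category.DOMAIN_LIKE.value)
            ]
        else:
            p.cath_row = (pdb, chain, "01", CATH_START_FAMILY, dom_start, dom_end, "-")
            p.truth = [
                (key(pdb, "CATH_SIDE", CATH_START_FAMILY, dom_start, dom_end),
                 Category.DOMAIN_LIKE.value)
            ]
        planted.append(p)

    # failed folds: even index -> un-mapped Pfam-side decoy (fails at the
    # instance level); odd index -> CATH-side decoy cross-mapped to a decoy
    # Pfam family (the whole family fails at the family level)
    for i in range(spec.n_failed_fold):
        pdb, acc = next_ids()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=None,
            cath_row=None,
            fold=DECOY_FOLD,
            fold_seed=_derive_seed(spec.seed, counter),
            structure_len=dom_end + 10,
        )
        if i % 2 == 0:
            p.pfam_row = (pdb, chain, "RRM_1", PFAM_START_FAMILY, dom_start, dom_end, acc)
            p.truth = [
                (key(pdb, "PFAM_SIDE", PFAM_START_FAMILY, dom_start, dom_end),
                 Category.FAILED.value)
            ]
        else:
            ps, pe = dom_start + jitter(), dom_end + jitter()
            p.cath_row = (pdb, chain, "01", CATH_START_FAMILY, dom_start, dom_end, "-")
            p.pfam_row = (pdb, chain, "decoy", PFAM_DECOY_FAMILY, ps, pe, acc)
            # only the CATH instance is parsed: the decoy family fails at
            # iteration 1, so its Pfam rows are never retrieved
            p.truth = [
                (key(pdb, "CATH_SIDE", CATH_START_FAMILY, dom_start, dom_end),
                 Category.FAILED.value)
            ]
        planted.append(p)

    # obsolete entries (CATH side; no structure file needed)
    for _ in range(spec.n_obsolete):
        pdb, acc = next_ids()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=None,
            cath_row=(pdb, chain, "01", CATH_START_FAMILY, dom_start, dom_end, "-"),
            fold=None,
            obsolete=True,
        )
        p.truth = [
            (key(pdb, "CATH_SIDE", CATH_START_FAMILY, dom_start, dom_end),
             Category.OBSOLETE.value)
        ]
        planted.append(p)

    # inconsistent: chain split between two accessions in SIFTS
    for _ in range(spec.n_inconsistent):
        pdb, acc = next_ids()
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=None,
            cath_row=(pdb, chain, "01", CATH_START_FAMILY, dom_start, dom_end, "-"),
            fold=None,
            split_sifts=True,
        )
        p.truth = [
            (key(pdb, "CATH_SIDE", CATH_START_FAMILY, dom_start, dom_end),
             Category.INCONSISTENT.value)
        ]
        planted.append(p)

    # short instances (Pfam side), removed by the length filter
    short_len = max(4, spec.min_length - 20)
    if short_len >= spec.min_length:
        raise GenerationError("min_length too small to plant short instances")
    for _ in range(spec.n_short):
        pdb, acc = next_ids()
        s, e = 20, 20 + short_len - 1
        p = _Planted(
            pdb_id=pdb,
            accession=acc,
            pfam_row=(pdb, chain, "RRM_1", PFAM_START_FAMILY, s, e, acc),
            cath_row=None,
            fold=None,
        )
        p.truth = [
            (key(pdb, "PFAM_SIDE", PFAM_START_FAMILY, s, e), Category.LENGTH_FILTERED.value)
        ]
        planted.append(p)

    # -- write the bundle ---------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(exist_ok=True)

    header = "#side\tpdb\tchain\tlabel\tfamily\tstart\tend\tuniprot"
    pfam_lines = [header]
    cath_lines = [header]
    sifts_lines = ["PDB\tCHAIN\tSP_PRIMARY\tSP_BEG\tSP_END\tPDB_BEG\tPDB_END"]
    obsolete_lines = ["# obsolete PDB entries"]
    truth_rows: list[tuple[str, str]] = []

    seg_len = 400  # identity segment, comfortably covering every span
    for p in planted:
        if p.pfam_row:
            pfam_lines.append("PFAM\t" + "\t".join(str(x) for x in p.pfam_row))
        if p.cath_row:
            cath_lines.append("CATH\t" + "\t".join(str(x) for x in p.cath_row))
        if p.split_sifts:
            half = dom_start + spec.domain_length // 2
            sifts_lines.append(
                f"{p.pdb_id}\t{chain}\tQ{p.accession[1:]}A\t1\t{half}\t1\t{half}"
            )
            sifts_lines.append(
                f"{p.pdb_id}\t{chain}\tQ{p.accession[1:]}B\t{half + 1}\t{seg_len}\t{half + 1}\t{seg_len}"
            )
        else:
            sifts_lines.append(
                f"{p.pdb_id}\t{chain}\t{p.accession}\t1\t{seg_len}\t1\t{seg_len}"
            )
        if p.obsolete:
            obsolete_lines.append(p.pdb_id)
        if p.fold is not None:
            fold = make_fold(
                p.fold, p.structure_len, spec.noise, p.fold_seed, structure_id=p.pdb_id
            )
            write_backbone(fold, pdb_dir / f"{p.pdb_id}.pdb", chain_id=chain)
        truth_rows.extend(p.truth)

    paths = {
        "pfam_table": out_dir / "pfam_table.tsv",
        "cath_table": out_dir / "cath_table.tsv",
        "sifts_table": out_dir / "sifts.tsv",
        "obsolete_list": out_dir / "obsolete.txt",
        "pdb_dir": pdb_dir,
        "truth": out_dir / "truth.csv",
        "config": out_dir / "config.yaml",
    }
    paths["pfam_table"].write_text("\n".join(pfam_lines) + "\n", encoding="utf-8")
    paths["cath_table"].write_text("\n".join(cath_lines) + "\n", encoding="utf-8")
    paths["sifts_table"].write_text("\n".join(sifts_lines) + "\n", encoding="utf-8")
    paths["obsolete_list"].write_text("\n".join(obsolete_lines) + "\n", encoding="utf-8")

    with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["instance_key", "category"])
        for row in sorted(truth_rows):
            writer.writerow(row)

    config = {
        "starting_families": {"pfam": [PFAM_START_FAMILY], "cath": [CATH_START_FAMILY]},
        "inputs": {
            "pfam_table": "pfam_table.tsv",
            "cath_table": "cath_table.tsv",
            "sifts_table": "sifts.tsv",
            "obsolete_list": "obsolete.txt",
            "pdb_dir": "pdb",
        },
        "output_dir": "out",
        "tolerance": spec.tolerance,
        "score_threshold": spec.score_threshold,
        "min_length": spec.min_length,
        "sigma": spec.sigma,
        "max_iterations": 10,
        "seed": spec.seed,
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "truth": dict(truth_rows),
        "spec": spec,
    }


def run_config_for_bundle(bundle_dir, out_dir=None) -> RunConfig:
    """RunConfig pointing at a generated bundle."""
    from .classify_iterate import load_config

    config = load_config(Path(bundle_dir) / "config.yaml")
    if out_dir is not None:
        config.out_dir = str(out_dir)
    return config
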