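# Methods

## Model and procedure

`domcross` treats a protein *domain type* as an equivalence class of
domain families across two databases: a sequence-profile resource
("Pfam side", boundaries in UniProt numbering) and a structural-domain
resource ("CATH side", boundaries in PDB author numbering). The unit
of work is the structural instance (StI): one domain region on one PDB
chain. The procedure is iterative:

1. retrieve all StIs of the current families from both tables;
2. drop StIs shorter than `min_length`; residue-map the rest through
   SIFTS-style segments so both numbering systems are populated;
3. partition the two sets into common pairs and uniques (boundary
   agreement within `tolerance` in UniProt numbering, same chain, same
   accession when both known);
4. at iteration 1, the common set is the Core and yields the frozen
   *core average structure*;
5. cross-map each unique StI into the full other database (same chain,
   same tolerance, boundaries in the target's native numbering);
6. family-average the StIs of each newly found family and align it to
   the core: pass ⇒ the family seeds the next iteration and its StIs
   are carried forward (recognized as True when re-found as common);
   fail ⇒ family and members are Failed;
7. instance-average the remaining un-mapped StIs per UniProt domain
   and align each group to the core: pass ⇒ Domain-like, fail ⇒ Failed;
8. repeat until an iteration accepts no new family.

Assumptions worth making explicit: domains are contiguous on both
numbering scales (discontinuous domains are out of scope and PDB
insertion codes are not modeled — records needing them are routed to
`INCONSISTENT`); one StI is judged once (un-mapped StIs are not
re-tested in later iterations); and the core prototype depends on the
starting families, which is inherent to the method, not an artifact.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `tolerance` | 30 | residues | max per-boundary difference for two records to be the same instance; also used for cross-mapping |
| `score_threshold` | 0.6 | — | minimum alignment score against the core |
| `min_length` | 30 | residues | length filter before mapping; the filter is part of the method, the value is this package's choice (≈ one third of a canonical ~90-residue domain) |
| `sigma` | 2.0 | Å | Gaussian width of the similarity score; ~1 CA-CA bond of slack per position |
| `coverage_min` | 0.5 | fraction | members that must contribute for an averaged position to be emitted |
| `max_iterations` | 10 | — | safety net; the loop also terminates structurally because processed families are never re-entered |

## The built-in aligner and its score

Production pipelines of this kind delegate structural alignment to a
dedicated program whose Gaussian-based quality measure ("M-score")
avoids the outlier sensitivity of plain RMSD. This package ships a
self-contained surrogate instead of wrapping an external binary: a
gapless offset scan of the query CA trace along the reference, each
offset superposed by Kabsch (SVD with reflection correction),
iteratively re-fitted on pairs within `2σ` (max 5 rounds), and scored

    score = (1/N_ref) · Σ_i exp(−d_i² / 2σ²)

over *all* paired CA distances, normalized by the reference length, so
truncated matches score in proportion to coverage and a perfect
full-length match scores exactly 1. Ties between offsets go to the
smaller offset; everything is deterministic.

Two consequences to keep in mind. First, the 0.6 threshold is retained
as the default but was validated against *this* score on synthetic
fold-separation tests; transferability of thresholds between this
surrogate and any external aligner's score is not established, so runs
with the `ExternalAligner` adapter should re-examine the threshold.
Second, the scan is gapless: it is adequate for single-domain regions
of comparable length (what the pipeline feeds it) but will under-score
genuinely gapped correspondences; the adapter exists for that case.

Alignment correspondence uses CA atoms only; the resulting rigid
transform is applied to all four backbone atoms. Averaged structures
are alignment prototypes, not physical models — locally averaged bond
geometry may be distorted.

## Averaging

Averages are computed at three levels. *UniProt-instance level*: StIs
of the same accession are clustered by single linkage on span overlap
≥ 0.5 and averaged, collapsing redundant depositions of one domain.
*Family level*: the instance-level averages are averaged again
("average of averages"), so a domain with thirty crystal forms weighs
the same as one with a single structure. *Core*: the family-level
construction applied to the Pfam-side members of the iteration-1
common pairs, frozen thereafter. The reference frame is the longest
member (ties: smallest id); positions kept must be covered by at least
`coverage_min` of the members; output residues are renumbered 1..k.

## Residue mapping rules

A span maps only if it falls entirely within one usable SIFTS segment
of one UniProt accession; the mapping is the segment's affine offset.
Spans crossing segments — even two segments of the same accession with
consistent offsets — are conservatively `INCONSISTENT`, as are spans
touching two accessions (the classic split-chain curation case),
chains absent from SIFTS, and records whose stated accession disagrees
with the covering segment. Obsolete PDB entries are caught first. All
failures are statuses, not exceptions, and are written to
`obsolete_inconsistent.csv` for curators.

A cross-map hit into a family processed in an earlier iteration (the
starting families included) is recorded (`novel=no` in
`crossmapped.csv`) but does not re-trigger the family; the StI is
judged at the instance level like an un-mapped one. This keeps the
iteration terminating and matches how remaining instances are
accounted in the method's published run shape.

## Synthetic data: what it emulates and what it does not

The generator plants a complete study in miniature: two database
tables, identity SIFTS segments (plus deliberately split chains for
the inconsistent class), an obsolete list, and per-entry PDB files.
Two geometric templates stand in for folds — an ideal α-helical
backbone (core) and an extended strand (decoy) — with per-instance
Gaussian coordinate noise (default 0.3 Å) and uniform boundary jitter
within ±tolerance/2 so planted pairs stay unambiguous. Generation
fails fast (writing nothing) unless freshly scored probes confirm that
same-template pairs pass and cross-template pairs fail the configured
threshold, which keeps the planted truth valid under future changes to
the scoring.

What passing on these bundles shows: the bookkeeping, mapping
arithmetic, set logic, iteration control and score thresholds behave
exactly as specified. What it does not show: performance on real
folds — no β-sheet topology, no gapped correspondences, no insertion
codes, no partial SIFTS coverage, no inter-domain ambiguity. Scale is
also modest by design: default scenarios carry ~20 entries of ~90
residues, so the whole test suite and the acceptance script run in
seconds; results on database-scale inputs are a matter of runtime, not
of different code paths.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 non-collinear pairs (second singular value
  > 1e-9 relative); reflections are corrected by the determinant sign.
- Refinement keeps the previous fit when fewer than 3 pairs survive
  the cutoff; score ties between offsets resolve to the smaller offset;
  greedy common-pair matching resolves ties by instance key; cross-map
  ties by family id — every tie-break is total, hence runs are
  bit-reproducible (asserted by test and acceptance script).
- `region_overlap_fraction` normalizes by the shorter span; 1-based
  inclusive coordinates everywhere, so `length = end − start + 1`.
- A single-member average is the member itself; an empty member list
  is an error; a zero-residue backbone is unconstructible.
- At forced termination (`max_iterations` with families still queued)
  carried instances are labeled True with an explanatory reason rather
  than left out of the ledger; natural convergence never hits this.

## Known limitations

Gapless alignment only (see above); no discontinuous domains; no
insertion codes; segment-splice mapping deliberately refused; the
published database-scale counts of the method this package
reimplements require full Pfam/CATH/PDB/SIFTS snapshots and are out of
scope here — the acceptance surface is the planted-truth recovery and
the numerical identities, not those counts.
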