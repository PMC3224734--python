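# Methods

## The annotation-transfer model

`cypmod` treats annotation transfer as alignment to a profile hidden Markov
model compiled from a structure-anchored seed alignment. The seed is a
multiple alignment of CYP sequences whose rows correspond to crystal
structures; a JSON sidecar carries everything the structural analysis
contributed and the model itself never re-derives: the column spans of the
19 structurally conserved regions (SCRs), the anchor columns (the
F87-equivalent hotspot, the ExxR glutamate/arginine, the heme cysteine),
the column pairs flanking the two reductase interaction sites, and a redox
class label per row. One row is the reference (CYP102A1/1BU7 in the real
seed) and defines the coordinate system; SCR boundaries are data, not code,
so any re-derived or corrected seed can be dropped in without touching the
implementation.

### Profile architecture and estimation

Standard match/insert/delete columns, with two deliberate choices:

* **Match-state rule.** A column becomes a match state when its non-gap
  fraction is at least the occupancy threshold (default 0.5, the classic
  profile convention). Anchor columns and SCR boundary columns are forced
  to match states regardless of occupancy — every annotation that must be
  transferred therefore lives on the match-state backbone, and no SCR can
  end up without match states.
* **Glocal alignment.** The model is always traversed begin→end (the
  delete chain absorbs missing ends), while query residues outside the
  model are free flanks at background odds. CYP queries are full-length
  proteins with variable termini; for fusion proteins such as P450 BM-3 the
  entire reductase domain lands in the C-flank.

Emissions use a single-parameter background-weighted pseudocount,
`e_k(a) = (n_k(a) + α·q(a)) / (n_k + α)`; transitions are estimated from
the observed state paths of the seed rows with the same scheme (prior
uniform over each state's outgoing edges). Defaults: α = 1 and a uniform
background, both overridable — the smallest defensible scheme for a
31-row seed. No sequence weighting is applied by default (the seed is small
and hand-curated). The state graph has no I↔D edges; seed insert runs
bordering a deletion are attributed to the direct transition during
counting. `X` is scored at background odds (0 bits) and excluded from
counts; B/Z/J/U/O are rejected at input so emission math stays
well-defined.

All scoring is log-space, in bits. Viterbi tie-breaking is fixed
(Match > Delete > Insert at every cell, match end preferred over delete
end), making outputs bit-reproducible. Viterbi and forward are validated
against an independent brute-force path enumerator on a thousand random
model/query instances per test run (relative tolerance 1e-9). Queries
shorter than 50 residues are refused as fragments (configurable) — SCR
transfer over a fragment would silently misreport the missing modules.

### Annotation read-off

* **SCR transfer**: an SCR's query interval runs from the first to the last
  non-deleted match state whose source column lies in its span; an SCR with
  every state deleted is reported ABSENT.
* **Hotspot call**: the query position and residue emitted by the
  F87-anchor state; a deletion there is a gap call, meaning the BC-loop
  houses no residue at the heme-facing position.
* **RIS length**: the number of query residues strictly between the emitted
  positions of the two flanking anchor states — matched residues of
  low-occupancy columns and insertions count alike. A deleted anchor is
  substituted by the nearest emitting match state inward within its
  flanking SCR; if that SCR is entirely deleted the length is UNDEFINED.
  The anchor columns are the terminal columns of the flanking SCRs by
  default and overridable in the sidecar, because the counting convention
  must be calibrated as data against known loop lengths, not hard-coded.
* **Redox class** from the two lengths (thresholds in residues):
  RIS1 ≤ 9 short, ≥ 16 long, 10–15 ambiguous; RIS2 ≤ 6 short, 11–17 long,
  ≥ 18 very long, 7–10 ambiguous; any length ≥ 36 is flagged unusual
  (formally class II). Two published edge cases are closed explicitly:
  RIS2 = 7 falls in the ambiguity window, and RIS2 = 18 is classified very
  long. Rule order: UNDEFINED → discordant; unusual; ambiguity windows;
  then short/short → class I, long/long → class II, long/very-long →
  reductase-independent subgroup; remaining mixtures → discordant. The
  function is total over non-negative lengths.
* **Applicability gate**: a database homology search is replaced by a
  database-free criterion — glocal forward score ≥ 100 bits plus the
  heme-cysteine anchor aligning to C. Random 450-residue sequences score
  far below 0 bits against the default profile while seed-like sequences
  score several hundred, so the floor separates the populations by a wide
  margin; it is a parameter, not a calibrated constant.

### Leave-one-out validation

Each non-reference row is dropped, the profile rebuilt from the remaining
rows with identical parameters, the dropped row's degapped sequence
re-aligned, and the predicted hotspot position compared with the row's true
position (the degapped position of its residue at the hotspot column; gap
if the row shows `-` there). Outcomes are categorised exact / deviation by
1 / by 2 / wrong / gap. The row is removed from the *fixed* alignment — the
structural alignment is input data here and is not recomputed per fold. The
reference row is exempt because the coordinate bookkeeping depends on it.

## The synthetic generator

The generator emulates the *shape* of a structure-based CYP seed: 19
fully-occupied conserved blocks with configurable per-column conservation;
universal ExxR/Cys anchors; a hotspot column drawn per row from the
family's observed hotspot composition (F 22%, L 22%, V 12%, I 10%, A 9%,
remainder spread below 4%); variable linkers; and two designated
inter-block regions acting as the interaction sites, with per-row lengths
drawn from class-conditional bands (class I 3–5/3–5, class II 21–22/11–17,
very-long-RIS2 subgroup 18–23). Default study conditions: 20 rows, full
conservation inside the conserved blocks, class mix 16% I / 73% II / 11%
very-long. Every artifact carries a truth record in its own coordinates.

Two identifiability choices matter for interpreting recovery results:

* Variable-region residues are resampled so they never equal the consensus
  of the adjacent conserved column. Without this a chance coincidence lets
  the alignment absorb a boundary residue into the anchor at equal score,
  and the true region length is not identifiable even in principle.
* Query indels never touch the three anchor-bearing blocks, so truth anchor
  coordinates stay valid; an indel inside a RIS-flanking block still makes
  the boundary ambiguous (the extra residue can sit on either side of the
  anchor at equal score), so recovery checks condition on indels falling
  outside the RIS spans and their flanking blocks.

What passing these tests shows: the engine recovers exactly what the model
can represent — anchored positions, region spans and inter-anchor counts —
under conditions where the truth is identifiable. What it does not show:
performance on real CYP sequences, whose conserved regions are
structurally, not sequence-wise, conserved (~25% identity), whose insert
regions are not background-random, and whose seed alignment carries
alignment error of its own. Real-data agreement is therefore
tolerance-framed wherever it is measured.

## Crystal-structure reproduction layer

The 31-chain seed set (12 class II CPR-type, 16 class I, 3
reductase-independent; reference 1BU7) is assembled from one observed chain
per PDB entry, cache-first, and aligned by pinning every chain at its ExxR
and Cys-pocket motifs followed by iterative profile re-alignment (default
two rounds; `refine_rounds=None` iterates to a fixed point). A best-effort
annotation is then derived: SCRs as maximal high-occupancy column runs,
anchors from the reference row, RIS anchors by the flanking-SCR
convention. This reconstruction stands in for a structure-derived
alignment and is approximate by construction — hold-out agreement against
published structure-derived positions is compared with wide tolerance, and
the layer is exercised in the offline test suite on synthetic stand-in
sequences (labelled as such) that carry the same motifs.

## Problem sizes and numerical notes

The default test and acceptance workloads use the 20-row seed
(~290 columns, 257 match states), 200 annotated queries, 19 + 30 hold-out
folds, 5,000-draw cohorts, and 1,000 enumeration instances with ≤ 6 match
states and ≤ 8 residues — sizes at which the enumeration oracle is exact
and the full run completes in well under a minute on one core. Dynamic
programming rows are vectorised over query positions; the insert recurrence
uses a running-maximum (Viterbi) or running log-sum (forward) scan.
Probabilities serialise as decimal strings so profile JSON round-trips are
bit-exact.

## Known limitations

* SCR boundaries and RIS anchor calibration are only as good as the
  sidecar; the published boundary data for the real seed is not packaged,
  so the real-data layer derives them by occupancy heuristics.
* RIS lengths adjacent to deleted anchors depend on the inward-substitution
  convention; alternatives (e.g. counting alignment columns) would differ
  for heavily gapped queries.
* The gate's 100-bit floor is appropriate for profiles of this size; very
  short or very diverged profiles warrant re-checking it against a random
  score distribution.
* No local-local alignment mode and no E-value calibration; multi-domain
  queries are handled only insofar as extra domains fall into the flanks.
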