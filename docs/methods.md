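# Methods

## Problem and coordinate conventions

Plant miRNAs recognise their mRNA targets by near-perfect antisense
complementarity; cleavage-competent interactions must pair through
the central region of the guide. Throughout the package miRNA
positions are 1-based from the 5' end (seed 2–8, central 9–11, core
2–12), while transcript coordinates are 0-based half-open intervals
on the sense strand. The 1-based miRNA convention keeps the region
windows in their field-standard form; half-open transcript intervals
make overlap and flank arithmetic exact. Only the supplied sense
strand is scanned — antisense recognition is modelled inside the
alignment (the miRNA is matched against the reverse complement of
each window), not by scanning a second strand. `T` is normalised to
`U` and case is folded on input. Mature miRNAs must be 15–30 nt
(a warning outside the typical 20–24 nt); for guides shorter than the
core window end the windows truncate at L, with a warning.

## Candidate scan and weighted score

Each transcript window of length L−g … L+g (g = max gaps × max gap
length, default 1) is aligned antiparallel against the miRNA, with
position 1 opposite the window's 3'-most aligned base. Pair states
are WC match, G:U wobble, mismatch, or a gap on either strand. The
penalty is the Allen-style weighted sum used across plant predictors:
mismatch 1.0, G:U 0.5, gap 2.0 per gapped base, each doubled when the
miRNA position lies in the core 2–12; WC matches cost nothing. All
weights and windows are configurable (`ScanParams`).

The search is exact over its declared space: at most `max_gaps`
maximal gap runs of length ≤ `max_gap_len` (default: one single-base
bulge), found by depth-first enumeration with branch-and-bound
pruning. Ties break deterministically — fewer gap runs first, then
the leftmost gap. Two conventions the scoring needs that the region
definitions do not fix:

* a target-side bulge (GAP_MIRNA state) sits between miRNA
  positions; it is assigned the position of the next un-consumed
  miRNA base, clamped to L, for core-window weighting;
* a gap run may not immediately follow another gap run, so a "gap"
  is always a maximal run — two adjacent length-1 runs cannot
  emulate a disallowed length-2 gap.

Windows pass at `weighted_score ≤ max_penalty_score` (inclusive, as
everywhere in the package: a stated cutoff is attainable). Within one
scan, hits sharing ≥ 90% of their positions are suppressed keeping
the lowest score (ties: leftmost, then shortest) — the same overlap
rule the filters use. Raising the cutoff can only add sites: kept
candidates are processed in (score, start, end) order, and new
candidates under a looser cutoff always score strictly worse than
previously kept ones. A correctness-first sliding scan is deliberate;
no heuristic seeding index is used at desk scale.

## Engines

All four engines consume the same scan candidates (the scan bound is
widened automatically to the loosest score any engine could accept,
e.g. 12.0 for a counts-cutoff-5 engine under default weights) and are
then applied with their own rules:

| engine | rule |
|---|---|
| WMD3-like | mismatches + G:U + gaps ≤ 5 (a wobble counts as one mismatch) and energy ratio ≥ 0.70; no region weighting |
| UEA-like | no non-paired state in 9–11, weighted score ≤ 4.0, ratio ≥ 0.70 |
| TAPIR-like | weighted score (core-doubled) ≤ 4.0, ratio ≥ 0.70 |
| psRNATarget-like | weighted score ≤ 3.0 only; classifies cleavage vs translation by a central-region mismatch (a central G:U stays cleavage) |

The "*-like" naming is deliberate: these implement the published
decision rules, not byte-compatibility with any web service. Only the
counts cutoff 5 and the 70% ratio are classic published constants;
the score cutoffs (4.0 / 4.0 / 3.0) are package defaults, exposed in
`EngineConfig`. One uniform energy model serves all engines (the
original services differ in their thermodynamic back-ends); the
UEA-family ratio against the miRNA:miRNA* duplex is not computable
from mature sequences alone, so the perfect-reverse-complement
denominator is used uniformly and documented rather than guessed.

## Energy model and accessibility

The energy layer is a deterministic simplified model so that every
result is reproducible with no external folding binary:

* duplex energy: per-pair sum, G:C −3, A:U −2, G:U −1 kcal/mol;
  mismatches and gaps contribute 0. Favourable values are negative.
* energy ratio: duplex energy over the energy of the miRNA against
  its exact reverse complement, clamped to [0, 1]; 1.0 iff the site
  is a perfect complement. Acceptance threshold 0.70.
* opening energy: E_fold(window with the site forced unpaired) −
  E_fold(window), where E_fold is the minimum-energy Nussinov-style
  nested-pairing DP with the same per-pair energies and a minimum
  hairpin loop of 3 nt. The difference is ≥ 0 by construction.
* accessibility: opening + duplex energy on a window of at most
  100 nt of flank on each side of the site (truncated at transcript
  ends); the filter keeps sites ≤ −15.87 kcal/mol (inclusive).

This is not a nearest-neighbour/partition-function model: stacking,
dangling ends and ensemble effects are out of scope. A rigorous
engine can be plugged in through the `accessibility` backend contract
(any replacement must return opening ≥ 0 and duplex ≤ 0 for the same
window and site); a failing or contract-violating backend marks the
site UNCOMPUTED instead of aborting the batch, and uncomputable sites
are removed (and counted separately) by the accessibility filter.

The Nussinov DP is vectorised over diagonals (numpy) and verified
against explicit enumeration of all nested structures for short
windows; note that under this model even a site planted in an all-A
context acquires a positive opening energy, because the site's own
G/C/U bases pair with the flanks — accessibility is always the
computed composition, never assumed equal to the duplex energy.

## Filters

Sites of one (miRNA, transcript) pair overlapping ≥ 90% (denominator:
the shorter site — the permissive standard choice, configurable) are
grouped into one common interaction. Groups are connected components
of the overlap graph: the grouping is deterministic and
order-independent, and transitivity needs no special-casing. A
group's representative is its best-scoring member (ties: leftmost
start, then engine order).

* multi-method: keep groups supported by ≥ N distinct engines
  (N ∈ 1..4), emitting representatives annotated with the support
  set. Tightening N can only shrink the output.
* multiplicity: keep sites of pairs with ≥ 2 distinct site groups.
  Multiplicity counts groups, not raw engine hits, so one physical
  site supported by four engines counts once — consensus and
  multiplicity stay distinct signals.
* accessibility: keep sites with total ≤ −15.87 kcal/mol.
* degradome: mRNA-level join against a (min-collapsed) evidence
  table; keep pairs present with score ≤ 4.5. Lower degradome
  category scores mean stronger cleavage support, hence ≤.

Every filter is a contraction and idempotent, and reports exact
bookkeeping: kept + removed = total, filter ratio = removed / total
(0 for empty input).

## Benchmarking

PM counts site groups, VM those groups whose pair is in the
(mRNA-level) reference, CM the distinct reference pairs recovered. A
validated pair predicted at three sites contributes 3 to VM and 1 to
CM — the reading under which VM exceeds the reference size and
AP = 100·(PM−VM)/PM reproduces the published percentages exactly.
Percentages are rounded half-away-from-zero to 2 decimals; column
averages round counts to the nearest integer. The column average is
the plain arithmetic mean (the published average TP entry does not
equal the mean of its column, 74.65; the package implements the mean
and reports only the verifiable averages in its acceptance script).
Pairwise agreement between predictors pools and regroups the two
sets' sites (site level) or intersects collapsed pairs (mRNA level),
against the smaller set. Region summaries count groups per transcript
region (5'UTR / CDS / 3'UTR / unsplit) with validated and collapsed
rows, plus region shares.

## Synthetic data

The generator defines the study conditions for all pipeline tests:
21 nt miRNAs, transcripts uniform over 300–2000 nt with uniform
25/25/25/25 composition (GC bias configurable), one planted site per
transcript, all planted pairs reference-true, degradome support
(score uniform in 1.0–4.4) with probability 0.9 for true pairs and
decoy pairs scored 4.6–7.0, plus 10 decoy pairs absent from the
predictions to exercise the mRNA-level join. Planted sites are the
reverse complement of the miRNA, optionally perturbed by an edit list
(mismatch / wobble / single-base bulges at distinct positions);
ground truth (coordinates, duplex states, weighted score, expected
engine acceptances) is recorded by construction. A fixed seed yields
byte-identical files (Python's portable Mersenne Twister, fixed float
formatting).

Scale choices in tests and the acceptance script: pipeline fixtures
use 10 miRNAs × 20 transcripts of 300–600 nt (20 planted sites), and
oracle-equivalence sampling uses 500 random alignment instances
(length ≤ 12) and 60 folding windows (≤ 14 nt) — sizes at which the
exhaustive oracles are exact and the whole suite stays desk-scale.
What passing on this generator shows: the machinery recovers what was
planted, at exact coordinates, with the predicted engine provenance.
What it does not show: performance on real transcriptomes, where
base composition, repeated families, shared seeds and genuine
degradome noise shape the false-positive landscape; the measured
background false-positive rate on random sequence is logged by tests,
not asserted against a fixed target.

## Known limitations

* The energy model is intentionally coarse; absolute kcal/mol values
  are comparable within the package, not with partition-function
  tools, even though the filter default (−15.87) is kept at the
  field-standard value for continuity.
* The gapped search space is one short bulge by default; engines
  whose services allow longer asymmetric loops will disagree on such
  sites.
* No conservation filtering, no genome coordinates or splice models,
  no degradome read processing — evidence enters only as a
  pre-computed score table.
* The scan is O(transcript × miRNA) per pair with constant-size
  alignment work; it favours auditability over throughput and is not
  meant for whole-transcriptome sweeps in pure Python.
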