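# Methods

This note records the conventions, defaults and design choices behind the
pipeline, in the order the data flows through it.

## Curation model

A candidate set (in practice, the hits of an InterPro P450-domain search) is
curated by motif evidence rather than domain score. Two signature motifs are
used:

* **ExxR** — the K-helix Glu-x-x-Arg salt bridge. Pattern `E..R`, accepted
  anywhere in the sequence.
* **CxG** — the heme-binding region around the axial cysteine. Pattern
  `C.G`, accepted only when the match starts in the C-terminal third of the
  sequence (`start >= floor(2L/3)`). The window exists because `C.G` is a
  weak pattern; without it, spurious matches far from the heme pocket would
  inflate the P450 count.

Wildcard positions span the 20 canonical residues plus X; an X in the
sequence can occupy a wildcard position but never satisfies a fixed letter.
Both patterns are configurable in `RulesConfig`. All match start positions
are reported (overlaps included); triage consumes only per-motif existence.

The triage rule: both motifs and length ≥ 350 residues → **P450**; exactly
one motif, or both motifs below 350 residues → **FRAGMENT**; no motif →
**FALSE_POSITIVE** if the best identity to a named reference is ≥ 20%, else
**NO_HIT**. The published workflow distinguishes false positives from
no-hits without stating a criterion; the 20% reference-identity cut-off is
this package's operationalisation (a degenerate P450-like protein retains
residual similarity; an unrelated protein does not). It is configurable and
recorded in every triage report.

## Percent identity and alignment

Identity is computed from an optimal global alignment: BLOSUM62, affine gap
cost `10 + (L-1) × 1` for a gap of length L, end gaps penalised. The
identity denominator excludes terminal-overhang gap columns (the contiguous
gap runs touching either end of the alignment), so a full-length protein
aligned to its own fragment scores 100%. This approximates the identity a
local aligner (the workflow this replaces used BLAST) would report over its
HSP, while keeping the computation global, gap-parameterised and
deterministic. Internal gap columns stay in the denominator.

Scores are produced by Biopython's `PairwiseAligner`; an independent Gotoh
dynamic program in the test suite verifies score equality on random pairs.
When several tracebacks are co-optimal the aligner's first reported
alignment is used; it is deterministic for fixed inputs, and only the score
and the terminal-gap-excluded identity are consumed downstream.

## Nomenclature thresholds

The International P450 Nomenclature convention is stated as ">40% identity
same family, >55% same subfamily", with below 40% founding a new family —
leaving exactly-40 unstated. This package resolves the boundary
conservatively: identity ≥ 40 keeps the family, identity > 55 keeps the
subfamily, and any call within ±2 percentage points of the subfamily
threshold (the `borderline_band_halfwidth`) is flagged borderline. Ties
among equally identical references go to the lexicographically smallest CYP
name. New families receive placeholder labels (`NEWFAM1`, … in query
order) — real CYP numbers are committee-assigned and out of scope.

Borderline calls may be overridden by phylogeny: if a tree over the query
and the named references is supplied, the subfamily is taken from the
nearest named leaf (minimum path length, ties lexicographic).

## Phylogeny

Distances are `1 − identity/100`. Trees are built with Saitou–Nei neighbor
joining: smallest Q-criterion pair joined at each step, ties broken by the
smallest label pair, negative branch-length estimates clamped to zero, final
three-node join forming a degree-3 unrooted root. NJ is exact on additive
matrices (verified to 1e-9 in the tests) and fully deterministic, which is
all the downstream nearest-neighbor queries require; likelihood methods
would add model choices without changing that relation. No bootstrap is
computed.

## Presence/absence and clustering

The conservation matrix encodes presence as 3 and absence as −3 (the
MeV heatmap convention; red/green in the figures). Both axes are clustered
agglomeratively with Euclidean distances and average linkage. The
agglomeration is implemented in-package because deterministic tie-breaking
matters here: presence/absence rows produce many exactly-tied distances, and
the implementation resolves them by label order (rows are pre-sorted), which
library implementations do not guarantee. Cluster–cluster distances follow
the Lance–Williams average-linkage update; the tests check the merge heights
against a quadratic recompute-from-scratch oracle and against scipy on
tie-free matrices. Average linkage is a choice — the original analysis names
only the metric — and the merge trees are exposed so any consumer can
re-order leaves differently.

Family statistics exclude fragments: per-species totals, half-away-from-zero
rounded means (the convention that reproduces every printed average, e.g.
580/19 → 31), extremes with their species, lifestyle Venn partitions
(shared = present in every group, unique = present in exactly one), and
bloom families (cohort-wide member count ≥ 30).

## Biosynthetic gene clusters

Cluster input is a minimal TSV contract (species, cluster index, type, gene
id, 1-based inclusive coordinates, strand) that anti-SMASH spreadsheet
exports can be munged into; running anti-SMASH is out of scope. Hybrid types
are comma-joined tokens and count once per token in per-type tallies but
once per cluster in totals. P450 membership is exact gene-id lookup against
the assignment map; each membership occurrence is one entry, so a P450 name
appearing in two species' clusters counts twice, matching the published
table's row semantics.

The packaged 12-species cluster table records only per-species counts plus
the P450-bearing clusters, so `clusters_from_fixture` synthesizes
placeholder member genes and types untyped clusters as `unknown`; the
reconstruction is labelled synthetic in its docstring and exists to drive
the census and cross-reference arithmetic, not to model real cluster
content.

## Synthetic cohorts

The generator emulates the *inputs* of the curation workflow with planted
truth:

* **References/founders** — random sequences (length 450–550, uniform
  residue usage) with ExxR implanted at 35% of the length and CxG at 88%,
  pairwise identity < 35%, named in a placeholder 9000-series to avoid
  collision with real families.
* **Members** — founders mutated by random substitutions (motif positions
  protected) into identity bands: (60, 75]% for same-subfamily calls,
  [42, 54]% for family-only calls, [20, 34]% for new families. The bands
  keep clear of the 40%/55% thresholds, so the expected assignment is
  unambiguous and recovery must be total; the band edges adjacent to the
  borderline flag region (53–57%) can set the flag, which changes nothing
  without a tree. Substitution-only mutation keeps identity monotone in the
  edit count, making band targeting a short guarded search; indel robustness
  is exercised separately with hand-made gapped cases in the alignment
  tests.
* **Fragments** — members truncated below 350 residues (the ExxR motif
  retained) or with every ExxR occurrence ablated; either way the triage
  rule must call FRAGMENT. Default rate 0.11 of the member count, matching
  the observed fragment fraction (88/779).
* **Decoys** — false positives are founders mutated to 27–34% identity with
  both motifs ablated (identity re-verified ≥ 22% so the heuristic fires);
  no-hits are random motif-free sequences re-sampled until best reference
  identity < 18% (random ~500-residue pairs align at roughly 15–17% under
  this scoring, so a 2-point guard band on each side of the 20% threshold
  makes the truth labels exact). Default no-hit rate 0.03 (≈ 23/779).
* **Clusters** — per species, a few typed clusters with three placeholder
  genes each; planted P450 member genes reuse member protein ids, and the
  truth cross-reference is recorded.

`SyntheticSpec.table4_sized()` instantiates the 19-species cohort with
per-species member/fragment/decoy counts copied from the packaged curation
table, giving 779 candidates in the published composition.

What passing on synthetic cohorts does **not** show: real proteomes have
biased residue composition, indels, paralog gradients that straddle the
thresholds, and genuinely ambiguous borderline cases — the generator
deliberately avoids all of these so that truth is exact. The pipeline's
behaviour on threshold-straddling inputs is specified (and tested) through
the boundary conventions above, not through the generator.

## Problem sizes and determinism

The test suite runs a 4-species, 5-family cohort (about 60 proteins); the
acceptance script runs the full 19-species, 779-candidate cohort plus all
fixture statistics, completing in well under a minute on one CPU. All
randomness flows from a single `numpy.random.default_rng(seed)`; identical
seeds give byte-identical cohorts.

## Known limitations

* The false-positive/no-hit split is a heuristic this package defines; the
  original counts cannot be re-derived without the original candidate sets.
* Motif patterns are the two-signature minimum; I-helix or other P450
  signatures are not scanned.
* Identity is global-alignment based; against very distant or multi-domain
  references it can differ from HSP-local identity near the family
  threshold.
* The NJ tree is a working tool for nearest-neighbor resolution, not a
  publication-grade phylogeny (no alignment masking, no support values).
* Per-genome counts for the real 19 species require the original proteomes,
  which are deliberately not downloaded; only the printed per-species tables
  ship with the package.
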