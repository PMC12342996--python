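# Methods

This note documents the models, algorithms and design choices behind
argscope: what each computed quantity means, how the incremental sweep and
the rasterizer work, what the fixture simulator does and does not emulate,
and where the design was genuinely open.

## Data model and validation

An ARG is held as four column-oriented tables (nodes, edges, sites,
mutations) plus a sequence length, mirroring the tskit conventions: genome
coordinates are 0-based half-open `[left, right)` throughout, missing
integer references are −1, and unknown mutation times are NaN (a dedicated
marker distinct from every real number; converted to/from tskit's unknown
marker at the `.trees` boundary).

On construction the model canonicalizes table order: edges are sorted by
(left, parent time, parent id, child id) and mutations are stable-sorted
by site with parent links remapped. Input files therefore need not be
pre-sorted; canonicalization makes the downstream sweep deterministic and
makes table equality meaningful after round trips. The fact that a resort
happened is recorded in the provenance metadata.

`validate()` returns a list of violations rather than raising: parsing and
validation are deliberately separate, so a structurally well-formed file
with nonsense coordinates loads and is then diagnosed row by row. Each
violation names a rule, a table and a row. Rules that depend on a
reference (e.g. edge time ordering, which needs valid node ids) are
skipped for rows that already failed the reference check, so a
single-field corruption produces exactly one violation — this makes the
validator's output directly usable as an error report.

`num_trees` counts the intervals of the breakpoint partition — the sorted
union of {0, L} with all edge endpoints — including edge-free gaps, which
are empty trees. A browser must tile the whole axis, so a gap is a
first-class (if empty) view; this also matches tskit's convention, which
the tests use as an independent oracle. An ARG with no edges has zero
trees.

## Feature computation

**Edge features** are plain arithmetic: branch length, span, area.

**Node spans** use edges where the node appears as parent *or* child. The
alternative (parent-only) under-reports where a node exists in the graph;
the envelope answers the visual question "over which part of the genome
does this node participate in the ARG at all".

**Inheritor counts** come from a single left-to-right sweep. The current
local tree is a parent array plus a per-node count of samples in its
subtree. At each breakpoint, leaving edges are detached (their child's
count is subtracted from every ancestor from the old parent upward) and
entering edges attached (count added likewise); insertion order is (left,
parent time, parent id, child id) and removal order (right, −parent time,
parent id, child id), so children detach before their ancestors and ties
are broken by id for determinism. Each site inside the current interval
then reads off, for each of its mutations, the count at the mutation's
node. The sweep is O(edges × tree height + mutations) instead of the
naive O(sites × edges); the naive per-site DFS is kept as
`inheritor_counts_naive` and serves as the independent oracle in tests,
never as the implementation.

A mutation above a node that is absent from the local tree at its site
(not a sample, no parent, nothing beneath it) gets inheritor count 0 and a
warning record in the store metadata — bad inputs should be browsable, not
fatal.

**Mutation time imputation**: where the time is unknown, the plotted time
is the midpoint of the branch the mutation sits on — `(t(node) +
t(local parent of node at the site)) / 2` — falling back to the node's own
time at local roots. The midpoint is the expectation of a uniformly placed
mutation on its branch, which is the least-informative consistent choice.

## The store

The browse store is a single-file zip archive of named, chunked,
zstd-compressed arrays (zarr v3) plus one JSON metadata document holding
format version, source identity, creation timestamp, summary counts and
collected warnings. Columns stream individually, so a viewer never loads
arrays it does not need. String columns (ancestral/derived states) are
packed as a UTF-8 byte buffer plus an int64 offsets array, which makes
round trips bit-identical by construction. Reading verifies the format
version first and then the presence of every expected key, naming the
first missing key in the corruption error. Round trips are lossless;
equality of stores is defined over arrays, counts and sequence length,
excluding timestamps.

## Rasterization

All bins are half-open with a closed top bin, so items sitting exactly on
a viewport's maximum edge are kept — nothing is silently lost at the
boundary, and grid totals exactly equal in-viewport item counts (the
conservation property the tests enforce). Points land in exactly one
pixel. Segments are zero-thickness horizontal lines: one y-row (the row of
their transformed time) and every column their clipped genome interval
overlaps; columns are found by binary search against the grid's own bin
edges and accumulated with a per-row difference array, so the cost is
O(segments + pixels) per grid rather than O(segments × pixels). Diagonal
parent–child connectors are not rasterized; they belong to a low-zoom
drawing layer, not to the aggregate grids.

The time axis may be linear or logarithmic; the log transform is
`log10(t + δ)` with δ defaulting to the smallest positive node time in
the store, which keeps time-0 sample nodes finite and on-screen. δ is
echoed in every view payload so a client can invert the axis. How to place
time-0 nodes on a log axis is a genuine free choice; this rule is ours.

## Views

Each browsable view restricts its items to the viewport (segment intervals
are clipped; an item's time must lie within the y-range, top edge
inclusive), computes linked histograms from exactly that in-viewport
subset — so histogram totals always equal the on-screen item count — and
returns both the raw items (when at most 50,000 are in view; the threshold
is configurable) and the count grid. The edges view defaults to child time
on the y-axis, foregrounding recent activity; the parent/child toggle is
exposed. Histogram sets: edges → branch length, clipped span, y-time;
mutations → plotted time, inheritor count; nodes → clipped span, node
time. Histogram ranges cover the in-view value range, updating on every
viewport change (pan as well as zoom).

The table viewer ANDs its filters (`==, <, <=, >, >=, contains`), sorts
stably with a final tie-break on row id, and pages last. Static export
writes deterministic PNGs (counts through a log-scaled viridis map,
zero-count pixels white) or an HTML snapshot with the image inlined; byte
determinism is part of the contract so snapshots can be diffed.

## The serve layer

The HTTP service is a thin shim: every JSON payload is exactly the
corresponding views-module call on the held store, which is also how it is
tested (20 random viewports, payload-for-payload). The store file is
opened read-only and its checksum is asserted unchanged after serving. The
wire protocol (JSON + PNG tiles over stdlib HTTP) is internal and
unstable; all logic that matters lives below it. Port 0 binds an ephemeral
port and reports it, which the tests use. Sequence names in annotation
files are ignored (beyond an optional contig filter) because the model has
a single linear coordinate system; BED is read verbatim as 0-based
half-open, GFF3 converted from 1-based closed, CSV requires
`start,end,label` and declares the 0-based half-open convention.

## The fixture simulator

`simulate_wf_arg` runs a discrete-generation Wright–Fisher ancestry of n
haploid samples backwards with segment tracking: each generation, every
lineage's ancestral material is cut at Poisson(recombination_rate)
crossover points and each chunk assigned a uniform parent in a population
of fixed size; chunks meeting at one parent coalesce wherever they
overlap, emitting a new node (one per parent per generation) and the
corresponding edges, and intervals that reach all samples stop being
tracked. Mutations are then dropped on edges at rate
`mutation_rate × area / L` with uniform positions, one site per mutation
(collisions, probability ≈ 0 with continuous positions, are dropped).
Defaults: sequence length 100, 200 generations, one crossover and one
mutation per genome per generation, population size 2 × n — small enough
to coalesce most lineages within the generation budget while leaving
recombination visible. The pseudo-random generator is numpy's default
(PCG64) seeded from the mandatory `seed`; identical parameters give
bit-identical tables within this package (cross-implementation equality is
not promised).

The sweep option is a deliberate caricature, not a selection model: any
chunk covering the focal position picks the focal parent (individual 0)
with probability `strength`. That concentrates recent coalescence at the
centre and reproduces the qualitative signature of a strong sweep — a
central deficit of edge coverage (the "wedge") — which the tests check as
a strict center-vs-flank coverage inequality across ten independent
seeds (50 samples, 1000 bp, strength 0.9, 400 generations).

What the simulator does **not** emulate: diploidy, variable recombination
maps, realistic sweep dynamics or timescales, gene conversion, or
sequencing error. Passing tests therefore demonstrate the correctness of
the *computations* on valid ARGs of realistic structure, not calibrated
population-genetic realism.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale ARGs (samples ≤ 50,
hundreds of trees, thousands of edges), which exercise every code path —
breakpoint handling, multiple roots, mutation chains, empty tables —
while keeping the whole suite and the acceptance script each well under a
minute. Area conservation is asserted at 1e−9 relative tolerance (observed
error is at the 1e−15 float rounding floor); every discrete check
(inheritor counts, grid counts, round trips) is exact. Degenerate inputs
are accepted deliberately: zero-edge or zero-mutation ARGs build stores
with empty arrays and render empty views, and non-coalesced simulations
yield multiple local roots.

## Known limitations

- Local tree *topology* drawing is out of scope; the views summarize
  tables, not tree shapes.
- The sweep caricature cannot be used to study selection quantitatively.
- Population-genetic statistics (diversity, Tajima's D, …) are not
  recomputed; only the structural features listed above.
- The HTTP protocol is unversioned and may change between releases.
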