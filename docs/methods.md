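# Methods

## The problem

A merged cohort VCF reports every variant in the coordinates of one
reference genome. Two things make that representation awkward for
population-scale variant search. First, each sample's genome has its own
coordinate system — every insertion or deletion the sample carries shifts
all downstream positions relative to the reference — so answering "what is
sample S's sequence between positions X and Y *of S's genome*" requires a
per-sample position mapping. Second, maintaining an explicit position index
per sample costs O(S·N) space for S samples and N variants, which is what
limits explicit-path variation-graph tools at cohort scale.

`vgindex` stores the cohort as a directed acyclic **variation graph**
G = (N, E, P): nodes carry sequence slices, each sample's genome is an
embedded source-to-sink path, and the position of a node on a path is the
sum of the lengths of the node sequences before it. A **position index** is
kept for only one designated path — the **marker** sequence, normally the
reference — and positions in any other sample's system are recovered by a
local graph search around the marker node with the same numeric position.
The index is *variant-oriented*: each alt node stores the set of samples
carrying it (inverted-index direction), so space grows as O(N·M) for a mean
of M carriers per variant, independent of the number of coordinate systems
supported.

## Graph model and storage

**Nodes.** Marker-path nodes carry slices of the reference; each variant
becomes one *alt node* holding the alternative sequence (zero-length for a
deletion), wired from the marker node that ends at the variant's start to
the marker node that starts where the replaced span ends. Splitting is
idempotent: boundaries created by earlier variants are reused, which is how
two variants anchored at the same position coexist. A variant whose span
crosses several existing boundaries connects the flanking marker nodes
directly. Normalization trims the maximal common prefix of REF and ALT (the
VCF anchor base for indels) before insertion and classifies edits as
SUB / INS / DEL; a trimmed edit with unequal nonzero lengths is kept as
COMPLEX and encoded by the same split-and-branch machinery.

**Sequence buffer.** All node sequences live in one append-only buffer
packed at 3 bits/base, since the alphabet {A, C, G, T, N} has five symbols.
The reference is appended first, so marker nodes slice [0, L); alt
sequences follow in insertion order. Code assignment A=0, C=1, G=2, T=3,
N=4 is an arbitrary fixed bijection.

**Sample classes.** Two variants are equivalent when exactly the same
samples carry them; each distinct carrier set (*sample class*) is stored
once as a bit vector over the sample roster, and alt nodes store only the
class id — the color-class deduplication used by colored de Bruijn graph
tools. Class id 0 is reserved for the empty set. Per-carrier data at a node
— (sample position, phasing) tuples — is stored in class-rank order, so a
carrier's tuple is found by a rank on the class bit vector. Phasing is 3
bits per carrier: phased flag plus the two allele bits of the genotype.
(Ploidy is retained at parse time but not encoded per node; carrier
genotypes of one alt are fully described by the three bits.)

**Topology.** Variation graphs built from VCFs have edge/node ratios near
1, so a node with one out-neighbor stores it inline in an associative
container, and only branch points pay for an indirection into a table of
neighbor lists. The original system realizes this contract inside a
counting quotient filter; any container with the same behavior is
semantically equivalent, so a hash map is used here. Neighbor order is
fixed — alt branches in creation order, then the marker successor — making
all traversals deterministic. Reverse (read-alignment) traversal is out of
scope; the graph is strictly forward, acyclic.

## Two-phase construction

Computing each carrier's position at insertion time would require
backtracking along that sample's path for every carrier of every variant.
Instead:

* **Phase 1** inserts variants (which must arrive position-sorted, as VCF
  guarantees) maintaining *marker* positions only.
* **Phase 2** sweeps the nodes once in marker-position order, carrying a
  per-sample **delta** — the running difference between the sample's
  coordinate and the marker coordinate. At an alt node, each carrier's
  position is `marker_pos + delta[s]`, after which
  `delta[s] += |alt| − |replaced span|`. A sample's final delta equals its
  sequence-length change, a checked invariant.

The original description calls phase 2 a breadth-first traversal; FIFO BFS
from the source can interleave alt nodes across branch points, so the sweep
here is defined as marker-position order (alt nodes before the co-located
marker node, creation order breaking ties), which is a topological order of
the DAG and the unique order that makes delta propagation well defined.
This also fixes exactly the "roughly breadth-first" serialization order:
after phase 2, node ids are relabeled to the sweep order, so ids increase
with marker position and chunk ranges are coordinate-aligned.

Zero-length deletion nodes keep `marker_pos0` = the start of the bypassed
span; in the carrier's own coordinates this equals the point where its
sequence resumes.

## Chunked node storage

Node records dominate index space. They are serialized in compressed,
position-ordered chunks (default 200,000 nodes, configurable; zlib by
default) with an offset-free one-file-per-chunk layout so a chunk loads
independently. During construction only the active chunk is in memory;
during query chunks load lazily and the two most recently loaded stay
resident. Because node ids increase along every path and batches are
executed in sorted order, chunk access is monotone and answers are
independent of capacity — capacity tunes memory, nothing else. Residency
counters (`current, max, loads`) are maintained and asserted ≤ 2 in the
test suite. The chunk-load bound for sorted batches (each chunk loaded at
most once, plus one) holds when a chunk's coordinate span is at least the
query window span, which is the intended operating regime; much smaller
chunks still give correct answers with more reloads.

## Position index and queries

The marker index is a bit vector (*position-bv*) of length L with a set bit
at each marker node's start plus the node ids in position order; rank over
the prefix [0..j] gives the predecessor node — the node containing the
queried position. Rank uses 512-bit superblock prefix counts plus a bounded
in-block scan (the RRR-compressed structure of the original is an
optimization, not semantics). Zero-length nodes are excluded, so set bits
are unique; they are reached by traversal only.

Six query types are supported (positions are 1-based inclusive at the API
and CLI boundary): ClosestVar(R;X), Seq(R,S;X,Y), Seq(S;X,Y), Vars(R,S;X,Y),
Vars(S;X,Y), AllVars(R;X,Y). Design choices where the original is silent:

* A variant is "in [X, Y]" iff its anchor start lies in the closed
  interval; variants merely overlapping from the left are excluded (this
  matches predecessor-based containment and keeps AllVars/Vars consistent).
* "Closest" is two-sided nearest by anchor distance, ties to the smaller
  position.
* For marker-coordinate sequence queries, alt detours anchored inside the
  window are emitted in full between marker boundaries; a window end inside
  a detour does not clip it.
* Paths are per-sample, not per-haplotype; phasing is reported in hits but
  does not split paths. With same-sample overlapping variants the traversal
  takes the first matching branch in neighbor order (query-time semantics;
  construction accepts such input).

**Sample-coordinate resolution.** Only alt nodes store sample positions, so
resolving position t in sample S's system uses a local search: start from
the marker predecessor of t, scan anchor boundaries backward for S's
nearest alt with stored position ≤ t (the *anchor*), then walk S's path
forward accumulating node lengths to the node containing t. If no anchor
exists the region is identity and the marker index answers directly. The
forward walk visits only nodes between anchor and target, so the cost is
governed by local variant density, not by chromosome length or total
variant count — the suite asserts this scale-independence directly. Note
the backward scan can be long for a sample whose variants are sparse around
t; `add_path_index` materializes a full position index over any designated
sample path (the second-standard-reference use case), after which
resolution in that system is a single predecessor lookup.

One traversal subtlety: when an alt node rejoins the marker path exactly
where another variant is anchored, that variant branches off the *bypassed*
marker node, which the carrier's path never visits. The walker therefore
probes the anchor boundary when leaving any alt node, keeping paths correct
for back-to-back variants of one sample.

## Synthetic data generator

`synth.simulate` emulates a merged cohort VCF: uniformly placed, sorted
variant positions with at least one reference base between consecutive
spans; a SUB/INS/DEL mix of (0.6, 0.2, 0.2) by default; indel lengths
uniform on 1–8 bp; diploid genotypes phased with probability 0.7; and
carrier sets of mean size M drawn per variant (1 + Binomial thinning over
the roster), so high M reproduces the dense-sharing regime of
population-panel data and M near 1 the sparse regime of tumor cohorts.
Default cohort shape (100 kb / 20 samples / 500 variants — about one
variant per 200 bp, a density comparable to a human cohort chromosome) is
the standard instance for the oracle-equivalence suites; the smoke test
uses 1 Mbp / 100 samples / 10,000 variants with 1,000 sorted 42 kb windows,
the typical-gene-sized query span.

What the generator does **not** emulate: realistic allele-frequency spectra
(carrier sets are exchangeable, not coalescent), overlapping same-sample
variants (optional stress flag for construction only), multi-allelic sites
written as one record, symbolic/structural alleles, and N runs in the
reference. Passing oracle-equivalence on these instances therefore
demonstrates correctness of the coordinate arithmetic, carrier bookkeeping
and traversal — not robustness to every pathology of real cohort VCFs,
though anchor-base conventions, multi-allelic splitting and genotype
parsing are exercised against real VCF syntax via cyvcf2.

The query oracles are independent by construction: string splicing of the
flat edit list (applied right to left) and linear scans; they share no code
with the graph.

## Numerical/degenerate-input choices

* Coordinates: VCF POS is 1-based; everything internal is 0-based
  half-open; CLI/API query positions are 1-based inclusive.
* Genotypes 0/0 and ./. and symbolic alts are skipped with a warning —
  only carriers define paths. Duplicate records are kept as distinct nodes
  with a warning.
* An insertion anchored at the very end of the marker sequence attaches as
  a sink alt; anchors are otherwise always marker-node boundaries.
* Indels at position 0 (no anchor base available) are representable in the
  graph (root alt nodes) but cannot be rendered back to anchored VCF.
* Deterministic throughout: sorted JSON serialization, fixed neighbor
  order, seeded generators — identical inputs give byte-identical indexes.

## Known limitations

* Dynamic updates (adding variants to an existing index) are unsupported.
* Haplotype-resolved path queries and genotype-algebra filtering are out of
  scope.
* The interval convention excludes variants whose span overlaps a window
  from the left; callers wanting overlap semantics must widen the window.
* Sample-coordinate resolution cost degrades (gracefully) for samples with
  very sparse variants unless a per-path position index is added.
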