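# vgindex

A variation-graph index over multi-sample VCF variant data, supporting
position-range variant and sequence queries **in the coordinate system of
any sample** — with memory-bounded, chunked construction and query.

## Why

A cohort VCF fixes one reference coordinate system. But every sample's
genome has its own coordinates: each indel the sample carries shifts all
downstream positions. Questions like *"what is sample S's sequence between
positions X and Y of S's own genome?"* or *"which variants does S carry in
that window?"* need a per-sample position mapping, and storing an explicit
index per sample costs O(S·N) for S samples and N variants.

`vgindex` instead encodes the cohort as a directed acyclic **variation
graph** G = (N, E, P): nodes carry sequence slices, each sample's genome is
an embedded source→sink path, and the position of a node on a path p = n₁…nₚ
is P(nₚ) = Σᵢ₌₁^{p−1} |seq(nᵢ)|. A rank-supported bit-vector **position
index** is kept only for a designated *marker* path (the reference);
positions in any other sample's system are recovered by a short local graph
search from the marker predecessor node. Each variant node stores its
carrier set once, deduplicated into *sample classes* (two variants are
equivalent iff the same samples carry them), so index size scales as
O(N·M) for a mean of M carriers per variant — independent of how many
coordinate systems are queryable. Node records are serialized in
compressed, position-ordered chunks of which at most two are ever
memory-resident.

Supported queries (1-based inclusive positions):

| query | meaning |
|---|---|
| `ClosestVar(R; X)` | variant nearest to X in marker coordinates |
| `Seq(R,S; X,Y)` | sample S's sequence, window in marker coordinates |
| `Seq(S; X,Y)` | sample S's sequence, window in S's own coordinates |
| `Vars(R,S; X,Y)` | S's variants, window in marker coordinates |
| `Vars(S; X,Y)` | S's variants, window in S's own coordinates |
| `AllVars(R; X,Y)` | all variants in the window, with carriers and phasing |

## Worked example

A 14 bp reference `CAATTTGCTGATCT` and three variants over samples
HG00096, HG00101, HG00103 — a substitution A→G at position 2 (carried by
HG00101 and HG00103), a deletion AATT→A at position 2 (HG00096), and an
insertion T→TACG at position 6 (HG00103):

```
$ vgindex construct tests/data/worked_example.fa tests/data/worked_example.vcf /tmp/idx
built 1 chromosome index(es) in 0.01s under /tmp/idx

$ vgindex stats /tmp/idx
chrom       ref
ref_len     14
n_nodes     8
n_edges     10
n_variants  3
n_classes   4
...
```

The graph has 8 nodes — marker path `[C][A][ATT][T][GCTGATCT]` plus alt
nodes `G`, a zero-length deletion node, and `ACG` — and 10 edges; the 4
classes are the three distinct carrier sets plus the reserved empty class.

```
$ vgindex query /tmp/idx --type all-vars --begin 1 --end 14
#start0 ref_span  alt_seq  type  carriers
1       A         G        SUB   HG00101:1:0|1;HG00103:1:0|1
2       ATT       -        DEL   HG00096:2:1|0
6       -         ACG      INS   HG00103:6:0|1
```

Each carrier entry is `sample:position-in-that-sample:genotype`. Sequence
queries resolve coordinates per sample — the deletion carrier's sequence in
marker window 1–6 drops the deleted bases:

```
$ vgindex query /tmp/idx --type seq-ref --sample HG00096 --begin 1 --end 6
>HG00096:1-6
CAT

$ vgindex query /tmp/idx --type seq-sample --sample HG00103 --begin 1 --end 17
>HG00103:1-17
CGATTTACGGCTGATCT
```

`CGATTTACGGCTGATCT` is exactly the reference with the G substitution and
the ACG insertion spliced in. The same calls are available as a library:

```python
from vgindex import build_index, VariantIndex
dirs = build_index("ref.fa", "cohort.vcf", "idx/")
idx = VariantIndex.open(dirs[0])
idx.sequence("HG00096", 1, 6)            # 'CAT'
idx.all_variants(1, 14)                  # three VariantHit records
idx.closest_variant(10).marker_start0    # 6  (the insertion)
idx.add_path_index("HG00103")            # index a second coordinate system
```

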