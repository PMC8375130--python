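"""Query engine over a serialized variation-graph index.

Opening an index loads the graph topology, sample-class table, position
index(es) and 3-bit sequence buffer into memory; node records stay on disk in
compressed chunks and are fetched lazily with at most two chunks resident.

Every query starts with a predecessor search in a position index (rank on
the position-bv), then a bounded traversal:

* marker-coordinate queries start directly at the predecessor node;
* sample-coordinate queries run a local search: scan backward from the
  predecessor for the sample's nearest alt node with a stored sample
  position at or before the target (the anchor), then walk the sample path
  forward accumulating node lengths until the target position is reached.
  If a position index was added for that sample's path, the local search is
  skipped entirely.

Batch queries are executed in ascending start-position order so chunk loads
stay monotone, and results are returned in input order.

Public positions are 1-based inclusive (VCF convention); internals are
0-based half-open.
"""

from __future__ import annotations

import enum
import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from . import formats
from .chunk_store import ChunkStore
from .graph import (
    ABSENT,
    GraphNode,
    GraphTopology,
    SampleClassTable,
    SequenceBuffer,
    decode_phase,
    tuple_for_sample,
)
from .position_index import MARKER, PositionIndex

log = logging.getLogger(__name__)


class QueryType(str, enum.Enum):
    CLOSEST_VAR = "closest-var"   # ClosestVar(R; X)
    SEQ_REF = "seq-ref"           # Seq(R, S; X, Y)
    SEQ_SAMPLE = "seq-sample"     # Seq(S; X, Y)
    VARS_REF = "vars-ref"         # Vars(R, S; X, Y)
    VARS_SAMPLE = "vars-sample"   # Vars(S; X, Y)
    ALL_VARS = "all-vars"         # AllVars(R; X, Y)


@dataclass(frozen=True)
class QuerySpec:
    qtype: QueryType
    begin1: int
    end1: int | None = None
    sample: str | None = None
    coord_path: str = MARKER

    def __post_init__(self):
        if self.end1 is not None and self.begin1 > self.end1:
            raise ValueError(f"begin {self.begin1} > end {self.end1}")
        if self.qtype in (QueryType.SEQ_REF, QueryType.SEQ_SAMPLE,
                          QueryType.VARS_REF, QueryType.VARS_SAMPLE) and not self.sample:
            raise ValueError(f"{self.qtype.value} requires a sample name")


@dataclass
class VariantHit:
    """One variant: the alt node plus its carriers and their coordinates."""

    node_id: int
    marker_start0: int
    ref_span: str
    alt_seq: str
    vtype: object
    carriers: tuple[str, ...]
    tuples: list[tuple[int, bool, int, int]]  # (sample_pos0, phased, allele0, allele1)

    def key(self) -> tuple:
        return (self.marker_start0, len(self.ref_span), self.alt_seq)

    def sample_pos0(self, sample: str) -> int:
        return self.tuples[self.carriers.index(sample)][0]


@dataclass
class Resolution:
    """Result of mapping a path position to a graph node."""

    node: GraphNode
    offset: int      # 0-based offset of the queried position inside the node
    path_pos: int    # path-coordinate position of the node's first base
    visits: int      # nodes inspected during the local search


class VariantIndex:
    """Read-only handle on one chromosome's index directory."""

    def __init__(self, chrom_dir: Path):
        self.chrom_dir = Path(chrom_dir)
        self.manifest = formats.read_manifest(self.chrom_dir)
        codec = self.manifest["codec"]
        self.chrom: str = self.manifest["chrom"]
        self.ref_len: int = self.manifest["ref_len"]
        self.topology = GraphTopology.from_dict(
            formats.load_zjson(self.chrom_dir / "topology.bin", codec)
        )
        self.classes = SampleClassTable.from_dict(
            json.loads((self.chrom_dir / "classes.json").read_text())
        )
        self.seqbuf = SequenceBuffer.from_bytes(
            (self.chrom_dir / "seqbuf.bin").read_bytes(), self.manifest["seqbuf_len"]
        )
        self.store = ChunkStore.open(self.chrom_dir, self.manifest)
        self.pos_indexes: dict[str, PositionIndex] = {
            name: PositionIndex.load(self.chrom_dir / "posidx", name, codec)
            for name in self.manifest["path_indexes"]
        }
        self.sample_deltas: dict[str, int] = self.manifest["sample_deltas"]
        self._last_resolution: Resolution | None = None

    @classmethod
    def open(cls, chrom_dir) -> "VariantIndex":
        return cls(chrom_dir)

    # -- basics ------------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return self.classes.sample_names

    @property
    def marker_index(self) -> PositionIndex:
        return self.pos_indexes[MARKER]

    def marker_seq(self) -> str:
        return self.seqbuf.slice(0, self.ref_len)

    def node(self, node_id: int) -> GraphNode:
        return self.store.get_node(node_id)

    def path_length(self, coord_path: str) -> int:
        if coord_path == MARKER:
            return self.ref_len
        if coord_path not in self.sample_deltas:
            raise KeyError(f"unknown sample {coord_path!r}")
        return self.ref_len + self.sample_deltas[coord_path]

    def stats(self) -> dict:
        return {
            "chrom": self.chrom,
            "ref_len": self.ref_len,
            "n_nodes": self.manifest["n_nodes"],
            "n_edges": self.manifest["n_edges"],
            "n_variants": self.manifest["n_variants"],
            "n_classes": self.manifest["n_classes"],
            "n_samples": len(self.samples),
            "n_chunks": self.manifest["n_chunks"],
            "chunk_capacity": self.manifest["chunk_capacity"],
            "path_indexes": sorted(self.pos_indexes),
        }

    # -- anchors and branches ----------------------------------------------

    def _alts_at_boundary(self, k: int) -> list[GraphNode]:
        """Alt nodes anchored at boundary index ``k`` of starts + [ref_len].

        k == 0: alts with no marker predecessor (anchored at position 0);
        k == len(starts): alts branching off the last marker node (anchored
        at the end of the marker sequence); otherwise alts hanging off the
        marker node that ends at ``starts[k]``.
        """
        if k == 0:
            ids = self.topology.root_alt_ids
        else:
            pred = int(self.marker_index.node_ids[k - 1])
            ids = self.topology.out_neighbors(pred)
        alts = []
        for nid in ids:
            n = self.node(nid)
            if n.is_alt:
                alts.append(n)
        return alts

    def _hit(self, n: GraphNode) -> VariantHit:
        ref_len = n.ref_len or 0
        return VariantHit(
            node_id=n.node_id,
            marker_start0=n.marker_pos0,
            ref_span=self.seqbuf.slice(n.marker_pos0, ref_len),
            alt_seq=self.seqbuf.slice(n.seq_offset, n.seq_len),
            vtype=n.vtype,
            carriers=self.classes.members(n.sample_class_id),
            tuples=[(p, *decode_phase(b)) for p, b in n.sample_tuples],
        )

    # -- path traversal ------------------------------------------------------

    def next_on_path(self, node_id: int, sample: str) -> int | None:
        """Successor of ``node_id`` on ``sample``'s path.

        Among out-neighbors the first alt node whose class contains the
        sample wins; otherwise the marker successor.  Returns None at a sink.
        """
        n = self._step(self.node(node_id), sample)
        return None if n is None else n.node_id

    def _step(self, n: GraphNode, sample: str) -> GraphNode | None:
        if n.is_alt:
            # a variant anchored exactly where this alt rejoins the marker
            # path branches off the *bypassed* marker node, so probe the
            # anchor boundary before resuming on the marker successor
            e = n.marker_pos0 + (n.ref_len or 0)
            for alt in self._alts_at_anchor_pos(e):
                if alt.node_id > n.node_id and self.classes.contains(
                    alt.sample_class_id, sample
                ):
                    return alt
            nbs = self.topology.out_neighbors(n.node_id)
            if not nbs:
                return None
            succ = self.node(nbs[-1])
            return succ if succ.is_marker else None
        nbs = self.topology.out_neighbors(n.node_id)
        chosen_marker = None
        for nid in nbs:
            nb = self.node(nid)
            if nb.is_alt:
                if self.classes.contains(nb.sample_class_id, sample):
                    return nb
            else:
                chosen_marker = nb
        return chosen_marker

    def _alts_at_anchor_pos(self, anchor: int) -> list[GraphNode]:
        starts = self.marker_index.starts
        if anchor >= self.ref_len:
            return self._alts_at_boundary(len(starts))
        k = bisect_right(starts, anchor) - 1
        if k < 0 or starts[k] != anchor:
            return []
        return self._alts_at_boundary(k)

    def path_start(self, sample: str) -> GraphNode:
        """First node on a sample's path: a carried root alt, else the source."""
        for nid in self.topology.root_alt_ids:
            n = self.node(nid)
            if self.classes.contains(n.sample_class_id, sample):
                return n
        return self.node(self.topology.source_id)

    # -- position resolution -------------------------------------------------

    def resolve_position(self, coord_path: str, pos0: int) -> Resolution:
        """Map a 0-based position in ``coord_path``'s system to a graph node."""
        plen = self.path_length(coord_path)
        if not 0 <= pos0 < plen:
            raise IndexError(
                f"position {pos0} outside [0, {plen}) of {coord_path} coordinates"
            )
        if coord_path in self.pos_indexes:
            nid, start = self.pos_indexes[coord_path].predecessor(pos0)
            res = Resolution(self.node(nid), pos0 - start, start, visits=1)
            self._last_resolution = res
            return res
        return self._resolve_by_local_search(coord_path, pos0)

    def _resolve_by_local_search(self, sample: str, t: int) -> Resolution:
        anchor, visits = self._nearest_anchor(sample, t)
        if anchor is None:
            # identity region: no sample variant precedes t on the path
            nid, start = self.marker_index.predecessor(t)
            res = Resolution(self.node(nid), t - start, start, visits + 1)
            self._last_resolution = res
            return res
        cur_pos = tuple_for_sample(anchor, self.classes, sample)[0]
        n = anchor
        while True:
            visits += 1
            if n.seq_len > 0 and cur_pos <= t < cur_pos + n.seq_len:
                res = Resolution(n, t - cur_pos, cur_pos, visits)
                self._last_resolution = res
                return res
            cur_pos += n.seq_len
            n = self._step(n, sample)
            if n is None:
                raise IndexError(f"position {t} beyond the end of {sample}'s path")

    def _nearest_anchor(self, sample: str, t: int) -> tuple[GraphNode | None, int]:
        """Sample's path-latest alt node with stored position ≤ t, by scanning
        anchor boundaries backward from the marker predecessor of t."""
        starts = self.marker_index.starts
        g = min(t, self.ref_len)
        k = int(bisect_right(starts, g))  # boundaries with value ≤ g are starts[:k]
        visits = 0
        for j in range(k, -1, -1):
            for alt in reversed(self._alts_at_boundary(j)):
                visits += 1
                tup = tuple_for_sample(alt, self.classes, sample)
                if tup is not ABSENT and tup[0] <= t:
                    return alt, visits
        return None, visits

    # -- queries ---------------------------------------------------------------

    def closest_variant(self, pos1: int) -> VariantHit | None:
        """Variant whose marker anchor is nearest to pos1; ties toward the
        smaller position.  None when the index holds no variants."""
        pos0 = pos1 - 1
        if not 0 <= pos0 < self.ref_len:
            raise IndexError(f"position {pos1} outside [1, {self.ref_len}]")
        starts = self.marker_index.starts
        n_b = len(starts) + 1  # + the end boundary
        k0 = bisect_right(starts, pos0)  # first boundary index with anchor > pos0
        left = right = None
        for j in range(k0 - 1, -1, -1):
            alts = self._alts_at_boundary(j)
            if alts:
                left = min(alts, key=lambda a: a.node_id)
                break
        for j in range(k0, n_b):
            anchor = starts[j] if j < len(starts) else self.ref_len
            if left is not None and anchor - pos0 > pos0 - left.marker_pos0:
                break
            alts = self._alts_at_boundary(j)
            if alts:
                right = min(alts, key=lambda a: a.node_id)
                break
        if left is None and right is None:
            return None
        if right is None:
            best = left
        elif left is None:
            best = right
        else:
            dl, dr = pos0 - left.marker_pos0, right.marker_pos0 - pos0
            best = left if dl <= dr else right
        return self._hit(best)

    def all_variants(self, begin1: int, end1: int) -> list[VariantHit]:
        """Every variant with marker anchor in [begin1, end1] (AllVars)."""
        b0, e0 = self._check_range(MARKER, begin1, end1)
        starts = self.marker_index.starts
        lo = int(bisect_right(starts, b0 - 1)) if b0 > 0 else 0
        hi = int(bisect_right(starts, e0))
        hits = []
        for j in range(lo, hi):
            for alt in self._alts_at_boundary(j):
                hits.append(self._hit(alt))
        hits.sort(key=lambda h: (h.marker_start0, h.node_id))
        return hits

    def variants(self, sample: str, begin1: int, end1: int, coord_path: str = MARKER) -> list[VariantHit]:
        """Variants carried by ``sample`` in the range (Vars(R,S) / Vars(S))."""
        if sample not in self.sample_deltas:
            raise KeyError(f"unknown sample {sample!r}")
        if coord_path == MARKER:
            self._check_range(MARKER, begin1, end1)
            return [h for h in self.all_variants(begin1, end1) if sample in h.carriers]
        if coord_path != sample:
            b0, e0 = self._translate_range(coord_path, begin1, end1)
            return [
                h for h in self.all_variants(b0 + 1, e0 + 1) if sample in h.carriers
            ]
        b0, e0 = self._check_range(sample, begin1, end1)
        hits = []
        # start one base early so zero-length deletion nodes sitting exactly
        # at b0 (they precede the node that contains b0) are not skipped
        if b0 == 0:
            n, cur = self.path_start(sample), 0
        else:
            res = self.resolve_position(sample, b0 - 1)
            n, cur = res.node, res.path_pos
        while n is not None and cur <= e0:
            if n.is_alt:
                tup = tuple_for_sample(n, self.classes, sample)
                if tup is not ABSENT and b0 <= tup[0] <= e0:
                    hits.append(self._hit(n))
            cur += n.seq_len
            n = self._step(n, sample)
        hits.sort(key=lambda h: (h.sample_pos0(sample), h.node_id))
        return hits

    def sequence(self, sample: str, begin1: int, end1: int, coord_path: str = MARKER) -> str:
        """Sample sequence in the range (Seq(R,S) / Seq(S))."""
        if sample not in self.sample_deltas:
            raise KeyError(f"unknown sample {sample!r}")
        if coord_path == MARKER:
            b0, e0 = self._check_range(MARKER, begin1, end1)
            return self._sequence_marker_coords(sample, b0, e0)
        if coord_path != sample:
            b0, e0 = self._translate_range(coord_path, begin1, end1)
            return self._sequence_marker_coords(sample, b0, e0)
        b0, e0 = self._check_range(sample, begin1, end1)
        res = self.resolve_position(sample, b0)
        pieces: list[str] = []
        n, cur = res.node, res.path_pos
        while n is not None and cur <= e0:
            if n.seq_len:
                lo = max(b0 - cur, 0)
                hi = min(e0 - cur + 1, n.seq_len)
                if hi > lo:
                    pieces.append(self.seqbuf.slice(n.seq_offset + lo, hi - lo))
            cur += n.seq_len
            n = self._step(n, sample)
        return "".join(pieces)

    def _sequence_marker_coords(self, sample: str, b0: int, e0: int) -> str:
        n = self._marker_walk_start(sample, b0)
        pieces: list[str] = []
        while n is not None:
            if n.is_marker:
                s = n.marker_pos0
                if s > e0:
                    break
                lo = max(b0 - s, 0)
                hi = min(e0 - s + 1, n.seq_len)
                if hi > lo:
                    pieces.append(self.seqbuf.slice(n.seq_offset + lo, hi - lo))
                if s + n.seq_len > e0:
                    break
            else:
                # alt detours are emitted in full between marker boundaries
                if n.marker_pos0 >= b0 and n.seq_len:
                    pieces.append(self.seqbuf.slice(n.seq_offset, n.seq_len))
            n = self._step(n, sample)
        return "".join(pieces)

    def _marker_walk_start(self, sample: str, b0: int) -> GraphNode:
        """Node at which the marker-coordinate walk of a sample path enters
        the query window: the sample's bypassing/insertion alt at b0 if any,
        else the marker predecessor of b0."""
        nid, start = self.marker_index.predecessor(b0)
        starts = self.marker_index.starts
        k = int(bisect_right(starts, b0))  # boundaries with anchor <= b0 are < k
        for j in range(k - 1, -1, -1):
            for alt in self._alts_at_boundary(j):
                if not self.classes.contains(alt.sample_class_id, sample):
                    continue
                a, span_end = alt.marker_pos0, alt.marker_pos0 + (alt.ref_len or 0)
                if a > b0:
                    continue
                if span_end > b0 or a == b0:
                    return alt  # sample bypasses b0, or inserts right before it
                return self.node(nid)  # nearest sample alt ends before b0
        return self.node(nid)

    # -- range plumbing -----------------------------------------------------

    def _check_range(self, coord_path: str, begin1: int, end1: int) -> tuple[int, int]:
        plen = self.path_length(coord_path)
        if not 1 <= begin1 <= end1 <= plen:
            raise IndexError(
                f"range [{begin1}, {end1}] outside [1, {plen}] of {coord_path} coordinates"
            )
        return begin1 - 1, end1 - 1

    def _translate_range(self, coord_path: str, begin1: int, end1: int) -> tuple[int, int]:
        """Translate a range in another sample's coordinates to marker coords."""
        b0, e0 = self._check_range(coord_path, begin1, end1)
        rb = self.resolve_position(coord_path, b0)
        re_ = self.resolve_position(coord_path, e0)
        mb = rb.node.marker_pos0 + (rb.offset if rb.node.is_marker else 0)
        me = re_.node.marker_pos0 + (re_.offset if re_.node.is_marker else 0)
        return mb, max(mb, me)

    # -- batch ----------------------------------------------------------------

    def run_query(self, spec: QuerySpec):
        qt = spec.qtype
        if qt == QueryType.CLOSEST_VAR:
            return self.closest_variant(spec.begin1)
        if spec.end1 is None:
            raise ValueError(f"{qt.value} requires an end position")
        if qt == QueryType.ALL_VARS:
            return self.all_variants(spec.begin1, spec.end1)
        coord = spec.coord_path
        if qt in (QueryType.SEQ_SAMPLE, QueryType.VARS_SAMPLE) and coord == MARKER:
            coord = spec.sample
        if qt in (QueryType.SEQ_REF, QueryType.SEQ_SAMPLE):
            return self.sequence(spec.sample, spec.begin1, spec.end1, coord)
        return self.variants(spec.sample, spec.begin1, spec.end1, coord)

    def run_batch(self, specs: list[QuerySpec]) -> list:
        """Execute specs sorted by start position; results in input order.

        Invalid specs yield an exception object in their slot instead of
        aborting the batch.
        """
        order = sorted(range(len(specs)), key=lambda i: specs[i].begin1)
        results: list = [None] * len(specs)
        for i in order:
            try:
                results[i] = self.run_query(specs[i])
            except (IndexError, KeyError, ValueError) as exc:
                log.warning("query %d failed: %s", i, exc)
                results[i] = exc
        return results

    # -- extra path indexes ----------------------------------------------------

    def add_path_index(self, path_name: str) -> bool:
        """Build and persist a position index over a sample's path.

        Returns True if a new index was written, False for a no-op (MARKER or
        an already-indexed path).  Idempotent.
        """
        if path_name == MARKER:
            log.warning("MARKER is always indexed; nothing to do")
            return False
        if path_name not in self.sample_deltas:
            raise KeyError(f"unknown sample {path_name!r}")
        if path_name in self.pos_indexes:
            return False
        starts, ids = [], []
        n = self.path_start(path_name)
        cur = 0
        while n is not None:
            if n.seq_len > 0:
                starts.append(cur)
                ids.append(n.node_id)
            cur += n.seq_len
            n = self._step(n, path_name)
        idx = PositionIndex.from_starts(path_name, cur, starts, ids)
        idx.save(self.chrom_dir / "posidx", self.manifest["codec"])
        self.pos_indexes[path_name] = idx
        self.manifest["path_indexes"] = sorted(set(self.manifest["path_indexes"]) | {path_name})
        formats.write_manifest(self.chrom_dir, {
            k: v for k, v in self.manifest.items() if k not in ("magic", "version")
        })
        return True
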