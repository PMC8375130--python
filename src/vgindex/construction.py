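"""Two-phase variation-graph construction.

Phase 1 inserts variants (which must arrive sorted by marker start) by
splitting marker-path nodes at the edit boundaries and wiring an alt node —
zero-length for deletions — from the marker node ending at the edit start to
the marker node starting at the end of the replaced span.  Only marker
positions are maintained; computing each carrier's position at insertion time
would require backtracking along that sample's path for every carrier of
every variant.

Phase 2 makes a single pass over the nodes in marker-position order (a
topological order of the DAG) carrying a per-sample *delta*: the running
difference between the sample's coordinate and the marker coordinate,
updated by |alt| - |replaced span| at each of the sample's variants.  At each
alt node every carrier's position is marker_pos0 + delta, after which the
carrier's delta absorbs the node's length change.  This replaces per-variant
backtracking with one linear sweep.

Finally nodes are renumbered so ids strictly increase in the sweep order,
which makes chunk ranges coordinate-aligned, and the whole index is
serialized.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right, insort
from dataclasses import dataclass, field
from pathlib import Path

from . import formats
from .chunk_store import DEFAULT_CHUNK_CAPACITY, ChunkWriter
from .graph import (
    GraphNode,
    GraphTopology,
    SampleClassTable,
    SequenceBuffer,
    VType,
)
from .position_index import PositionIndex, build_marker_index
from .vcf_io import NormalizedVariant, list_chromosomes, read_normalized, read_reference

log = logging.getLogger(__name__)


@dataclass
class IndexConfig:
    """Build-time knobs."""

    chunk_capacity: int = DEFAULT_CHUNK_CAPACITY
    codec: str = "zlib"

    def __post_init__(self) -> None:
        if self.chunk_capacity < 1:
            raise ValueError("chunk_capacity must be >= 1")
        if self.codec not in formats.CODECS:
            raise ValueError(f"codec must be one of {formats.CODECS}")


@dataclass
class GraphBuilder:
    """In-memory builder state for one chromosome."""

    seqbuf: SequenceBuffer
    topology: GraphTopology
    classes: SampleClassTable
    nodes: dict[int, GraphNode] = field(default_factory=dict)
    # marker path as parallel sorted start list + start -> node id map
    _starts: list[int] = field(default_factory=list)
    _start_map: dict[int, int] = field(default_factory=dict)
    ref_len: int = 0
    _next_id: int = 0
    _last_start0: int = -1
    sample_deltas: dict[str, int] = field(default_factory=dict)
    finalized: bool = False

    # -- phase 0 -----------------------------------------------------------

    @classmethod
    def init_graph(cls, marker_seq: str, sample_names: list[str]) -> "GraphBuilder":
        """Single-node graph over the linear marker sequence."""
        if not marker_seq:
            raise ValueError("marker sequence is empty")
        b = cls(
            seqbuf=SequenceBuffer(),
            topology=GraphTopology(),
            classes=SampleClassTable(sample_names),
        )
        b.seqbuf.append(marker_seq)
        b.ref_len = len(marker_seq)
        nid = b._new_node(
            seq_offset=0, seq_len=len(marker_seq), marker_pos0=0, is_marker=True
        )
        b.topology.source_id = nid
        b._starts.append(0)
        b._start_map[0] = nid
        return b

    def _new_node(self, **kw) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = GraphNode(node_id=nid, **kw)
        self.topology.node_count = self._next_id
        return nid

    # -- phase 1 -----------------------------------------------------------

    def _split(self, pos0: int) -> None:
        """Ensure a marker-node boundary at ``pos0`` (reused if present)."""
        if pos0 <= 0 or pos0 >= self.ref_len or pos0 in self._start_map:
            return
        i = bisect_right(self._starts, pos0) - 1
        a = self._starts[i]
        left = self.nodes[self._start_map[a]]
        head_len = pos0 - a
        right_id = self._new_node(
            seq_offset=left.seq_offset + head_len,
            seq_len=left.seq_len - head_len,
            marker_pos0=pos0,
            is_marker=True,
        )
        # the tail inherits everything that followed the original node
        self.topology.set_out(right_id, self.topology.out_neighbors(left.node_id))
        self.topology.set_out(left.node_id, [right_id])
        left.seq_len = head_len
        insort(self._starts, pos0)
        self._start_map[pos0] = right_id

    def insert_variant(self, nv: NormalizedVariant) -> int:
        """Phase-1 insertion; returns the new alt node id."""
        if self.finalized:
            raise RuntimeError("graph already finalized")
        if nv.start0 < self._last_start0:
            raise ValueError(
                f"variants must arrive sorted by start: {nv.start0} after {self._last_start0}"
            )
        end0 = nv.start0 + nv.ref_len
        if end0 > self.ref_len:
            raise ValueError(
                f"variant span [{nv.start0}, {end0}) extends past reference end {self.ref_len}"
            )
        self._last_start0 = nv.start0
        self._split(nv.start0)
        self._split(end0)

        class_id = self.classes.get_or_add(nv.calls.keys())
        alt_seq_offset = self.seqbuf.append(nv.alt_seq)
        alt_id = self._new_node(
            seq_offset=alt_seq_offset,
            seq_len=len(nv.alt_seq),
            marker_pos0=nv.start0,
            is_marker=False,
            vtype=nv.vtype,
            sample_class_id=class_id,
            ref_len=nv.ref_len,
        )
        # phase-2 placeholders: phase bits now, sample positions later
        phase_by_sample = {s: c.phase_bits for s, c in nv.calls.items()}
        self.nodes[alt_id].sample_tuples = [
            (-1, phase_by_sample[s]) for s in self.classes.members(class_id)
        ]

        if nv.start0 == 0:
            self.topology.root_alt_ids.append(alt_id)
        else:
            pred_start = self._starts[bisect_right(self._starts, nv.start0 - 1) - 1]
            pred = self._start_map[pred_start]
            self.topology.insert_before_last(pred, alt_id)
        if end0 < self.ref_len:
            self.topology.set_out(alt_id, [self._start_map[end0]])
        # else: the alt reaches the end of the marker sequence and is a sink
        return alt_id

    # -- phase 2 -----------------------------------------------------------

    def _sweep_order(self) -> list[int]:
        """Node ids in marker-position order, alts before the co-located marker
        node, creation order breaking remaining ties."""
        return sorted(
            self.nodes, key=lambda i: (self.nodes[i].marker_pos0, self.nodes[i].is_marker, i)
        )

    def propagate_sample_positions(self) -> None:
        """Phase 2: fill per-carrier positions via the delta sweep."""
        delta = {s: 0 for s in self.classes.sample_names}
        order = self._sweep_order()
        seen_key = None
        for nid in order:
            n = self.nodes[nid]
            key = (n.marker_pos0, n.is_marker, nid)
            if seen_key is not None and key < seen_key:
                raise RuntimeError("cycle or order violation in variation graph")
            seen_key = key
            if n.is_marker:
                continue
            members = self.classes.members(n.sample_class_id)
            shift = n.seq_len - (n.ref_len or 0)
            n.sample_tuples = [
                (n.marker_pos0 + delta[s], bits)
                for s, (_, bits) in zip(members, n.sample_tuples)
            ]
            for s in members:
                delta[s] += shift
        self.sample_deltas = delta

    # -- finalize ----------------------------------------------------------

    def renumber_and_finalize(self) -> list[GraphNode]:
        """Relabel ids to the sweep order; returns nodes sorted by new id."""
        order = self._sweep_order()
        old_to_new = {old: new for new, old in enumerate(order)}
        self.topology = self.topology.remap(old_to_new)
        renumbered: dict[int, GraphNode] = {}
        for old, node in self.nodes.items():
            node.node_id = old_to_new[old]
            renumbered[node.node_id] = node
        self.nodes = renumbered
        self._start_map = {p: old_to_new[i] for p, i in self._start_map.items()}
        self.finalized = True
        return [self.nodes[i] for i in range(len(self.nodes))]

    # -- convenience -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.topology.edge_count

    def marker_node_ids(self) -> list[int]:
        return [self._start_map[p] for p in self._starts]

    def get_node(self, nid: int) -> GraphNode:
        return self.nodes[nid]


def build_chromosome(
    marker_seq: str,
    variants,
    sample_names: list[str],
    chrom_dir: Path,
    chrom: str,
    config: IndexConfig | None = None,
) -> dict:
    """Build and serialize one chromosome index; returns its manifest."""
    config = config or IndexConfig()
    builder = GraphBuilder.init_graph(marker_seq, sample_names)
    n_variants = 0
    for nv in variants:
        builder.insert_variant(nv)
        n_variants += 1
    builder.propagate_sample_positions()
    nodes = builder.renumber_and_finalize()

    chrom_dir = Path(chrom_dir)
    chrom_dir.mkdir(parents=True, exist_ok=True)
    writer = ChunkWriter(chrom_dir / "chunks", config.chunk_capacity, config.codec)
    for node in nodes:
        writer.append(node)
    chunk_meta = writer.close()

    marker_index = build_marker_index(builder)
    marker_index.save(chrom_dir / "posidx", config.codec)

    (chrom_dir / "seqbuf.bin").write_bytes(builder.seqbuf.to_bytes())
    formats.dump_zjson(builder.topology.to_dict(), chrom_dir / "topology.bin", config.codec)
    (chrom_dir / "classes.json").write_text(
        json.dumps(builder.classes.to_dict(), sort_keys=True)
    )
    meta = {
        "chrom": chrom,
        "ref_len": builder.ref_len,
        "seqbuf_len": builder.seqbuf.total_len,
        "n_edges": builder.n_edges,
        "n_variants": n_variants,
        "n_classes": builder.classes.n_classes,
        "samples": builder.classes.sample_names,
        "sample_deltas": builder.sample_deltas,
        "path_indexes": ["MARKER"],
        "max_resident_chunks_build": writer.stats.max_resident,
        **chunk_meta,
    }
    formats.write_manifest(chrom_dir, meta)
    return meta


def build_index(ref_fasta, vcf_path, out_dir, config: IndexConfig | None = None) -> list[Path]:
    """Build one index directory per chromosome present in the VCF.

    Runs parse -> normalize -> phase 1 -> phase 2 -> renumber -> position
    index -> serialize for each chromosome and returns the directories built.
    """
    config = config or IndexConfig()
    out_dir = Path(out_dir)
    built: list[Path] = []
    chroms = list_chromosomes(vcf_path)
    if not chroms:  # header-only VCF: index every reference chromosome, no variants
        from pyfaidx import Fasta

        chroms = list(Fasta(str(ref_fasta), rebuild=False).keys())
    for chrom in chroms:
        marker_seq = read_reference(ref_fasta, chrom)
        chrom_dir = out_dir / chrom
        variants = read_normalized(vcf_path, chrom, marker_seq)
        names = _sample_names(vcf_path)
        meta = build_chromosome(marker_seq, variants, names, chrom_dir, chrom, config)
        log.info(
            "built %s: %d nodes, %d edges, %d classes, %d chunks",
            chrom, meta["n_nodes"], meta["n_edges"], meta["n_classes"], meta["n_chunks"],
        )
        built.append(chrom_dir)
    if not built:
        raise ValueError(f"no records found in {vcf_path}")
    return built


def _sample_names(vcf_path) -> list[str]:
    from cyvcf2 import VCF

    return list(VCF(str(vcf_path)).samples)
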