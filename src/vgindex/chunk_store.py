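"""Position-ordered, compressed node-record chunks with bounded residency.

Node records dominate index space, so they are kept on disk in chunks of a
configurable number of nodes (default 200,000) and loaded lazily.  Node ids
within and across chunks are strictly increasing, so sorted query batches
touch chunks in sequential order and at most two chunks are memory-resident
at any time — during construction the active chunk (and at query time the two
most recently loaded ones).  Query answers are independent of the chunk
capacity; it tunes memory only.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path

from . import _bitpack, formats
from .graph import GraphNode, VType

DEFAULT_CHUNK_CAPACITY = 200_000


def _encode_node(n: GraphNode) -> list:
    positions = [p for p, _ in n.sample_tuples]
    phases = _bitpack.pack([b for _, b in n.sample_tuples]).hex()
    return [
        n.node_id,
        n.seq_offset,
        n.seq_len,
        n.marker_pos0,
        1 if n.is_marker else 0,
        -1 if n.vtype is None else int(n.vtype),
        n.sample_class_id,
        -1 if n.ref_len is None else n.ref_len,
        positions,
        phases,
    ]


def _decode_node(rec: list) -> GraphNode:
    nid, off, slen, mpos, ism, vt, cid, rlen, positions, phases_hex = rec
    phases = _bitpack.unpack(bytes.fromhex(phases_hex), len(positions))
    return GraphNode(
        node_id=nid,
        seq_offset=off,
        seq_len=slen,
        marker_pos0=mpos,
        is_marker=bool(ism),
        vtype=None if vt < 0 else VType(vt),
        sample_class_id=cid,
        ref_len=None if rlen < 0 else rlen,
        sample_tuples=[(p, int(b)) for p, b in zip(positions, phases)],
    )


def _chunk_path(chunk_dir: Path, idx: int) -> Path:
    return chunk_dir / f"chunk_{idx:05d}.bin"


@dataclass
class ResidencyStats:
    current_resident: int = 0
    max_resident: int = 0
    loads: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.current_resident, self.max_resident, self.loads)


class ChunkWriter:
    """Construction-mode store: append nodes in final id order, flush chunks."""

    def __init__(self, chunk_dir: Path, capacity: int = DEFAULT_CHUNK_CAPACITY, codec: str = "zlib"):
        if capacity < 1:
            raise ValueError("chunk capacity must be >= 1")
        self.chunk_dir = Path(chunk_dir)
        self.chunk_dir.mkdir(parents=True, exist_ok=True)
        self.capacity = capacity
        self.codec = codec
        self._active: list[list] = []
        self._next_id = 0
        self._n_chunks = 0
        self.stats = ResidencyStats()
        self._closed = False

    def append(self, node: GraphNode) -> int:
        if self._closed:
            raise RuntimeError("store is read-only: writer already closed")
        if node.node_id != self._next_id:
            raise ValueError(
                f"nodes must be appended in id order: got {node.node_id}, expected {self._next_id}"
            )
        self._active.append(_encode_node(node))
        self.stats.current_resident = 1
        self.stats.max_resident = max(self.stats.max_resident, 1)
        self._next_id += 1
        if len(self._active) >= self.capacity:
            self._flush()
        return node.node_id

    def _flush(self) -> None:
        if not self._active:
            return
        payload = json.dumps(self._active, separators=(",", ":")).encode()
        _chunk_path(self.chunk_dir, self._n_chunks).write_bytes(
            formats.compress(payload, self.codec)
        )
        self._n_chunks += 1
        self._active = []

    def close(self) -> dict:
        """Flush the tail chunk; returns chunk metadata for the manifest."""
        self._flush()
        self._closed = True
        self.stats.current_resident = 0
        return {
            "n_chunks": self._n_chunks,
            "chunk_capacity": self.capacity,
            "n_nodes": self._next_id,
            "codec": self.codec,
        }


class ChunkStore:
    """Read-mode store: lazy chunk loading with at most two chunks resident."""

    MAX_RESIDENT = 2

    def __init__(self, chunk_dir: Path, n_nodes: int, capacity: int, n_chunks: int, codec: str = "zlib"):
        self.chunk_dir = Path(chunk_dir)
        self.n_nodes = n_nodes
        self.capacity = capacity
        self.n_chunks = n_chunks
        self.codec = codec
        self._resident: OrderedDict[int, list] = OrderedDict()
        self.stats = ResidencyStats()

    @classmethod
    def open(cls, chrom_dir: Path, manifest: dict) -> "ChunkStore":
        return cls(
            Path(chrom_dir) / "chunks",
            n_nodes=manifest["n_nodes"],
            capacity=manifest["chunk_capacity"],
            n_chunks=manifest["n_chunks"],
            codec=manifest["codec"],
        )

    def _load(self, idx: int) -> list:
        chunk = self._resident.get(idx)
        if chunk is not None:
            return chunk
        raw = formats.decompress(_chunk_path(self.chunk_dir, idx).read_bytes(), self.codec)
        chunk = json.loads(raw)
        self._resident[idx] = chunk
        while len(self._resident) > self.MAX_RESIDENT:
            self._resident.popitem(last=False)  # evict least-recently loaded
        self.stats.loads += 1
        self.stats.current_resident = len(self._resident)
        self.stats.max_resident = max(self.stats.max_resident, len(self._resident))
        return chunk

    def get_node(self, node_id: int) -> GraphNode:
        if not 0 <= node_id < self.n_nodes:
            raise KeyError(f"unknown node id {node_id}")
        chunk = self._load(node_id // self.capacity)
        return _decode_node(chunk[node_id % self.capacity])

    def residency_stats(self) -> tuple[int, int, int]:
        return self.stats.as_tuple()
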