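"""Position index: a rank-supported bit vector over one path's coordinates.

The index over a path (by default the marker sequence) is a bit vector —
the *position-bv* — of length equal to the path's sequence length, with one
set bit at the start position of every non-empty node on the path, plus a
list of those node ids in increasing path position.  RANK(j), the number of
set bits in the prefix [0..j], maps a position to its *predecessor* node: the
node whose start is the largest ≤ the queried position.  By the way marker
nodes are split during construction, the sequence at the queried position is
contained in that node.

Zero-length deletion nodes contribute no set bit (two nodes can share a start
position only if one is zero-length); they are reached by traversal from
their flanking nodes, never by direct lookup.

Rank uses fixed-size superblock prefix counts (one per 64 bytes = 512 bits)
plus a bounded in-block byte scan, so a query costs at most one block scan
regardless of position.  Only the marker index is mandatory; extra indexes
over designated sample paths (e.g. a second standard reference ingested as a
sample) can be added to skip the local graph search in that coordinate
system.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import formats

MARKER = "MARKER"

_BLOCK_BYTES = 64  # 512-bit rank superblocks


class PositionIndex:
    def __init__(self, path_name: str, length: int, bv_bytes: bytes, node_ids) -> None:
        self.path_name = path_name
        self.length = length
        self._bv = np.frombuffer(bv_bytes, dtype=np.uint8)
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        # derived: set-bit positions (= node start positions, sorted)
        bits = np.unpackbits(self._bv, bitorder="little")[:length]
        self.starts = np.flatnonzero(bits).astype(np.int64)
        if len(self.starts) != len(self.node_ids):
            raise ValueError("position-bv popcount does not match node list length")
        pad = (-len(self._bv)) % _BLOCK_BYTES
        counts = np.bitwise_count(np.concatenate([self._bv, np.zeros(pad, dtype=np.uint8)]))
        self._block_prefix = np.concatenate(
            [[0], np.cumsum(counts.reshape(-1, _BLOCK_BYTES).sum(axis=1, dtype=np.int64))]
        )
        self._byte_counts = counts[: len(self._bv)]

    def __len__(self) -> int:
        return len(self.node_ids)

    @classmethod
    def from_starts(cls, path_name: str, length: int, starts, node_ids) -> "PositionIndex":
        bits = np.zeros(length, dtype=np.uint8)
        bits[np.asarray(starts, dtype=np.int64)] = 1
        return cls(path_name, length, np.packbits(bits, bitorder="little").tobytes(), node_ids)

    def rank(self, j: int) -> int:
        """Number of set bits in the prefix [0..j] of the position-bv."""
        if not 0 <= j < self.length:
            raise IndexError(f"rank position {j} out of range [0, {self.length})")
        byte, bit = divmod(j, 8)
        block = byte // _BLOCK_BYTES
        partial = int(self._byte_counts[block * _BLOCK_BYTES : byte].sum())
        last = int(self._bv[byte]) & ((1 << (bit + 1)) - 1)
        return int(self._block_prefix[block]) + partial + int(last.bit_count())

    def predecessor(self, pos0: int) -> tuple[int, int]:
        """(node_id, node_start0) of the node whose start is the largest ≤ pos0."""
        r = self.rank(pos0)
        if r == 0:
            raise IndexError(f"no indexed node at or before position {pos0}")
        return int(self.node_ids[r - 1]), int(self.starts[r - 1])

    # -- serialization -----------------------------------------------------

    def save(self, posidx_dir: Path, codec: str = "zlib") -> None:
        posidx_dir = Path(posidx_dir)
        posidx_dir.mkdir(parents=True, exist_ok=True)
        formats.dump_zjson(
            {
                "path": self.path_name,
                "length": self.length,
                "bv": self._bv.tobytes().hex(),
                "node_ids": self.node_ids.tolist(),
            },
            posidx_dir / f"{self.path_name}.bin",
            codec,
        )

    @classmethod
    def load(cls, posidx_dir: Path, path_name: str, codec: str = "zlib") -> "PositionIndex":
        d = formats.load_zjson(Path(posidx_dir) / f"{path_name}.bin", codec)
        return cls(d["path"], d["length"], bytes.fromhex(d["bv"]), d["node_ids"])


def build_marker_index(builder) -> PositionIndex:
    """Index the marker path of a finalized (or in-build) graph.

    Follows the marker path from the source node; every marker node sets the
    bit at its start position and appends its id.
    """
    ids = builder.marker_node_ids()
    starts = [builder.get_node(i).marker_pos0 for i in ids]
    return PositionIndex.from_starts(MARKER, builder.ref_len, starts, ids)
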