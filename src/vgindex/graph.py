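"""Variation-graph data model.

A variation graph is a directed acyclic sequence graph G = (N, E, P): nodes
carry sequence slices, edges connect consecutive nodes on paths, and each
sample's genome is the concatenation of node sequences along its embedded
source-to-sink path. The position of a node on a path is the sum of the
lengths of the node sequences traversed before it, so every path induces its
own coordinate system.

Four storage components make the graph compact:

* :class:`SequenceBuffer` — one append-only 3-bit-packed nucleotide store;
  nodes reference it by (offset, length) instead of owning strings.
* :class:`GraphTopology` — sparse out-adjacency.  Variation graphs built from
  VCFs have an edge/node ratio close to 1, so a single out-neighbor is stored
  inline and only branch points pay for an indirection into a neighbor-list
  table.
* :class:`SampleClassTable` — deduplicated carrier sets.  Two variants are
  equivalent when exactly the same samples carry them; each distinct carrier
  set (a *sample class*) is stored once as a bit vector over the sample roster
  and nodes store only the class id.  This mirrors the color-class trick of
  colored de Bruijn graph tools.
* :class:`GraphNode` — the per-node record: sequence slice, marker-coordinate
  start, and (for alt nodes) the class id plus one (sample position, phasing)
  tuple per carrier, ordered by the carrier's rank in the class bit vector.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import _bitpack

ALPHABET = "ACGTN"

# 3-bit nucleotide codes; any bijection works, this one is fixed for
# reproducible serialization.
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE_OF[ord(_c)] = _i
_CHAR_OF = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class VType(enum.IntEnum):
    """Variant shape after anchor trimming."""

    SUB = 0
    INS = 1
    DEL = 2
    COMPLEX = 3


def encode_phase(phased: bool, allele0: int, allele1: int) -> int:
    """Pack per-carrier phasing metadata into 3 bits.

    bit 0: genotype was phased ('|' in the VCF GT field)
    bit 1: haplotype 0 carries the alt allele
    bit 2: haplotype 1 carries the alt allele
    """
    return int(bool(phased)) | (int(bool(allele0)) << 1) | (int(bool(allele1)) << 2)


def decode_phase(bits: int) -> tuple[bool, int, int]:
    return bool(bits & 1), (bits >> 1) & 1, (bits >> 2) & 1


class SequenceBuffer:
    """Append-only nucleotide store packed at 3 bits per base.

    The marker (reference) sequence is appended first, so marker-path nodes
    slice the region [0, reference length); alt sequences from substitutions
    and insertions follow in insertion order.
    """

    def __init__(self) -> None:
        self._buf = np.zeros(64, dtype=np.uint8)
        self.total_len = 0

    def __len__(self) -> int:
        return self.total_len

    @property
    def nbytes_packed(self) -> int:
        """Size of the minimal packed image: ceil(3 * total_len / 8) bytes."""
        return _bitpack.nbytes_for(self.total_len)

    def _ensure(self, n_codes: int) -> None:
        need = _bitpack.nbytes_for(n_codes) + 1
        if need > len(self._buf):
            cap = len(self._buf)
            while cap < need:
                cap *= 2
            grown = np.zeros(cap, dtype=np.uint8)
            grown[: len(self._buf)] = self._buf
            self._buf = grown

    def append(self, seq: str) -> int:
        """Append ``seq`` and return the offset (in bases) of its first base."""
        offset = self.total_len
        if not seq:
            return offset
        codes = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (codes == 255).any():
            bad = seq[int(np.argmax(codes == 255))]
            raise ValueError(f"illegal sequence character {bad!r}; alphabet is {ALPHABET}")
        self._ensure(self.total_len + len(seq))
        _bitpack.write_codes(self._buf, self.total_len, codes)
        self.total_len += len(seq)
        return offset

    def slice(self, offset: int, length: int) -> str:
        """Decode ``length`` bases starting at base ``offset``."""
        if offset < 0 or length < 0 or offset + length > self.total_len:
            raise IndexError(
                f"slice [{offset}, {offset + length}) out of range for buffer of {self.total_len} bases"
            )
        codes = _bitpack.read_codes(self._buf, offset, length)
        return _CHAR_OF[codes].tobytes().decode("ascii")

    def to_bytes(self) -> bytes:
        return self._buf[: self.nbytes_packed].tobytes()

    @classmethod
    def from_bytes(cls, data: bytes, total_len: int) -> "SequenceBuffer":
        sb = cls()
        buf = np.zeros(len(data) + 1, dtype=np.uint8)
        buf[: len(data)] = np.frombuffer(data, dtype=np.uint8)
        sb._buf = buf
        sb.total_len = total_len
        if _bitpack.nbytes_for(total_len) > len(data):
            raise ValueError("sequence buffer payload shorter than declared length")
        return sb


class SampleClassTable:
    """Deduplicated carrier-set bit vectors.

    Class id 0 is reserved for the empty set (marker nodes carry no samples).
    Sample rank is the sample's index in the roster, and the position of a
    carrier's tuple inside a node equals the carrier's rank among the set bits
    of the class vector.
    """

    def __init__(self, sample_names: list[str]) -> None:
        if len(set(sample_names)) != len(sample_names):
            raise ValueError("duplicate sample names")
        self.sample_names = list(sample_names)
        self._rank = {s: i for i, s in enumerate(sample_names)}
        self._classes: list[bytes] = []   # packed bit vectors, little-bit-order per byte
        self._lookup: dict[bytes, int] = {}
        self._members_cache: dict[int, tuple[str, ...]] = {}
        empty = self._pack(frozenset())
        self._classes.append(empty)
        self._lookup[empty] = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def n_classes(self) -> int:
        return len(self._classes)

    def _pack(self, sample_set) -> bytes:
        bv = np.zeros(self.n_samples, dtype=np.uint8)
        for s in sample_set:
            if s not in self._rank:
                raise KeyError(f"unknown sample {s!r}")
            bv[self._rank[s]] = 1
        return np.packbits(bv, bitorder="little").tobytes()

    def get_or_add(self, sample_set) -> int:
        """Return the class id for ``sample_set``, creating it if unseen."""
        key = self._pack(sample_set)
        cid = self._lookup.get(key)
        if cid is None:
            cid = len(self._classes)
            self._classes.append(key)
            self._lookup[key] = cid
        return cid

    def bit_vector(self, class_id: int) -> np.ndarray:
        bv = np.unpackbits(
            np.frombuffer(self._classes[class_id], dtype=np.uint8), bitorder="little"
        )
        return bv[: self.n_samples]

    def members(self, class_id: int) -> tuple[str, ...]:
        """Carrier names of a class, in sample-rank order."""
        got = self._members_cache.get(class_id)
        if got is None:
            bv = self.bit_vector(class_id)
            got = tuple(self.sample_names[i] for i in np.flatnonzero(bv))
            self._members_cache[class_id] = got
        return got

    def size(self, class_id: int) -> int:
        return len(self.members(class_id))

    def contains(self, class_id: int, sample: str) -> bool:
        i = self._rank.get(sample)
        if i is None:
            raise KeyError(f"unknown sample {sample!r}")
        return bool(self._classes[class_id][i // 8] >> (i % 8) & 1)

    def rank_in_class(self, class_id: int, sample: str) -> int | None:
        """Rank of ``sample`` among the set bits of the class, or None if absent.

        This is the index of the sample's tuple in the node's tuple list.
        """
        i = self._rank.get(sample)
        if i is None:
            raise KeyError(f"unknown sample {sample!r}")
        bv = self.bit_vector(class_id)
        if not bv[i]:
            return None
        return int(bv[:i].sum())

    def to_dict(self) -> dict:
        return {
            "samples": self.sample_names,
            "classes": [c.hex() for c in self._classes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleClassTable":
        t = cls(list(d["samples"]))
        for key_hex in d["classes"][1:]:
            key = bytes.fromhex(key_hex)
            t._lookup[key] = len(t._classes)
            t._classes.append(key)
        return t


# tuple_for_sample returns this sentinel, not an exception, when the sample is
# not in the node's class: path traversal probes alt branches with it.
ABSENT = object()


@dataclass
class GraphNode:
    """One variation-graph node.

    ``marker_pos0`` is the node's 0-based start in marker coordinates; for a
    zero-length deletion node it is the marker index at which the bypassed
    span begins.  ``ref_len`` on an alt node is the length of the marker span
    the alt branch replaces (0 for insertions); it is None on marker nodes.
    ``sample_tuples`` holds one ``(sample_pos0, phase_bits)`` pair per carrier,
    in class-rank order, filled during the second construction phase.
    """

    node_id: int
    seq_offset: int
    seq_len: int
    marker_pos0: int
    is_marker: bool
    vtype: VType | None = None
    sample_class_id: int = 0
    ref_len: int | None = None
    sample_tuples: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_alt(self) -> bool:
        return not self.is_marker


def tuple_for_sample(node: GraphNode, table: SampleClassTable, sample: str):
    """The (sample_pos0, phase_bits) tuple of ``sample`` at ``node``.

    Performs a rank on the node's class bit vector and selects the tuple at
    that rank.  Returns :data:`ABSENT` when the sample is not in the class.
    """
    r = table.rank_in_class(node.sample_class_id, sample)
    if r is None:
        return ABSENT
    return node.sample_tuples[r]


class GraphTopology:
    """Sparse out-adjacency over node ids.

    A node with a single out-neighbor stores the neighbor id inline; a node
    with two or more stores an index into a table of neighbor-id lists
    (indirection).  The original system realises this contract inside a
    counting quotient filter; any associative container with the same
    inline/indirect behavior is equivalent for query semantics.

    Neighbor order is fixed and meaningful: alt-node neighbors (in creation
    order) precede the next marker node, which makes path traversal
    deterministic.
    """

    def __init__(self) -> None:
        self._single: dict[int, int] = {}
        self._multi_ref: dict[int, int] = {}
        self._multi: list[list[int]] = []
        self.source_id: int | None = None
        self.root_alt_ids: list[int] = []  # alt nodes anchored at marker position 0
        self.node_count = 0

    @property
    def edge_count(self) -> int:
        return len(self._single) + sum(len(v) for v in self._multi)

    def has_indirection(self, node_id: int) -> bool:
        return node_id in self._multi_ref

    def out_neighbors(self, node_id: int) -> list[int]:
        if node_id in self._single:
            return [self._single[node_id]]
        if node_id in self._multi_ref:
            return list(self._multi[self._multi_ref[node_id]])
        if 0 <= node_id < self.node_count:
            return []
        raise KeyError(f"unknown node id {node_id}")

    def set_out(self, node_id: int, neighbors: list[int]) -> None:
        self._single.pop(node_id, None)
        ref = self._multi_ref.pop(node_id, None)
        if ref is not None:
            self._multi[ref] = []  # tombstone; compacted on serialization
        if len(neighbors) == 1:
            self._single[node_id] = neighbors[0]
        elif len(neighbors) > 1:
            self._multi_ref[node_id] = len(self._multi)
            self._multi.append(list(neighbors))

    def insert_before_last(self, node_id: int, new_neighbor: int) -> None:
        """Add an alt branch, keeping the marker successor in last position."""
        cur = self.out_neighbors(node_id)
        self.set_out(node_id, cur[:-1] + [new_neighbor] + cur[-1:] if cur else [new_neighbor])

    def remap(self, old_to_new: dict[int, int]) -> "GraphTopology":
        t = GraphTopology()
        for old, nb in self._single.items():
            t._single[old_to_new[old]] = old_to_new[nb]
        for old, ref in self._multi_ref.items():
            t._multi_ref[old_to_new[old]] = len(t._multi)
            t._multi.append([old_to_new[n] for n in self._multi[ref]])
        t.source_id = old_to_new[self.source_id] if self.source_id is not None else None
        t.root_alt_ids = [old_to_new[n] for n in self.root_alt_ids]
        t.node_count = self.node_count
        return t

    def to_dict(self) -> dict:
        return {
            "single": {str(k): v for k, v in sorted(self._single.items())},
            "multi": [
                [k, self._multi[ref]] for k, ref in sorted(self._multi_ref.items())
            ],
            "source": self.source_id,
            "root_alts": self.root_alt_ids,
            "node_count": self.node_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GraphTopology":
        t = cls()
        t._single = {int(k): v for k, v in d["single"].items()}
        for k, lst in d["multi"]:
            t._multi_ref[int(k)] = len(t._multi)
            t._multi.append(list(lst))
        t.source_id = d["source"]
        t.root_alt_ids = list(d["root_alts"])
        t.node_count = d["node_count"]
        return t
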