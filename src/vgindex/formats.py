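"""On-disk index format constants and helpers.

An index directory holds one subdirectory per chromosome:

    <out>/<chrom>/
        manifest.json       format magic + version, counts, sample roster
        topology.bin        zlib-compressed JSON adjacency
        classes.json        sample roster + deduplicated class bit vectors
        seqbuf.bin          3-bit-packed nucleotide buffer (raw bytes)
        chunks/chunk_*.bin  zlib-compressed JSON node records
        posidx/<path>.bin   position-bv + node-id list per indexed path

All JSON is written with sorted keys so identical inputs produce
byte-identical indexes.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

MAGIC = "vgindex"
VERSION = 1

CODECS = ("zlib", "none")


def compress(data: bytes, codec: str) -> bytes:
    if codec == "zlib":
        return zlib.compress(data, 6)
    if codec == "none":
        return data
    raise ValueError(f"unknown codec {codec!r}")


def decompress(data: bytes, codec: str) -> bytes:
    if codec == "zlib":
        return zlib.decompress(data)
    if codec == "none":
        return data
    raise ValueError(f"unknown codec {codec!r}")


def dump_zjson(obj, path: Path, codec: str = "zlib") -> None:
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    path.write_bytes(compress(payload, codec))


def load_zjson(path: Path, codec: str = "zlib"):
    return json.loads(decompress(path.read_bytes(), codec))


def write_manifest(chrom_dir: Path, meta: dict) -> None:
    meta = dict(meta)
    meta["magic"] = MAGIC
    meta["version"] = VERSION
    (chrom_dir / "manifest.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )


def read_manifest(chrom_dir: Path) -> dict:
    p = Path(chrom_dir) / "manifest.json"
    if not p.exists():
        raise FileNotFoundError(f"no index manifest at {p}")
    meta = json.loads(p.read_text())
    if meta.get("magic") != MAGIC:
        raise ValueError(f"{p} is not a {MAGIC} index")
    if meta.get("version") != VERSION:
        raise ValueError(f"unsupported index version {meta.get('version')}")
    return meta
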