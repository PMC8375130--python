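"""Packed 3-bit integer arrays.

Genomic sequences here use a five-symbol alphabet {A, C, G, T, N}, so each
character fits in 3 bits; the same packer stores per-carrier phasing triples
(phased flag + two allele bits). Codes are written little-endian into a byte
stream; a 3-bit code starting at bit offset ``p`` occupies bits ``p..p+2`` and
may straddle a byte boundary, never more than two bytes.
"""

from __future__ import annotations

import numpy as np

BITS = 3
MAX_CODE = (1 << BITS) - 1


def nbytes_for(n_codes: int) -> int:
    """Bytes needed to hold ``n_codes`` packed codes."""
    return (BITS * n_codes + 7) // 8


def write_codes(buf: np.ndarray, start_code: int, codes: np.ndarray) -> None:
    """OR ``codes`` into ``buf`` starting at code index ``start_code``.

    ``buf`` must be uint8, zero-initialized in the target region, and at least
    ``nbytes_for(start_code + len(codes)) + 1`` long (one spare byte so the
    straddling high-byte write never falls off the end).
    """
    if len(codes) == 0:
        return
    pos = BITS * start_code + BITS * np.arange(len(codes), dtype=np.int64)
    lo = pos >> 3
    sh = (pos & 7).astype(np.uint16)
    val = codes.astype(np.uint16) << sh
    np.bitwise_or.at(buf, lo, (val & 0xFF).astype(np.uint8))
    np.bitwise_or.at(buf, lo + 1, (val >> 8).astype(np.uint8))


def read_codes(buf: np.ndarray, start_code: int, n_codes: int) -> np.ndarray:
    """Gather ``n_codes`` 3-bit codes from ``buf`` starting at ``start_code``."""
    if n_codes == 0:
        return np.empty(0, dtype=np.uint8)
    pos = BITS * start_code + BITS * np.arange(n_codes, dtype=np.int64)
    lo = pos >> 3
    sh = pos & 7
    if lo[-1] + 1 >= len(buf):  # pad so the straddle gather is in-bounds
        buf = np.concatenate([buf, np.zeros(1, dtype=np.uint8)])
    pair = buf[lo].astype(np.uint16) | (buf[lo + 1].astype(np.uint16) << 8)
    return ((pair >> sh) & MAX_CODE).astype(np.uint8)


def pack(codes: np.ndarray) -> bytes:
    """Pack an array of 3-bit codes into a minimal byte string."""
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.size and codes.max() > MAX_CODE:
        raise ValueError("code does not fit in 3 bits")
    buf = np.zeros(nbytes_for(len(codes)) + 1, dtype=np.uint8)
    write_codes(buf, 0, codes)
    return buf[: nbytes_for(len(codes))].tobytes()


def unpack(data: bytes, n_codes: int) -> np.ndarray:
    """Inverse of :func:`pack`."""
    if len(data) < nbytes_for(n_codes):
        raise ValueError("packed buffer too short")
    return read_codes(np.frombuffer(data, dtype=np.uint8), 0, n_codes)
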