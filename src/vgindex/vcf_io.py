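"""Reference FASTA and multi-sample VCF input, variant normalization, output.

Coordinate conventions: VCF POS is 1-based; everything internal is 0-based,
half-open. Multi-allelic records are split into one record per alt allele.
Samples whose genotype carries no copy of the alt (0/0, ./.) are dropped from
that record's calls — only carriers define paths through the graph.

Normalization trims the longest common prefix of REF and ALT (the VCF anchor
base for indels) and classifies the remaining edit:

* SUB      ref span and alt have equal nonzero length
* INS      empty ref span, nonempty alt (start0 is the insertion point)
* DEL      nonzero ref span, empty alt
* COMPLEX  nonzero, unequal lengths (kept; encoded by the same machinery)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cyvcf2 import VCF
from pyfaidx import Fasta

from .graph import ALPHABET, VType, encode_phase

log = logging.getLogger(__name__)

_ALLOWED = set(ALPHABET)


@dataclass(frozen=True)
class GenotypeCall:
    """One carrier's genotype for one alt allele."""

    phased: bool
    allele0: int
    allele1: int
    ploidy: int = 2

    @property
    def phase_bits(self) -> int:
        return encode_phase(self.phased, self.allele0, self.allele1)


@dataclass
class VariantRecord:
    """One VCF alt allele with its carrier genotypes."""

    chrom: str
    pos1: int
    ref_allele: str
    alt_allele: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)


@dataclass
class NormalizedVariant:
    """Anchor-trimmed edit in 0-based marker coordinates.

    For an insertion, ``start0`` is the marker index before which ``alt_seq``
    is inserted; ``ref_len`` is the replaced marker span length (0 for INS)
    and ``alt_seq`` is empty for DEL.
    """

    start0: int
    ref_len: int
    alt_seq: str
    vtype: VType
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def len_delta(self) -> int:
        return len(self.alt_seq) - self.ref_len

    def key(self) -> tuple:
        return (self.start0, self.ref_len, self.alt_seq)


def read_reference(fasta_path, chrom: str) -> str:
    """Read one chromosome from a FASTA file, upper-cased.

    Characters outside {A, C, G, T, N} raise; an empty sequence raises.
    """
    fa = Fasta(str(fasta_path), rebuild=False)
    if chrom not in fa:
        raise KeyError(f"chromosome {chrom!r} not in {fasta_path}")
    seq = str(fa[chrom][:]).upper()
    if not seq:
        raise ValueError(f"chromosome {chrom!r} in {fasta_path} is empty")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"illegal reference character(s) {sorted(bad)} in {chrom!r}")
    return seq


def list_chromosomes(vcf_path) -> list[str]:
    """Chromosome names in record order of the VCF."""
    seen: list[str] = []
    for v in VCF(str(vcf_path), gts012=False):
        if v.CHROM not in seen:
            seen.append(v.CHROM)
    return seen


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt == "*"


def parse_vcf(vcf_path, chrom: str):
    """Yield :class:`VariantRecord` for ``chrom``, splitting multi-allelics.

    Records must be position-sorted within the chromosome; a GT FORMAT field
    is required.  Symbolic alts and records with no carrying sample are
    skipped with a warning.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path} has no sample columns")
    last_pos = 0
    for v in vcf:
        if v.CHROM != chrom:
            continue
        if v.POS < last_pos:
            raise ValueError(
                f"VCF not position-sorted: {v.CHROM}:{v.POS} after {chrom}:{last_pos}"
            )
        last_pos = v.POS
        if "GT" not in (v.FORMAT or ""):
            raise ValueError(f"record {v.CHROM}:{v.POS} has no GT field")
        gts = v.genotypes  # per sample: [allele0, allele1, ..., phased]
        for ai, alt in enumerate(v.ALT, start=1):
            alt = alt.upper()
            if _is_symbolic(alt):
                log.warning("skipping symbolic alt %s at %s:%d", alt, v.CHROM, v.POS)
                continue
            if not set(alt) <= _ALLOWED:
                log.warning("skipping non-nucleotide alt %s at %s:%d", alt, v.CHROM, v.POS)
                continue
            calls: dict[str, GenotypeCall] = {}
            for name, gt in zip(samples, gts):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if not alleles or not any(a == ai for a in alleles):
                    continue
                a0 = 1 if alleles[0] == ai else 0
                a1 = 1 if len(alleles) > 1 and alleles[1] == ai else 0
                calls[name] = GenotypeCall(
                    phased=bool(gt[-1]), allele0=a0, allele1=a1, ploidy=min(len(alleles), 2)
                )
            if not calls:
                log.warning("skipping %s:%d alt %s: no carrying sample", v.CHROM, v.POS, alt)
                continue
            yield VariantRecord(
                chrom=v.CHROM,
                pos1=v.POS,
                ref_allele=v.REF.upper(),
                alt_allele=alt,
                calls=calls,
            )


def normalize(record: VariantRecord, marker_seq: str) -> NormalizedVariant:
    """Trim the common prefix of REF/ALT and classify the edit.

    Verifies REF against the marker sequence at the record's position.
    """
    start0 = record.pos1 - 1
    ref, alt = record.ref_allele, record.alt_allele
    if marker_seq[start0 : start0 + len(ref)] != ref:
        raise ValueError(
            f"REF mismatch at {record.chrom}:{record.pos1}: VCF says {ref!r}, "
            f"reference has {marker_seq[start0:start0 + len(ref)]!r}"
        )
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    start0 += k
    ref_len = len(ref) - k
    alt_seq = alt[k:]
    if ref_len == 0 and not alt_seq:
        raise ValueError(f"record at {record.chrom}:{record.pos1} is identical to the reference")
    if ref_len == len(alt_seq):
        vtype = VType.SUB
    elif ref_len == 0:
        vtype = VType.INS
    elif not alt_seq:
        vtype = VType.DEL
    else:
        vtype = VType.COMPLEX
    return NormalizedVariant(
        start0=start0, ref_len=ref_len, alt_seq=alt_seq, vtype=vtype, calls=dict(record.calls)
    )


def read_normalized(vcf_path, chrom: str, marker_seq: str):
    """parse_vcf + normalize, warning on duplicate (start0, ref, alt) records."""
    seen: set[tuple] = set()
    for rec in parse_vcf(vcf_path, chrom):
        nv = normalize(rec, marker_seq)
        if nv.key() in seen:
            log.warning(
                "duplicate variant at %s:%d (%d bp ref -> %r); keeping as a distinct node",
                chrom, rec.pos1, nv.ref_len, nv.alt_seq,
            )
        seen.add(nv.key())
        yield nv


def _gt_string(phased: bool, a0: int, a1: int, ploidy: int = 2) -> str:
    if ploidy == 1:
        return str(a0)
    return f"{a0}{'|' if phased else '/'}{a1}"


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_hits(hits, fmt: str, marker_seq: str | None = None, chrom: str = "ref") -> str:
    """Render query hits as TSV or VCF text.

    Each hit must expose ``marker_start0``, ``ref_span``, ``alt_seq``,
    ``vtype``, ``carriers`` and ``tuples`` (per-carrier ``(sample_pos0,
    phased, allele0, allele1)``).  The VCF dialect restores the anchor base
    and 1-based POS for indels so output round-trips through
    ``parse_vcf`` + ``normalize``; it requires ``marker_seq``.
    """
    if fmt == "tsv":
        lines = ["#start0\tref_span\talt_seq\ttype\tcarriers"]
        for h in hits:
            per = ";".join(
                f"{s}:{p}:{_gt_string(ph, a0, a1)}"
                for s, (p, ph, a0, a1) in zip(h.carriers, h.tuples)
            )
            lines.append(
                f"{h.marker_start0}\t{h.ref_span or '-'}\t{h.alt_seq or '-'}\t"
                f"{h.vtype.name}\t{per}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "vcf":
        if marker_seq is None:
            raise ValueError("marker_seq is required for VCF output")
        sample_order: list[str] = []
        for h in hits:
            for s in h.carriers:
                if s not in sample_order:
                    sample_order.append(s)
        out = [VCF_HEADER + f"##contig=<ID={chrom},length={len(marker_seq)}>"]
        out.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_order)
        )
        for h in hits:
            s0, ref, alt = h.marker_start0, h.ref_span, h.alt_seq
            if not ref or not alt:  # indel: restore the VCF anchor base
                if s0 == 0:
                    raise ValueError("cannot restore an anchor base for an indel at position 0")
                anchor = marker_seq[s0 - 1]
                pos1, ref, alt = s0, anchor + ref, anchor + alt
            else:
                pos1 = s0 + 1
            gt = {s: _gt_string(ph, a0, a1) for s, (_, ph, a0, a1) in zip(h.carriers, h.tuples)}
            cols = [gt.get(s, "0/0") for s in sample_order]
            out.append(
                f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cols)
            )
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown output format {fmt!r}; expected 'tsv' or 'vcf'")
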