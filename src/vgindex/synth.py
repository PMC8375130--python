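"""Synthetic reference + multi-sample VCF instances, and brute-force oracles.

The generator emulates a merged cohort VCF: substitutions, insertions and
deletions at sorted positions, diploid phased/unphased genotypes, and carrier
sets drawn so that a variant is shared by ``mean_carriers`` samples on
average.  Sharing matters: a high mean (1000 Genomes-like cohorts) makes
sample-class deduplication and the per-node carrier lists dense, a mean near
1 (tumor-cohort-like data) makes the graph sparse.  Variant spans are
non-overlapping with at least one reference base between consecutive spans
by default, so every sample's path is well defined; an overlap fraction can
be enabled to stress boundary reuse during construction only.

The oracles answer every query type by plain string splicing and linear
scans over the flat variant list — no graph, no index — and are the
independent ground truth the graph queries are checked against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import VType
from .vcf_io import GenotypeCall, NormalizedVariant

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class SimConfig:
    ref_length: int = 100_000
    n_samples: int = 20
    n_variants: int = 500
    type_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # SUB, INS, DEL
    indel_length_range: tuple[int, int] = (1, 8)
    mean_carriers: float = 4.0
    phased_fraction: float = 0.7
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix proportions must sum to 1")
        if not 1 <= self.mean_carriers <= self.n_samples:
            raise ValueError("mean_carriers must be in [1, n_samples]")
        if self.indel_length_range[0] < 1 or self.indel_length_range[0] > self.indel_length_range[1]:
            raise ValueError("bad indel_length_range")


@dataclass
class SimInstance:
    """A generated instance: reference, VCF text, and the flat truth table."""

    chrom: str
    reference: str
    sample_names: list[str]
    variants: list[NormalizedVariant]
    vcf_text: str
    fasta_text: str = field(repr=False, default="")

    def write(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fa = directory / "ref.fa"
        vcf = directory / "cohort.vcf"
        fa.write_text(self.fasta_text)
        vcf.write_text(self.vcf_text)
        return fa, vcf

    def truth_tsv(self) -> str:
        lines = ["#start0\tref_len\talt_seq\ttype\tcarriers"]
        for v in self.variants:
            carriers = ",".join(sorted(v.calls))
            lines.append(f"{v.start0}\t{v.ref_len}\t{v.alt_seq or '-'}\t{v.vtype.name}\t{carriers}")
        return "\n".join(lines) + "\n"


def _draw_carrier_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    if cfg.n_samples == 1:
        return 1
    p = (cfg.mean_carriers - 1) / (cfg.n_samples - 1)
    return 1 + int(rng.binomial(cfg.n_samples - 1, p))


def simulate(cfg: SimConfig, chrom: str = "chr1") -> SimInstance:
    """Generate a deterministic instance from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    ref = "".join(np.array(list(_BASES))[rng.integers(0, 4, cfg.ref_length)])
    max_len = cfg.indel_length_range[1]
    # positions leave >= 1 base between spans so sample paths are unambiguous;
    # each slot reserves room for the longest deletion
    slot = max_len + 2
    n_slots = (cfg.ref_length - 2) // slot
    if cfg.n_variants > n_slots:
        raise ValueError(
            f"{cfg.n_variants} variants do not fit a {cfg.ref_length} bp reference "
            f"with spans up to {max_len} bp"
        )
    chosen = np.sort(rng.choice(n_slots, size=cfg.n_variants, replace=False))
    positions = 1 + chosen * slot + rng.integers(0, 2, cfg.n_variants)

    variants: list[NormalizedVariant] = []
    sample_names = [f"S{i:03d}" for i in range(cfg.n_samples)]
    kinds = rng.choice(3, size=cfg.n_variants, p=list(cfg.type_mix))
    for start0, kind in zip(positions.tolist(), kinds.tolist()):
        if kind == 0:  # SUB
            old = ref[start0]
            alt = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
            nv = NormalizedVariant(start0, 1, alt, VType.SUB)
        elif kind == 1:  # INS
            k = int(rng.integers(cfg.indel_length_range[0], cfg.indel_length_range[1] + 1))
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, k))
            # avoid an alt starting with the next ref base (keeps the edit
            # normalized: no shared prefix with the replaced span)
            if ins[0] == ref[start0]:
                ins = _BASES[(_BASES.index(ins[0]) + 1) % 4] + ins[1:]
            nv = NormalizedVariant(start0, 0, ins, VType.INS)
        else:  # DEL
            k = int(rng.integers(cfg.indel_length_range[0], cfg.indel_length_range[1] + 1))
            nv = NormalizedVariant(start0, k, "", VType.DEL)
        n_car = _draw_carrier_count(rng, cfg)
        carriers = rng.choice(cfg.n_samples, size=n_car, replace=False)
        for ci in np.sort(carriers).tolist():
            phased = bool(rng.random() < cfg.phased_fraction)
            a0, a1 = [(0, 1), (1, 0), (1, 1)][int(rng.integers(0, 3))]
            if not phased and (a0, a1) == (1, 0):
                a0, a1 = 0, 1  # unphased genotypes are reported low-allele-first
            nv.calls[sample_names[ci]] = GenotypeCall(phased, a0, a1)
        variants.append(nv)

    if cfg.overlap_fraction > 0:
        variants = _inject_overlaps(variants, ref, rng, cfg)

    vcf_text = render_vcf(chrom, ref, sample_names, variants)
    fasta = f">{chrom}\n" + "\n".join(
        ref[i : i + 70] for i in range(0, len(ref), 70)
    ) + "\n"
    return SimInstance(chrom, ref, sample_names, variants, vcf_text, fasta)


def _inject_overlaps(variants, ref, rng, cfg) -> list[NormalizedVariant]:
    """Duplicate a fraction of variants at overlapping positions (construction
    stress only; the splice oracle refuses overlapping same-sample edits)."""
    extra = []
    for nv in variants:
        if nv.vtype is VType.DEL and nv.ref_len >= 2 and rng.random() < cfg.overlap_fraction:
            inner = nv.start0 + 1
            old = ref[inner]
            alt = _BASES[(_BASES.index(old) + 1) % 4]
            other = NormalizedVariant(inner, 1, alt, VType.SUB, dict(nv.calls))
            extra.append(other)
    merged = sorted(variants + extra, key=lambda v: (v.start0, v.ref_len))
    return merged


def render_vcf(chrom: str, ref: str, sample_names: list[str], variants) -> str:
    """Standard VCF text with anchor-base indel records."""
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(ref)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    lines = []
    for nv in variants:
        if nv.vtype is VType.SUB:
            pos1 = nv.start0 + 1
            vref, valt = ref[nv.start0 : nv.start0 + nv.ref_len], nv.alt_seq
        else:  # anchor-base convention for indels (and COMPLEX)
            if nv.start0 == 0:
                raise ValueError("cannot render an indel at position 0 with an anchor base")
            anchor = ref[nv.start0 - 1]
            pos1 = nv.start0
            vref = anchor + ref[nv.start0 : nv.start0 + nv.ref_len]
            valt = anchor + nv.alt_seq
        gts = []
        for s in sample_names:
            call = nv.calls.get(s)
            if call is None:
                gts.append("0/0")
            else:
                sep = "|" if call.phased else "/"
                gts.append(f"{call.allele0}{sep}{call.allele1}")
        lines.append(f"{chrom}\t{pos1}\t.\t{vref}\t{valt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    lines.sort(key=lambda ln: int(ln.split("\t")[1]))
    return "\n".join(header + lines) + "\n"


# ---------------------------------------------------------------------------
# brute-force oracles (no graph, no index)
# ---------------------------------------------------------------------------


def sample_variants(variants, sample: str) -> list[NormalizedVariant]:
    return [v for v in variants if sample in v.calls]


def apply_edits_oracle(reference: str, variants) -> str:
    """Splice sorted, non-overlapping edits into the reference, right to left."""
    end = -1
    for v in variants:
        if v.start0 < end:
            raise ValueError(f"overlapping edits at {v.start0} (previous span ends at {end})")
        end = v.start0 + v.ref_len
    seq = reference
    for v in reversed(list(variants)):
        seq = seq[: v.start0] + v.alt_seq + seq[v.start0 + v.ref_len :]
    return seq


def sample_coordinate_of(variants, sample: str, v: NormalizedVariant) -> int:
    """Position of variant ``v`` on ``sample``'s sequence: marker start plus
    the cumulative length change of the sample's earlier variants."""
    delta = 0
    for u in sample_variants(variants, sample):
        if (u.start0, u.ref_len, u.alt_seq) == (v.start0, v.ref_len, v.alt_seq):
            break
        delta += u.len_delta
    return v.start0 + delta


def closest_variant_oracle(variants, pos0: int):
    """argmin |start0 - pos0|, ties toward the smaller position."""
    best = None
    for v in variants:
        d = abs(v.start0 - pos0)
        if best is None or d < best[0] or (d == best[0] and v.start0 < best[1].start0):
            best = (d, v)
    return None if best is None else best[1]


def all_variants_oracle(variants, b0: int, e0: int):
    return [v for v in variants if b0 <= v.start0 <= e0]


def vars_sample_marker_oracle(variants, sample: str, b0: int, e0: int):
    return [v for v in all_variants_oracle(variants, b0, e0) if sample in v.calls]


def vars_sample_own_oracle(variants, sample: str, b0: int, e0: int):
    """Sample's variants whose position on its own sequence falls in [b0, e0]."""
    out = []
    delta = 0
    for v in sample_variants(variants, sample):
        pos = v.start0 + delta
        if b0 <= pos <= e0:
            out.append(v)
        delta += v.len_delta
    return out


def seq_marker_oracle(reference: str, variants, sample: str, b0: int, e0: int) -> str:
    """Sample sequence restricted to marker window [b0, e0]: splice only the
    sample's edits anchored inside the window into the window's slice."""
    mine = sample_variants(variants, sample)
    # clip the window's edges against deletions crossing them
    lo, hi = b0, e0 + 1
    seq = reference[lo:hi]
    for v in reversed(mine):
        if not (b0 <= v.start0 <= e0):
            continue
        s = v.start0 - lo
        span = min(v.ref_len, hi - v.start0)
        seq = seq[:s] + v.alt_seq + seq[s + span :]
    # a deletion anchored before the window can swallow its head
    for v in mine:
        if v.start0 < b0 < v.start0 + v.ref_len:
            cut = min(v.start0 + v.ref_len, hi) - lo
            seq = seq[cut:]
    return seq


def seq_own_oracle(reference: str, variants, sample: str, b0: int, e0: int) -> str:
    full = apply_edits_oracle(reference, sample_variants(variants, sample))
    return full[b0 : e0 + 1]
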