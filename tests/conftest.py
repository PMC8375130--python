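"""Shared fixtures: the three-sample worked example and synthetic builders.

The worked example is a 14 bp reference CAATTTGCTGATCT with three variants
over samples HG00096/HG00101/HG00103: a substitution A->G at 1-based
position 2 (carried by HG00101 and HG00103), a 3 bp deletion of ATT starting
at 0-based position 2 (HG00096), and an insertion of ACG after 0-based
position 5 (HG00103).  Hand-derived ground truth used across the suite:

    graph: 8 nodes, 10 edges
      marker path [C][A][ATT][T][GCTGATCT], alt nodes G, DEL(len 0), ACG
    sample sequences: HG00096 CATGCTGATCT, HG00101 CGATTTGCTGATCT,
                      HG00103 CGATTTACGGCTGATCT
"""

from pathlib import Path

import pytest

from vgindex import IndexConfig, SimConfig, VariantIndex, build_index, simulate

DATA = Path(__file__).parent / "data"

REF = "CAATTTGCTGATCT"
SAMPLES = ["HG00096", "HG00101", "HG00103"]
SAMPLE_SEQS = {
    "HG00096": "CATGCTGATCT",
    "HG00101": "CGATTTGCTGATCT",
    "HG00103": "CGATTTACGGCTGATCT",
}


@pytest.fixture(scope="session")
def worked_fa() -> Path:
    return DATA / "worked_example.fa"


@pytest.fixture(scope="session")
def worked_vcf() -> Path:
    return DATA / "worked_example.vcf"


@pytest.fixture(scope="session")
def worked_index(worked_fa, worked_vcf, tmp_path_factory) -> VariantIndex:
    out = tmp_path_factory.mktemp("worked_idx")
    dirs = build_index(worked_fa, worked_vcf, out)
    return VariantIndex.open(dirs[0])


def build_instance(inst, tmp_path: Path, **config_kwargs) -> VariantIndex:
    """Write a simulated instance to disk, build, and open its index."""
    fa, vcf = inst.write(tmp_path / "in")
    dirs = build_index(fa, vcf, tmp_path / "idx", IndexConfig(**config_kwargs))
    return VariantIndex.open(dirs[0])


@pytest.fixture()
def small_instance():
    return simulate(SimConfig(ref_length=20_000, n_samples=10, n_variants=150, seed=11))


@pytest.fixture()
def small_index(small_instance, tmp_path) -> VariantIndex:
    return build_instance(small_instance, tmp_path)
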