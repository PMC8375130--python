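"""Two-phase graph construction: splits, delta propagation, renumbering."""

import hashlib
from pathlib import Path

import pytest

from vgindex import GraphBuilder, NormalizedVariant, SimConfig, build_index, simulate
from vgindex.graph import ABSENT, VType, tuple_for_sample
from vgindex.vcf_io import GenotypeCall

from conftest import REF, SAMPLES, build_instance


def _nv(start0, ref_len, alt_seq, vtype, carriers):
    calls = {s: GenotypeCall(True, 0, 1) for s in carriers}
    return NormalizedVariant(start0, ref_len, alt_seq, vtype, calls)


WORKED = [
    _nv(1, 1, "G", VType.SUB, ["HG00101", "HG00103"]),
    _nv(2, 3, "", VType.DEL, ["HG00096"]),
    _nv(6, 0, "ACG", VType.INS, ["HG00103"]),
]


class TestInitGraph:
    def test_single_node_no_edges(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        assert (b.n_nodes, b.n_edges) == (1, 0)
        n = b.get_node(0)
        assert (n.marker_pos0, n.seq_len) == (0, 14)
        assert b.seqbuf.slice(n.seq_offset, n.seq_len) == REF

    def test_length_one_reference(self):
        b = GraphBuilder.init_graph("A", ["S"])
        assert b.get_node(0).seq_len == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            GraphBuilder.init_graph("", ["S"])


class TestPhaseOneSplits:
    def test_substitution_splits_into_three(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        b.insert_variant(WORKED[0])
        assert (b.n_nodes, b.n_edges) == (4, 4)
        marker_seqs = [
            b.seqbuf.slice(b.get_node(i).seq_offset, b.get_node(i).seq_len)
            for i in b.marker_node_ids()
        ]
        assert marker_seqs == ["C", "A", "ATTTGCTGATCT"]

    def test_deletion_reuses_existing_boundary(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        b.insert_variant(WORKED[0])
        alt = b.insert_variant(WORKED[1])
        assert (b.n_nodes, b.n_edges) == (6, 7)
        assert b.get_node(alt).seq_len == 0  # deletions are zero-length nodes
        marker_seqs = [
            b.seqbuf.slice(b.get_node(i).seq_offset, b.get_node(i).seq_len)
            for i in b.marker_node_ids()
        ]
        assert marker_seqs == ["C", "A", "ATT", "TGCTGATCT"]

    def test_insertion_completes_worked_example(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        for nv in WORKED:
            b.insert_variant(nv)
        assert (b.n_nodes, b.n_edges) == (8, 10)

    def test_unsorted_arrival_rejected(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        b.insert_variant(WORKED[2])
        with pytest.raises(ValueError, match="sorted"):
            b.insert_variant(WORKED[0])

    def test_span_past_reference_end_rejected(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        with pytest.raises(ValueError, match="past"):
            b.insert_variant(_nv(10, 10, "", VType.DEL, ["HG00096"]))


class TestPhaseTwoDeltas:
    def _built(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        ids = [b.insert_variant(nv) for nv in WORKED]
        b.propagate_sample_positions()
        return b, ids

    def test_worked_example_sample_positions(self):
        b, (sub, dele, ins) = self._built()
        assert b.get_node(sub).sample_tuples == [(1, 5), (1, 5)]  # both at pos 1
        assert b.get_node(dele).sample_tuples == [(2, 5)]         # HG00096 at 2
        assert b.get_node(ins).sample_tuples == [(6, 5)]          # HG00103 at 6
        assert b.sample_deltas == {"HG00096": -3, "HG00101": 0, "HG00103": 3}

    def test_no_variants_leaves_all_deltas_zero(self):
        b = GraphBuilder.init_graph(REF, SAMPLES)
        b.propagate_sample_positions()
        assert set(b.sample_deltas.values()) == {0}

    def test_single_insertion_shifts_downstream_nodes(self):
        b = GraphBuilder.init_graph("A" * 100, ["S"])
        b.insert_variant(_nv(10, 0, "CGT", VType.INS, ["S"]))
        b.insert_variant(_nv(50, 1, "G", VType.SUB, ["S"]))
        b.propagate_sample_positions()
        nodes = [n for n in b.nodes.values() if n.is_alt]
        by_pos = {n.marker_pos0: n.sample_tuples[0][0] for n in nodes}
        assert by_pos == {10: 10, 50: 53}  # +3 after the insertion


def _backtracking_positions(index, sample):
    """The rejected per-variant backtracking scheme, as an oracle: walk the
    sample's path from the source accumulating sequence lengths, recording
    the position of every alt node the sample carries."""
    positions = {}
    n = index.path_start(sample)
    pos = 0
    while n is not None:
        if n.is_alt and index.classes.contains(n.sample_class_id, sample):
            positions[n.node_id] = pos
        pos += n.seq_len
        n = index._step(n, sample)
    return positions


def test_phase2_equals_backtracking_oracle(small_index):
    idx = small_index
    for sample in idx.samples:
        expected = _backtracking_positions(idx, sample)
        for nid, pos in expected.items():
            tup = tuple_for_sample(idx.node(nid), idx.classes, sample)
            assert tup is not ABSENT
            assert tup[0] == pos, (sample, nid)


def test_final_delta_equals_sample_length_change(small_index, small_instance):
    for s in small_instance.sample_names:
        expected = sum(v.len_delta for v in small_instance.variants if s in v.calls)
        assert small_index.sample_deltas[s] == expected


class TestRenumbering:
    def test_ids_increase_in_marker_position_order(self, small_index):
        prev = -1
        for i in range(small_index.stats()["n_nodes"]):
            pos = small_index.node(i).marker_pos0
            assert pos >= prev
            prev = pos

    def test_worked_example_ids_are_dense(self, worked_index):
        assert sorted(worked_index.node(i).node_id for i in range(8)) == list(range(8))

    def test_queries_unchanged_by_relabeling(self, tmp_path):
        """Answers computed straight off the builder equal the serialized
        (renumbered) index's answers."""
        inst = simulate(SimConfig(ref_length=3000, n_samples=5, n_variants=30, seed=5))
        idx = build_instance(inst, tmp_path)
        hits = idx.all_variants(1, idx.ref_len)
        assert [(h.marker_start0, h.alt_seq) for h in hits] == [
            (v.start0, v.alt_seq) for v in inst.variants
        ]


def test_construction_is_deterministic(tmp_path):
    inst = simulate(SimConfig(ref_length=4000, n_samples=5, n_variants=40, seed=9))
    fa, vcf = inst.write(tmp_path / "in")

    def tree_digest(d: Path) -> str:
        h = hashlib.sha256()
        for p in sorted(d.rglob("*")):
            if p.is_file() and p.suffix != ".fai":
                h.update(p.relative_to(d).as_posix().encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    build_index(fa, vcf, tmp_path / "a")
    build_index(fa, vcf, tmp_path / "b")
    assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")


def test_zero_variant_vcf_builds_single_node_index(tmp_path, worked_fa):
    p = tmp_path / "empty.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    from vgindex import VariantIndex

    dirs = build_index(worked_fa, p, tmp_path / "idx")
    idx = VariantIndex.open(dirs[0])
    assert idx.stats()["n_nodes"] == 1
    assert idx.all_variants(1, idx.ref_len) == []
    assert idx.closest_variant(5) is None


def test_overlapping_variants_accepted_at_build(tmp_path):
    inst = simulate(
        SimConfig(ref_length=10_000, n_samples=6, n_variants=80, seed=2,
                  type_mix=(0.2, 0.2, 0.6), overlap_fraction=0.5)
    )
    idx = build_instance(inst, tmp_path)
    assert idx.stats()["n_variants"] == len(inst.variants)
    hits = idx.all_variants(1, idx.ref_len)
    assert [(h.marker_start0, h.alt_seq) for h in hits] == [
        (v.start0, v.alt_seq) for v in inst.variants
    ]
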