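"""Query engine: the six query types, sample-coordinate resolution, batches."""

import random

import pytest

from vgindex import QuerySpec, QueryType, SimConfig, simulate
from vgindex import synth

from conftest import REF, SAMPLE_SEQS, build_instance


def _seq_of(idx, node):
    return idx.seqbuf.slice(node.seq_offset, node.seq_len)


class TestResolvePosition:
    def test_marker_position_four(self, worked_index):
        r = worked_index.resolve_position("MARKER", 4)
        assert (_seq_of(worked_index, r.node), r.offset) == ("ATT", 2)

    def test_sample_position_inside_insertion(self, worked_index):
        # HG00103 base 7 (0-based) of CGATTTACGGCTGATCT is the C of ACG
        r = worked_index.resolve_position("HG00103", 7)
        assert (_seq_of(worked_index, r.node), r.offset) == ("ACG", 1)

    def test_variant_free_sample_resolves_like_marker(self, worked_index):
        # HG00101 carries only a substitution; positions past it are identity
        rm = worked_index.resolve_position("MARKER", 9)
        rs = worked_index.resolve_position("HG00101", 9)
        assert rs.node.node_id == rm.node.node_id
        assert rs.offset == rm.offset

    def test_position_past_sample_length(self, worked_index):
        with pytest.raises(IndexError):
            worked_index.resolve_position("HG00096", 11)  # its sequence has 11 bases

    def test_every_sample_base_resolves_correctly(self, worked_index):
        for s, seq in SAMPLE_SEQS.items():
            for p, base in enumerate(seq):
                r = worked_index.resolve_position(s, p)
                assert _seq_of(worked_index, r.node)[r.offset] == base, (s, p)


class TestNextOnPath:
    def _id_of(self, idx, seq, marker_pos0):
        for i in range(idx.stats()["n_nodes"]):
            n = idx.node(i)
            if n.marker_pos0 == marker_pos0 and _seq_of(idx, n) == seq:
                return i
        raise AssertionError("node not found")

    def test_carrier_takes_deletion_branch(self, worked_index):
        a = self._id_of(worked_index, "A", 1)
        nxt = worked_index.next_on_path(a, "HG00096")
        assert worked_index.node(nxt).seq_len == 0  # the zero-length DEL node

    def test_non_carrier_follows_reference(self, worked_index):
        a = self._id_of(worked_index, "A", 1)
        nxt = worked_index.next_on_path(a, "HG00101")
        assert _seq_of(worked_index, worked_index.node(nxt)) == "ATT"

    def test_source_to_first_marker_for_reference_follower(self, worked_index):
        c = worked_index.topology.source_id
        nxt = worked_index.next_on_path(c, "HG00096")
        assert _seq_of(worked_index, worked_index.node(nxt)) == "A"

    def test_sink_returns_none(self, worked_index):
        sink = self._id_of(worked_index, "GCTGATCT", 6)
        assert worked_index.next_on_path(sink, "HG00103") is None


class TestClosestVariant:
    def test_position_ten_is_nearest_to_insertion(self, worked_index):
        h = worked_index.closest_variant(10)
        assert (h.marker_start0, h.alt_seq) == (6, "ACG")

    def test_exact_variant_position(self, worked_index):
        h = worked_index.closest_variant(2)  # 0-based 1, the substitution
        assert (h.marker_start0, h.alt_seq) == (1, "G")

    def test_tie_broken_toward_smaller_position(self, small_instance, tmp_path):
        idx = build_instance(small_instance, tmp_path)
        rng = random.Random(7)
        for _ in range(200):
            p0 = rng.randrange(idx.ref_len)
            got = idx.closest_variant(p0 + 1)
            exp = synth.closest_variant_oracle(small_instance.variants, p0)
            assert got.marker_start0 == exp.start0, p0


class TestWorkedExampleQueries:
    def test_all_vars_full_range(self, worked_index):
        hits = worked_index.all_variants(1, 14)
        assert [h.marker_start0 for h in hits] == [1, 2, 6]
        assert [set(h.carriers) for h in hits] == [
            {"HG00101", "HG00103"}, {"HG00096"}, {"HG00103"},
        ]

    def test_all_vars_empty_tail(self, worked_index):
        assert worked_index.all_variants(8, 14) == []

    def test_vars_marker_coords(self, worked_index):
        assert [h.marker_start0 for h in worked_index.variants("HG00103", 1, 14)] == [1, 6]
        assert worked_index.variants("HG00096", 6, 14) == []
        assert worked_index.variants("HG00101", 3, 14) == []

    def test_seq_marker_coords_applies_deletion(self, worked_index):
        assert worked_index.sequence("HG00096", 1, 6) == "CAT"

    def test_full_sample_sequences(self, worked_index):
        for s, expected in SAMPLE_SEQS.items():
            L = worked_index.path_length(s)
            assert L == len(expected)
            assert worked_index.sequence(s, 1, L, coord_path=s) == expected
            assert worked_index.sequence(s, 1, 14) == expected

    def test_vars_sample_coords(self, worked_index):
        hits = worked_index.variants("HG00103", 1, 17, coord_path="HG00103")
        assert [h.sample_pos0("HG00103") for h in hits] == [1, 6]
        # window covering only the insertion in HG00103's own coordinates
        hits = worked_index.variants("HG00103", 7, 10, coord_path="HG00103")
        assert [h.alt_seq for h in hits] == ["ACG"]


class TestValidation:
    def test_range_outside_coordinate_space(self, worked_index):
        with pytest.raises(IndexError):
            worked_index.all_variants(1, 15)
        with pytest.raises(IndexError):
            worked_index.sequence("HG00096", 1, 12, coord_path="HG00096")

    def test_unknown_sample(self, worked_index):
        with pytest.raises(KeyError):
            worked_index.sequence("NOPE", 1, 5)

    def test_spec_requires_sample_for_seq(self):
        with pytest.raises(ValueError):
            QuerySpec(qtype=QueryType.SEQ_REF, begin1=1, end1=5)

    def test_spec_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            QuerySpec(qtype=QueryType.ALL_VARS, begin1=9, end1=5)


class TestOracleEquivalence:
    """Graph queries vs the flat-list/string-splice oracles on synthetics."""

    @pytest.mark.parametrize("seed", range(6))
    def test_all_query_types_match_oracles(self, seed, tmp_path):
        inst = simulate(SimConfig(ref_length=15_000, n_samples=8, n_variants=120, seed=seed))
        idx = build_instance(inst, tmp_path)
        rng = random.Random(seed)
        L = idx.ref_len
        assert [h.key() for h in idx.all_variants(1, L)] == [v.key() for v in inst.variants]
        for s in inst.sample_names:
            mine = synth.sample_variants(inst.variants, s)
            oracle = synth.apply_edits_oracle(inst.reference, mine)
            assert idx.path_length(s) == len(oracle)
            assert idx.sequence(s, 1, len(oracle), coord_path=s) == oracle
        for _ in range(25):
            s = rng.choice(inst.sample_names)
            b0 = rng.randrange(L)
            e0 = min(L - 1, b0 + rng.randrange(1, 2500))
            assert [h.key() for h in idx.all_variants(b0 + 1, e0 + 1)] == [
                v.key() for v in synth.all_variants_oracle(inst.variants, b0, e0)
            ]
            assert [h.key() for h in idx.variants(s, b0 + 1, e0 + 1)] == [
                v.key() for v in synth.vars_sample_marker_oracle(inst.variants, s, b0, e0)
            ]
            assert idx.sequence(s, b0 + 1, e0 + 1) == synth.seq_marker_oracle(
                inst.reference, inst.variants, s, b0, e0
            )
            Ls = idx.path_length(s)
            bs = rng.randrange(Ls)
            es = min(Ls - 1, bs + rng.randrange(1, 2500))
            assert [h.key() for h in idx.variants(s, bs + 1, es + 1, coord_path=s)] == [
                v.key() for v in synth.vars_sample_own_oracle(inst.variants, s, bs, es)
            ]
            assert idx.sequence(s, bs + 1, es + 1, coord_path=s) == synth.seq_own_oracle(
                inst.reference, inst.variants, s, bs, es
            )
            p0 = rng.randrange(L)
            assert idx.closest_variant(p0 + 1).marker_start0 == \
                synth.closest_variant_oracle(inst.variants, p0).start0


def test_sample_resolution_is_local(tmp_path):
    """The local-search cost of resolving a sample position is bounded by the
    variant density around the query window — it does not grow with the
    chromosome length or the total variant count."""
    sizes = [30_000, 120_000]
    worst = []
    for L in sizes:
        inst = simulate(SimConfig(
            ref_length=L, n_samples=10, n_variants=L // 200, seed=13))
        idx = build_instance(inst, tmp_path / str(L))
        rng = random.Random(13)
        visits = []
        for _ in range(120):
            s = rng.choice(inst.sample_names)
            t = rng.randrange(idx.path_length(s))
            visits.append(idx.resolve_position(s, t).visits)
        worst.append(max(visits))
    # same local density => same visit scale regardless of total size
    assert worst[1] <= 2 * worst[0] + 8
    assert max(worst) < 200


class TestBatch:
    def test_shuffled_batch_equals_one_by_one(self, small_instance, tmp_path):
        idx = build_instance(small_instance, tmp_path)
        rng = random.Random(5)
        L = idx.ref_len
        specs = []
        for _ in range(60):
            b = rng.randrange(1, L - 500)
            specs.append(QuerySpec(qtype=QueryType.ALL_VARS, begin1=b, end1=b + 500))
            s = rng.choice(small_instance.sample_names)
            specs.append(QuerySpec(qtype=QueryType.SEQ_REF, begin1=b, end1=b + 500, sample=s))
            specs.append(QuerySpec(qtype=QueryType.CLOSEST_VAR, begin1=b))
        rng.shuffle(specs)
        one_by_one = [idx.run_query(sp) for sp in specs]
        batch = idx.run_batch(specs)

        def norm(r):
            if isinstance(r, list):
                return [h.key() for h in r]
            return r.key() if hasattr(r, "key") else r

        assert [norm(r) for r in batch] == [norm(r) for r in one_by_one]

    def test_empty_batch(self, worked_index):
        assert worked_index.run_batch([]) == []

    def test_invalid_spec_reported_without_aborting(self, worked_index):
        specs = [
            QuerySpec(qtype=QueryType.ALL_VARS, begin1=1, end1=14),
            QuerySpec(qtype=QueryType.ALL_VARS, begin1=1, end1=999),
            QuerySpec(qtype=QueryType.SEQ_REF, begin1=1, end1=6, sample="HG00096"),
        ]
        res = worked_index.run_batch(specs)
        assert len(res[0]) == 3
        assert isinstance(res[1], IndexError)
        assert res[2] == "CAT"

    def test_sorted_windows_load_chunks_monotonically(self, tmp_path):
        """With chunk spans wider than the query window, a sorted batch of
        overlapping windows loads each chunk at most once (plus one)."""
        inst = simulate(SimConfig(ref_length=100_000, n_samples=10, n_variants=1000, seed=17))
        idx = build_instance(inst, tmp_path, chunk_capacity=400)
        rng = random.Random(17)
        L = idx.ref_len
        window = 4_200
        specs = [
            QuerySpec(qtype=QueryType.ALL_VARS, begin1=b, end1=min(L, b + window))
            for b in sorted(rng.randrange(1, L - window) for _ in range(1000))
        ]
        idx.run_batch(specs)
        assert idx.store.stats.loads <= idx.store.n_chunks + 1
        assert idx.store.stats.max_resident <= 2


def test_cross_coordinate_query(tmp_path):
    """A range given in one sample's coordinates can constrain another
    sample's variants (second-reference use case)."""
    inst = simulate(SimConfig(ref_length=10_000, n_samples=6, n_variants=80, seed=23))
    idx = build_instance(inst, tmp_path)
    ref2, other = inst.sample_names[0], inst.sample_names[1]
    hits = idx.variants(other, 1, idx.path_length(ref2), coord_path=ref2)
    expected = [v.key() for v in synth.sample_variants(inst.variants, other)]
    got = [h.key() for h in hits]
    assert set(got) <= set(expected)
    assert len(got) >= len(expected) - 8  # edges may clip the outermost hits
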