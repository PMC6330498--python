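"""Topology representation, encoding, implicit edges, cycles, clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netfunc.topology import (
    LinkVector,
    Node,
    Topology,
    augmented,
    cluster_order,
    decode,
    encode,
    enumerate_three_node,
    find_signed_cycles,
    hamming,
    implicit_edges,
    motif_labels,
    sign_options,
    three_node_nodes,
)

digit = st.sampled_from([-1, 0, 1])
vectors = st.tuples(*([digit] * 9)).map(LinkVector)


def _reachable_oracle(v: LinkVector) -> bool:
    """Independent receptor->output reachability via boolean matrix closure."""
    a = np.abs(np.array(v.digits).reshape(3, 3)).astype(bool)
    closure = a.copy()
    for _ in range(3):
        closure = closure | (closure @ a)
    return bool(closure[0, 2])  # R is index 0, O index 2


class TestEnumeration:
    def test_full_count_is_3_to_the_9(self):
        assert sum(1 for _ in enumerate_three_node(require_io_path=False)) == 3**9

    def test_io_path_filter_matches_reachability_oracle(self):
        expected = sum(
            1
            for digits in itertools.product((1, -1, 0), repeat=9)
            if _reachable_oracle(LinkVector(digits))
        )
        got = sum(1 for _ in enumerate_three_node(require_io_path=True))
        assert got == expected

    def test_empty_network_only_without_filter(self):
        empty = LinkVector((0,) * 9)
        unfiltered = {encode(t) for t in enumerate_three_node(require_io_path=False)}
        filtered = {encode(t) for t in enumerate_three_node(require_io_path=True)}
        assert empty in unfiltered and empty not in filtered


class TestEncoding:
    def test_empty_and_repressilator(self):
        assert encode(decode(LinkVector((0,) * 9))).digits == (0,) * 9
        a1 = Topology(
            three_node_nodes(), {("R", "M"): -1, ("M", "O"): -1, ("O", "R"): -1}
        )
        assert encode(a1).digits == (0, -1, 0, 0, 0, -1, -1, 0, 0)

    @given(vectors)
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, v):
        assert encode(decode(v)) == v

    def test_encode_rejects_non_three_node(self, n5):
        with pytest.raises(ValueError):
            encode(n5[0])

    def test_string_form(self):
        v = LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0))
        assert str(v) == "0-000--00"
        assert LinkVector.from_string(str(v)) == v


class TestHamming:
    def test_basic(self):
        a = LinkVector((0,) * 9)
        b = LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0))
        assert hamming(a, a) == 0
        assert hamming(a, b) == 3

    @given(vectors, vectors, vectors)
    @settings(max_examples=100, deadline=None)
    def test_metric_properties(self, a, b, c):
        assert hamming(a, b) == hamming(b, a) <= 9
        assert (hamming(a, b) == 0) == (a == b)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)

    @given(vectors, vectors)
    @settings(max_examples=50, deadline=None)
    def test_matches_elementwise_oracle(self, a, b):
        assert hamming(a, b) == sum(x != y for x, y in zip(a.digits, b.digits))


class TestImplicitEdges:
    def test_shared_activation_gives_mutual_activation(self):
        # a regulator activating both targets couples them positively
        t = decode(LinkVector((0, 1, 1, 0, 0, 0, 0, 0, 0)))  # R->M, R->O
        edges = implicit_edges(t)
        assert {(e.source, e.target, e.sign) for e in edges} == {
            ("M", "O", 1),
            ("O", "M", 1),
        }
        assert all(e.mediator == "R" for e in edges)

    def test_mixed_direction_gives_mutual_deactivation(self):
        t = decode(LinkVector((0, 1, -1, 0, 0, 0, 0, 0, 0)))  # R->M, R-|O
        assert {(e.source, e.target, e.sign) for e in implicit_edges(t)} == {
            ("M", "O", -1),
            ("O", "M", -1),
        }

    def test_no_competition_no_edges(self):
        t = decode(LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0)))  # out-degrees all 1
        assert implicit_edges(t) == []

    @given(vectors)
    @settings(max_examples=100, deadline=None)
    def test_pair_count_is_twice_choose_two(self, v):
        t = decode(v)
        expected = sum(
            2 * (k * (k - 1) // 2)
            for k in (len(t.targets_of(n)) for n in t.node_ids)
        )
        assert len(implicit_edges(t)) == expected

    def test_self_link_participates(self):
        t = decode(LinkVector((1, 1, 0, 0, 0, 0, 0, 0, 0)))  # R->R, R->M
        assert {(e.source, e.target) for e in implicit_edges(t)} == {
            ("R", "M"),
            ("M", "R"),
        }


class TestAugmented:
    def test_no_competition_unchanged(self):
        t = decode(LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0)))
        assert augmented(t).links == t.links

    def test_conflicting_signs_both_retained(self):
        # R->M, R->O gives implicit M->O (+1); explicit M-|O conflicts
        t = decode(LinkVector((0, 1, 1, 0, 0, -1, 0, 0, 0)))
        aug = augmented(t)
        assert sign_options(aug, ("M", "O")) == frozenset({1, -1})
        assert aug.explicit_links[("M", "O")] == -1


class TestSignedCycles:
    def test_repressilator_and_delayed_loop(self):
        a1 = decode(LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0)))
        assert find_signed_cycles(a1) == [(("M", "O", "R"), -1)]
        a2 = decode(LinkVector((0, 1, 0, 0, 0, 1, -1, 0, 0)))
        assert find_signed_cycles(a2) == [(("M", "O", "R"), -1)]

    @given(vectors)
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, v):
        t = decode(v)
        # oracle: try every candidate node sequence up to length 3
        expected = set()
        ids = t.node_ids
        for L in (1, 2, 3):
            for seq in itertools.permutations(ids, L):
                if min(seq) != seq[0]:
                    continue  # canonical rotation only
                pairs = [(seq[i], seq[(i + 1) % L]) for i in range(L)]
                if all(p in t.links for p in pairs):
                    sign = 1
                    for p in pairs:
                        sign *= t.links[p]
                    expected.add((seq, sign))
        assert set(find_signed_cycles(t)) == expected


class TestMotifLabels:
    def test_repressilators(self):
        for digits in ((0, -1, 0, 0, 0, -1, -1, 0, 0), (0, 0, -1, -1, 0, 0, 0, -1, 0)):
            assert motif_labels(decode(LinkVector(digits))) == {"repressilator"}

    def test_empty_topology(self):
        assert motif_labels(decode(LinkVector((0,) * 9))) == set()

    def test_iffl_proportional(self):
        t = decode(LinkVector((0, 1, 1, 0, 0, -1, 0, 0, 0)))
        assert "IFFL-proportional" in motif_labels(t)

    def test_nfbl_buffer(self):
        t = decode(LinkVector((0, 0, 1, 0, 0, -1, 0, 1, 0)))  # R->O, O->M, M-|O
        assert "NFBL-buffer" in motif_labels(t)


class TestClustering:
    def test_identical_vectors_zero_heights(self):
        pool = [LinkVector((0, 1, 0, 0, 0, 1, -1, 0, 0))] * 4
        res = cluster_order(pool)
        assert sorted(res.order) == [0, 1, 2, 3]
        assert np.allclose(res.linkage[:, 2], 0.0)

    def test_separated_groups_stay_contiguous(self):
        g1 = [
            LinkVector((0, 1, 1, 1, 0, 0, 0, 0, 0)),
            LinkVector((0, 1, 1, 1, 1, 0, 0, 0, 0)),  # distance 1 within
        ]
        g2 = [
            LinkVector((0, -1, -1, -1, 0, 0, 0, 0, -1)),
            LinkVector((0, -1, -1, -1, 0, 0, -1, 0, -1)),  # >= 5 between groups
        ]
        res = cluster_order(g1 + g2)
        first_half = set(res.order[:2])
        assert first_half in ({0, 1}, {2, 3})

    def test_core_motifs_pair_by_hand_computed_distances(self):
        """The same-orientation motif pairs (hand distance 2) merge before
        the opposite-orientation pairs (hand distance 6)."""
        from netfunc.io_cli import MOTIFS_F1

        pool = [MOTIFS_F1[k] for k in ("a1", "a2", "a3", "a4")]
        d = {
            (i, j): hamming(pool[i], pool[j])
            for i in range(4)
            for j in range(i + 1, 4)
        }
        assert d[(0, 1)] == d[(2, 3)] == 2  # a1-a2, a3-a4
        assert min(v for k, v in d.items() if k not in ((0, 1), (2, 3))) >= 4
        res = cluster_order(pool)
        assert set(res.order[:2]) in ({0, 1}, {2, 3})

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            cluster_order([])


class TestInvariants:
    def test_topology_validation(self):
        with pytest.raises(ValueError):
            Topology([Node("A", "output"), Node("B", "output")], {})
        with pytest.raises(ValueError):
            Topology([Node("A", "receptor-1")], {})
        with pytest.raises(ValueError):
            Topology(three_node_nodes(), {("R", "M"): 2})
        with pytest.raises(ValueError):
            Topology(three_node_nodes(), {("R", "X"): 1})
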