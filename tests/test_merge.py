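"""Node merging, tri-functional extension, conditional Q, atlas."""

import numpy as np
import pytest

from netfunc.merge import (
    CANDIDATE_PLANS,
    MergeConflictError,
    MergePlan,
    MergedNetwork,
    build_atlas,
    conditional_q,
    enumerate_merge_plans,
    extend_trifunctional,
    merge,
    new_parameter_slots,
)
from netfunc.topology import LinkVector, Node, Topology, decode, encode

A1 = decode(LinkVector((0, -1, 0, 0, 0, -1, -1, 0, 0)))
A3 = decode(LinkVector((0, 0, -1, -1, 0, 0, 0, -1, 0)))
B1 = decode(LinkVector((0, 0, 1, 0, 0, -1, 0, 1, 0)), receptor_role="receptor-2")


class TestMergePlans:
    def test_rule_violations_rejected(self):
        with pytest.raises(ValueError):
            MergePlan((("R", "R"), ("O", "O")))  # receptor-receptor
        with pytest.raises(ValueError):
            MergePlan((("R", "O"), ("O", "O")))  # receptor-output
        with pytest.raises(ValueError):
            MergePlan((("M", "M"),))  # outputs not merged

    def test_candidate_plans_have_expected_classes(self):
        assert [p.klass for p in CANDIDATE_PLANS] == [
            "one-node", "two-node", "two-node", "two-node", "three-node",
        ]

    def test_enumerate_matches_bruteforce_conflict_check(self, rng):
        """Plan filtering equals trying all five candidates directly."""
        for _ in range(25):
            da = tuple(rng.choice([-1, 0, 1], size=9))
            db = tuple(rng.choice([-1, 0, 1], size=9))
            ta, tb = decode(LinkVector(da)), decode(
                LinkVector(db), receptor_role="receptor-2"
            )
            expected = []
            for plan in CANDIDATE_PLANS:
                try:
                    merge(ta, tb, plan)
                    expected.append(plan)
                except MergeConflictError:
                    pass
            assert enumerate_merge_plans(ta, tb) == expected

    def test_one_node_plan_always_valid_without_o_self_links(self):
        assert CANDIDATE_PLANS[0] in enumerate_merge_plans(A1, B1)


class TestMerge:
    def test_node_counts_by_plan_class(self):
        for plan, n in zip(CANDIDATE_PLANS, (5, 4, 4, 4, 3)):
            try:
                m = merge(A3, B1, plan)
            except MergeConflictError:
                continue
            assert len(m.topology.nodes) == n

    def test_conflicting_m_to_o_links_block_m_merge(self):
        ta = decode(LinkVector((0, 0, 0, 0, 0, 1, -1, 0, 0)))  # M -> O
        tb = decode(LinkVector((0, 0, 0, 0, 0, -1, 1, 0, 0)),
                    receptor_role="receptor-2")  # M -| O
        plan = CANDIDATE_PLANS[1]  # {O-O, M-M}
        with pytest.raises(MergeConflictError) as err:
            merge(ta, tb, plan)
        assert err.value.pair == ("M", "O")
        assert plan not in enumerate_merge_plans(ta, tb)

    def test_a3_b1_one_node_merge_contains_both_motifs(self):
        m = merge(A3, B1, CANDIDATE_PLANS[0])
        t = m.topology
        assert len(t.nodes) == 5
        # oscillator triangle R1 -| O -| M1 -| R1 survives
        assert t.links[("R1", "O")] == -1
        assert t.links[("O", "M1")] == -1
        assert t.links[("M1", "R1")] == -1
        # adaptation loop R2 -> O, O -> M2, M2 -| O survives
        assert t.links[("R2", "O")] == 1
        assert t.links[("O", "M2")] == 1
        assert t.links[("M2", "O")] == -1

    def test_full_overlap_self_merge_recovers_original(self):
        """Merging a module with its R/M-swapped relabeling under the
        three-node plan reproduces the original wiring."""
        swap = {"R": "M", "M": "R", "O": "O"}
        tb = Topology(
            [Node("R", "receptor-2"), Node("M", "intermediate"), Node("O", "output")],
            {(swap[s], swap[g]): v for (s, g), v in A1.links.items()},
        )
        m = merge(A1, tb, CANDIDATE_PLANS[4])
        got = {(s, g): v for (s, g), v in m.topology.links.items()}
        expected = {
            (s.replace("R", "R1").replace("M", "R2"),
             g.replace("R", "R1").replace("M", "R2")): v
            for (s, g), v in A1.links.items()
        }
        assert got == expected

    def test_merge_symmetric_up_to_relabelling(self):
        ma = merge(A3, B1, CANDIDATE_PLANS[0]).topology
        mb = merge(B1, A3, CANDIDATE_PLANS[0]).topology
        relabel = {"R1": "R2", "R2": "R1", "M1": "M2", "M2": "M1", "O": "O"}
        assert {(relabel[s], relabel[g]): v for (s, g), v in mb.links.items()} == dict(
            ma.links
        )


class TestExtension:
    def test_adopt_and_add_candidates(self):
        m = merge(A3, B1, CANDIDATE_PLANS[0])
        cands = extend_trifunctional(m, "both")
        kinds = sorted(c.extension for c in cands)
        assert kinds == ["add", "adopt:M1", "adopt:M2"]
        for c in cands:
            roles = [n.role for n in c.topology.nodes]
            assert roles.count("output") == 1
            for i in (1, 2, 3):
                assert roles.count(f"receptor-{i}") == 1

    def test_three_node_network_only_add_applies(self):
        # the R/M-swapped repressilator full-merges with a1 conflict-free
        tb = decode(LinkVector((0, 0, -1, -1, 0, 0, 0, -1, 0)),
                    receptor_role="receptor-2")
        m = merge(A1, tb, CANDIDATE_PLANS[4])
        assert len(m.topology.nodes) == 3
        cands = extend_trifunctional(m, "both")
        assert [c.extension for c in cands] == ["add"]

    def test_added_receptor_activates_output(self):
        m = merge(A3, B1, CANDIDATE_PLANS[0])
        (added,) = extend_trifunctional(m, "add")
        assert added.topology.links[("R3", "O")] == 1


class TestConditionalQ:
    def test_new_parameter_slots_for_added_node(self, n5):
        topology, params = n5
        base = type(params)(
            link={k: v for k, v in params.link.items()},
            input={k: v for k, v in params.input.items() if k != "R3"},
            basal=dict(params.basal),
        )
        slots = new_parameter_slots(topology, base)
        assert slots["input"] == ["R3"]
        assert slots["link"] == []

    def test_n5_extension_is_robust(self, n5):
        """With the printed base parameters the third function is achieved
        for sampled third-stimulus kinetics."""
        topology, params = n5
        tri = MergedNetwork(topology, extension="add")
        base = type(params)(
            link=dict(params.link),
            input={k: v for k, v in params.input.items() if k != "R3"},
            basal=dict(params.basal),
            stimulus_amplitude=1.0,
        )
        rep = conditional_q(tri, base, n=60, seed=1, check_base=False)
        assert rep.Q >= 1

    def test_seed_reproducibility(self, n5):
        topology, params = n5
        tri = MergedNetwork(topology, extension="add")
        base = type(params)(
            link=dict(params.link),
            input={k: v for k, v in params.input.items() if k != "R3"},
            basal=dict(params.basal),
            stimulus_amplitude=1.0,
        )
        a = conditional_q(tri, base, n=25, seed=9, check_base=False)
        b = conditional_q(tri, base, n=25, seed=9, check_base=False)
        assert a.Q == b.Q and a.passing == b.passing


class TestAtlas:
    def test_single_link_difference_gives_one_edge(self, n5):
        t, _ = n5
        bigger_links = dict(t.links)
        bigger_links[("R2", "R3")] = 1
        bigger = Topology(t.nodes, bigger_links)
        nets = [MergedNetwork(t), MergedNetwork(bigger)]
        g = build_atlas(nets)
        assert g.number_of_edges() == 1
        assert g.edges[0, 1]["kind"] == "atlas"

    def test_no_self_edges_and_no_edge_for_identical(self, n5):
        t, _ = n5
        g = build_atlas([MergedNetwork(t), MergedNetwork(t)])
        assert g.number_of_edges() == 0

    def test_node_removal_is_reduction_not_atlas_edge(self, n5):
        from netfunc.io_cli import catalogue

        cat = catalogue()
        nets = [MergedNetwork(cat["N3"]), MergedNetwork(cat["N5"])]
        g = build_atlas(nets)
        assert g.number_of_edges() == 1
        assert g.edges[0, 1]["kind"] == "reduction"
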