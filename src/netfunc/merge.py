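"""Combining functional modules by node merging.

An oscillation module (nodes R1, M1, O1) and an adaptation module (R2, M2,
O2) are united by identifying pairs of their nodes under the rules:

(i)   the output nodes are always identified;
(ii)  the two intermediate nodes may be identified;
(iii) a receptor may be identified with the *other* pathway's intermediate;
(iv)  two receptors are never identified;
(v)   a receptor is never identified with an output node.

This yields exactly five candidate plans -- the one-node plan {O1-O2}, three
two-node plans adding one of {M1-M2, R1-M2, R2-M1}, and the three-node plan
{O1-O2, R1-M2, R2-M1} -- producing merged networks of 5, 4 and 3 nodes.  A
plan is rejected when the union of the two link sets maps some ordered node
pair to both signs (a contradictory linkage).

Bi-functional candidates are extended to tri-functional ones either by
adopting an existing intermediate node as the third receptor or by adding a
fresh receptor node with a single activation onto the output; both leave
the competition structure untouched.  Robustness of the extension is scored
conditionally: new parameters are resampled while the parent circuit's
parameters stay frozen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
from scipy.stats import qmc

from .classify import ClassifierConfig, DEFAULT_CONFIG, evaluate
from .dynamics import ParameterSet, basal_requirements, build_rate_function, equilibrate
from .search import AMPLITUDE_RANGE, QReport, _topology_id, _k, _v
from .topology import Node, Topology


class MergeConflictError(ValueError):
    """Two modules assign opposite signs to the same merged link."""

    def __init__(self, pair: tuple[str, str]):
        super().__init__(f"contradictory linkage on merged pair {pair[0]}->{pair[1]}")
        self.pair = pair


@dataclass(frozen=True)
class MergePlan:
    """Node identifications between module A (F1) and module B (F2).

    Each identification is an ``(a_node, b_node)`` pair of original module
    node ids (both modules use the standard R/M/O naming).  The output pair
    ("O", "O") must always be present.
    """

    identifications: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if ("O", "O") not in self.identifications:
            raise ValueError("output nodes must be merged (rule i)")
        a_used = [a for a, _ in self.identifications]
        b_used = [b for _, b in self.identifications]
        if len(set(a_used)) != len(a_used) or len(set(b_used)) != len(b_used):
            raise ValueError("a node may appear in at most one identification")
        for a, b in self.identifications:
            if (a, b) == ("O", "O"):
                continue
            if a == "R" and b == "R":
                raise ValueError("receptors cannot be merged (rule iv)")
            if "O" in (a, b):
                raise ValueError("receptors/intermediates cannot merge with O (rule v)")

    @property
    def klass(self) -> str:
        return {1: "one-node", 2: "two-node", 3: "three-node"}[len(self.identifications)]

    def __len__(self) -> int:
        return len(self.identifications)


#: The five structurally admissible plans (before sign-conflict filtering).
CANDIDATE_PLANS: tuple[MergePlan, ...] = (
    MergePlan((("O", "O"),)),
    MergePlan((("O", "O"), ("M", "M"))),
    MergePlan((("O", "O"), ("R", "M"))),  # R1 with M2
    MergePlan((("O", "O"), ("M", "R"))),  # M1 with R2
    MergePlan((("O", "O"), ("R", "M"), ("M", "R"))),
)


@dataclass
class MergedNetwork:
    """A combined topology with provenance."""

    topology: Topology
    parents: tuple[Topology, Topology] | None = None
    plan: MergePlan | None = None
    extension: str | None = None  # None | "adopt:<node>" | "add"
    base_q: QReport | None = None


def _merged_names(plan: MergePlan) -> tuple[dict[str, str], dict[str, str]]:
    """Maps from module-A / module-B node ids to merged node ids."""
    a_map = {"R": "R1", "M": "M1", "O": "O"}
    b_map = {"R": "R2", "M": "M2", "O": "O"}
    for a, b in plan.identifications:
        if (a, b) == ("O", "O"):
            continue
        if (a, b) == ("M", "M"):
            a_map["M"] = b_map["M"] = "M"
        elif (a, b) == ("R", "M"):
            b_map["M"] = "R1"  # M2 folded into receptor-1
        elif (a, b) == ("M", "R"):
            a_map["M"] = "R2"  # M1 folded into receptor-2
        else:  # pragma: no cover - excluded by MergePlan validation
            raise ValueError(f"unsupported identification {(a, b)}")
    return a_map, b_map


def merge(tA: Topology, tB: Topology, plan: MergePlan) -> MergedNetwork:
    """Union of two three-node modules under a merge plan.

    Identical duplicate links collapse; a pair mapped to both signs raises
    :class:`MergeConflictError` naming the offending merged pair.  The
    merged network keeps receptor-1 from the F1 module, receptor-2 from the
    F2 module and the shared output; the result has ``6 - len(plan)`` nodes.
    """
    for t in (tA, tB):
        if set(t.node_ids) != {"R", "M", "O"}:
            raise ValueError("merge expects three-node R/M/O modules")
    a_map, b_map = _merged_names(plan)
    links: dict[tuple[str, str], int] = {}
    for mapping, t in ((a_map, tA), (b_map, tB)):
        for (src, tgt), sign in t.links.items():
            pair = (mapping[src], mapping[tgt])
            if links.get(pair, sign) != sign:
                raise MergeConflictError(pair)
            links[pair] = sign
    roles = {"R1": "receptor-1", "R2": "receptor-2", "O": "output",
             "M": "intermediate", "M1": "intermediate", "M2": "intermediate"}
    ids = sorted(set(a_map.values()) | set(b_map.values()))
    nodes = [Node(i, roles[i]) for i in ids]
    return MergedNetwork(Topology(nodes, links), parents=(tA, tB), plan=plan)


def enumerate_merge_plans(tA: Topology, tB: Topology) -> list[MergePlan]:
    """Candidate plans for a module pair that merge without sign conflicts."""
    out = []
    for plan in CANDIDATE_PLANS:
        try:
            merge(tA, tB, plan)
        except MergeConflictError:
            continue
        out.append(plan)
    return out


# ---------------------------------------------------------------------------
# Tri-functional extension


def extend_trifunctional(
    m: MergedNetwork, strategy: str = "both"
) -> list[MergedNetwork]:
    """Tri-functional candidates from a bi-functional network.

    ``adopt``: every intermediate node (anything that is not receptor-1,
    receptor-2 or the output) is designated receptor-3, one candidate per
    node.  ``add``: a new node R3 is introduced with a single activation
    onto the output.  Neither move creates a new competition group: adoption
    adds no link, and the added node is a fresh regulator with one target.
    """
    if strategy not in ("adopt", "add", "both"):
        raise ValueError(f"unknown strategy {strategy!r}")
    t = m.topology
    out: list[MergedNetwork] = []
    if strategy in ("adopt", "both"):
        for node in t.nodes:
            if node.role != "intermediate":
                continue
            nodes = [
                Node(n.id, "receptor-3") if n.id == node.id else n for n in t.nodes
            ]
            tri = Topology(nodes, t.links)
            assert tri.links == t.links  # adoption adds no regulation
            out.append(replace(m, topology=tri, extension=f"adopt:{node.id}"))
    if strategy in ("add", "both"):
        nodes = list(t.nodes) + [Node("R3", "receptor-3")]
        links = dict(t.links)
        links[("R3", t.output)] = +1
        tri = Topology(nodes, links)
        assert len(tri.targets_of("R3")) == 1  # fresh regulator: no competition
        out.append(replace(m, topology=tri, extension="add"))
    for cand in out:
        roles = [n.role for n in cand.topology.nodes]
        assert sum(r == "output" for r in roles) == 1
        assert all(roles.count(f"receptor-{i}") == 1 for i in (1, 2, 3))
    return out


def new_parameter_slots(tri: Topology, base: ParameterSet) -> dict[str, list]:
    """Parameter slots the extended network needs beyond the base set."""
    return {
        "link": [p for p in sorted(tri.links) if p not in base.link],
        "input": [r for r in sorted(tri.receptors.values()) if r not in base.input],
        "basal": [b for b in basal_requirements(tri) if b not in base.basal],
    }


def conditional_q(
    tri: MergedNetwork,
    base: ParameterSet,
    n: int = 1000,
    seed: int = 0,
    config: ClassifierConfig = DEFAULT_CONFIG,
    check_base: bool = True,
) -> QReport:
    """Q(F3 | F1,2): robustness of the third function given a working pair.

    Samples ``n`` Latin-hypercube draws of only the *new* parameters (the
    third receptor's input kinetics, the added activation link if any, new
    basal slots, and the third stimulus amplitude) while the parent
    circuit's parameters stay frozen, and counts draws for which the
    extended network passes all of F1, F2 and F3.  F1 and F2 replay under
    the base stimulus amplitude; F3 uses the freshly sampled amplitude.
    """
    t = tri.topology
    if check_base and tri.parents is not None and tri.plan is not None:
        parent = merge(*tri.parents, tri.plan).topology
        for fn in ("F1", "F2"):
            if not evaluate(parent, base, fn, config).passed:
                raise ValueError(f"base parameter set does not pass {fn} on the parent")
    slots = new_parameter_slots(t, base)
    n_vk = len(slots["link"]) + len(slots["input"]) + len(slots["basal"])
    dim = 2 * n_vk + 1
    u = qmc.LatinHypercube(d=dim, seed=seed).random(n)
    passing = []
    for i in range(n):
        row = u[i]
        p = ParameterSet(
            link=dict(base.link),
            input=dict(base.input),
            basal=dict(base.basal),
            B=base.B,
            basal_input=base.basal_input,
            stimulus_amplitude=base.stimulus_amplitude,
        )
        c = 0
        for pair in slots["link"]:
            p.link[pair] = (_v(row[c]), _k(row[c + 1]))
            c += 2
        for rid in slots["input"]:
            p.input[rid] = (_v(row[c]), _k(row[c + 1]))
            c += 2
        for key in slots["basal"]:
            p.basal[key] = (_v(row[c]), _k(row[c + 1]))
            c += 2
        lo, hi = AMPLITUDE_RANGE
        amp3 = lo + (hi - lo) * row[c]
        if _passes_tri(t, p, amp3, config):
            passing.append(i)
    tid, vec = _topology_id(t)
    return QReport(
        topology_id=tid,
        link_vector=vec,
        function="F3|F1,2",
        Q=len(passing),
        n_samples=n,
        seed=seed,
        edge_count=t.n_edges,
        passing=passing,
    )


def _passes_tri(
    t: Topology, p: ParameterSet, amp3: float, config: ClassifierConfig
) -> bool:
    try:
        rf = build_rate_function(t, p)
        converged, x0 = equilibrate(rf)
    except Exception:
        return False
    if not converged:
        return False
    for fn, amp in (("F1", None), ("F2", None), ("F3", amp3)):
        v = evaluate(t, p, fn, config, amplitude=amp, rate_fn=rf, basal_state=x0)
        if not v.passed:
            return False
    return True


def conditional_q_best(
    tri: MergedNetwork,
    base_sets: Sequence[ParameterSet],
    n: int = 1000,
    seed: int = 0,
    max_bases: int = 10,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> QReport:
    """Maximum conditional Q over up to ``max_bases`` passing base sets."""
    best: QReport | None = None
    for j, base in enumerate(base_sets[:max_bases]):
        rep = conditional_q(tri, base, n, seed, config, check_base=False)
        rep.function = f"F3|F1,2[base={j}]"
        if best is None or rep.Q > best.Q:
            best = rep
    if best is None:
        raise ValueError("no base parameter sets supplied")
    return best


# ---------------------------------------------------------------------------
# Structure atlas


def _net_key(t: Topology):
    return frozenset((n.id, n.role) for n in t.nodes)


def build_atlas(nets: Sequence[MergedNetwork]) -> nx.Graph:
    """One-interaction-difference atlas of a family of networks.

    Nodes are indices into ``nets`` (with node/link counts as attributes);
    an undirected edge joins two networks exactly when they share the same
    node set and roles and one link set equals the other plus one signed
    link.  Relations across different node sets (a network reducing to a
    smaller one by deleting a node) are recorded separately as ``reduction``
    edges with attribute ``kind="reduction"``.
    """
    g = nx.Graph()
    for i, m in enumerate(nets):
        g.add_node(
            i,
            n_nodes=len(m.topology.nodes),
            n_links=m.topology.n_edges,
            extension=m.extension,
        )
    for i, j in itertools.combinations(range(len(nets)), 2):
        ti, tj = nets[i].topology, nets[j].topology
        if _net_key(ti) == _net_key(tj):
            li, lj = set(ti.links.items()), set(tj.links.items())
            small, big = sorted((li, lj), key=len)
            if len(big) - len(small) == 1 and small < big:
                g.add_edge(i, j, kind="atlas")
        elif _is_reduction(ti, tj) or _is_reduction(tj, ti):
            g.add_edge(i, j, kind="reduction")
    return g


def _is_reduction(big: Topology, small: Topology) -> bool:
    """True when deleting one node (with its links) from ``big`` yields ``small``."""
    extra = set(n.id for n in big.nodes) - set(n.id for n in small.nodes)
    if len(extra) != 1:
        return False
    drop = extra.pop()
    kept_nodes = frozenset((n.id, n.role) for n in big.nodes if n.id != drop)
    if kept_nodes != _net_key(small):
        return False
    kept_links = {p: s for p, s in big.links.items() if drop not in p}
    return kept_links == small.links
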