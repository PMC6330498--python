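"""Signed enzymatic network topologies.

A network is a small signed directed graph whose nodes are enzymes that
interconvert between active and inactive forms.  A link ``A -> B`` with sign
``+1`` means the active form of A catalyses activation of B; sign ``-1``
means it catalyses deactivation.  Because several substrates can compete for
the same regulator enzyme, a topology also carries *implicit* interactions:
effective couplings between two targets of a shared regulator that exist even
though no explicit link is drawn between them.

This module covers representation, three-node enumeration, the nine-digit
link encoding, Hamming distances and clustering, implicit-edge derivation,
signed-cycle search and motif labelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

ROLES = ("receptor-1", "receptor-2", "receptor-3", "intermediate", "output")
RECEPTOR_ROLES = ("receptor-1", "receptor-2", "receptor-3")

#: Row-major (regulator-major) slot order of the nine possible links of a
#: three-node network over nodes (R, M, O).  The choice of order is a fixed
#: convention; any fixed order gives an equivalent encoding.
SLOT_ORDER: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(3) for j in range(3)
)


@dataclass(frozen=True)
class Node:
    """A network node: an enzyme with a functional role."""

    id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for node {self.id!r}")


@dataclass(frozen=True)
class ImplicitEdge:
    """Competition-induced effective interaction between two substrates.

    When regulator ``mediator`` acts on both ``source`` and ``target``, the
    two substrates compete for the same enzyme; depleting one frees enzyme
    for the other.  The effective sign is ``+1`` (mutual activation) when the
    mediator regulates both endpoints in the same direction and ``-1``
    (mutual deactivation) when the directions differ.
    """

    source: str
    target: str
    sign: int
    mediator: str


class Topology:
    """A signed directed network over role-labelled enzyme nodes.

    Parameters
    ----------
    nodes
        Sequence of :class:`Node` (or ``(id, role)`` pairs); exactly one node
        must carry the ``output`` role, and the node count must be 2-6.
    links
        Mapping from ordered ``(regulator, target)`` id pairs to a sign in
        ``{+1, -1}``.  Absence of a pair means no regulation; self-links are
        permitted.
    """

    def __init__(
        self,
        nodes: Sequence[Node | tuple[str, str]],
        links: Mapping[tuple[str, str], int],
    ) -> None:
        self.nodes: tuple[Node, ...] = tuple(
            n if isinstance(n, Node) else Node(*n) for n in nodes
        )
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        if not 2 <= len(ids) <= 6:
            raise ValueError(f"node count must be 2-6, got {len(ids)}")
        outputs = [n for n in self.nodes if n.role == "output"]
        if len(outputs) != 1:
            raise ValueError("exactly one node must have role 'output'")
        id_set = set(ids)
        self.links: dict[tuple[str, str], int] = {}
        for (src, tgt), sign in links.items():
            if sign not in (+1, -1):
                raise ValueError(f"link {src}->{tgt}: sign must be +1 or -1")
            if src not in id_set or tgt not in id_set:
                raise ValueError(f"link {src}->{tgt} references unknown node")
            self.links[(src, tgt)] = int(sign)

    # -- basic accessors -------------------------------------------------

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    @property
    def output(self) -> str:
        return next(n.id for n in self.nodes if n.role == "output")

    def receptor(self, role: str) -> str | None:
        """Id of the node with the given receptor role, or None."""
        for n in self.nodes:
            if n.role == role:
                return n.id
        return None

    @property
    def receptors(self) -> dict[str, str]:
        return {n.role: n.id for n in self.nodes if n.role in RECEPTOR_ROLES}

    def role_of(self, node_id: str) -> str:
        return next(n.role for n in self.nodes if n.id == node_id)

    @property
    def n_edges(self) -> int:
        return len(self.links)

    def targets_of(self, regulator: str) -> list[tuple[str, int]]:
        return [(t, s) for (r, t), s in self.links.items() if r == regulator]

    def regulators_of(self, target: str, sign: int | None = None) -> list[str]:
        return [
            r
            for (r, t), s in self.links.items()
            if t == target and (sign is None or s == sign)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.nodes == other.nodes and self.links == other.links

    def __hash__(self) -> int:
        return hash((self.nodes, tuple(sorted(self.links.items()))))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ls = ", ".join(
            f"{s}{'>' if v > 0 else '|'}{t}" for (s, t), v in sorted(self.links.items())
        )
        return f"Topology({[n.id for n in self.nodes]}, [{ls}])"

    def replace_links(self, links: Mapping[tuple[str, str], int]) -> "Topology":
        return Topology(self.nodes, links)

    def has_io_path(self) -> bool:
        """True if the output is reachable from some receptor via links."""
        g = nx.DiGraph(list(self.links))
        g.add_nodes_from(self.node_ids)
        out = self.output
        return any(
            nx.has_path(g, rid, out) for rid in self.receptors.values() if rid != out
        )


class AugmentedTopology(Topology):
    """A topology with implicit (competition-induced) links materialized.

    Where an implicit edge coincides with an explicit link of the opposite
    sign, both signs are retained: ``multi_signs`` maps the ordered pair to
    the full set of coexisting signs, and downstream cycle/motif detection
    may use either.  ``links`` keeps the explicit sign for such pairs.
    """

    def __init__(self, base: Topology, implicit: Sequence[ImplicitEdge]) -> None:
        multi: dict[tuple[str, str], set[int]] = {
            pair: {sign} for pair, sign in base.links.items()
        }
        for e in implicit:
            multi.setdefault((e.source, e.target), set()).add(e.sign)
        flat = {pair: base.links.get(pair, max(signs)) for pair, signs in multi.items()}
        super().__init__(base.nodes, flat)
        self.multi_signs: dict[tuple[str, str], frozenset[int]] = {
            pair: frozenset(signs) for pair, signs in multi.items()
        }
        self.implicit: tuple[ImplicitEdge, ...] = tuple(implicit)
        self.explicit_links: dict[tuple[str, str], int] = dict(base.links)


def sign_options(t: Topology, pair: tuple[str, str]) -> frozenset[int]:
    """All coexisting signs of a link (singleton for a plain topology)."""
    if isinstance(t, AugmentedTopology):
        return t.multi_signs.get(pair, frozenset())
    s = t.links.get(pair)
    return frozenset() if s is None else frozenset({s})


# -- three-node encoding -------------------------------------------------


@dataclass(frozen=True)
class LinkVector:
    """Nine-digit encoding of a three-node network.

    ``digits`` lists the signs of the 3x3 ordered regulator->target pairs in
    row-major order over the node sequence (R, M, O):
    R->R, R->M, R->O, M->R, M->M, M->O, O->R, O->M, O->O.
    """

    digits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.digits) != 9 or any(d not in (-1, 0, 1) for d in self.digits):
            raise ValueError("LinkVector needs 9 digits over {-1, 0, +1}")

    def __str__(self) -> str:
        return "".join({1: "+", -1: "-", 0: "0"}[d] for d in self.digits)

    @classmethod
    def from_string(cls, s: str) -> "LinkVector":
        return cls(tuple({"+": 1, "-": -1, "0": 0}[c] for c in s))

    @property
    def n_edges(self) -> int:
        return sum(1 for d in self.digits if d != 0)


THREE_NODE_IDS = ("R", "M", "O")
THREE_NODE_ROLES = ("receptor-1", "intermediate", "output")


def three_node_nodes(receptor_role: str = "receptor-1") -> tuple[Node, ...]:
    """Standard (R, M, O) node triple; the receptor role is configurable so
    that oscillation modules use receptor-1 and adaptation modules receptor-2."""
    return (
        Node("R", receptor_role),
        Node("M", "intermediate"),
        Node("O", "output"),
    )


def encode(t: Topology) -> LinkVector:
    """Nine-digit encoding of a three-node topology (inverse of :func:`decode`)."""
    if len(t.nodes) != 3:
        raise ValueError("encode is defined for three-node topologies only")
    ids = t.node_ids
    digits = tuple(t.links.get((ids[i], ids[j]), 0) for i, j in SLOT_ORDER)
    return LinkVector(digits)


def decode(v: LinkVector, receptor_role: str = "receptor-1") -> Topology:
    """Three-node topology for a nine-digit link vector."""
    nodes = three_node_nodes(receptor_role)
    ids = tuple(n.id for n in nodes)
    links = {
        (ids[i], ids[j]): d for (i, j), d in zip(SLOT_ORDER, v.digits) if d != 0
    }
    return Topology(nodes, links)


def enumerate_three_node(
    require_io_path: bool = True, receptor_role: str = "receptor-1"
) -> Iterator[Topology]:
    """Yield all 3^9 = 19,683 three-node topologies.

    With ``require_io_path`` (the default) only topologies in which the
    output node is reachable from the receptor through directed links are
    yielded; a network without such a path cannot transduce the signal.
    """
    for digits in itertools.product((1, -1, 0), repeat=9):
        t = decode(LinkVector(digits), receptor_role)
        if require_io_path and not t.has_io_path():
            continue
        yield t


def hamming(a: LinkVector, b: LinkVector) -> int:
    """Number of the nine link slots on which two encodings differ."""
    return sum(1 for x, y in zip(a.digits, b.digits) if x != y)


# -- implicit interactions -----------------------------------------------


def implicit_edges(t: Topology) -> list[ImplicitEdge]:
    """Competition-induced implicit interactions of a topology.

    For every regulator with two or more targets and every unordered target
    pair {X, Y}, a mutual pair of implicit edges X<->Y is emitted whose sign
    is the product of the two explicit link signs: same regulation direction
    gives mutual activation, opposite directions mutual deactivation.
    Self-link targets participate like any other target.
    """
    edges: list[ImplicitEdge] = []
    for reg in t.node_ids:
        targets = sorted(t.targets_of(reg))
        for (x, sx), (y, sy) in itertools.combinations(targets, 2):
            sign = sx * sy
            edges.append(ImplicitEdge(x, y, sign, reg))
            edges.append(ImplicitEdge(y, x, sign, reg))
    return edges


def augmented(t: Topology) -> AugmentedTopology:
    """Topology with all implicit edges materialized as ordinary links."""
    return AugmentedTopology(t, implicit_edges(t))


# -- signed cycles and motifs --------------------------------------------


def find_signed_cycles(
    t: Topology, max_len: int | None = None
) -> list[tuple[tuple[str, ...], int]]:
    """All distinct simple directed cycles up to ``max_len`` with sign products.

    Returns ``(cycle, sign)`` pairs where ``cycle`` is the node sequence
    rotated to start at its lexicographically smallest node, and ``sign`` the
    product of link signs along it; a negative product marks a negative
    feedback loop.  On an :class:`AugmentedTopology`, links carrying both
    signs contribute one entry per sign combination (duplicates removed).
    """
    if max_len is None:
        max_len = len(t.nodes)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    g = nx.DiGraph(list(t.links))
    out: set[tuple[tuple[str, ...], int]] = set()
    for cyc in nx.simple_cycles(g):
        if len(cyc) > max_len:
            continue
        k = cyc.index(min(cyc))
        cyc = tuple(cyc[k:] + cyc[:k])
        pairs = [
            (cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))
        ]
        for choice in itertools.product(*(sign_options(t, p) for p in pairs)):
            sign = 1
            for s in choice:
                sign *= s
            out.add((cyc, sign))
    return sorted(out)


#: Motif labels attached by :func:`motif_labels`.
OSCILLATION_LABELS = ("repressilator", "delayed-negative-feedback")
ADAPTATION_LABELS = ("NFBL-buffer", "IFFL-proportional")


def motif_labels(t: Topology, use_implicit: bool = False) -> set[str]:
    """Functional motif labels detected as subgraphs.

    * ``repressilator`` -- a three-cycle of pure inhibitions;
    * ``delayed-negative-feedback`` -- a three-cycle with two activations
      and one inhibition;
    * ``NFBL-buffer`` -- a negative two-cycle (X activates Y, Y inhibits X)
      buffering a node that is activated by a third node;
    * ``IFFL-proportional`` -- an incoherent feedforward: Z activates both a
      proportional node P and the target X while P inhibits X.

    With ``use_implicit``, detection runs on :func:`augmented` ``t`` and a
    link carrying both an explicit and an implicit sign may match either.
    """
    g = augmented(t) if use_implicit and not isinstance(t, AugmentedTopology) else t
    labels: set[str] = set()
    for cyc, sign in find_signed_cycles(g, max_len=3):
        if len(cyc) == 3 and sign < 0:
            n_inhib = _count_inhibitions(g, cyc)
            if 3 in n_inhib:
                labels.add("repressilator")
            if 1 in n_inhib:
                labels.add("delayed-negative-feedback")
    ids = g.node_ids
    for x, y in itertools.permutations(ids, 2):
        if +1 in sign_options(g, (x, y)) and -1 in sign_options(g, (y, x)):
            # negative 2-loop: x -> y, y -| x with buffer y
            if any(
                +1 in sign_options(g, (z, x)) for z in ids if z not in (x, y)
            ):
                labels.add("NFBL-buffer")
    for z, p, x in itertools.permutations(ids, 3):
        if (
            +1 in sign_options(g, (z, p))
            and +1 in sign_options(g, (z, x))
            and -1 in sign_options(g, (p, x))
        ):
            labels.add("IFFL-proportional")
    return labels


def _count_inhibitions(t: Topology, cyc: tuple[str, ...]) -> set[int]:
    """Possible inhibition counts along a cycle across multi-sign choices."""
    pairs = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]
    counts = set()
    for choice in itertools.product(*(sign_options(t, p) for p in pairs)):
        counts.add(sum(1 for s in choice if s < 0))
    return counts


def has_negative_cycle(t: Topology, max_len: int | None = None) -> bool:
    return any(sign < 0 for _, sign in find_signed_cycles(t, max_len))


# -- clustering -----------------------------------------------------------


@dataclass
class ClusterResult:
    """Hierarchical-clustering summary of a pool of encodings."""

    order: list[int]  # leaf order (indices into the input pool)
    linkage: np.ndarray  # scipy linkage matrix
    pool: list[LinkVector] = field(repr=False, default_factory=list)


def cluster_order(pool: Sequence[LinkVector]) -> ClusterResult:
    """Average-linkage hierarchical clustering on pairwise Hamming distances.

    Ties are broken deterministically by pre-sorting the pool in
    lexicographic digit order; the returned leaf order indexes the *input*
    ordering.
    """
    if len(pool) == 0:
        raise ValueError("cannot cluster an empty pool")
    perm = sorted(range(len(pool)), key=lambda i: pool[i].digits)
    mat = np.array([pool[i].digits for i in perm])
    if len(pool) == 1:
        return ClusterResult([0], np.empty((0, 4)), list(pool))
    dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    z = sch.linkage(squareform(dist, checks=False), method="average")
    leaves = sch.leaves_list(z)
    order = [perm[i] for i in leaves]
    return ClusterResult(order, z, list(pool))
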