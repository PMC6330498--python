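"""Latin-hypercube parameter screening and functional-pool selection.

The robustness of a topology for a target function is its Q-value: the
number of sampled parameter sets under which it achieves the function.
Rate constants V are sampled log-uniformly on [0.1, 10], Michaelis
constants K log-uniformly on [1e-3, 10] (the ranges span 2-4 decades), and
the step-stimulus amplitude uniformly on [0.5, 1], using Latin hypercube
stratification: one draw per equal stratum per dimension.

One LHS matrix is drawn per (n, seed, node count) with a fixed column for
every possible parameter slot, and reused across all topologies of that
size, so that Q-values across topologies reflect the same sampling budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import qmc

from .classify import (
    ClassifierConfig,
    DEFAULT_CONFIG,
    FUNCTIONS,
    evaluate,
)
from .dynamics import ParameterSet, basal_requirements, build_rate_function, equilibrate
from .topology import LinkVector, Topology, encode

V_LOG10_RANGE = (-1.0, 1.0)  # rate constants 0.1 .. 10
K_LOG10_RANGE = (-3.0, 1.0)  # Michaelis constants 1e-3 .. 10
AMPLITUDE_RANGE = (0.5, 1.0)

_LHS_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _layout(n_nodes: int) -> dict[str, int]:
    """Column offsets of the full parameter-slot layout for a node count."""
    n_pairs = n_nodes * n_nodes
    return {
        "link": 0,  # 2 columns per ordered node pair (V, K)
        "input": 2 * n_pairs,  # 2 columns per node
        "basal": 2 * n_pairs + 2 * n_nodes,  # 4 columns per node (act, deact)
        "amplitude": 2 * n_pairs + 6 * n_nodes,
        "dim": 2 * n_pairs + 6 * n_nodes + 1,
    }


def lhs_unit_matrix(n: int, seed: int, n_nodes: int = 3) -> np.ndarray:
    """Cached (n, dim) Latin hypercube sample on the unit cube."""
    key = (n, seed, n_nodes)
    if key not in _LHS_CACHE:
        sampler = qmc.LatinHypercube(d=_layout(n_nodes)["dim"], seed=seed)
        _LHS_CACHE[key] = sampler.random(n)
    return _LHS_CACHE[key]


def _v(u: float) -> float:
    lo, hi = V_LOG10_RANGE
    return 10.0 ** (lo + (hi - lo) * u)


def _k(u: float) -> float:
    lo, hi = K_LOG10_RANGE
    return 10.0 ** (lo + (hi - lo) * u)


def parameter_set_from_row(topology: Topology, row: np.ndarray) -> ParameterSet:
    """Map one unit-cube LHS row onto the parameter slots a topology uses."""
    ids = topology.node_ids
    n = len(ids)
    idx = {nid: i for i, nid in enumerate(ids)}
    lay = _layout(n)
    link = {}
    for (src, tgt), _ in topology.links.items():
        c = lay["link"] + 2 * (idx[src] * n + idx[tgt])
        link[(src, tgt)] = (_v(row[c]), _k(row[c + 1]))
    inp = {}
    for rid in topology.receptors.values():
        c = lay["input"] + 2 * idx[rid]
        inp[rid] = (_v(row[c]), _k(row[c + 1]))
    basal = {}
    for (nid, direction) in basal_requirements(topology):
        c = lay["basal"] + 4 * idx[nid] + (0 if direction == "act" else 2)
        basal[(nid, direction)] = (_v(row[c]), _k(row[c + 1]))
    lo, hi = AMPLITUDE_RANGE
    amp = lo + (hi - lo) * row[lay["amplitude"]]
    return ParameterSet(link=link, input=inp, basal=basal, stimulus_amplitude=amp)


def lhs_sample(topology: Topology, n: int, seed: int) -> list[ParameterSet]:
    """n Latin-hypercube parameter sets for a topology."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = lhs_unit_matrix(n, seed, len(topology.nodes))
    return [parameter_set_from_row(topology, u[i]) for i in range(n)]


@dataclass
class QReport:
    """Robustness count of one topology for one function (or conjunction)."""

    topology_id: str
    link_vector: str | None
    function: str
    Q: int
    n_samples: int
    seed: int
    edge_count: int
    passing: list[int] = field(default_factory=list)  # LHS row indices that passed

    def __post_init__(self) -> None:
        assert 0 <= self.Q <= self.n_samples


def _topology_id(t: Topology) -> tuple[str, str | None]:
    if len(t.nodes) == 3:
        v = str(encode(t))
        return v, v
    desc = ";".join(f"{s}{'+' if v > 0 else '-'}{g}" for (s, g), v in sorted(t.links.items()))
    return desc, None


def q_value(
    t: Topology,
    function: str,
    n: int,
    seed: int,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> QReport:
    """Number of n LHS-sampled parameter sets achieving one function."""
    return q_multi(t, (function,), n, seed, config)


def q_multi(
    t: Topology,
    functions: Sequence[str],
    n: int,
    seed: int,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> QReport:
    """Parameter sets achieving *all* listed functions simultaneously.

    Each function is evaluated under its own single-stimulus protocol with
    the same parameter set (including the same sampled stimulus amplitude);
    the basal equilibration is shared across functions.
    """
    for fn in functions:
        if fn not in FUNCTIONS:
            raise ValueError(f"unknown function {fn!r}")
    u = lhs_unit_matrix(n, seed, len(t.nodes))
    tid, vec = _topology_id(t)
    passing = []
    for i in range(n):
        params = parameter_set_from_row(t, u[i])
        if _passes_all(t, params, functions, config):
            passing.append(i)
    return QReport(
        topology_id=tid,
        link_vector=vec,
        function="+".join(functions),
        Q=len(passing),
        n_samples=n,
        seed=seed,
        edge_count=t.n_edges,
        passing=passing,
    )


def _passes_all(
    t: Topology,
    params: ParameterSet,
    functions: Sequence[str],
    config: ClassifierConfig,
) -> bool:
    try:
        rf = build_rate_function(t, params)
        converged, x0 = equilibrate(rf)
    except Exception:
        return False
    if not converged:
        return False
    for fn in functions:
        verdict = evaluate(t, params, fn, config, rate_fn=rf, basal_state=x0)
        if not verdict.passed:
            return False
    return True


# ---------------------------------------------------------------------------
# Pools


@dataclass(frozen=True)
class PoolThreshold:
    """One (edge range, Q range) selection band; bounds on Q are strict."""

    edge_min: int
    edge_max: int
    q_min: float
    q_max: float = float("inf")

    def admits(self, report: QReport) -> bool:
        return (
            self.edge_min <= report.edge_count <= self.edge_max
            and self.q_min < report.Q < self.q_max
        )


#: Published selection bands at n = 10,000 samples: Q1 > 50 for 3-6 edges
#: plus 10 < Q1 < 50 for the simplest 3-edge oscillators, and Q2 > 55 /
#: 10 < Q2 < 55 for adaptation.
DEFAULT_THRESHOLDS: dict[str, tuple[PoolThreshold, ...]] = {
    "F1": (PoolThreshold(3, 6, 50), PoolThreshold(3, 3, 10, 50)),
    "F2": (PoolThreshold(3, 6, 55), PoolThreshold(3, 3, 10, 55)),
}


@dataclass
class Pool:
    function: str
    members: list[QReport]
    thresholds: tuple[PoolThreshold, ...]
    n_samples: int
    seed: int

    def __len__(self) -> int:
        return len(self.members)


def build_pool(
    function: str,
    topologies: Iterable[Topology],
    thresholds: Sequence[PoolThreshold] | None = None,
    n: int = 10_000,
    seed: int = 0,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> Pool:
    """Screen topologies and keep those admitted by any threshold band."""
    bands = tuple(thresholds) if thresholds is not None else DEFAULT_THRESHOLDS[function]
    members = []
    for t in topologies:
        report = q_value(t, function, n, seed, config)
        if any(b.admits(report) for b in bands):
            members.append(report)
    return Pool(function, members, bands, n, seed)
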