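"""Competition-modified Michaelis-Menten dynamics.

Every node is an enzyme with total concentration normalized to 1; the state
variable is the active-form fraction.  A regulator E converts each of its
targets between forms with Michaelis-Menten kinetics, and because all of E's
substrates bind the same enzyme they share a single saturation denominator:

    activation of T by E:    V * [E] * ((1-T)/K) / D_E
    deactivation of T by E:  V * [E] * (T/K)     / D_E
    D_E = 1 + sum over E's targets of substrate/K,

where the substrate concentration is ``1-T`` for an activated target and
``T`` for a deactivated one.  With out-degree one the denominator reduces to
the classic single-substrate Michaelis-Menten form.  Input signals regulate
only their receptor and never compete; a node lacking any in-network
activator (resp. deactivator) is regulated by a basally available background
enzyme at fixed concentration ``B``, also without competition.

Integration uses an adaptive Runge-Kutta-Fehlberg 4(5) stepper compiled with
numba (screening requires ~1e4 trajectory solves per topology), with a
scipy LSODA fallback for stiff parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .topology import Topology, RECEPTOR_ROLES

# Integrator defaults: relative/absolute tolerances of the adaptive RKF45
# stepper, the sampling grid for peak detection, and the equilibration
# horizon (time units are arbitrary).
RTOL = 1e-6
ATOL = 1e-9
SAMPLE_DT = 0.05
EQUILIBRATE_TMAX = 500.0
EQUILIBRATE_TOL = 1e-6
DEFAULT_INIT = 0.1
MAX_STEPS = 50_000

BASAL_INPUT = 0.1
BACKGROUND_B = 0.5


class IntegrationError(RuntimeError):
    """Raised when both the explicit stepper and the stiff fallback fail."""


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ParameterSet:
    """Kinetic constants for one topology.

    ``link`` carries (V, K) per explicit regulator->target link, ``input``
    per receptor's external-signal regulation, and ``basal`` per background
    regulation keyed by ``(node, "act"|"deact")``.  V is a catalytic rate
    constant (1/time, sampled in 0.1-10), K a Michaelis constant on the
    normalized concentration scale (sampled in 1e-3-10).
    """

    link: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    input: dict[str, tuple[float, float]] = field(default_factory=dict)
    basal: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    B: float = BACKGROUND_B
    basal_input: float = BASAL_INPUT
    stimulus_amplitude: float = 1.0

    def validate(self) -> None:
        for (v, k) in (
            list(self.link.values()) + list(self.input.values()) + list(self.basal.values())
        ):
            if v <= 0 or k <= 0:
                raise ValueError("all V and K must be strictly positive")
        if self.B <= 0 or self.basal_input <= 0:
            raise ValueError("B and basal_input must be strictly positive")
        if self.stimulus_amplitude < self.basal_input:
            raise ValueError("stimulus_amplitude must be >= basal_input")


def basal_requirements(t: Topology) -> list[tuple[str, str]]:
    """Background regulations a topology needs, per the basal rule.

    A node gets a basal activation exactly when it has no in-network
    activator (the input signal counts as the activator of its receptor),
    and a basal deactivation exactly when it has no in-network deactivator.
    """
    req = []
    receptor_ids = set(t.receptors.values())
    for n in t.node_ids:
        if not t.regulators_of(n, +1) and n not in receptor_ids:
            req.append((n, "act"))
        if not t.regulators_of(n, -1):
            req.append((n, "deact"))
    return req


def required_parameters(t: Topology) -> dict[str, list]:
    """Parameter slots a topology requires: explicit links, input links of
    its receptors, and basal regulations."""
    return {
        "link": sorted(t.links),
        "input": sorted(t.receptors.values()),
        "basal": basal_requirements(t),
    }


# ---------------------------------------------------------------------------
# Protocols and trajectories


@dataclass(frozen=True)
class StimulusProtocol:
    """A step stimulus on a single receptor: the input jumps instantaneously
    from ``pre`` to ``post`` at ``t_step`` and stays there until ``duration``."""

    receptor: str | None
    pre: float = BASAL_INPUT
    post: float = 1.0
    t_step: float = 0.0
    duration: float = 200.0


@dataclass
class Trajectory:
    """Sampled state time course."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_nodes)
    nodes: tuple[str, ...]
    protocol: StimulusProtocol | None = None

    def of(self, node: str) -> np.ndarray:
        return self.y[:, self.nodes.index(node)]


# ---------------------------------------------------------------------------
# Rate-law compilation


class RateFunction:
    """Compiled vector field for one (topology, parameter set) pair.

    The Michaelis-Menten terms are flattened into parallel arrays consumed
    both by the numba stepper and by a pure-numpy evaluator (used for
    root-finding and Jacobians; it accepts complex states, so complex-step
    differentiation works).  Calling the object evaluates d/dt of the state.
    """

    def __init__(
        self, topology: Topology, params: ParameterSet, competition: bool = True
    ) -> None:
        params.validate()
        self.topology = topology
        self.params = params
        self.competition = competition
        ids = topology.node_ids
        self.n = len(ids)
        idx = {nid: i for i, nid in enumerate(ids)}

        receptors = topology.receptors  # role -> id
        self.input_slot: dict[str, int] = {}  # receptor id -> ext-const slot
        const_slots = 0
        for role in RECEPTOR_ROLES:
            if role in receptors:
                self.input_slot[receptors[role]] = const_slots
                const_slots += 1
        self.b_slot = const_slots
        self.n_const = const_slots + 1

        V, K, reg, tgt, act, grp = [], [], [], [], [], []
        n_grp = 0

        def add(v: float, k: float, r: int, target: int, activating: bool, g: int):
            V.append(v)
            K.append(k)
            reg.append(r)
            tgt.append(target)
            act.append(1 if activating else 0)
            grp.append(g)

        # in-network regulations: all targets of one regulator share a group
        for rid in ids:
            targets = topology.targets_of(rid)
            if not targets:
                continue
            shared = n_grp
            if competition:
                n_grp += 1
            for tid, sign in sorted(targets):
                if rid not in idx:
                    raise KeyError(f"unknown node {rid!r}")
                if (rid, tid) not in params.link:
                    raise KeyError(f"missing (V, K) for link {rid}->{tid}")
                v, k = params.link[(rid, tid)]
                g = shared if competition else n_grp
                if not competition:
                    n_grp += 1
                add(v, k, idx[rid], idx[tid], sign > 0, g)
        # input signals: one private group each (no competition)
        for rid, slot in self.input_slot.items():
            if rid not in params.input:
                raise KeyError(f"missing (V, K) for input of receptor {rid}")
            v, k = params.input[rid]
            add(v, k, self.n + slot, idx[rid], True, n_grp)
            n_grp += 1
        # basal background regulation: node-private groups
        for (nid, direction) in basal_requirements(topology):
            if (nid, direction) not in params.basal:
                raise KeyError(f"missing basal (V, K) for {nid} ({direction})")
            v, k = params.basal[(nid, direction)]
            add(v, k, self.n + self.b_slot, idx[nid], direction == "act", n_grp)
            n_grp += 1

        self.V = np.asarray(V, float)
        self.K = np.asarray(K, float)
        self.reg = np.asarray(reg, np.int64)
        self.tgt = np.asarray(tgt, np.int64)
        self.act = np.asarray(act, np.int64)
        self.grp = np.asarray(grp, np.int64)
        self.n_grp = n_grp

    # -- input levels ----------------------------------------------------

    def const_vector(self, levels: Mapping[str, float] | None = None) -> np.ndarray:
        """Constant-entity concentrations: input level per receptor (basal
        unless overridden in ``levels``) and the background enzyme B."""
        c = np.empty(self.n_const)
        for rid, slot in self.input_slot.items():
            c[slot] = self.params.basal_input
        if levels:
            for rid, val in levels.items():
                c[self.input_slot[rid]] = val
        c[self.b_slot] = self.params.B
        return c

    # -- evaluation ------------------------------------------------------

    def __call__(self, x: np.ndarray, levels: Mapping[str, float] | None = None,
                 const: np.ndarray | None = None) -> np.ndarray:
        """d/dt of the state (numpy path; accepts complex ``x``)."""
        c = self.const_vector(levels) if const is None else const
        ext = np.concatenate([x, c.astype(x.dtype)])
        e = ext[self.reg]
        xt = np.asarray(x)[self.tgt]
        sub = np.where(self.act == 1, 1.0 - xt, xt) if not np.iscomplexobj(x) else (
            self.act * (1.0 - xt) + (1 - self.act) * xt
        )
        s = sub / self.K
        d = np.ones(self.n_grp, dtype=ext.dtype)
        np.add.at(d, self.grp, s)
        rate = self.V * e * s / d[self.grp]
        f = np.zeros(self.n, dtype=ext.dtype)
        np.add.at(f, self.tgt, np.where(self.act == 1, 1, -1) * rate)
        return f


def build_rate_function(
    topology: Topology, params: ParameterSet, competition: bool = True
) -> RateFunction:
    """Compile a topology + parameter set into a rate evaluator."""
    return RateFunction(topology, params, competition)


# ---------------------------------------------------------------------------
# Numba RKF45 stepper

@njit(cache=True)
def _rhs_nb(x, const, V, K, reg, tgt, act, grp, n_grp, f):  # pragma: no cover
    n = x.shape[0]
    nt = V.shape[0]
    d = np.ones(n_grp)
    s = np.empty(nt)
    for i in range(nt):
        xt = x[tgt[i]]
        sub = 1.0 - xt if act[i] == 1 else xt
        si = sub / K[i]
        s[i] = si
        d[grp[i]] += si
    for i in range(n):
        f[i] = 0.0
    for i in range(nt):
        r = reg[i]
        e = x[r] if r < n else const[r - n]
        rate = V[i] * e * s[i] / d[grp[i]]
        if act[i] == 1:
            f[tgt[i]] += rate
        else:
            f[tgt[i]] -= rate
    return f


@njit(cache=True)
def _integrate_nb(
    x0, t0, t1, const, V, K, reg, tgt, act, grp, n_grp,
    rtol, atol, max_steps, grid, out, conv_tol,
):  # pragma: no cover - exercised through the python wrappers
    """Adaptive RKF45 from t0 to t1.

    Samples onto ``grid`` (monotone times within [t0, t1]) by cubic Hermite
    interpolation; if ``conv_tol > 0`` stops early once the max-norm of the
    vector field drops below it.  Returns (status, t, x) with status 0 =
    reached t1, 1 = converged early, 2 = step budget exhausted, 3 = numerical
    failure.
    """
    n = x0.shape[0]
    x = x0.copy()
    t = t0
    f0 = np.empty(n)
    _rhs_nb(x, const, V, K, reg, tgt, act, grp, n_grp, f0)
    gi = 0
    ng = grid.shape[0]
    while gi < ng and grid[gi] <= t0:
        for j in range(n):
            out[gi, j] = x[j]
        gi += 1
    if conv_tol > 0.0:
        mx = 0.0
        for j in range(n):
            a = abs(f0[j])
            if a > mx:
                mx = a
        if mx < conv_tol:
            return 1, t, x
    h = 0.01
    hmax = 5.0
    k = np.empty((6, n))
    xs = np.empty(n)
    x4 = np.empty(n)
    x5 = np.empty(n)
    f1 = np.empty(n)
    a2 = (0.25,)
    steps = 0
    while t < t1:
        if steps >= max_steps:
            return 2, t, x
        steps += 1
        if t + h > t1:
            h = t1 - t
        for j in range(n):
            k[0, j] = f0[j]
        # stages 2..6
        for j in range(n):
            xs[j] = x[j] + h * 0.25 * k[0, j]
        _rhs_nb(xs, const, V, K, reg, tgt, act, grp, n_grp, k[1])
        for j in range(n):
            xs[j] = x[j] + h * (3.0 / 32.0 * k[0, j] + 9.0 / 32.0 * k[1, j])
        _rhs_nb(xs, const, V, K, reg, tgt, act, grp, n_grp, k[2])
        for j in range(n):
            xs[j] = x[j] + h * (
                1932.0 / 2197.0 * k[0, j]
                - 7200.0 / 2197.0 * k[1, j]
                + 7296.0 / 2197.0 * k[2, j]
            )
        _rhs_nb(xs, const, V, K, reg, tgt, act, grp, n_grp, k[3])
        for j in range(n):
            xs[j] = x[j] + h * (
                439.0 / 216.0 * k[0, j]
                - 8.0 * k[1, j]
                + 3680.0 / 513.0 * k[2, j]
                - 845.0 / 4104.0 * k[3, j]
            )
        _rhs_nb(xs, const, V, K, reg, tgt, act, grp, n_grp, k[4])
        for j in range(n):
            xs[j] = x[j] + h * (
                -8.0 / 27.0 * k[0, j]
                + 2.0 * k[1, j]
                - 3544.0 / 2565.0 * k[2, j]
                + 1859.0 / 4104.0 * k[3, j]
                - 11.0 / 40.0 * k[4, j]
            )
        _rhs_nb(xs, const, V, K, reg, tgt, act, grp, n_grp, k[5])
        # 4th/5th order solutions and error estimate
        err = 0.0
        ok = True
        for j in range(n):
            x5[j] = x[j] + h * (
                16.0 / 135.0 * k[0, j]
                + 6656.0 / 12825.0 * k[2, j]
                + 28561.0 / 56430.0 * k[3, j]
                - 9.0 / 50.0 * k[4, j]
                + 2.0 / 55.0 * k[5, j]
            )
            x4[j] = x[j] + h * (
                25.0 / 216.0 * k[0, j]
                + 1408.0 / 2565.0 * k[2, j]
                + 2197.0 / 4104.0 * k[3, j]
                - 1.0 / 5.0 * k[4, j]
            )
            if not np.isfinite(x5[j]) or abs(x5[j]) > 10.0:
                ok = False
                break
            sc = atol + rtol * max(abs(x[j]), abs(x5[j]))
            e = abs(x5[j] - x4[j]) / sc
            if e > err:
                err = e
        if not ok:
            h *= 0.25
            if h < 1e-14:
                return 3, t, x
            continue
        if err <= 1.0:
            t_new = t + h
            _rhs_nb(x5, const, V, K, reg, tgt, act, grp, n_grp, f1)
            # cubic Hermite sampling over [t, t_new]
            while gi < ng and grid[gi] <= t_new:
                s = (grid[gi] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for j in range(n):
                    out[gi, j] = (
                        h00 * x[j] + h10 * h * f0[j] + h01 * x5[j] + h11 * h * f1[j]
                    )
                gi += 1
            for j in range(n):
                x[j] = x5[j]
                f0[j] = f1[j]
            t = t_new
            if conv_tol > 0.0:
                mx = 0.0
                for j in range(n):
                    a = abs(f0[j])
                    if a > mx:
                        mx = a
                if mx < conv_tol:
                    return 1, t, x
        fac = 0.9 * err ** -0.2 if err > 1e-12 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.1:
            fac = 0.1
        h *= fac
        if h > hmax:
            h = hmax
        if h < 1e-14:
            return 3, t, x
    return 0, t, x


def _run_numba(
    rf: RateFunction,
    x0: np.ndarray,
    t0: float,
    t1: float,
    const: np.ndarray,
    grid: np.ndarray,
    conv_tol: float = 0.0,
    rtol: float = RTOL,
    atol: float = ATOL,
    max_steps: int = MAX_STEPS,
) -> tuple[int, float, np.ndarray, np.ndarray]:
    out = np.empty((len(grid), rf.n))
    status, t, x = _integrate_nb(
        np.asarray(x0, float), float(t0), float(t1), const,
        rf.V, rf.K, rf.reg, rf.tgt, rf.act, rf.grp, rf.n_grp,
        rtol, atol, max_steps, np.asarray(grid, float), out, conv_tol,
    )
    return status, t, x, out


def _run_scipy(
    rf: RateFunction,
    x0: np.ndarray,
    t0: float,
    t1: float,
    const: np.ndarray,
    grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Stiff fallback: LSODA via solve_ivp (numba-compiled right-hand side)."""
    buf = np.empty(rf.n)
    sol = solve_ivp(
        lambda t, x: _rhs_nb(
            x, const, rf.V, rf.K, rf.reg, rf.tgt, rf.act, rf.grp, rf.n_grp, buf
        ).copy(),
        (t0, t1),
        x0,
        method="LSODA",
        dense_output=bool(len(grid)),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message)
    out = sol.sol(grid).T if len(grid) else np.empty((0, rf.n))
    return out, sol.y[:, -1] if sol.y.size else x0


# ---------------------------------------------------------------------------
# High-level operations


def initial_state(rf: RateFunction, value: float = DEFAULT_INIT) -> np.ndarray:
    return np.full(rf.n, value)


def equilibrate(
    rf: RateFunction,
    init: np.ndarray | None = None,
    tol: float = EQUILIBRATE_TOL,
    t_max: float = EQUILIBRATE_TMAX,
    levels: Mapping[str, float] | None = None,
    strict: bool = False,
) -> tuple[bool, np.ndarray]:
    """Integrate under (basal) inputs until the rate norm drops below tol.

    Returns ``(converged, state)``; ``converged`` is False when the horizon
    ``t_max`` is reached first (e.g. a basal-state oscillator).  With
    ``strict`` a numerical failure raises :class:`IntegrationError` instead
    of being reported as non-converged.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x0 = initial_state(rf) if init is None else np.asarray(init, float)
    const = rf.const_vector(levels)
    empty = np.empty(0)
    status, t, x, _ = _run_numba(rf, x0, 0.0, t_max, const, empty, conv_tol=tol)
    if status in (2, 3):
        try:
            _, x = _run_scipy(rf, x0, 0.0, t_max, const, empty)
            status = 1 if np.max(np.abs(rf(x, const=const))) < tol else 0
        except IntegrationError:
            if strict:
                raise
            return False, x0
    return status == 1, x


def simulate(
    rf: RateFunction,
    protocol: StimulusProtocol,
    init: np.ndarray,
    sample_dt: float = SAMPLE_DT,
) -> Trajectory:
    """Integrate a step-stimulus protocol, sampling on a fixed grid.

    The stimulated receptor's input sits at ``protocol.pre`` until
    ``t_step`` and jumps instantaneously to ``protocol.post``; all other
    inputs stay basal.  A numerical failure of the explicit stepper is
    retried with the stiff LSODA fallback and raises
    :class:`IntegrationError` only if that fails too.
    """
    init = np.asarray(init, float)
    if np.any(init < -1e-6) or np.any(init > 1 + 1e-6):
        raise ValueError("init must lie in [0, 1] componentwise")
    init = np.clip(init, 0.0, 1.0)
    grid = np.round(
        np.arange(0.0, protocol.duration + sample_dt / 2, sample_dt), 10
    )
    pre_levels = {} if protocol.receptor is None else {protocol.receptor: protocol.pre}
    post_levels = {} if protocol.receptor is None else {protocol.receptor: protocol.post}
    segments = []
    x = init
    if protocol.t_step > 0:
        segments.append((0.0, protocol.t_step, rf.const_vector(pre_levels)))
    segments.append((protocol.t_step, protocol.duration, rf.const_vector(post_levels)))
    ys = np.empty((len(grid), rf.n))
    for (t0, t1, const) in segments:
        mask = (grid >= t0) & (grid <= t1) if t0 == 0 else (grid > t0) & (grid <= t1)
        sub = grid[mask]
        status, _, x_end, out = _run_numba(rf, x, t0, t1, const, sub)
        if status in (2, 3):
            out, x_end = _run_scipy(rf, x, t0, t1, const, sub)
        ys[mask] = out
        x = x_end
    if len(grid) and grid[0] == 0.0:
        ys[0] = init
    return Trajectory(grid, ys, rf.topology.node_ids, protocol)


def jacobian(
    rf: RateFunction,
    x: np.ndarray,
    levels: Mapping[str, float] | None = None,
    method: str = "central",
    h: float = 1e-6,
) -> np.ndarray:
    """Jacobian of the vector field at ``x``.

    ``central`` uses second-order finite differences; ``complex`` uses
    complex-step differentiation (exact to machine precision for these
    rational rate laws).
    """
    x = np.asarray(x, float)
    const = rf.const_vector(levels)
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        if method == "complex":
            xc = x.astype(complex)
            xc[j] += 1j * 1e-20
            J[:, j] = rf(xc, const=const).imag / 1e-20
        elif method == "central":
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (rf(xp, const=const) - rf(xm, const=const)) / (2 * h)
        else:
            raise ValueError(f"unknown method {method!r}")
    return J
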