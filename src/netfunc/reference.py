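"""The N5 tri-functional reference network and its dynamics analysis.

N5 is the simplest robust network found by the module-combination search:
four nodes (receptors R1, R2, R3 and the output O) wired as

    R3 -| R1,   R1 -| O,   R2 -> O,   O -| R3,

with each receptor activated by its own external signal and R2 deactivated
by the background enzyme.  The R1-R3-O triangle is a negative feedback loop
that oscillates under stimulus I1; R3 is a buffer node whose saturated
kinetics (K3 << 1 - R3, K7 << R3) enforce dR3/dt ~ V3*I3 - V7*O and hence a
perfectly adapting output steady state O_ss = V3*I3/V7, independent of I2;
and I3 drives sustained activation of O directly through that same balance.

This module provides the printed model constants, steady-state continuation
in a stimulus amplitude with Hopf detection and sub/supercritical
classification, the oscillation-onset scan, the adaptation closed form, and
steady-state response curves, plus a minimal SBML Level 3 export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import root

from .classify import ClassifierConfig, DEFAULT_CONFIG, extract_features, is_oscillation
from .dynamics import (
    ParameterSet,
    RateFunction,
    StimulusProtocol,
    build_rate_function,
    equilibrate,
    initial_state,
    jacobian,
    simulate,
)
from .topology import Node, Topology

#: Printed kinetic constants of the N5 model (V1..V8, K1..K8 index the
#: regulations in the order: I1->R1, I2->R2, I3->R3, R2->O, R3-|R1, B-|R2,
#: O-|R3, R1-|O).
N5_CONSTANTS = {
    "V1": 0.3156, "V2": 1.8362, "V3": 0.7503, "V4": 0.5559,
    "V5": 2.3514, "V6": 0.2716, "V7": 0.7010, "V8": 0.6726,
    "K1": 5.1160, "K2": 0.3030, "K3": 0.0111, "K4": 1.2833,
    "K5": 0.0259, "K6": 0.0277, "K7": 0.0014, "K8": 0.0099,
    "B": 0.5,
}


def n5_model() -> tuple[Topology, ParameterSet]:
    """The N5 topology and its printed parameter set.

    Compiling this pair with :func:`~netfunc.dynamics.build_rate_function`
    reproduces the reference equations exactly: every regulator has a single
    target, so all competition denominators reduce to the classic
    single-substrate Michaelis-Menten form.
    """
    c = N5_CONSTANTS
    topology = Topology(
        nodes=[
            Node("R1", "receptor-1"),
            Node("R2", "receptor-2"),
            Node("R3", "receptor-3"),
            Node("O", "output"),
        ],
        links={("R3", "R1"): -1, ("R2", "O"): +1, ("R1", "O"): -1, ("O", "R3"): -1},
    )
    params = ParameterSet(
        input={
            "R1": (c["V1"], c["K1"]),
            "R2": (c["V2"], c["K2"]),
            "R3": (c["V3"], c["K3"]),
        },
        link={
            ("R2", "O"): (c["V4"], c["K4"]),
            ("R3", "R1"): (c["V5"], c["K5"]),
            ("O", "R3"): (c["V7"], c["K7"]),
            ("R1", "O"): (c["V8"], c["K8"]),
        },
        basal={("R2", "deact"): (c["V6"], c["K6"])},
        B=c["B"],
    )
    return topology, params


# ---------------------------------------------------------------------------
# Steady-state continuation and Hopf detection


@dataclass
class SteadyStateCurve:
    """Steady states along a stimulus grid; each accepted point satisfies
    ||f|| < 1e-8.  ``envelope`` carries (min, max) of the output tail where
    the attractor is a limit cycle rather than a fixed point."""

    stimulus: str
    values: np.ndarray
    states: np.ndarray  # (len(values), n_nodes); nan rows where unconverged
    converged: np.ndarray
    nodes: tuple[str, ...]
    envelope: np.ndarray | None = None  # (len(values), 2) for oscillatory scans


@dataclass
class HopfScanResult:
    control: str
    grid: np.ndarray
    leading_real: np.ndarray  # max real part of the Jacobian spectrum on the branch
    I_c: float | None
    classification: str  # "subcritical" | "supercritical" | "none"
    onset_amplitude: float | None = None
    states: np.ndarray | None = None


_ROLE_OF = {"I1": "receptor-1", "I2": "receptor-2", "I3": "receptor-3"}


def _receptor_id(topology: Topology, control: str) -> str:
    rid = topology.receptor(_ROLE_OF[control])
    if rid is None:
        raise ValueError(f"model has no {_ROLE_OF[control]} node for {control}")
    return rid


def _steady_state(
    rf: RateFunction, levels: Mapping[str, float], x0: np.ndarray, tol: float = 1e-11
) -> np.ndarray | None:
    const = rf.const_vector(levels)
    sol = root(lambda x: rf(x, const=const), x0, tol=tol)
    if not sol.success or np.max(np.abs(rf(sol.x, const=const))) > 1e-8:
        return None
    if np.any(sol.x < -1e-9) or np.any(sol.x > 1 + 1e-9):
        return None
    return sol.x


def _leading_eigs(rf: RateFunction, x: np.ndarray, levels: Mapping[str, float]):
    eigs = np.linalg.eigvals(jacobian(rf, x, levels=levels, method="complex"))
    return eigs[np.argsort(eigs.real)[::-1]]


def hopf_scan(
    model: tuple[Topology, ParameterSet] | None = None,
    control: str = "I1",
    lo: float = 0.1,
    hi: float = 0.5,
    n_grid: int = 41,
    refine_tol: float = 1e-3,
    probe_offset: float = 0.02,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> HopfScanResult:
    """Locate a Hopf bifurcation in a stimulus amplitude by continuation.

    Tracks the steady-state branch over ``n_grid`` points (each root solve
    seeded by the previous solution), watches the real part of the leading
    complex eigenvalue pair, bisects its zero crossing to ``refine_tol`` and
    classifies criticality with a simulation probe just below the crossing:
    a sustained oscillation reached by a step from the resting state while
    the fixed point is still stable means a coexisting stable limit cycle,
    the signature of a subcritical Hopf.
    """
    topology, params = n5_model() if model is None else model
    rf = build_rate_function(topology, params)
    rid = _receptor_id(topology, control)
    grid = np.linspace(lo, hi, n_grid)
    conv, x = equilibrate(rf, levels={rid: grid[0]})
    states = np.full((n_grid, rf.n), np.nan)
    leading = np.full(n_grid, np.nan)
    complex_pair = np.zeros(n_grid, dtype=bool)
    for i, val in enumerate(grid):
        ss = _steady_state(rf, {rid: val}, x)
        if ss is None:
            raise RuntimeError(f"no steady state found on branch at {control}={val}")
        x = ss
        states[i] = ss
        eigs = _leading_eigs(rf, ss, {rid: val})
        leading[i] = eigs[0].real
        complex_pair[i] = abs(eigs[0].imag) > 1e-9
    # zero crossing of the leading real part with a complex pair
    I_c = None
    for i in range(n_grid - 1):
        if leading[i] < 0 <= leading[i + 1] or leading[i] >= 0 > leading[i + 1]:
            if not (complex_pair[i] or complex_pair[i + 1]):
                continue
            a, b = grid[i], grid[i + 1]
            xa = states[i]
            while b - a > refine_tol:
                mid = 0.5 * (a + b)
                ss = _steady_state(rf, {rid: mid}, xa)
                if ss is None:
                    break
                r = _leading_eigs(rf, ss, {rid: mid})[0].real
                if (r >= 0) == (leading[i + 1] >= 0):
                    b = mid
                else:
                    a, xa = mid, ss
            I_c = 0.5 * (a + b)
            break
    if I_c is None:
        return HopfScanResult(control, grid, leading, None, "none", states=states)
    # criticality probe below the crossing
    probe = I_c - probe_offset
    classification = "supercritical"
    ss = _steady_state(rf, {rid: probe}, states[np.argmin(np.abs(grid - probe))])
    if ss is not None and _leading_eigs(rf, ss, {rid: probe})[0].real < 0:
        conv0, x0 = equilibrate(rf)
        traj = simulate(
            rf,
            StimulusProtocol(rid, pre=params.basal_input, post=probe,
                             duration=config.duration),
            x0,
        )
        feats = extract_features(traj, topology.output, config.tail_fraction)
        if is_oscillation(feats, config.min_cycles, config).passed:
            classification = "subcritical"
    return HopfScanResult(control, grid, leading, float(I_c), classification,
                          states=states)


def onset_scan(
    model: tuple[Topology, ParameterSet] | None = None,
    amplitudes: Sequence[float] | None = None,
    control: str = "I1",
    from_rest: bool = False,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> float | None:
    """Smallest stimulus amplitude whose step response oscillates.

    Applies the stimulus from the standard uniform initial state (all
    active fractions 0.1) to each amplitude in ascending order and returns
    the first one classified as sustained oscillation (None if none
    passes).  In the bistable window of a subcritical Hopf the outcome
    depends on the initial condition: with ``from_rest`` the system is
    first equilibrated at basal inputs, and the fully settled rest state
    can fall inside the stable fixed point's basin, giving a later onset.
    """
    topology, params = n5_model() if model is None else model
    if amplitudes is None:
        amplitudes = np.arange(0.10, 0.5001, 0.05)
    amplitudes = np.asarray(sorted(amplitudes), float)
    rf = build_rate_function(topology, params)
    rid = _receptor_id(topology, control)
    if from_rest:
        conv, x0 = equilibrate(rf)
        if not conv:
            raise RuntimeError("basal state does not converge")
    else:
        x0 = initial_state(rf)
    for amp in amplitudes:
        traj = simulate(
            rf,
            StimulusProtocol(rid, pre=params.basal_input, post=float(amp),
                             duration=config.duration),
            x0,
        )
        feats = extract_features(traj, topology.output, config.tail_fraction)
        if is_oscillation(feats, config.min_cycles, config).passed:
            return float(amp)
    return None


# ---------------------------------------------------------------------------
# Adaptation closed form and response curves


@dataclass
class AdaptationPrediction:
    O_ss: float
    K3_saturated: bool
    K7_saturated: bool


def adaptation_prediction(
    params: ParameterSet | None = None, I3: float = 0.1
) -> AdaptationPrediction:
    """Closed-form adapted output level O_ss = V3 * I3 / V7.

    Valid when the buffer node R3 operates in its saturated regime:
    K3 << 1 - R3 for the activation by I3 and K7 << R3 for the deactivation
    by O, which turns the R3 balance into the integral relation
    dR3/dt ~ V3*I3 - V7*O.  The saturation premises are checked at the
    simulated basal steady state.
    """
    topology, p = n5_model()
    if params is not None:
        p = params
    V3, K3 = p.input["R3"]
    V7, K7 = p.link[("O", "R3")]
    rf = build_rate_function(topology, p)
    conv, x = equilibrate(rf, levels={"R3": I3})
    r3 = x[list(topology.node_ids).index("R3")]
    return AdaptationPrediction(
        O_ss=V3 * I3 / V7,
        K3_saturated=bool(K3 < 0.1 * (1 - r3)),
        K7_saturated=bool(K7 < 0.1 * r3) if r3 > 0 else False,
    )


def response_curves(
    model: tuple[Topology, ParameterSet] | None = None,
    stimulus: str = "I2",
    grid: Sequence[float] | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> SteadyStateCurve:
    """Steady states across a stimulus grid (oscillation envelope for I1).

    For I2 and I3 the fixed point is continued across the grid; grid points
    where no steady state is found are flagged unconverged.  For I1 the
    long-run output envelope (tail min/max of a step simulation) is
    recorded instead, since the attractor becomes a limit cycle.
    """
    topology, params = n5_model() if model is None else model
    rid = _receptor_id(topology, stimulus)
    if grid is None:
        grid = np.linspace(0.1, 1.0, 10)
    grid = np.asarray(grid, float)
    rf = build_rate_function(topology, params)
    n = rf.n
    states = np.full((len(grid), n), np.nan)
    converged = np.zeros(len(grid), dtype=bool)
    envelope = None
    if stimulus == "I1":
        envelope = np.full((len(grid), 2), np.nan)
        _, x0 = equilibrate(rf)
        for i, val in enumerate(grid):
            traj = simulate(
                rf,
                StimulusProtocol(rid, pre=params.basal_input, post=float(val),
                                 duration=config.duration),
                x0,
            )
            o = traj.of(topology.output)
            tail = o[len(o) // 2:]
            envelope[i] = (tail.min(), tail.max())
            states[i] = traj.y[-1]
            converged[i] = True
    else:
        conv, x = equilibrate(rf)
        for i, val in enumerate(grid):
            ss = _steady_state(rf, {rid: val}, x)
            if ss is not None:
                states[i] = x = ss
                converged[i] = True
    return SteadyStateCurve(stimulus, grid, states, converged, topology.node_ids,
                            envelope)


# ---------------------------------------------------------------------------
# SBML export


def export_sbml(path: str | None = None) -> str:
    """Minimal SBML Level 3 core serialization of the N5 model.

    Species are the active-form fractions (dimensionless, totals normalized
    to 1), parameters the printed constants plus the three basal input
    levels, and the dynamics are expressed as rate rules whose MathML is
    generated symbolically.  Returns the document as a string and optionally
    writes it to ``path``.
    """
    import sympy as sp
    from sympy.printing.mathml import mathml

    c = N5_CONSTANTS
    R1, R2, R3, O = sp.symbols("R1 R2 R3 O")
    syms = {name: sp.Symbol(name) for name in list(c) + ["I1", "I2", "I3"]}
    s = syms
    rates = {
        "R1": s["V1"] * s["I1"] * (1 - R1) / (s["K1"] + 1 - R1)
        - s["V5"] * R3 * R1 / (s["K5"] + R1),
        "R2": s["V2"] * s["I2"] * (1 - R2) / (s["K2"] + 1 - R2)
        - s["V6"] * s["B"] * R2 / (s["K6"] + R2),
        "R3": s["V3"] * s["I3"] * (1 - R3) / (s["K3"] + 1 - R3)
        - s["V7"] * O * R3 / (s["K7"] + R3),
        "O": s["V4"] * R2 * (1 - O) / (s["K4"] + 1 - O)
        - s["V8"] * R1 * O / (s["K8"] + O),
    }
    species = {"R1": 0.1, "R2": 0.1, "R3": 0.1, "O": 0.1}
    params = dict(c, I1=0.1, I2=0.1, I3=0.1)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" '
        'level="3" version="2">',
        '  <model id="N5" name="N5 tri-functional enzymatic network">',
        '    <listOfCompartments>',
        '      <compartment id="cell" spatialDimensions="3" size="1" constant="true"/>',
        '    </listOfCompartments>',
        '    <listOfSpecies>',
    ]
    for sid, init in species.items():
        lines.append(
            f'      <species id="{sid}" compartment="cell" '
            f'initialConcentration="{init}" hasOnlySubstanceUnits="false" '
            f'boundaryCondition="false" constant="false"/>'
        )
    lines.append("    </listOfSpecies>")
    lines.append("    <listOfParameters>")
    for pid, val in params.items():
        lines.append(f'      <parameter id="{pid}" value="{val}" constant="true"/>')
    lines.append("    </listOfParameters>")
    lines.append("    <listOfRules>")
    import re

    def _content_mathml(expr) -> str:
        # sympy's content printer renders subscripted symbols (R1, K5, ...)
        # as presentation <mml:msub> inside <ci>; SBML wants a plain <ci>.
        s = mathml(expr)
        return re.sub(
            r"<ci><mml:msub><mml:mi>(\w+)</mml:mi><mml:mi>(\w+)</mml:mi>"
            r"</mml:msub></ci>",
            r"<ci>\1\2</ci>",
            s,
        )

    for sid, expr in rates.items():
        body = _content_mathml(expr)
        lines.append(f'      <rateRule variable="{sid}">')
        lines.append('        <math xmlns="http://www.w3.org/1998/Math/MathML">')
        lines.append(f"          {body}")
        lines.append("        </math>")
        lines.append("      </rateRule>")
    lines.append("    </listOfRules>")
    lines.append("  </model>")
    lines.append("</sbml>")
    doc = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc
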