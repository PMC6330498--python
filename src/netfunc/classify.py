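"""Trajectory features and function verdicts.

Three target input-output behaviours are screened for, each tied to a step
stimulus on its own receptor:

* F1 (oscillation, receptor-1): sustained limit-cycle output with amplitude
  and period both above 0.1 and a clearly nonzero tail variance;
* F2 (transient activation / adaptation, receptor-2): the output pulses up
  by more than 0.2 and returns to within 0.1 of its pre-stimulus level (and
  within half the pulse height);
* F3 (sustained activation, receptor-3): the output settles more than 0.2
  above its pre-stimulus level.

All criteria are evaluated on scalar features extracted from the output
node's time course after the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .dynamics import (
    IntegrationError,
    ParameterSet,
    RateFunction,
    StimulusProtocol,
    Trajectory,
    build_rate_function,
    equilibrate,
    simulate,
)
from .topology import Topology

FUNCTIONS = ("F1", "F2", "F3")
FUNCTION_RECEPTOR = {"F1": "receptor-1", "F2": "receptor-2", "F3": "receptor-3"}


@dataclass(frozen=True)
class ClassifierConfig:
    """Numerical thresholds and windows of the three function classifiers.

    The thresholds default to the published criteria (amplitude/period 0.1,
    pulse 0.2, return band 0.1); the windows (200-time-unit horizon, tail =
    last half) are package choices for "after the transient dies out".
    ``enforce_half_return`` switches the third adaptation condition
    |O_end - O_ini| < 0.5 (O_peak - O_ini); loosening any threshold can only
    grow a functional pool.
    """

    osc_amplitude: float = 0.1
    osc_period: float = 0.1
    eps_var: float = 1e-6
    min_cycles: int = 3
    adapt_pulse: float = 0.2
    adapt_return: float = 0.1
    enforce_half_return: bool = True
    sustained_delta: float = 0.2
    duration: float = 200.0
    tail_fraction: float = 0.5


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class TrajectoryFeatures:
    """Scalar summary of the output node's response to a step stimulus."""

    O_ini: float
    O_peak: float
    O_end: float
    amplitude: float
    period: float  # nan when too few peaks to estimate
    tail_variance: float
    n_peaks: int


@dataclass
class FunctionVerdict:
    function: str
    passed: bool
    features: TrajectoryFeatures | None = None
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed

    def to_record(self, topology_id: str = "") -> dict:
        """Flat record for CSV serialization of screening verdicts."""
        f = self.features
        return {
            "topology": topology_id,
            "function": self.function,
            "passed": self.passed,
            "O_ini": f.O_ini if f else math.nan,
            "O_peak": f.O_peak if f else math.nan,
            "O_end": f.O_end if f else math.nan,
            "amplitude": f.amplitude if f else math.nan,
            "period": f.period if f else math.nan,
            "reason": self.reason or "",
        }


def extract_features(
    traj: Trajectory,
    output: str | None = None,
    tail_fraction: float = DEFAULT_CONFIG.tail_fraction,
) -> TrajectoryFeatures:
    """Features of the output time course.

    ``O_ini`` is the first sample (the pre-stimulus steady state when the
    trajectory starts from an equilibrated state), ``O_peak`` the maximum
    over the whole post-step course, and the tail window (the trailing
    ``tail_fraction`` of the horizon) yields ``O_end`` (mean), amplitude
    (max - min), variance, and the period as the mean spacing of tail maxima.
    """
    o = traj.y[:, -1] if output is None else traj.of(output)
    n = len(o)
    if n < 8:
        raise ValueError("trajectory too short for feature extraction")
    k = int(n * (1.0 - tail_fraction))
    tail = o[k:]
    tail_t = traj.t[k:]
    peaks, _ = find_peaks(tail, prominence=1e-4)
    period = float(np.mean(np.diff(tail_t[peaks]))) if len(peaks) >= 2 else math.nan
    return TrajectoryFeatures(
        O_ini=float(o[0]),
        O_peak=float(np.max(o)),
        O_end=float(np.mean(tail)),
        amplitude=float(np.max(tail) - np.min(tail)),
        period=period,
        tail_variance=float(np.var(tail)),
        n_peaks=int(len(peaks)),
    )


def is_oscillation(
    f: TrajectoryFeatures,
    min_cycles: int = DEFAULT_CONFIG.min_cycles,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> FunctionVerdict:
    """Sustained-oscillation verdict (F1)."""
    if f.tail_variance <= config.eps_var:
        return FunctionVerdict("F1", False, f, "tail-variance-zero")
    if f.amplitude <= config.osc_amplitude:
        return FunctionVerdict("F1", False, f, "amplitude-below-threshold")
    if f.n_peaks < min_cycles + 1:
        return FunctionVerdict("F1", False, f, "too-few-cycles")
    if not (f.period > config.osc_period):
        return FunctionVerdict("F1", False, f, "period-below-threshold")
    return FunctionVerdict("F1", True, f)


def is_adaptation(
    f: TrajectoryFeatures, config: ClassifierConfig = DEFAULT_CONFIG
) -> FunctionVerdict:
    """Transient-activation (adaptation) verdict (F2)."""
    pulse = f.O_peak - f.O_ini
    resid = abs(f.O_end - f.O_ini)
    if not pulse > config.adapt_pulse:
        return FunctionVerdict("F2", False, f, "pulse-too-small")
    if not resid < config.adapt_return:
        return FunctionVerdict("F2", False, f, "no-return-to-baseline")
    if config.enforce_half_return and not resid < 0.5 * pulse:
        return FunctionVerdict("F2", False, f, "residual-above-half-pulse")
    return FunctionVerdict("F2", True, f)


def is_sustained(
    f: TrajectoryFeatures, config: ClassifierConfig = DEFAULT_CONFIG
) -> FunctionVerdict:
    """Sustained-activation verdict (F3): a non-oscillatory shift up by > 0.2."""
    if f.tail_variance > config.eps_var:
        return FunctionVerdict("F3", False, f, "tail-oscillatory")
    if not f.O_end - f.O_ini > config.sustained_delta:
        return FunctionVerdict("F3", False, f, "shift-too-small")
    return FunctionVerdict("F3", True, f)


_CLASSIFIERS = {
    "F1": lambda f, c: is_oscillation(f, c.min_cycles, c),
    "F2": lambda f, c: is_adaptation(f, c),
    "F3": lambda f, c: is_sustained(f, c),
}


def _receptor_for(topology: Topology, function: str) -> str:
    role = FUNCTION_RECEPTOR[function]
    rid = topology.receptor(role)
    if rid is None:
        receptors = topology.receptors
        if len(receptors) == 1:
            return next(iter(receptors.values()))
        raise ValueError(
            f"topology has no {role} node required for {function}"
        )
    return rid


def evaluate(
    topology: Topology,
    params: ParameterSet,
    function: str,
    config: ClassifierConfig = DEFAULT_CONFIG,
    amplitude: float | None = None,
    rate_fn: RateFunction | None = None,
    basal_state: np.ndarray | None = None,
) -> FunctionVerdict:
    """Full single-stimulus evaluation of one function on one topology.

    Equilibrates under basal inputs (failing with ``no-basal-steady-state``
    if the resting state does not converge), then steps the function's
    receptor to the stimulus amplitude while all other inputs stay basal,
    simulates, and classifies.  Integration failures are recorded as a
    failing verdict, never raised, so parameter screens are never aborted.
    ``rate_fn``/``basal_state`` allow reuse across functions evaluated on
    the same parameter set.
    """
    if function not in FUNCTIONS:
        raise ValueError(f"unknown function {function!r}")
    rid = _receptor_for(topology, function)
    try:
        rf = rate_fn if rate_fn is not None else build_rate_function(topology, params)
        if basal_state is None:
            converged, x0 = equilibrate(rf)
            if not converged:
                return FunctionVerdict(function, False, None, "no-basal-steady-state")
        else:
            x0 = basal_state
        amp = params.stimulus_amplitude if amplitude is None else amplitude
        protocol = StimulusProtocol(
            rid, pre=params.basal_input, post=amp, t_step=0.0, duration=config.duration
        )
        traj = simulate(rf, protocol, x0)
    except IntegrationError:
        return FunctionVerdict(function, False, None, "integration-error")
    except ValueError:
        # equilibration left the state numerically out of bounds
        return FunctionVerdict(function, False, None, "state-out-of-bounds")
    feats = extract_features(traj, topology.output, config.tail_fraction)
    return _CLASSIFIERS[function](feats, config)
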