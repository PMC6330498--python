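# Methods

## Model class

Networks are signed directed graphs over 2–6 enzyme nodes. Each node has a
fixed total concentration normalized to 1 and interconverts between an
active and an inactive form; only the active fraction regulates other
nodes. A link carries sign +1 (the regulator catalyses activation of the
target) or −1 (catalytic deactivation); self-links are allowed. One node is
the output; up to three nodes are receptors, each driven by its own
external signal.

The rate laws are Michaelis–Menten with *substrate competition*: all
targets of one regulator enzyme share a single saturation denominator,

    d[T]/dt gains  ± V · [E] · (substrate/K) / D_E,
    D_E = 1 + Σ over E's targets of substrate/K,

where the substrate is the inactive fraction 1−T for an activated target
and the active fraction T for a deactivated one. Competition grouping
follows the regulator, not the direction: a regulator that activates one
target and deactivates another still couples them through D_E, which is
what generates implicit mutual-inhibition interactions. Self-links join
their regulator's own group. Two kinds of regulators never compete:

* external input signals, which drive only their receptor; and
* background enzymes (concentration B = 0.5), which provide basal
  activation to any node lacking an in-network activator (a receptor's
  input counts as its activator) and basal deactivation to any node
  lacking an in-network deactivator, each through a private classic
  Michaelis–Menten term.

With all out-degrees ≤ 1 every denominator reduces to the classic
single-substrate form; the four-node reference model N5 is exactly this
case, and the compiled vector field reproduces its printed equations
term for term (tested against a hand-coded copy).

## Stimulus protocols and classifiers

Inputs rest at the basal level 0.1. A protocol steps exactly one
receptor's input instantaneously to an amplitude (sampled in [0.5, 1]
during screening) and holds it. Function verdicts are computed from the
output node's sampled time course (grid 0.05 time units; time units are
arbitrary):

* **F1, oscillation** — tail variance > 10⁻⁶, tail amplitude > 0.1,
  period > 0.1 (mean spacing of tail maxima), and at least `min_cycles`
  = 3 full cycles in the tail window.
* **F2, transient activation** — peak excursion O_peak − O_ini > 0.2,
  residual |O_end − O_ini| < 0.1, and residual < ½ of the excursion. The
  third condition is enforced by default (it is part of the complete
  definition of the target pulse shape); a config flag drops it.
* **F3, sustained activation** — O_end − O_ini > 0.2 with a
  non-oscillatory tail.

Windows: responses are integrated for 200 time units after the step and
the tail is the trailing 50%. These are package choices for "after the
transient dies out"; they bound the detectable period at roughly 30 time
units (≥ 4 maxima in a 100-unit tail), which comfortably covers the
reference oscillator (period ≈ 12–23). O_peak is the maximum, not the
maximum deviation: the target dynamic is an upward pulse, and downward
pulses are meant to fail F2. Loosening any threshold can only add verdicts
(tested), so pool membership responds monotonically to the config.

Evaluation equilibrates the network under basal inputs first (from the
uniform state 0.1, until the max-norm of the vector field is < 10⁻⁶, up to
500 time units); a non-convergent resting state fails the verdict with a
dedicated reason code rather than raising.

## Numerics

The screening integrator is an adaptive Runge–Kutta–Fehlberg 4(5) stepper
(rtol 10⁻⁶, atol 10⁻⁹, max step 5) compiled with numba, with cubic-Hermite
sampling onto the output grid, propagating the 5th-order solution. A step
budget of 50,000 guards against stiff parameter draws; on exhaustion or a
non-finite state the integration is retried with LSODA, and only a second
failure raises. During screening such failures count as non-functional
parameter sets. Trajectories stay in [0,1]ⁿ up to integrator tolerance
because activation terms vanish at T = 1 and deactivation terms at T = 0;
states that drift a hair outside are clipped at protocol boundaries.

Steady states for continuation are found with a Newton root solve seeded
by the previous branch point and accepted only when ‖f‖ < 10⁻⁸. Jacobians
use central differences by default and complex-step differentiation
(exact for these rational rate laws) in validation; eigenvalues come from
the dense solver.

## Parameter screening

Latin-hypercube sampling draws one point per equal stratum per dimension.
Rate constants V are log-uniform on [0.1, 10] and Michaelis constants K
log-uniform on [10⁻³, 10] — the ranges span 2–4 decades, and linear
sampling would essentially never visit K ≈ 10⁻³ — while the stimulus
amplitude is uniform on [0.5, 1]. One amplitude is drawn per parameter set
and shared by all functions evaluated on that set. The unit-cube matrix
for a given (n, seed, node count) carries a column for every possible
parameter slot and is reused across all topologies of that size, so
Q-values are comparable under a fixed sampling budget. All randomness
flows through these seeded generators; identical seeds give bitwise
identical screens.

Q-values count passing parameter sets. Published pool selection bands are
the defaults (Q₁ > 50 for 3–6 edges plus 10 < Q₁ < 50 for 3-edge
oscillators; Q₂ > 55 / 10 < Q₂ < 55 for adaptation) and are configurable;
they refer to a depth of n = 10,000 over the full enumeration, which is a
cluster-scale computation. The test suite runs the same machinery at
reduced depth (n = 1,000 over the named motifs) and asserts functionality
(Q > 0) and structural claims, not the published counts.

## Module merging and extension

Bi-functional candidates come from five merge plans between an oscillation
module (R1, M1, O1) and an adaptation module (R2, M2, O2): outputs always
identified; optionally M1–M2, R1–M2 or R2–M1; or the full three-node plan
{O–O, R1–M2, R2–M1}. Receptor–receptor and receptor–output
identifications are forbidden and machine-checked. A plan is rejected when
the union of link sets maps an ordered pair to both signs. (The published
rule list contains one two-node identification written as "R2–M2"; only
cross-pathway receptor–intermediate merges are consistent with the other
rules, so it is treated as R2–M1.) Only explicit-link conflicts block a
merge; conflicts that would arise between one module's explicit link and
the other's competition-induced implicit interaction are not counted as
contradictory, since implicit couplings are emergent rate-law properties
rather than links.

Tri-functional extension either adopts an intermediate node as receptor-3
(no link added) or adds a fresh node R3 with a single activation onto the
output; neither changes any competition group. Conditional robustness
Q(F3 | F1,2) freezes the parent circuit's parameters and Latin-hypercube
samples only the new slots (the third input's V and K, the added link's V
and K if any, new basal slots, and the third stimulus amplitude); F1 and
F2 replay under the base amplitude. When several base parameter sets pass
{F1, F2}, up to 10 are tried and the maximum Q reported, with the base-set
index retained.

The structure atlas links two networks when they share node ids and roles
and differ by exactly one signed link; a network that collapses onto a
smaller one by deleting a node is recorded as a separate *reduction*
relation, not an atlas edge.

## Encodings and clustering

Three-node topologies map bijectively to nine-digit vectors over
{+1, −1, 0} in regulator-major (row-major) order over the node sequence
(R, M, O) — the order is a documented convention. Topological distance is
the Hamming distance between vectors; pools are clustered with average
linkage, ties broken by lexicographic pre-sorting, returning the leaf
order and merge tree (no drawing).

Enumeration exposes a receptor→output reachability filter, on by default
for screening: a topology without a directed input–output path cannot
transduce the signal, so the filter is a pure optimization that cannot
change which topologies are functional.

## Fixture catalogue and provenance

The motif catalogue distinguishes printed wiring from figure-derived
reconstruction:

* **N5** is printed as equations and constants; its fixture and the
  reference model are one source of truth.
* **a1–a4** are the two repressilator orientations and the two
  delayed-negative-feedback orientations; **b1** is the buffered negative
  two-loop on the output, **b2** the delayed (three-node) negative
  feedback loop whose intermediate integrates the output against the
  constant background — wiring it shares with a4, since the same delayed
  loop oscillates or adapts depending on kinetics — **b4** the incoherent
  feedforward loop with a proportional node, and **b3** the buffered
  feedback in which the receptor activates both the intermediate and the
  output, so the two compete for it. These sign patterns are read off
  figure panels and validated functionally at reduced depth (each must
  achieve its function under Latin-hypercube screening); they carry
  `figure_derived: true` and are never tested against published counts.
* The **simple implicit-motif sets** (three-edge oscillators with no
  explicit oscillation motif, and three-edge adapters built on
  competition) are *reconstructions*: the published screen was re-run at
  reduced depth over all three-edge candidates with the corresponding
  structural signature, and the highest-Q hits were frozen into the
  catalogue. They are marked figure-derived and tested structurally
  (the negative feedback loop exists only in the augmented topology).
* **N1–N4, N6, N7** follow the described construction where one is given
  (N4 = motifs a3 + b1 united at the output plus an added R3; N3 reduces
  to N5 by deleting its buffer node M) and are otherwise plausible
  reconstructions used as fixtures for structural tests only.
* The **competition-dichotomy fixture** (a topology + parameter set that
  oscillates with competition enabled and settles to a fixed point with
  competition disabled) was found once by screening the implicit-motif
  oscillators and frozen as package data.

## What the synthetic conditions do and do not show

The generator's defaults are the study conditions: basal inputs 0.1, step
amplitudes in [0.5, 1], B = 0.5, V and K ranges as above, n = 10,000 for
module screens and n = 1,000 for conditional extension screens. The tests
exercise the identical machinery at reduced sampling depth and over the
named motifs instead of the full enumeration, so they demonstrate
correctness of the pipeline and the qualitative claims (which motifs are
functional, which merges are sterile, how N5 behaves), not the exact
published pool sizes — those require ~10⁸ trajectory solves. Real
signaling networks violate several idealizations here: totals are not
conserved or normalized, inputs are not clean steps, and enzymatic
regulation is not exclusively catalytic interconversion of two forms.

## Reference-model analyses

The Hopf scan continues the steady-state branch over the I1 amplitude
(41-point grid on [0.1, 0.5]), watches the leading complex eigenvalue
pair, bisects the real-part zero crossing to 10⁻³, and probes criticality
at I₁c − 0.02: a sustained oscillation reached while the fixed point is
still linearly stable implies a coexisting stable cycle, i.e. a
subcritical bifurcation. The onset scan classifies step responses on the
0.05-step amplitude grid, applying the stimulus from the uniform initial
state (all active fractions 0.1). This initial condition matters: in the
bistable window below the Hopf point the fully equilibrated rest state
falls inside the fixed point's basin, and a step from rest first
oscillates only at the Hopf point itself (0.25), whereas from the uniform
state the onset is 0.20, consistent with the subcritical scenario. Both
protocols are available; the uniform-init one is the default.

Two caveats about the printed reference values, documented here because
the tests surface them:

* the printed resting state is not the exact fixed point of the printed
  equations — root-solving gives (0.11819, 0.34314, 0.00241, 0.16746),
  whose output component differs from the printed 0.1690 by 1.5·10⁻³
  (the printed state leaves a ~6·10⁻⁴ residual in the buffer-node
  equation, consistent with a not-fully-converged simulation snapshot:
  the slow mode is −0.044 ± 0.217i);
* the adaptation closed form O_ss = V₃I₃/V₇ requires K₇ ≪ R₃, but at the
  printed constants K₇ = 0.0014 against R₃ ≈ 0.0024, so the simulated
  adapted level (~0.19) sits ≈ 0.08 above the closed-form 0.107. The
  *independence* of the adapted level from the I2 amplitude — the actual
  perfect-adaptation property — holds to < 0.03 across I2 ∈ [0.2, 1], and
  the saturation flags are reported alongside the prediction.

## Known limitations

* The SBML export is a minimal Level 3 rate-rule serialization (species,
  parameters, rules) sufficient for exchange, not a full-featured writer.
* Criticality classification uses a single simulation probe below the
  crossing; fold-of-cycles continuation is out of scope.
* Merge enumeration covers the five canonical plans of the three-node
  module geometry; larger modules would need a general matching rule.
* The screening integrator is explicit; extremely stiff parameter draws
  fall back to LSODA and, if that fails, count as non-functional rather
  than being resolved.
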