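# Methods

This note records the model exactly as implemented, the parameters that
matter, the numerical choices, and what the synthetic circuits used in the
tests can and cannot show.

## Neuron model and integration

Neurons are Izhikevich two-variable units: a fast membrane potential v (mV)
with quadratic intrinsic dynamics and a slow recovery variable u, coupled
through dv/dt = 0.04v² + 5v + 140 − u + I and du/dt = a(bv − u), with an
algebraic reset (v > 30 mV ⇒ v ← c, u ← u + d).  The five phenotype
parameter sets are

| phenotype | a (1/ms) | b (1/ms) | c (mV) | d |
|-----------|----------|----------|--------|---|
| RS  | 0.02 | 0.2  | −65 | 8 |
| IB  | 0.02 | 0.2  | −55 | 4 |
| CH  | 0.02 | 0.2  | −50 | 2 |
| FS  | 0.05 | 0.2  | −50 | 2 |
| LTS | 0.1  | 0.25 | −50 | 2 |

u is treated as dimensionless with d as a per-spike increment; v and c are
in mV, time in ms.

Integration is forward Euler with dt = 0.5 ms (configurable, dt ≤ 1 ms must
divide the 1 ms recording grid).  Euler at this step is the convention for
this model family; the test suite checks subthreshold trajectories against
an adaptive Runge–Kutta reference (scipy `solve_ivp`, rtol 1e−10) and the
error over 10 ms stays well inside 0.5 mV for all five phenotypes.  Spike
detection uses the strict post-update test v > 30 mV.  In recorded traces v
is clamped to 30 mV on the step a spike occurs so spikes have uniform
height; the reset value c is what enters the next step.

## Circuit

The default circuit has 17 groups / 10,000 neurons (80% excitatory, 20%
inhibitory) across layers L1–L6, with per-group counts, cell classes,
phenotypes, and receptor assignments as packaged in
`src/izhcortex/data/default_cortex.yaml`.  Excitatory sources drive AMPA
(superficial/granular pyramidal and spiny cells) or NMDA (deep pyramidal
cells); inhibitory sources drive GABA.  Neuron indices are global,
contiguous, excitatory groups first.

Connectivity: every ordered group pair, including a group with itself, is a
"sparse" block — each neuron pair is wired independently with probability
0.1 (the low end of the biological 0.1–0.2 range; configurable per
connection), all edges of a block carrying one scalar weight (default
10 mV).  Autapses are excluded in recurrent blocks.  Edge realisation is a
seeded Bernoulli draw and is reproduced bit for bit for a given seed.

## Synapses

Each neuron carries one conductance-like variable g per receptor class.
Decay dg/dt = −g/τ is integrated exactly (g ← g·e^(−dt/τ)), which is
unconditionally stable for any dt; each presynaptic spike adds the edge
weight to the target's g, convergent spikes summing.  Time constants:
τ_AMPA = 5 ms, τ_NMDA = 150 ms, τ_GABA = 10 ms — standard literature values
for these receptor classes, configurable.  Initial conductances are uniform
on [0, 1) per neuron per receptor, seeded.

Coupling into the membrane is current-based, I_syn = g_AMPA + g_NMDA −
g_GABA, the simplest form in which excitation depolarises and GABA
hyperpolarises.  A conductance-based alternative (Σ g_r(E_r − v) with
E_AMPA = E_NMDA = 0 mV, E_GABA = −70 mV) is available as a configuration
switch; with the default weight scale it shunts membranes onto the reversal
potentials and yields flat traces at every swept weight, so it is not the
default.

Voltage-dependent NMDA block, short-term plasticity and receptor saturation
are deliberately out of scope.

## Thalamic drive

Thalamocortical input is not simulated as explicit relay populations; it is
a per-step i.i.d. zero-mean Gaussian current into layers L2/3, L4 and L6
(merged labels overlap: L2 and L3 count as L2/3 targets, L5/6 as an L6
target), with σ = 5 for excitatory and σ = 2 for inhibitory target neurons
— the convention of the original Izhikevich network recipe.  The stream is
counter-based (Philox keyed on seed and time), so the current of neuron i
at time t is a pure function of (seed, t, i), independent of what else is
recorded.

## Engine

Per step: (1) assemble I = I_syn + noise + constant external current;
(2) Euler-update all membranes and apply resets; (3) decay conductances;
(4) deliver this step's spikes — an implicit one-step synaptic delay.
Initial conditions: v = c + U[0,5) mV jitter, u = bv.  A non-finite
membrane aborts the run naming the first offending neuron and time.
Recorders: spike raster, per-group counts per 1 ms bin, one probe trace
(v, u, g) per group (its first neuron), and optionally the full membrane
matrix.  Rate rows are binned from the raster, so event conservation holds
by construction and is asserted in tests.

A rate-based Hebbian rule (Δw_i = η·x_i·y on per-epoch spike counts of the
edge's endpoints, weights floored at 0) can update all edge weights every
epoch (default 50 ms).  It is purely potentiating, off by default, and
never active in the synchrony sweep, which studies fixed weights.

## Synchrony measure

χ²(N) = σ²_V / ((1/N)Σσ²_{V_i}) on the 1 ms membrane traces of one group,
with variances in the ⟨x²⟩_t − ⟨x⟩²_t form.  The matrix is first centred on
its grand mean — χ² is invariant under a global additive shift (tested) and
centring avoids the catastrophic cancellation this form suffers for
potentials near −65 mV.  Round-off can nudge the ratio marginally outside
[0, 1]; it is clipped to the analytic bounds.  The first 50 ms of each run
are discarded as transient before computing variances (configurable).

Degenerate input (every trace constant, mean variance below 1e−12 mV² —
fluctuations under a microvolt) makes the ratio 0/0.  Two regimes are
distinguished:

* quiescent traces (constant anywhere below the clamp) report χ² = 0 with a
  `degenerate` flag, so sweeps over silent circuits complete;
* traces constant **at the 30 mV spike clamp** mean every neuron spiked in
  every 1 ms sampling interval — a population firing in lockstep at the
  sampling ceiling.  Refining dt/sampling of the same dynamics yields
  identical non-constant traces, for which the measure is exactly 1, so
  this case reports χ² = 1 with `degenerate` and `saturated` flags.  The
  clamp level is context the sweep passes in; the bare measure without that
  context uses the quiescent convention.

This distinction matters: with current-based coupling, sparseness 0.1 and
the swept weight grid, every weight ≥ 11 drives the circuit to the ceiling
regime, which is total synchronization, not silence.

## Weight sweep

The experiment overrides every connection weight with one global value from
the grid 1, 11, …, 91 (start 1, step 10 — the grid is configurable,
including a {10, …, 100} variant), runs the circuit for 150 ms, and
computes χ² per group from the full group membrane matrix.  Each weight
uses seed = base + weight-index, so runs are independent but the sweep is
reproducible.  Both χ² and χ = √χ² are reported per (group, weight).

## Problem sizes used in the tests

The acceptance-style tests run the sweep on a 1000-neuron reduction of the
default circuit (all counts × 0.1, composition ratios preserved), which
this package treats as the standard benchmark size; the full 10,000-neuron
circuit runs with the same code path (a 150 ms run completes in well under
a minute on a single core).  Unit tests use programmatically generated miniature circuits
(2 groups × 10–50 neurons).

## What the synthetic circuits do and do not show

The generated circuits reproduce the composition (counts, layers,
phenotypes, receptors, 80/20 balance) and the sparse uniform connectivity
of the model, so passing tests demonstrate the internal consistency of the
dynamics, recorders and statistics.  They do not capture distance-dependent
or layer-specific connection probabilities, conduction delays, structured
thalamic input, or conductance heterogeneity of real cortex, so agreement
here says nothing about quantitative fidelity to biological recordings —
only about the behaviour of this model class.

## Known limitations

* Forward Euler overshoots the quadratic nullcline under very strong
  hyperpolarising input (large GABA conductance at small dt), which can
  produce spurious spikes; the inhibition tests therefore operate in the
  stable weight regime.
* At strong weights the circuit sits at the integrator's maximal firing
  rate (one spike per substep); rate and synchrony values there describe
  the saturated regime of the discretised model, not a biological firing
  rate.
* The χ² measure operates on membrane potentials with clamped spikes;
  alternative substrates (spike trains, unclamped potentials) would give
  different absolute values.
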