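# Methods

`cerebsim` simulates a bi-hemispheric spiking model of the cerebellar
cortex together with the arithmetic of the 16-bit fixed-point device it
emulates, and closes the loop around a simulated DC motor. This note
records the model, the numerical choices, and what the package's synthetic
test conditions do and do not establish.

## Network model

Each hemisphere contains 246 mossy fibres (MF), 8 climbing fibres (CF),
4096 granule cells (GrC), 369 Golgi cells (GoC), 25 molecular-layer
inhibitory interneurons (MLI, also called basket cells), and 8 Purkinje
cells (PkC) — 9,504 neurons and 240,484 synapses in total. Every unit,
fibres included, is a leaky integrate-and-fire neuron

    C dv/dt = -g_L (v - E_L) + i_syn + i_spont,

with per-type constants (C in pF, g_L in nS, E in mV, I_spont in pA):

| type | C | g_L | E_L | I_spont | V_r | V_th |
|------|-----|-----|-----|---------|-----|------|
| MF | 1.0 | 0.03 | -70 | 5.0 | -80 | -55 |
| CF | 1.0 | 0.3 | -70 | 0.015 | -80 | -55 |
| GrC | 3.0 | 1.5 | -65 | 0.0 | -75 | -55 |
| GoC | 76.0 | 3.6 | -74 | 36.8 | -84 | -42 |
| MLI | 14.6 | 1.0 | -68 | 15.6 | -78 | -53 |
| PkC | 620.0 | 7.0 | -62 | 600.0 | -72 | -47 |

The leak-conductance column is interpreted in nS: that gives membrane time
constants from 2 ms (GrC) to ~89 ms (PkC), all physiological, whereas any
larger unit gives sub-microsecond time constants. Spontaneous drive is a
fresh uniform draw on [0, 2·I_spont] per neuron per step, which
desynchronises spontaneous spiking across a population. On threshold
crossing the neuron emits a unit impulse and v is translated down by
V_th − V_r; the suprathreshold excursion is not stored.

Synapses are conductance-based: dg_m/dt = Σ_n δ_n w − g_m/τ_syn and
i = −Σ g_m (v − E_m), with per-class weights (pS), reversals and time
constants from the reference table (GrC←MF 19.5/0 mV/0.5 ms, GrC←GoC
3.9/−70/10, GoC←MF 171.9/0/0.5, GoC←GrC 31.2/0/0.5, PkC←GrC 0 (plastic),
PkC←MLI 3.9/−70/1.6, MLI←GrC 3.9/0/0.64). Initial weights are Gaussian
with coefficient of variation 0.1 (the reference gives only means),
clipped at zero. Impulses registered at step t reach postsynaptic
conductances at step t+1 (one-step transmission delay, mirroring the
device's registered spike storage).

Connectivity is random with replacement, drawn from per-projection LFSR
streams; a source drawn twice contributes two edges (equivalent to a
doubled weight). Two convergence ratios are fixed by the reference
description (GoC←GrC = 100; each PkC receives all 4096 parallel fibres);
the remaining defaults — GrC←MF 8, GrC←GoC 3, GoC←MF 12, MLI←GrC 42,
PkC←MLI 5 — are package choices constrained to (a) reproduce exactly
240,484 synapses and (b) keep the circuit functional: with 19.5 pS
mossy-fibre weights a granule cell needs on the order of eight converging
inputs before attainable mossy-fibre rates can drive it past threshold.
Hemispheres share parameters but use disjoint seed streams.

## Plasticity

Only parallel-fibre→PkC weights are plastic:

    dw/dt = −γ_LTD s_CF(t) q(t) + γ_LTP (1 − s_CF(t)) s_GrC(t),
    τ_LTD dq/dt = δ_GrC(t) − q(t),

with γ_LTD = 5.94e−8, γ_LTP = 4.17e−7, τ_LTD = 100 ms, w clipped to
[0, 1] in storage units of 1 µS. The rate trace q is integrated with
unit-area impulses in seconds, so its stationary mean equals the granule
cell's firing rate in spikes/s (per-spike increment 1000/τ_LTD = 10).
This unit choice matters: it makes LTP and LTD balance when each climbing
fibre fires at γ_LTP/γ_LTD ≈ 7 spikes/s — the physiological climbing-fibre
range — so learning is self-limiting. With a dimensionless q ≤ 1 the LTD
term could never offset LTP and the weights (and closed-loop error) grow
without bound; we verified this failure mode directly. Each CF is paired
1:1 with a PkC and acts purely as the teaching signal (it forms no
conductance synapse). In the same step a given weight receives either LTD
or LTP, never both (the CF impulse gates them disjointly).

## Discretisation (Δt = 1 ms)

All first-order decays use exact exponential factors: membrane
β_m = exp(−g_L Δt/C), conductance β_syn = exp(−Δt/max(τ_syn, Δt)).
Two deliberate departures from the naive forward-Euler map:

* **τ_syn clamp.** Three synapse classes have τ_syn < Δt (0.5 and
  0.64 ms); their forward-Euler coefficient 1 − Δt/τ is negative
  (sign-alternating, unstable). A sampled system cannot represent decay
  faster than its own step, so τ_syn is clamped to Δt, making e⁻¹ the
  fastest one-step decay. A literal-Euler scheme (clamped at zero) is
  retained as the `euler` option for comparison.
* **Forcing term.** The input enters with the plain Euler weight
  (Δt/C)·i. Combined with the exact decay, the map's steady-state gain is
  (Δt/C)/(1−β_m) rather than 1/g_L, i.e. the discrete cell is somewhat
  more sensitive than the continuous one where τ_m approaches the step:
  the GrC's discrete rheobase is 11.8 pA against the continuous 15 pA
  (`dynamics.discrete_rheobase`), while for slow membranes (GoC, MLI,
  PkC) the distortion is negligible. This additional per-step summation
  is what lets the single-granule-cell benchmark reproduce the reference
  mean rate (see below); a strict Euler map underestimates it by roughly
  a factor of two.

Update order per tick: (1) conductance decay + jumps from the previous
step's impulses, (2) synaptic currents, (3) membrane update with
threshold/reset, (4) rate trace and plasticity from this step's GrC/CF
impulses.

## Random streams

Every stochastic element draws from a named 32-bit Fibonacci LFSR stream
(taps 32, 22, 2, 1 — maximal length; the tap set is a package choice, the
reference states only the width), seeded from one master seed through a
splitmix-style hash, so every pipeline is a pure function of its master
seed. Consecutive single shifts of an LFSR share 31 of 32 bits; sampled
once per millisecond and thresholded they would produce pathologically
bursty spike trains. The hardware clocks its registers at MHz rates
between samples, so each emitted word here advances the register 32
shifts (a decimation that preserves the full 2³²−1 period since
gcd(32, 2³²−1) = 1). Gaussian draws use Box–Muller over LFSR uniforms;
`uniform_int` reduces the register modulo m (bias < 2⁻¹⁹ for m ≤ 2¹³).

## Fixed-point emulation

The device stores state in 16-bit words and rounds each
multiply-accumulate once per update, either half-up
(⌊x·2ⁿ + ½⌋·2⁻ⁿ) or randomized (truncate, round up with probability
equal to the discarded fraction — unbiased in expectation). The actual
integer/fraction split per quantity is not documented; this build stores
conductances and plastic weights as 16-bit fractions of 1 µS
(ulp ≈ 0.0153 nS; every tabulated weight and summed conductance fits),
membrane potentials as signed 16-bit fractions of 1 V (±500 mV range),
and the rate trace as a fraction of its 1000 spikes/s ceiling. Overflow
saturates silently and is counted in per-site diagnostics. Rounding is
applied at the membrane, conductance and plasticity updates only; the
current path carries extended precision, matching the emulated datapath.
Plasticity increments (≈4e−7) are far below one weight ulp (1.5e−5), so
under half-up rounding learning freezes entirely — with stochastic
rounding the increments survive in expectation, which is precisely why
the device rounds its plasticity processor stochastically.

For a first-order lag driven to zero, half-up rounding stalls at a
residual: y ceases to change once |y| < 2^(−n−1)·τ/Δt (`stall_band`;
2⁻¹² for n = 16, τ/Δt = 2⁵). Randomized rounding drains the same state
to zero in sample mean; both behaviours are verified by direct iteration.

## Single-granule-cell validation

One GrC driven for 50 s by one GoC (31 spikes/s mean, 93.8 pS,
inhibitory) and one MF (62 spikes/s mean, 320.0 pS, excitatory), with
LFSR-timed Bernoulli trains fed bit-identically to three arithmetic arms.
Averaged over 20 seeds this build gives a float64 mean rate of
≈6.8 spikes/s (reference: 6.58), a |float64 − fixed/randomized| gap of
≈0.04 spikes/s (reference: 0.030), and a |float64 − fixed/half-up| gap of
≈0.13 spikes/s. The reference device reported a much larger half-up gap
(1.64 spikes/s, an increase). In this build the only half-up residual in
the circuit is the slow inhibitory conductance's stall (≈5 ulp ≈0.08 nS,
weakly hyperpolarizing); a paper-sized excitatory residual would require
an effective per-step decay ≥ ½ on the fast excitatory synapse, which no
defensible reading of the published constants produces. The half-up gap
is therefore reported as measured and the corresponding acceptance check
is expected to fail; the randomized-rounding conclusion (fixed-point
accuracy restored to float64 levels) is reproduced.

## Closed-loop testbed

The physical rig (DC motor, Hall sensor, relay load) is replaced by a
first-order plant T_m dv/dt = K y − v with K = 500 rps per unit command,
T_m = 200 ms, and K halved while the load is engaged; the speed sensor
adds Gaussian noise (sd 1 rps). The PD controller uses G_P = 0.00635,
G_D = 1e−5; each hemisphere's Purkinje output is low-passed by
T_P dR/dt = −R + g_P Σ δ_m (g_P = 0.35, T_P = 310 ms) and the command is
y = G_P E + G_D ΔE + R_L − R_R. The target is a sine of amplitude 32 rps
and period 2.048 s.

The analog front end is undocumented, so the encoding is a package
design: the mossy-fibre pool splits into three equal groups (target,
error, efference copy); within each group the positive part of the signal
drives the left hemisphere's fibres and the negative part the right
(gains 2, 3 and 200 pA per signal unit), consistent with the
antisymmetric R_L − R_R readout. The rectified error also drives the
climbing fibres at 3 pA/rps, crossed (positive error teaches the right
hemisphere) so that LTD prunes whichever side currently overshoots.
Under these defaults the PD-only loop tracks with ≈6.4 rps RMS error and
the cerebellum reduces it to ≈3 rps within ~15 cycles, stably; engaging
the load mid-run makes the error jump and then decline again as the
weights re-adapt. Learning onset is faster than in the real-world
reference experiment (tens of seconds of ambient noise delayed it there);
the synthetic plant has no such noise floor, so passing these tests shows
the learning rule's sign, stability and load-adaptation — not real-world
latencies or absolute error magnitudes.

Repeated trials derive per-repetition seeds from the master seed, pairing
the with/without-cerebellum conditions trial for trial. Acceptance-scale
runs use 60 cycles × 10 repetitions (learning) and one 100-cycle run with
load onset at cycle 70 (re-adaptation); these sizes keep a full suite run
in the tens of minutes on one CPU while leaving the learning effect
(≈2× error reduction against a ≈0.1 rps repetition spread) unambiguous.

## Performance

The float64 path optionally uses a numba kernel that visits only the
edges of neurons that fired (pre-major order) and fuses the per-tick
updates; without numba a pure-numpy path (CSR matrix–vector products,
post-major) runs the identical map. The two paths are cross-checked spike
for spike on a miniature topology, and the network step is additionally
validated against a per-neuron, per-edge pure-Python oracle for 1000
steps. Edge-accumulation order differs between paths, which can move
conductances by an ulp; no observable divergence within the tested
horizons.

## Known limitations

* Spatial geometry of axonal arbors is abstracted to uniform random
  wiring; no deep cerebellar nuclei; plasticity only at PF→PkC.
* The discrete membrane map's DC gain exceeds the continuous model's for
  fast membranes (see above); the `euler` scheme restores the continuous
  rheobase at the cost of the validation rate.
* The fixed-point Q formats, the FPGA's true decay coefficients, and the
  analog encoding are reconstructions; conclusions about the half-up
  rounding *magnitude* therefore carry an irreducible model uncertainty,
  while the stall-band analysis and the unbiasedness of stochastic
  rounding are exact properties verified independently.
* The plant is first-order with an instantaneous load switch; absolute
  closed-loop error magnitudes are not comparable to the physical rig.
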