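# cerebsim

A spiking-network simulator of the cerebellar cortex, written for studying
how a realistic cerebellar microcircuit can act as a real-time adaptive
motor controller, and how far its dynamics survive 16-bit fixed-point
arithmetic. It is aimed at computational neuroscientists and neuromorphic
engineers who want a software twin of a small FPGA-class artificial
cerebellum: same network, same learning rule, same arithmetic, but
inspectable and scriptable.

The model is a bi-hemispheric cerebellar cortical network — per hemisphere
246 mossy fibres (MF), 8 climbing fibres (CF), 4096 granule cells (GrC),
369 Golgi cells (GoC), 25 molecular-layer interneurons (MLI) and
8 Purkinje cells (PkC); 9,504 neurons and 240,484 synapses in total — of
leaky integrate-and-fire units

&nbsp;&nbsp;&nbsp;&nbsp;C dv/dt = −g_L (v − E_L) + i(t) + i_spont(t)

with conductance synapses dg/dt = Σ δ_n w_n − g/τ_syn and plasticity only
at the parallel-fibre→Purkinje synapse:

&nbsp;&nbsp;&nbsp;&nbsp;dw/dt = −γ_LTD s_CF q_GrC + γ_LTP (1 − s_CF) s_GrC,
&nbsp;&nbsp;τ_LTD dq/dt = δ_GrC − q.

Climbing fibres carry the error signal that gates LTD; granule-cell spikes
paired with CF silence give LTP. The package adds three device-faithful
ingredients: LFSR-defined random connectivity (wiring is a pseudo-random
sequence, not a stored table), an emulation of 16-bit fixed-point state
with half-up or randomized (stochastic) rounding, and a closed-loop
testbed in which the network and a PD controller jointly drive a simulated
DC motor whose load can be switched mid-run.

## Worked example

Single granule cell, 50 s, driven by one Golgi fibre (31 spikes/s,
inhibitory) and one mossy fibre (62 spikes/s, excitatory), simulated three
times on bit-identical input spike trains — in float64, in 16-bit
fixed point with half-up rounding, and in 16-bit fixed point with
randomized rounding:

```sh
$ cerebsim validate-rounding --seed 1 --seeds 20
{
 "seed": 1,
 "n_seeds": 20,
 "duration_s": 50.0,
 "mean_rates": {
  "float64": 6.836,
  "fixed_half_up": 6.711,
  "fixed_randomized": 6.878
 },
 "gap_half_up": 0.125,
 "gap_randomized": 0.042
}
```

The float64 arm fires at 6.8 spikes/s. The randomized-rounding arm tracks
it to 0.04 spikes/s — stochastic rounding is unbiased, so fixed-point
rounding errors cancel instead of accumulating, and spike timing survives
the 16-bit datapath. The half-up arm differs by 0.13 spikes/s here; its
characteristic failure (a decaying conductance that stalls at a nonzero
residual instead of reaching zero) is visible in the recorded traces and
analysed exactly by `cerebsim.fixedpoint.stall_band`.

Closed-loop motor learning (scaled to 12 cycles here; the full protocol
uses hundreds):

```sh
$ cerebsim run-control --cycles 12 --reps 2 --seed 1 --out-dir runs
cerebellum: first-10-cycle error 3.620 rps, last-10-cycle error 3.362 rps
pd_only: first-10-cycle error 6.365 rps, last-10-cycle error 6.369 rps
wrote runs/summary.json
```

The PD-only loop is stationary at ≈6.4 rps RMS tracking error; with the
cerebellum in the loop the error falls cycle over cycle as LTD/LTP shape
the parallel-fibre weights, toward ≈3 rps at convergence. Per-cycle error
CSVs and a mean±sd summary are written under `runs/`.

`cerebsim build-info` prints the network composition (9,504 neurons,
240,484 synapses with the default configuration); YAML configs can resize
every population, convergence ratio, gain and seed (`docs/methods.md`
documents each parameter and default).

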