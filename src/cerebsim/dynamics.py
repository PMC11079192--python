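"""Discrete-time neuron, synapse and plasticity dynamics (1 ms step).

All quantities use the consistent unit system (pF, nS, mV, pA, ms) in which
the leaky integrate-and-fire (LIF) membrane equation

    C dv/dt = -g_L (v - E_L) + i_syn + i_spont

balances dimensionally.  The leak conductance column of the parameter table
is read in nS (giving physiological membrane time constants of 2 ms for
granule cells up to ~89 ms for Purkinje cells); synaptic weights tabulated
in pS are converted to nS.

Discretisation
--------------
Linear decays use the exponential-integrator form: the homogeneous part of
each first-order equation is advanced by its exact decay factor
``exp(-dt/tau)`` and the forcing is added once per step.  Synaptic time
constants shorter than the step (0.5 and 0.64 ms at dt = 1 ms) are clamped
to the step, so the fastest representable one-step decay is ``exp(-1)``: a
sampled system cannot resolve decay faster than its own step, and the
forward-Euler coefficient ``1 - dt/tau`` would be negative (sign-alternating
and unstable) for those synapses.  A literal forward-Euler scheme (clamped
at zero) is retained as an option for comparison.

Spikes are unit impulses: when v crosses threshold the neuron emits delta=1
and v is translated down by (V_th - V_r); the supra-threshold excursion
itself is not stored.  Impulses computed at step t are consumed by
postsynaptic conductances at step t+1 (one-step transmission delay,
mirroring registered spike storage).

Plasticity acts only at the parallel-fibre -> Purkinje-cell synapse:
LTD depresses a weight by gamma_LTD * q when the paired climbing fibre
spikes (q is a 100 ms low-pass of the granule cell's impulse train), LTP
potentiates by gamma_LTP when the granule cell spikes and the climbing
fibre is silent.  Weights live in [0, w_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixedpoint import ArithmeticContext, RoundingMode

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "PlasticityParams",
    "NEURON_PARAMS",
    "SYNAPSE_PARAMS",
    "membrane_decay",
    "synaptic_decay",
    "spontaneous_current",
    "step_membrane",
    "step_conductance",
    "synaptic_current",
    "step_grc_trace",
    "apply_plasticity",
]

DT_MS = 1.0  # model time step


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants of one cell/fibre type."""

    C: float        # membrane capacitance [pF]
    g_L: float      # leak conductance [nS]
    E_L: float      # leak reversal potential [mV]
    I_spont: float  # mean spontaneous-discharge current [pA]
    V_r: float      # reset potential [mV]
    V_th: float     # firing threshold [mV]

    def __post_init__(self):
        if self.C <= 0 or self.g_L < 0 or self.V_r >= self.V_th:
            raise ValueError("invalid neuron parameters")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L [ms]."""
        return self.C / self.g_L if self.g_L > 0 else np.inf

    @property
    def rheobase(self) -> float:
        """Minimum constant current that reaches threshold [pA]."""
        return self.g_L * (self.V_th - self.E_L)


#: Per-type LIF constants.  MLI (molecular-layer inhibitory interneuron) and
#: BkC (basket cell) name the same population; MLI is canonical here.
NEURON_PARAMS: dict[str, NeuronParams] = {
    "MF": NeuronParams(C=1.0, g_L=0.03, E_L=-70.0, I_spont=5.0, V_r=-80.0, V_th=-55.0),
    "CF": NeuronParams(C=1.0, g_L=0.3, E_L=-70.0, I_spont=0.015, V_r=-80.0, V_th=-55.0),
    "GrC": NeuronParams(C=3.0, g_L=1.5, E_L=-65.0, I_spont=0.0, V_r=-75.0, V_th=-55.0),
    "GoC": NeuronParams(C=76.0, g_L=3.6, E_L=-74.0, I_spont=36.8, V_r=-84.0, V_th=-42.0),
    "MLI": NeuronParams(C=14.6, g_L=1.0, E_L=-68.0, I_spont=15.6, V_r=-78.0, V_th=-53.0),
    "PkC": NeuronParams(C=620.0, g_L=7.0, E_L=-62.0, I_spont=600.0, V_r=-72.0, V_th=-47.0),
}
NEURON_PARAMS["BkC"] = NEURON_PARAMS["MLI"]


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-synapse constants of one pre -> post class."""

    w_mean: float   # mean initial weight [pS]
    E: float        # reversal potential [mV]; 0 excitatory, -70 inhibitory
    tau_syn: float  # conductance decay time constant [ms]
    plastic: bool = False

    def __post_init__(self):
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")

    @property
    def w_mean_nS(self) -> float:
        return self.w_mean * 1e-3


#: Synapse classes keyed (post, pre).  Only the parallel-fibre (GrC axon) ->
#: PkC synapse is plastic; its initial weight is exactly zero.
SYNAPSE_PARAMS: dict[tuple[str, str], SynapseParams] = {
    ("GrC", "MF"): SynapseParams(19.5, 0.0, 0.50),
    ("GrC", "GoC"): SynapseParams(3.9, -70.0, 10.00),
    ("GoC", "MF"): SynapseParams(171.9, 0.0, 0.50),
    ("GoC", "GrC"): SynapseParams(31.2, 0.0, 0.50),
    ("PkC", "GrC"): SynapseParams(0.0, 0.0, 0.50, plastic=True),
    ("PkC", "MLI"): SynapseParams(3.9, -70.0, 1.60),
    ("MLI", "GrC"): SynapseParams(3.9, 0.0, 0.64),
}


@dataclass(frozen=True)
class PlasticityParams:
    """Parallel-fibre -> Purkinje-cell learning-rule constants.

    The weight is stored as a fraction of a 1 uS full scale (so ``w_max`` is
    1.0 in storage units, i.e. 1000 nS); the LTD/LTP increments below are in
    the same storage unit per event.
    """

    gamma_ltd: float = 5.94e-8
    gamma_ltp: float = 4.17e-7
    tau_ltd: float = 100.0  # ms, q-trace low-pass
    w_max: float = 1.0      # upper clip, storage units (1 uS)
    w_scale_nS: float = 1000.0  # nS per storage unit

    @property
    def cf_equilibrium_rate(self) -> float:
        """CF rate [spikes/s] at which LTD balances LTP for equally active
        granule cells: gamma_LTP / gamma_LTD (~7 spikes/s at the defaults,
        the physiological climbing-fibre range)."""
        return self.gamma_ltp / self.gamma_ltd


def discrete_rheobase(params: NeuronParams, dt: float = DT_MS, scheme: str = "exponential") -> float:
    """Threshold constant current of the discrete membrane map [pA].

    The update ``v' = E_L + beta (v - E_L) + (dt/C) i`` has steady state
    ``E_L + (dt/C) i / (1 - beta)``, so the firing threshold current is
    ``(1 - beta)(C/dt)(V_th - E_L)``.  With the forward-Euler decay
    (beta = 1 - g_L dt/C) this equals the continuous rheobase
    g_L (V_th - E_L); with the exact exponential decay the map is somewhat
    more sensitive (e.g. 11.8 pA instead of 15 pA for the granule cell,
    whose membrane time constant is only twice the step).  For slow
    membranes the two coincide.
    """
    beta = membrane_decay(params, dt, scheme)
    return (1.0 - beta) * (params.C / dt) * (params.V_th - params.E_L)


def membrane_decay(params: NeuronParams, dt: float = DT_MS, scheme: str = "exponential") -> float:
    """Per-step decay factor of v toward E_L."""
    if scheme == "exponential":
        return float(np.exp(-params.g_L * dt / params.C))
    if scheme == "euler":
        return max(0.0, 1.0 - params.g_L * dt / params.C)
    raise ValueError(f"unknown scheme {scheme!r}")


def synaptic_decay(tau_syn: float, dt: float = DT_MS, scheme: str = "exponential") -> float:
    """Per-step conductance decay factor; tau clamped to >= dt (see module doc)."""
    if scheme == "exponential":
        return float(np.exp(-dt / max(tau_syn, dt)))
    if scheme == "euler":
        return max(0.0, 1.0 - dt / tau_syn)
    raise ValueError(f"unknown scheme {scheme!r}")


def spontaneous_current(params: NeuronParams, stream, n: int | None = None):
    """Uniform draw on [0, 2 I_spont] per neuron per step [pA].

    The uniform jitter desynchronises spontaneous spike timing across
    neurons of a type; the mean drive equals I_spont.
    """
    if params.I_spont == 0.0:
        return 0.0 if n is None else np.zeros(n)
    return 2.0 * params.I_spont * stream.uniform()


def step_membrane(
    v: np.ndarray,
    i_syn,
    i_spont,
    params: NeuronParams,
    dt: float = DT_MS,
    scheme: str = "exponential",
    arith: ArithmeticContext | None = None,
    site: str = "v",
):
    """Advance membrane potentials one step; return (v_new, impulses).

    The update decays v toward E_L by the membrane decay factor and adds the
    current forcing (dt/C)(i_syn + i_spont); where the result exceeds V_th
    the neuron spikes and v is translated by (V_r - V_th).  The whole
    multiply-accumulate is carried at double precision and rounded once (in
    fixed-point modes) before threshold detection.
    """
    total = np.asarray(i_syn, dtype=np.float64) + i_spont
    if not np.all(np.isfinite(np.atleast_1d(total))):
        raise FloatingPointError("non-finite synaptic drive in membrane update")
    beta = membrane_decay(params, dt, scheme)
    v_new = params.E_L + beta * (v - params.E_L) + (dt / params.C) * total
    shift = params.V_r - params.V_th
    if arith is not None and not arith.is_float:
        v_new = arith.round("voltage", site, v_new)
        # the reset constant is itself a stored fixed-point word
        shift = arith.quantize_parameter("voltage", shift)
    impulses = v_new > params.V_th
    if np.ndim(v_new) == 0:
        if impulses:
            v_new = v_new + shift
        return v_new, bool(impulses)
    v_new = np.where(impulses, v_new + shift, v_new)
    return v_new, impulses


def step_conductance(
    g: np.ndarray,
    jump,
    tau_syn: float,
    dt: float = DT_MS,
    scheme: str = "exponential",
    arith: ArithmeticContext | None = None,
    site: str = "g",
):
    """Advance synaptic conductances one step: decay plus spike-driven jumps.

    ``jump`` is the summed weight of presynaptic impulses landing on each
    postsynaptic conductance this step (already delayed by one step by the
    caller).  Decay and jump are accumulated at double precision and rounded
    once per step in fixed-point modes.
    """
    beta = synaptic_decay(tau_syn, dt, scheme)
    g_new = beta * g + jump
    if arith is not None and not arith.is_float:
        g_new = arith.round("conductance", site, g_new)
    return np.maximum(g_new, 0.0) if scheme == "euler" else g_new


def synaptic_current(conductances, v):
    """Total synaptic current i = -sum_m g_m (v - E_m) [pA].

    ``conductances`` is an iterable of (g_array, E_reversal) pairs, one per
    presynaptic type converging on the population.  Excitatory conductances
    (E = 0) depolarise at sub-zero potentials; inhibitory ones (E = -70)
    drive v toward -70.  Never rounded: the hardware current path carries
    extended precision into the membrane accumulate.
    """
    i = np.zeros_like(np.asarray(v, dtype=np.float64))
    for g, E in conductances:
        i = i - g * (np.asarray(v, dtype=np.float64) - E)
    return i


def step_grc_trace(
    q: np.ndarray,
    grc_impulses,
    params: PlasticityParams,
    dt: float = DT_MS,
    arith: ArithmeticContext | None = None,
    site: str = "q",
):
    """Low-pass the granule-cell impulse train into a rate trace [spikes/s].

    ``tau_LTD dq/dt = delta(t) - q`` with delta a unit-area impulse per
    spike, so the stationary mean of q equals the granule cell's firing
    rate in spikes/s: each spike increments q by 1000/tau_LTD (= 10 at the
    100 ms default) and q decays by (1 - dt/tau_LTD) per step, saturating
    at the 1000 spikes/s one-spike-per-step ceiling.
    """
    a = dt / params.tau_ltd
    q_new = (1.0 - a) * q + (1000.0 / params.tau_ltd) * np.asarray(
        grc_impulses, dtype=np.float64
    )
    if arith is not None and not arith.is_float:
        q_new = arith.round("trace", site, q_new)
    return q_new


def apply_plasticity(
    w: np.ndarray,
    q: np.ndarray,
    grc_impulses: np.ndarray,
    cf_impulses: np.ndarray,
    params: PlasticityParams,
    arith: ArithmeticContext | None = None,
    site: str = "w",
):
    """One step of the LTD/LTP rule on the (n_PkC, n_GrC) weight matrix.

    Per synapse (m, j):  dw = -gamma_LTD * s_CF[m] * q[j]
                              + gamma_LTP * (1 - s_CF[m]) * s_GrC[j]
    then clip to [0, w_max].  Each PkC m is paired 1:1 with climbing fibre m,
    whose impulse is the teaching signal.  Weight increments are far below
    one 16-bit ulp, so in fixed-point mode they survive only through
    randomized rounding (with half-up rounding learning freezes entirely --
    a faithful property of the emulated arithmetic, not a bug).
    """
    s_cf = np.asarray(cf_impulses, dtype=np.float64)
    s_grc = np.asarray(grc_impulses, dtype=np.float64)
    dw = (
        -params.gamma_ltd * np.outer(s_cf, q)
        + params.gamma_ltp * np.outer(1.0 - s_cf, s_grc)
    )
    w_new = w + dw
    if arith is not None and not arith.is_float:
        w_new = arith.round("weight", site, w_new)
    return np.clip(w_new, 0.0, params.w_max)
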