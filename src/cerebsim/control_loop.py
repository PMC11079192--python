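"""Closed-loop adaptive speed control of a simulated DC motor.

The cerebellar network sits beside a proportional-derivative (PD) controller.
Each 1 ms tick:

1. the plant's shaft speed is measured (plus Gaussian sensor noise),
2. the tracking error E = target - measured is formed,
3. target, error and efference-copy signals are rate-coded into mossy-fibre
   drive currents and the error into climbing-fibre drive,
4. the network advances one step,
5. each hemisphere's Purkinje population drives a leaky output filter
   T_P dR/dt = -R + g_P sum_m delta_m,
6. the motor command y = G_P E + G_D (E - E_prev) + R_L - R_R is applied to
   a first-order plant  T_m dv/dt = K y - v,  whose gain K halves while the
   switchable load is engaged.

The physical rig the emulated device drove (DC motor, Hall sensor, relay
load) is replaced by this first-order plant model; its parameters are
package defaults chosen so the PD-only loop shows the characteristic
attenuated, slightly delayed sine tracking, not measured values.

Signal encoding (the device's analog front end is not described in detail):
the mossy-fibre pool is split into three equal groups carrying target speed,
error and efference copy; within each group the *positive* part of the
signal drives the left hemisphere's fibres and the negative part the right,
matching the antisymmetric R_L - R_R readout.  The rectified error also
drives the climbing fibres, crossed (a positive error teaches the right
hemisphere's Purkinje cells, a negative error the left), so that LTD prunes
the side whose output currently overshoots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CerebellumTopology
from .rng import SeedTable

__all__ = [
    "ControllerGains",
    "ControllerState",
    "PlantParams",
    "PlantState",
    "EncodingParams",
    "ExperimentSchedule",
    "TrialLog",
    "purkinje_output",
    "motor_command",
    "encode_inputs",
    "step_plant",
    "run_closed_loop",
]

DT_MS = 1.0


@dataclass(frozen=True)
class ControllerGains:
    g_P: float = 0.35       # Purkinje output filter gain
    T_P: float = 310.0      # output filter time constant [ms]
    G_P: float = 0.00635    # PD proportional gain [command/rps]
    G_D: float = 0.00001    # PD derivative gain [command/rps]


@dataclass
class ControllerState:
    gains: ControllerGains = field(default_factory=ControllerGains)
    R_L: float = 0.0
    R_R: float = 0.0
    E_prev: float = 0.0


@dataclass(frozen=True)
class PlantParams:
    """First-order DC-motor stand-in with a switchable load.

    Engaging the load halves the speed gain (a stalled twin motor shorted
    across the shaft dissipates torque), leaving the time constant as is.
    """

    K: float = 500.0          # steady-state speed per unit command [rps]
    T_m: float = 200.0        # mechanical time constant [ms]
    K_loaded: float = 250.0
    T_m_loaded: float = 200.0
    noise_sd: float = 1.0     # speed-sensor noise SD [rps]


@dataclass
class PlantState:
    params: PlantParams = field(default_factory=PlantParams)
    speed: float = 0.0
    load_on: bool = False


@dataclass(frozen=True)
class EncodingParams:
    """Analog -> injected-current encoding of the three mossy-fibre groups
    and the climbing-fibre teaching signal [pA per signal unit]."""

    target_gain: float = 2.0     # pA per rps of target speed
    error_gain: float = 3.0      # pA per rps of error
    efference_gain: float = 200.0  # pA per unit motor command
    baseline: float = 0.0        # added to every driven fibre
    cf_gain: float = 3.0         # pA per rps of rectified error


@dataclass(frozen=True)
class ExperimentSchedule:
    """Sinusoidal target and load-switching schedule."""

    amplitude: float = 32.0    # rps
    period_s: float = 2.048
    cycles: int = 360
    load_on_cycles: tuple = (120, 300)   # load engaged at these cycle indices
    load_off_cycles: tuple = (240,)      # ... and released at these
    repetitions: int = 10

    @property
    def period_steps(self) -> int:
        return int(round(self.period_s * 1000.0 / DT_MS))

    def load_state(self, cycle: int) -> bool:
        on = False
        events = sorted(
            [(c, True) for c in self.load_on_cycles]
            + [(c, False) for c in self.load_off_cycles]
        )
        for c, state in events:
            if cycle >= c:
                on = state
        return on


@dataclass
class TrialLog:
    condition: str
    seed: int
    cycle_errors: np.ndarray
    weight_sums: np.ndarray | None = None  # per-cycle sum of PF->PkC weights (L, R)

    def write_csv(self, path, repetition: int = 0):
        with open(path, "w") as fh:
            fh.write("cycle,condition,repetition,error_rms\n")
            for c, e in enumerate(self.cycle_errors):
                fh.write(f"{c},{self.condition},{repetition},{e:.6f}\n")


def purkinje_output(R: float, pkc_impulses, gains: ControllerGains, dt: float = DT_MS) -> float:
    """Leaky integration of the Purkinje population spike count (Eq. of R)."""
    s = float(np.sum(pkc_impulses))
    return R + (dt / gains.T_P) * (-R + gains.g_P * s)


def motor_command(E: float, ctrl: ControllerState) -> float:
    """PD command plus the antisymmetric cerebellar contribution."""
    g = ctrl.gains
    y = g.G_P * E + g.G_D * (E - ctrl.E_prev) + ctrl.R_L - ctrl.R_R
    ctrl.E_prev = E
    return y


def _split_groups(n: int) -> list[slice]:
    base = n // 3
    sizes = [base, base, n - 2 * base]
    out, off = [], 0
    for s in sizes:
        out.append(slice(off, off + s))
        off += s
    return out


def encode_inputs(
    target: float,
    error: float,
    efference: float,
    enc: EncodingParams,
    n_mf: int,
    n_cf: int,
):
    """Rate-code the three input modalities into per-fibre drive currents.

    Returns ``(mf_L, mf_R, cf_L, cf_R)`` arrays of injected currents [pA].
    Positive signal parts drive the left hemisphere, negative parts the
    right; the climbing-fibre error drive is crossed (see module doc).
    """
    mf_L = np.full(n_mf, enc.baseline)
    mf_R = np.full(n_mf, enc.baseline)
    groups = _split_groups(n_mf)
    for sl, sig, gain in zip(
        groups,
        (target, error, efference),
        (enc.target_gain, enc.error_gain, enc.efference_gain),
    ):
        mf_L[sl] += gain * max(sig, 0.0)
        mf_R[sl] += gain * max(-sig, 0.0)
    cf_L = np.full(n_cf, enc.cf_gain * max(-error, 0.0))
    cf_R = np.full(n_cf, enc.cf_gain * max(error, 0.0))
    return mf_L, mf_R, cf_L, cf_R


def step_plant(plant: PlantState, y: float, noise_stream=None, dt: float = DT_MS):
    """Advance the plant one step; return the measured (noisy) speed [rps]."""
    p = plant.params
    K, T = (p.K_loaded, p.T_m_loaded) if plant.load_on else (p.K, p.T_m)
    plant.speed += (dt / T) * (K * y - plant.speed)
    noise = (
        noise_stream.gaussian(0.0, p.noise_sd)
        if (noise_stream is not None and p.noise_sd > 0.0)
        else 0.0
    )
    return plant.speed + noise


def run_closed_loop(
    topology: CerebellumTopology | None,
    schedule: ExperimentSchedule,
    seed_table: SeedTable,
    gains: ControllerGains | None = None,
    plant_params: PlantParams | None = None,
    encoding: EncodingParams | None = None,
    plasticity: bool = True,
    record_weights: bool = False,
) -> TrialLog:
    """Run one closed-loop trial; ``topology=None`` gives the PD-only loop.

    Returns a :class:`TrialLog` with the per-cycle RMS tracking error.
    """
    gains = gains or ControllerGains()
    enc = encoding or EncodingParams()
    ctrl = ControllerState(gains=gains)
    plant = PlantState(params=plant_params or PlantParams())
    noise_stream = seed_table.stream("sensor_noise")

    n_steps = schedule.cycles * schedule.period_steps
    period = schedule.period_steps
    omega = 2.0 * np.pi / period
    sq_err = np.zeros(schedule.cycles)
    wsum = np.zeros((schedule.cycles, 2)) if record_weights else None
    y = 0.0
    use_cereb = topology is not None
    if use_cereb:
        n_mf = topology.hemispheres["L"].counts["MF"]
        n_cf = topology.hemispheres["L"].counts["CF"]

    load_flags = [schedule.load_state(c) for c in range(schedule.cycles)]
    for t in range(n_steps):
        cycle = t // period
        plant.load_on = load_flags[cycle]
        target = schedule.amplitude * np.sin(omega * t)
        measured = step_plant(plant, y, noise_stream)
        E = target - measured
        sq_err[cycle] += E * E
        if use_cereb:
            mf_L, mf_R, cf_L, cf_R = encode_inputs(target, E, y, enc, n_mf, n_cf)
            impulses = topology.step(mf_L, mf_R, cf_L, cf_R, plasticity=plasticity)
            ctrl.R_L = purkinje_output(ctrl.R_L, impulses["L"]["PkC"], gains)
            ctrl.R_R = purkinje_output(ctrl.R_R, impulses["R"]["PkC"], gains)
        y = motor_command(E, ctrl)
        if record_weights and use_cereb and (t + 1) % period == 0:
            wsum[cycle, 0] = topology.hemispheres["L"].w_pf_pkc.sum()
            wsum[cycle, 1] = topology.hemispheres["R"].w_pf_pkc.sum()

    return TrialLog(
        condition="cerebellum" if use_cereb else "pd_only",
        seed=seed_table.master_seed,
        cycle_errors=np.sqrt(sq_err / period),
        weight_sums=wsum,
    )
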