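"""Packaged pipelines: rounding-accuracy validation and load-adaptation runs.

The rounding validation simulates one granule cell driven by one Golgi fibre
(31 spikes/s mean, inhibitory, 93.8 pS) and one mossy fibre (62 spikes/s
mean, excitatory, 320.0 pS) for 50 s at 1 ms steps, under three arithmetic
arms fed *bit-identical* input spike trains:

1. 64-bit floating point (reference),
2. 16-bit fixed point with half-up rounding,
3. 16-bit fixed point with randomized rounding.

Because the arms are paired on identical inputs, any difference in the mean
output firing rate is attributable to arithmetic alone.  The printed
headline statistic is the mean rate (and the two rate gaps) averaged over a
batch of seeds, since a single seed's rate carries binomial jitter of a few
tenths of a spike/s.

The load-adaptation pipeline repeats closed-loop motor-control trials with
and without the cerebellar network and summarises the per-cycle tracking
error across repetitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import dynamics as dyn
from .control_loop import (
    ControllerGains,
    EncodingParams,
    ExperimentSchedule,
    PlantParams,
    TrialLog,
    run_closed_loop,
)
from .fixedpoint import DEFAULT_FORMATS, RoundingMode, quantize
from .network import build_cerebellum
from .rng import SeedTable, derive_seed

__all__ = [
    "ValidationConfig",
    "ValidationResult",
    "generate_input_trains",
    "run_single_grc_validation",
    "run_load_experiment",
]

DT_MS = 1.0
_MOD32 = 1 << 32


@dataclass(frozen=True)
class ValidationConfig:
    duration_s: float = 50.0
    goc_rate: float = 31.0       # spikes/s
    mf_rate: float = 62.0        # spikes/s
    w_goc_pS: float = 93.8       # GoC -> GrC weight, inhibitory (E = -70, tau 10 ms)
    w_mf_pS: float = 320.0       # MF -> GrC weight, excitatory (E = 0, tau 0.5 ms)
    n_seeds: int = 20
    scheme: str = "exponential"

    def __post_init__(self):
        if self.goc_rate * DT_MS > 1000.0 or self.mf_rate * DT_MS > 1000.0:
            raise ValueError("rate * dt must not exceed one impulse per step")


@dataclass
class ValidationResult:
    rates: dict[str, np.ndarray]            # arm -> per-seed mean rate [spikes/s]
    traces: dict[str, dict[str, np.ndarray]] | None = None

    def mean_rate(self, arm: str) -> float:
        return float(self.rates[arm].mean())

    @property
    def gap_half_up(self) -> float:
        """|float64 - fixed/half-up| seed-averaged rate difference."""
        return abs(self.mean_rate("float64") - self.mean_rate("fixed_half_up"))

    @property
    def gap_randomized(self) -> float:
        """|float64 - fixed/randomized| seed-averaged rate difference."""
        return abs(self.mean_rate("float64") - self.mean_rate("fixed_randomized"))

    def summary(self) -> dict:
        out = {arm: self.mean_rate(arm) for arm in self.rates}
        out["gap_half_up"] = self.gap_half_up
        out["gap_randomized"] = self.gap_randomized
        return out


def generate_input_trains(
    config: ValidationConfig, seed_table: SeedTable, lanes: int
) -> tuple[np.ndarray, np.ndarray]:
    """LFSR-timed impulse trains, shape (n_steps, lanes) of {0,1}.

    Per 1 ms step an impulse occurs iff the fibre's 32-bit LFSR register
    falls below rate * dt * 2**32 -- a uniform-threshold draw, giving a
    Bernoulli train with the requested mean rate.  One independent stream
    (lane) per fibre per seed.
    """
    n = int(round(config.duration_s * 1000.0 / DT_MS))
    trains = []
    for name, rate in (("train:goc", config.goc_rate), ("train:mf", config.mf_rate)):
        thr = np.uint64(int(rate * DT_MS / 1000.0 * _MOD32))
        stream = seed_table.stream(name, lanes=lanes)
        out = np.empty((n, lanes), dtype=bool)
        for t in range(n):
            out[t] = stream.next_u32().astype(np.uint64) < thr
        trains.append(out)
    return trains[0], trains[1]


def _run_arm(
    config: ValidationConfig,
    goc_train: np.ndarray,
    mf_train: np.ndarray,
    mode: RoundingMode,
    seed_table: SeedTable,
    record_lane: int | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray] | None]:
    """One arithmetic arm of the single-GrC simulation, lane-parallel."""
    n, lanes = goc_train.shape
    p = dyn.NEURON_PARAMS["GrC"]
    bm = dyn.membrane_decay(p, scheme=config.scheme)
    b_goc = dyn.synaptic_decay(10.0, scheme=config.scheme)
    b_mf = dyn.synaptic_decay(0.5, scheme=config.scheme)
    fmt_g = DEFAULT_FORMATS["conductance"]
    fmt_v = DEFAULT_FORMATS["voltage"]
    w_goc = config.w_goc_pS * 1e-3
    w_mf = config.w_mf_pS * 1e-3
    reset_shift = p.V_r - p.V_th
    if mode != RoundingMode.FLOAT64:
        # stored constants live on the same 16-bit grids as the state
        w_goc = quantize(w_goc, fmt_g, RoundingMode.HALF_UP)
        w_mf = quantize(w_mf, fmt_g, RoundingMode.HALF_UP)
        reset_shift = quantize(reset_shift, fmt_v, RoundingMode.HALF_UP)
    streams = {}
    if mode == RoundingMode.RANDOMIZED:
        streams = {
            site: seed_table.stream(f"round:{site}", lanes=lanes)
            for site in ("g_goc", "g_mf", "v")
        }

    def q(x, fmt, site):
        if mode == RoundingMode.FLOAT64:
            return x
        return quantize(x, fmt, mode, streams.get(site))

    v = np.full(lanes, p.E_L)
    g1 = np.zeros(lanes)
    g2 = np.zeros(lanes)
    spikes = np.zeros(lanes, dtype=np.int64)
    rec = (
        {"g_goc": np.empty(n), "g_mf": np.empty(n), "v": np.empty(n),
         "spike": np.empty(n, dtype=bool)}
        if record_lane is not None
        else None
    )
    dt_over_C = DT_MS / p.C
    for t in range(n):
        g1 = q(b_goc * g1 + w_goc * goc_train[t], fmt_g, "g_goc")
        g2 = q(b_mf * g2 + w_mf * mf_train[t], fmt_g, "g_mf")
        i = -g1 * (v + 70.0) - g2 * v
        v = q(p.E_L + bm * (v - p.E_L) + dt_over_C * i, fmt_v, "v")
        fired = v > p.V_th
        spikes += fired
        v = np.where(fired, v + reset_shift, v)
        if rec is not None:
            k = record_lane
            rec["g_goc"][t] = g1[k]
            rec["g_mf"][t] = g2[k]
            rec["v"][t] = v[k]
            rec["spike"][t] = fired[k]
    return spikes / config.duration_s, rec


ARM_MODES = {
    "float64": RoundingMode.FLOAT64,
    "fixed_half_up": RoundingMode.HALF_UP,
    "fixed_randomized": RoundingMode.RANDOMIZED,
}


def run_single_grc_validation(
    config: ValidationConfig = ValidationConfig(),
    master_seed: int = 1,
    arms: tuple[str, ...] = ("float64", "fixed_half_up", "fixed_randomized"),
    record_traces: bool = False,
) -> ValidationResult:
    """Run the paired-arm single-GrC simulation; see module docstring."""
    table = SeedTable(master_seed)
    goc_train, mf_train = generate_input_trains(config, table, config.n_seeds)
    rates = {}
    traces = {} if record_traces else None
    for arm in arms:
        r, rec = _run_arm(
            config, goc_train, mf_train, ARM_MODES[arm], table,
            record_lane=0 if record_traces else None,
        )
        rates[arm] = r
        if record_traces:
            traces[arm] = rec
    return ValidationResult(rates=rates, traces=traces)


def run_load_experiment(
    master_seed: int = 1,
    schedule: ExperimentSchedule = ExperimentSchedule(),
    encoding: EncodingParams | None = None,
    plant_params: PlantParams | None = None,
    gains: ControllerGains | None = None,
    conditions: tuple[str, ...] = ("cerebellum", "pd_only"),
    record_weights: bool = False,
) -> dict[str, list[TrialLog]]:
    """Repeated closed-loop trials with and without the cerebellar network.

    Repetition k of either condition uses the derived seed ``(master, k)``
    for everything stochastic, so the two conditions are paired trial for
    trial and a rerun with the same master seed is bit-identical.
    """
    logs: dict[str, list[TrialLog]] = {c: [] for c in conditions}
    for k in range(schedule.repetitions):
        rep_seed = derive_seed(master_seed, k)
        for cond in conditions:
            topo = build_cerebellum(rep_seed) if cond == "cerebellum" else None
            log = run_closed_loop(
                topo, schedule, SeedTable(rep_seed),
                gains=gains, plant_params=plant_params, encoding=encoding,
                record_weights=record_weights and cond == "cerebellum",
            )
            logs[cond].append(log)
    return logs


def summarize_load_experiment(logs: dict[str, list[TrialLog]]) -> dict:
    """Per-cycle mean +/- sd of the error metric across repetitions."""
    out = {}
    for cond, trial_list in logs.items():
        errs = np.stack([t.cycle_errors for t in trial_list])
        out[cond] = {
            "mean": errs.mean(axis=0).tolist(),
            "sd": errs.std(axis=0).tolist(),
            "n": len(trial_list),
        }
    return out


def write_summary_json(summary: dict, path):
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
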