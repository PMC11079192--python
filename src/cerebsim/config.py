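"""Run configuration: defaults, YAML loading and object construction.

A run is fully described by a nested mapping with these (all optional)
sections; anything omitted takes the package defaults::

    populations:  {MF: 246, CF: 8, GrC: 4096, GoC: 369, MLI: 25, PkC: 8}
    projections:
      convergence: {"GrC<-MF": 8, "GrC<-GoC": 3, "GoC<-MF": 12,
                    "GoC<-GrC": 100, "PkC<-GrC": all, "PkC<-MLI": 5,
                    "MLI<-GrC": 42}
      weight_cv: 0.1
    plasticity:   {gamma_ltd: 5.94e-8, gamma_ltp: 4.17e-7, tau_ltd: 100.0}
    controller:   {g_P: 0.35, T_P: 310.0, G_P: 0.00635, G_D: 0.00001}
    plant:        {K: 500.0, T_m: 200.0, K_loaded: 250.0, noise_sd: 1.0}
    encoding:     {target_gain: 2.0, error_gain: 3.0, efference_gain: 200.0,
                   cf_gain: 3.0, baseline: 0.0}
    schedule:     {amplitude: 32.0, period_s: 2.048, cycles: 360,
                   load_on_cycles: [120, 300], load_off_cycles: [240],
                   repetitions: 10}
    arithmetic:   {mode: float64_reference | fixed16_half_up |
                         fixed16_randomized,
                   scheme: exponential | euler}
    seeds:        {master: 1, overrides: {}}

The mapping can live in a YAML file (``load_config``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

from .control_loop import (
    ControllerGains,
    EncodingParams,
    ExperimentSchedule,
    PlantParams,
)
from .dynamics import PlasticityParams
from .fixedpoint import ArithmeticContext, RoundingMode
from .network import (
    DEFAULT_CONVERGENCE,
    DEFAULT_POPULATION_COUNTS,
    CerebellumTopology,
    build_cerebellum,
)
from .rng import SeedTable

__all__ = ["RunConfig", "load_config"]

_ARITH_MODES = {
    "float64_reference": RoundingMode.FLOAT64,
    "fixed16_half_up": RoundingMode.HALF_UP,
    "fixed16_randomized": RoundingMode.RANDOMIZED,
}


def _take(cls, mapping: dict) -> dict:
    """Filter a mapping down to the dataclass's fields, erroring on unknowns."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}; "
            f"expected a subset of {sorted(names)}"
        )
    return mapping


@dataclass
class RunConfig:
    populations: dict = field(default_factory=lambda: dict(DEFAULT_POPULATION_COUNTS))
    convergence: dict = field(default_factory=lambda: dict(DEFAULT_CONVERGENCE))
    weight_cv: float = 0.1
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    controller: ControllerGains = field(default_factory=ControllerGains)
    plant: PlantParams = field(default_factory=PlantParams)
    encoding: EncodingParams = field(default_factory=EncodingParams)
    schedule: ExperimentSchedule = field(default_factory=ExperimentSchedule)
    arith_mode: str = "float64_reference"
    scheme: str = "exponential"
    master_seed: int = 1
    seed_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        cfg = cls()
        if "populations" in data:
            pops = dict(DEFAULT_POPULATION_COUNTS)
            pops.update(data.pop("populations"))
            cfg.populations = pops
        if "projections" in data:
            proj = data.pop("projections") or {}
            conv = dict(DEFAULT_CONVERGENCE)
            for key, val in (proj.get("convergence") or {}).items():
                post, pre = key.split("<-")
                conv[(post.strip(), pre.strip())] = val
            cfg.convergence = conv
            cfg.weight_cv = float(proj.get("weight_cv", cfg.weight_cv))
        for section, attr, klass in (
            ("plasticity", "plasticity", PlasticityParams),
            ("controller", "controller", ControllerGains),
            ("plant", "plant", PlantParams),
            ("encoding", "encoding", EncodingParams),
            ("schedule", "schedule", ExperimentSchedule),
        ):
            if section in data:
                body = _take(klass, data.pop(section) or {})
                if section == "schedule":
                    for k in ("load_on_cycles", "load_off_cycles"):
                        if k in body:
                            body[k] = tuple(body[k])
                setattr(cfg, attr, klass(**body))
        if "arithmetic" in data:
            a = data.pop("arithmetic") or {}
            mode = a.get("mode", cfg.arith_mode)
            if mode not in _ARITH_MODES:
                raise ValueError(
                    f"unknown arithmetic mode {mode!r}; choose from {sorted(_ARITH_MODES)}"
                )
            cfg.arith_mode = mode
            cfg.scheme = a.get("scheme", cfg.scheme)
        if "seeds" in data:
            s = data.pop("seeds") or {}
            cfg.master_seed = int(s.get("master", cfg.master_seed))
            cfg.seed_overrides = dict(s.get("overrides", {}))
        if data:
            raise ValueError(f"unknown config section(s): {sorted(data)}")
        return cfg

    # -- builders --------------------------------------------------------

    def seed_table(self, master_seed: int | None = None) -> SeedTable:
        return SeedTable(
            self.master_seed if master_seed is None else master_seed,
            overrides=self.seed_overrides,
        )

    def arithmetic(self, seed_table: SeedTable | None = None) -> ArithmeticContext | None:
        mode = _ARITH_MODES[self.arith_mode]
        if mode == RoundingMode.FLOAT64:
            return None
        return ArithmeticContext(mode=mode, seed_table=seed_table or self.seed_table())

    def build_topology(self, master_seed: int | None = None) -> CerebellumTopology:
        table = self.seed_table(master_seed)
        return build_cerebellum(
            master_seed=table.master_seed,
            counts=self.populations,
            convergence=self.convergence,
            weight_cv=self.weight_cv,
            scheme=self.scheme,
            plasticity_params=self.plasticity,
            arith=self.arithmetic(table),
            seed_table=table,
        )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration (missing keys fall back to defaults)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping at top level")
    return RunConfig.from_mapping(data)
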