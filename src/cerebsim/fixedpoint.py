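"""16-bit fixed-point arithmetic emulation with half-up or randomized rounding.

The hardware this package emulates stores all dynamic state in 16-bit
fixed-point words and rounds the 32-bit fraction of each multiply-accumulate
back to 16 bits once per state update.  Two rounding rules are modelled:

* ``half_up`` -- deterministic round-half-up, ``floor(x/ulp + 1/2) * ulp``.
  Per-operation error is bounded by ulp/2 but is *systematic* near the fixed
  point of a decaying map: a first-order lag driven to zero stalls at a
  nonzero residual (see :func:`stall_band`).
* ``randomized`` -- stochastic rounding: truncate, then add one ulp with
  probability equal to the discarded fraction (uniform LFSR draw compared
  against the fraction).  Expectation equals the unrounded value, so decays
  converge to zero in the mean and rounding errors do not accumulate.
* ``float64_reference`` -- bypasses quantisation entirely; the plain
  double-precision arm used as the accuracy reference.

A :class:`FixedPointFormat` carries an optional ``unit_scale`` so a quantity
can be stored in a hardware-natural unit (e.g. conductances as a 16-bit
fraction of 1 uS) while the simulator computes in its working unit (nS).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .rng import LFSRStream

__all__ = [
    "FixedPointFormat",
    "RoundingMode",
    "quantize",
    "first_order_step",
    "stall_band",
    "ArithmeticContext",
]


class RoundingMode(str, enum.Enum):
    HALF_UP = "half_up"
    RANDOMIZED = "randomized"
    FLOAT64 = "float64_reference"


@dataclass(frozen=True)
class FixedPointFormat:
    """A binary fixed-point format: ``total_bits`` wide, ``frac_bits`` of fraction.

    ``unit_scale`` is the working-unit value of the format's unit (e.g. 1000
    if the quantity is stored in uS but the simulator works in nS); the grid
    step is ``ulp = 2**-frac_bits * unit_scale``.
    """

    total_bits: int = 16
    frac_bits: int = 16
    signed: bool = True
    unit_scale: float = 1.0

    def __post_init__(self):
        if not (0 <= self.frac_bits <= 32) or self.total_bits <= 0:
            raise ValueError("invalid fixed-point format")

    @property
    def ulp(self) -> float:
        return self.unit_scale * 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        n = self.total_bits - 1 if self.signed else self.total_bits
        return ((1 << n) - 1) * self.ulp

    @property
    def min_value(self) -> float:
        if not self.signed:
            return 0.0
        return -(1 << (self.total_bits - 1)) * self.ulp


def quantize(
    x,
    fmt: FixedPointFormat,
    mode: RoundingMode = RoundingMode.HALF_UP,
    stream: LFSRStream | None = None,
    saturation_counter: list | None = None,
):
    """Round ``x`` onto the format's grid, saturating silently at the range ends.

    ``randomized`` mode rounds up iff a uniform LFSR draw falls below the
    discarded fraction, which makes the rounding unbiased:
    ``E[quantize(x)] == x`` for representable neighbourhoods.
    """
    if mode == RoundingMode.FLOAT64:
        return x
    t = np.asarray(x, dtype=np.float64) / fmt.ulp
    if mode == RoundingMode.HALF_UP:
        q = np.floor(t + 0.5)
    elif mode == RoundingMode.RANDOMIZED:
        if stream is None:
            raise ValueError("randomized rounding requires an LFSR stream")
        f = np.floor(t)
        u = stream.uniform()
        if np.ndim(u) and np.shape(u) != t.shape:
            u = np.reshape(u, t.shape)
        q = f + (u < (t - f))
    else:  # pragma: no cover
        raise ValueError(f"unknown rounding mode {mode}")
    y = q * fmt.ulp
    lo, hi = fmt.min_value, fmt.max_value
    clipped = np.clip(y, lo, hi)
    if saturation_counter is not None:
        saturation_counter[0] += int(np.sum(clipped != y))
    if np.ndim(x) == 0:
        return float(clipped)
    return clipped


def first_order_step(
    y,
    u,
    tau_over_dt: float,
    fmt: FixedPointFormat,
    mode: RoundingMode = RoundingMode.HALF_UP,
    stream: LFSRStream | None = None,
):
    """One Euler step of the first-order lag ``tau dy/dt = u - y``.

    The multiply-accumulate ``(dt/tau) u + (1 - dt/tau) y`` is carried at
    double precision (standing in for the hardware's 32-bit product fraction)
    and rounded once onto the format grid.
    """
    if tau_over_dt < 1:
        raise ValueError("tau_over_dt must be >= 1 for a stable explicit step")
    a = 1.0 / tau_over_dt
    acc = a * np.asarray(u, dtype=np.float64) + (1.0 - a) * np.asarray(y, dtype=np.float64)
    return quantize(acc, fmt, mode, stream)


def stall_band(n: int, tau_over_dt: float) -> float:
    """Half-width of the half-up rounding stall interval of a first-order lag.

    With ``u = 0`` and ``n`` fractional bits, the half-up Euler map
    ``y -> round(y (1 - dt/tau))`` ceases to change once
    ``|y| < 2**(-n-1) * tau/dt``: the per-step decrement falls below half an
    ulp and is rounded away, leaving a constant residual.  The longer the
    time constant, the wider the band.
    """
    if n < 0 or tau_over_dt <= 0:
        raise ValueError("need n >= 0 and tau_over_dt > 0")
    return 2.0 ** (-n - 1) * tau_over_dt


#: Default per-quantity formats.  Conductances and plastic weights are stored
#: as 16-bit fractions of 1 uS (ulp ~ 0.0153 nS; covers every tabulated
#: weight and summed conductance without saturation), membrane potentials as
#: signed 16-bit fractions of 1 V (range +-500 mV, ulp ~ 0.0153 mV), the
#: plasticity rate trace as a 16-bit fraction of 1.
DEFAULT_FORMATS: dict[str, FixedPointFormat] = {
    "conductance": FixedPointFormat(16, 16, signed=False, unit_scale=1000.0),
    "voltage": FixedPointFormat(16, 16, signed=True, unit_scale=1000.0),
    # plastic weights are stored as a dimensionless fraction of 1 uS
    "weight": FixedPointFormat(16, 16, signed=False, unit_scale=1.0),
    # rate trace [spikes/s] as a fraction of the 1000 sp/s ceiling
    "trace": FixedPointFormat(16, 16, signed=False, unit_scale=1000.0),
}


@dataclass
class ArithmeticContext:
    """Arithmetic mode of a simulation run.

    ``float64_reference`` mode makes every ``round_*`` call the identity, so
    the dynamics reduce to plain double-precision Euler integration.  In the
    fixed-point modes each named rounding *site* (one per state variable of
    each population/projection) owns an independent lane-parallel LFSR stream
    so randomized rounding is reproducible from the seed table.
    """

    mode: RoundingMode = RoundingMode.FLOAT64
    formats: dict[str, FixedPointFormat] = field(
        default_factory=lambda: dict(DEFAULT_FORMATS)
    )
    seed_table: object | None = None  # rng.SeedTable, set for randomized mode
    saturations: dict[str, int] = field(default_factory=dict)
    _streams: dict[str, LFSRStream] = field(default_factory=dict)

    @property
    def is_float(self) -> bool:
        return self.mode == RoundingMode.FLOAT64

    def stream_for(self, site: str, lanes: int | None = None) -> LFSRStream:
        if site not in self._streams:
            if self.seed_table is None:
                raise ValueError("randomized rounding requires a seed table")
            self._streams[site] = self.seed_table.stream("round:" + site, lanes)
        return self._streams[site]

    def round(self, quantity: str, site: str, x, lanes: int | None = None):
        """Round ``x`` at the named site using the quantity's format."""
        if self.mode == RoundingMode.FLOAT64:
            return x
        fmt = self.formats[quantity]
        stream = None
        if self.mode == RoundingMode.RANDOMIZED:
            if lanes is None and np.ndim(x) > 0:
                lanes = np.shape(x)[-1] if np.ndim(x) == 1 else int(np.size(x))
            stream = self.stream_for(site, lanes)
        counter = [0]
        out = quantize(x, fmt, self.mode, stream, saturation_counter=counter)
        if counter[0]:
            self.saturations[site] = self.saturations.get(site, 0) + counter[0]
        return out

    def quantize_parameter(self, quantity: str, x):
        """Snap a constant (e.g. an initial weight) onto the storage grid."""
        if self.mode == RoundingMode.FLOAT64:
            return x
        return quantize(x, self.formats[quantity], RoundingMode.HALF_UP)
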