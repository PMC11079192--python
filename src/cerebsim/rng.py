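"""Deterministic pseudo-random streams based on a 32-bit linear feedback shift register.

Every stochastic element of the simulator -- synaptic wiring, initial weights,
spontaneous-discharge currents, input spike timing, stochastic rounding and
sensor noise -- draws from an :class:`LFSRStream`.  A stream is a pure function
of its seed, so any pipeline rerun with the same seed table is bit-identical.

The register is a Fibonacci LFSR over GF(2) with the maximal-length tap set
(32, 22, 2, 1): the feedback bit is the XOR parity of those register bits and
is shifted in from the top.  The all-zero state is absorbing and therefore
forbidden as a seed.  With a primitive tap polynomial the state sequence
visits all 2**32 - 1 nonzero states before repeating.

Streams vectorise: a stream may carry one register per lane (e.g. one lane per
neuron for spontaneous currents), advancing all lanes in lock-step with numpy
integer ops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LFSRStream",
    "DEFAULT_TAPS",
    "lfsr_init",
    "lfsr_next",
    "derive_seed",
    "SeedTable",
]

#: Tap mask for the maximal-length polynomial x^32 + x^22 + x^2 + x + 1,
#: bits numbered 1..32 from the LSB (taps 32, 22, 2, 1).
DEFAULT_TAPS = np.uint32((1 << 31) | (1 << 21) | (1 << 1) | (1 << 0))

_U32 = np.uint32
_MOD32 = 1 << 32


def _parity32(x: np.ndarray | np.uint32) -> np.ndarray | np.uint32:
    """XOR parity of the set bits of a uint32 (vectorised)."""
    x = x ^ (x >> _U32(16))
    x = x ^ (x >> _U32(8))
    x = x ^ (x >> _U32(4))
    x = x ^ (x >> _U32(2))
    x = x ^ (x >> _U32(1))
    return x & _U32(1)


_ADV32_CACHE: dict[int, tuple] = {}


def _advance32_tables(taps: int) -> tuple:
    """Byte lookup tables for the linear 32-shift advance of the register.

    The one-shift map is linear over GF(2), so 32 shifts are too; the image
    of any state is the XOR of the images of its set bits, tabulated here
    per byte (4 tables of 256 uint32 entries).
    """
    if taps not in _ADV32_CACHE:
        basis = []
        for i in range(32):
            reg = 1 << i
            for _ in range(32):
                fb = bin(reg & taps).count("1") & 1
                reg = (reg >> 1) | (fb << 31)
            basis.append(reg)
        tables = []
        for byte in range(4):
            tab = np.zeros(256, dtype=np.uint32)
            for b in range(256):
                acc = 0
                for j in range(8):
                    if b >> j & 1:
                        acc ^= basis[8 * byte + j]
                tab[b] = acc
            tables.append(tab)
        _ADV32_CACHE[taps] = tuple(tables)
    return _ADV32_CACHE[taps]


class LFSRStream:
    """A 32-bit Fibonacci LFSR stream (scalar or lane-parallel).

    Parameters
    ----------
    seed:
        A nonzero integer in [1, 2**32 - 1], or an array of such integers for
        a lane-parallel stream.
    taps:
        Feedback tap mask; defaults to the maximal-length set (32, 22, 2, 1).
    """

    __slots__ = ("register", "taps", "seed", "draws")

    def __init__(self, seed, taps: int = int(DEFAULT_TAPS)):
        arr = np.asarray(seed)
        if np.any(arr <= 0) or np.any(arr >= _MOD32):
            raise ValueError(
                "LFSR seed(s) must lie in [1, 2**32 - 1]; the all-zero "
                "register state is absorbing"
            )
        self.register = arr.astype(np.uint32) if arr.ndim else _U32(int(seed))
        self.taps = _U32(taps)
        self.seed = seed
        self.draws = 0

    # -- core ------------------------------------------------------------

    def step(self):
        """Advance one shift-feedback step; return the new register value(s).

        This is the primitive hardware clock tick: feedback bit = XOR parity
        of the tapped bits, shifted in at the top.
        """
        fb = _parity32(self.register & self.taps)
        self.register = (self.register >> _U32(1)) | (fb << _U32(31))
        return self.register

    def next_u32(self):
        """Advance one full 32-shift word and return the register value(s).

        Successive single shifts of a Fibonacci LFSR share 31 of 32 bits, so
        thresholding *consecutive* register values would produce strongly
        serially-correlated (bursty) draws.  The hardware this emulates
        clocks its LFSRs at MHz rates between 1 ms samples; accordingly each
        emitted word is separated by 32 register shifts (a decimation that
        preserves the full 2**32 - 1 period, since gcd(32, 2**32 - 1) = 1).
        The 32-step linear map is applied in one go via byte lookup tables.
        """
        t = _advance32_tables(int(self.taps))
        r = self.register
        self.register = (
            t[0][r & _U32(0xFF)]
            ^ t[1][(r >> _U32(8)) & _U32(0xFF)]
            ^ t[2][(r >> _U32(16)) & _U32(0xFF)]
            ^ t[3][r >> _U32(24)]
        )
        self.draws += 1
        return self.register

    def next_array(self, n: int) -> np.ndarray:
        """Return the next ``n`` word draws of a scalar stream."""
        t0, t1, t2, t3 = _advance32_tables(int(self.taps))
        out = np.empty(n, dtype=np.uint32)
        reg = int(self.register)
        for i in range(n):
            reg = int(
                t0[reg & 0xFF]
                ^ t1[(reg >> 8) & 0xFF]
                ^ t2[(reg >> 16) & 0xFF]
                ^ t3[reg >> 24]
            )
            out[i] = reg
        self.register = _U32(reg)
        self.draws += n
        return out

    # -- derived draws ---------------------------------------------------

    def uniform(self):
        """Uniform float in (0, 1) -- the register never hits 0."""
        return self.next_u32() / np.float64(_MOD32)

    def uniform_int(self, m: int):
        """Uniform integer in [0, m) by modulo reduction of the register.

        The modulo bias is below 2**-19 for any m <= 2**13 (register values
        are uniform over the 2**32 - 1 nonzero states), negligible at the
        population sizes used here.
        """
        if m < 1:
            raise ValueError("uniform_int range m must be >= 1")
        return self.next_u32() % _U32(m) if m > 1 else (
            np.zeros_like(self.register, dtype=np.uint32)
            if isinstance(self.register, np.ndarray) else _U32(0)
        )

    def gaussian(self, mean: float = 0.0, sd: float = 1.0):
        """Draw from N(mean, sd**2) by Box-Muller over two LFSR uniforms.

        Each call consumes exactly two draws per lane (no spare caching), so
        replaying a seed replays the sample sequence.
        """
        if sd < 0:
            raise ValueError("gaussian sd must be nonnegative")
        u1 = self.uniform()
        u2 = self.uniform()
        z = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
        return mean + sd * z

    def copy(self) -> "LFSRStream":
        dup = LFSRStream.__new__(LFSRStream)
        dup.register = (
            self.register.copy()
            if isinstance(self.register, np.ndarray)
            else self.register
        )
        dup.taps = self.taps
        dup.seed = self.seed
        dup.draws = self.draws
        return dup


def lfsr_init(seed: int, taps: int = int(DEFAULT_TAPS)) -> LFSRStream:
    """Construct a stream from a nonzero 32-bit seed."""
    return LFSRStream(seed, taps)


def lfsr_next(stream: LFSRStream):
    """Advance ``stream`` one shift-feedback step; return the register value.

    This is the raw hardware clock tick (see :meth:`LFSRStream.step`); the
    word-level draw used for sampling is :meth:`LFSRStream.next_u32`.
    """
    return stream.step()


# -- seed derivation -----------------------------------------------------

def derive_seed(master: int, index: int) -> int:
    """Derive the ``index``-th consumer seed from a master seed.

    Uses a splitmix-style integer hash so that nearby master seeds and nearby
    indices give unrelated streams.  The result is a nonzero 31-bit integer.
    """
    x = (master + 0x9E3779B9 * (index + 1)) & 0xFFFFFFFF
    x = (x ^ (x >> 16)) * 0x85EBCA6B & 0xFFFFFFFF
    x = (x ^ (x >> 13)) * 0xC2B2AE35 & 0xFFFFFFFF
    x = (x ^ (x >> 16)) & 0x7FFFFFFF
    return x if x != 0 else 0x5EED


class SeedTable:
    """Maps named consumers to independent LFSR streams.

    One stream per consumer (each projection's wiring, each rounding site,
    each input-spike generator, ...) with seeds derived from a single master
    seed by a fixed hash of the consumer name's registration order, so a run
    is reproducible from the master seed alone.  Individual consumers can be
    pinned to explicit seeds via ``overrides``.
    """

    def __init__(self, master_seed: int, overrides: dict[str, int] | None = None):
        if not (0 <= master_seed < _MOD32):
            raise ValueError("master seed must be a 32-bit unsigned integer")
        self.master_seed = int(master_seed)
        self.overrides = dict(overrides or {})
        self._index: dict[str, int] = {}

    def seed_for(self, name: str) -> int:
        if name in self.overrides:
            return int(self.overrides[name])
        if name not in self._index:
            # stable per-name index from the name itself, not registration order
            h = 0
            for ch in name:
                h = (h * 131 + ord(ch)) & 0xFFFFFFFF
            self._index[name] = h
        return derive_seed(self.master_seed, self._index[name])

    def stream(self, name: str, lanes: int | None = None) -> LFSRStream:
        """A fresh stream for ``name``; lane-parallel if ``lanes`` is given."""
        base = self.seed_for(name)
        if lanes is None:
            return LFSRStream(base)
        seeds = [derive_seed(base, k) for k in range(lanes)]
        return LFSRStream(np.asarray(seeds, dtype=np.uint64))
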