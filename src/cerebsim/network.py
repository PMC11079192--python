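"""Bi-hemispheric cerebellar topology: populations, LFSR-drawn wiring, stepping.

Each hemisphere holds 246 mossy fibres (MF), 8 climbing fibres (CF), 4096
granule cells (GrC), 369 Golgi cells (GoC), 25 molecular-layer inhibitory
interneurons (MLI, a.k.a. basket cells BkC) and 8 Purkinje cells (PkC) --
4752 units, 9504 in the two hemispheres.  Wiring is random with replacement:
for every postsynaptic neuron, ``convergence`` presynaptic sources are drawn
by uniform LFSR draws (a source drawn twice simply contributes two edges,
equivalent to doubling that weight).  Each PkC receives parallel fibres from
*all* granule cells of its hemisphere.

Only two convergence ratios are fixed by the reference network description
(GoC <- GrC = 100 and PkC <- all GrC); the remaining defaults below were
chosen to preserve plausible convergence ratios (e.g. a handful of mossy
fibre inputs per granule cell) under the constraint that the default build
reproduces exactly 240,484 synapses in total:

    GrC<-MF 8, GrC<-GoC 3, GoC<-MF 12, GoC<-GrC 100,
    PkC<-GrC all (4096), PkC<-MLI 5, MLI<-GrC 42

per hemisphere: 32768 + 12288 + 4428 + 36900 + 32768 + 40 + 1050 = 120,242
edges, times two hemispheres = 240,484.  The constraint is re-checked at
build time for the default configuration.

Climbing fibres form no conductance synapse; CF m is paired 1:1 with PkC m
and acts purely as the plasticity teaching signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dynamics as dyn
from .dynamics import (
    NEURON_PARAMS,
    SYNAPSE_PARAMS,
    NeuronParams,
    PlasticityParams,
    SynapseParams,
)
from .fixedpoint import ArithmeticContext
from .rng import LFSRStream, SeedTable

__all__ = [
    "DEFAULT_POPULATION_COUNTS",
    "DEFAULT_CONVERGENCE",
    "ProjectionSpec",
    "ProjectionGroup",
    "Hemisphere",
    "CerebellumTopology",
    "draw_connections",
    "init_weights",
    "build_cerebellum",
    "step_network",
]

DEFAULT_POPULATION_COUNTS: dict[str, int] = {
    "MF": 246,
    "CF": 8,
    "GrC": 4096,
    "GoC": 369,
    "MLI": 25,
    "PkC": 8,
}

#: (post, pre) -> presynaptic inputs per postsynaptic neuron ("all" = full fan-in)
DEFAULT_CONVERGENCE: dict[tuple[str, str], int | str] = {
    ("GrC", "MF"): 8,
    ("GrC", "GoC"): 3,
    ("GoC", "MF"): 12,
    ("GoC", "GrC"): 100,
    ("PkC", "GrC"): "all",
    ("PkC", "MLI"): 5,
    ("MLI", "GrC"): 42,
}

REFERENCE_NEURON_TOTAL = 9504
REFERENCE_SYNAPSE_TOTAL = 240484

_ALIAS = {"BkC": "MLI"}


def _canon(name: str) -> str:
    return _ALIAS.get(name, name)


@dataclass(frozen=True)
class ProjectionSpec:
    post: str
    pre: str
    convergence: int | str
    params: SynapseParams

    def edge_count(self, counts: dict[str, int]) -> int:
        n_post = counts[self.post]
        if self.convergence == "all":
            return n_post * counts[self.pre]
        return n_post * int(self.convergence)


def gaussian_array(stream: LFSRStream, n: int, mean: float, sd: float) -> np.ndarray:
    """n Box-Muller Gaussians from a scalar LFSR stream (2n draws)."""
    if sd == 0.0:
        return np.full(n, mean)
    u = stream.next_array(2 * n).astype(np.float64) / 2.0**32
    u1, u2 = u[:n], u[n:]
    z = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
    return mean + sd * z


def draw_connections(
    pre_count: int, post_count: int, convergence: int | str, stream: LFSRStream | None
) -> np.ndarray | None:
    """Presynaptic ids per postsynaptic neuron, shape (post, convergence).

    Sources are drawn uniformly *with replacement* (duplicate edges are kept
    as distinct synapses).  ``"all"`` means deterministic full fan-in and
    consumes nothing from the stream; it is represented by ``None``.
    """
    if convergence == "all":
        return None
    convergence = int(convergence)
    if convergence <= 0:
        raise ValueError("convergence must be positive")
    raw = stream.next_array(post_count * convergence)
    return (raw % np.uint32(pre_count)).astype(np.int64).reshape(post_count, convergence)


def init_weights(
    spec: ProjectionSpec,
    shape: tuple[int, ...],
    stream: LFSRStream,
    cv: float = 0.1,
) -> np.ndarray:
    """Initial weights [nS]: Gaussian around the tabulated mean, clipped at 0.

    The standard deviation is ``cv * mean``.  A zero mean (the plastic
    parallel-fibre -> PkC class) yields an exactly-zero weight vector and
    consumes no draws.
    """
    mean = spec.params.w_mean_nS
    if mean == 0.0:
        return np.zeros(shape)
    n = int(np.prod(shape))
    w = gaussian_array(stream, n, mean, cv * mean)
    return np.maximum(w, 0.0).reshape(shape)


class ProjectionGroup:
    """One pre -> post synapse class within a hemisphere.

    Holds the edge list (post-major), weights [nS] and one conductance per
    postsynaptic neuron [nS].  The plastic parallel-fibre class instead
    reads its weights from the hemisphere's plasticity matrix each step.
    """

    def __init__(
        self,
        spec: ProjectionSpec,
        counts: dict[str, int],
        wiring_stream: LFSRStream | None,
        weight_stream: LFSRStream | None,
        weight_cv: float = 0.1,
        scheme: str = "exponential",
    ):
        self.spec = spec
        self.n_pre = counts[spec.pre]
        self.n_post = counts[spec.post]
        self.pre_ids = draw_connections(self.n_pre, self.n_post, spec.convergence, wiring_stream)
        if self.pre_ids is None:
            shape = (self.n_post, self.n_pre)
        else:
            shape = self.pre_ids.shape
        self.w = init_weights(spec, shape, weight_stream, weight_cv) if weight_stream else np.zeros(shape)
        self.g = np.zeros(self.n_post)
        self.beta = dyn.synaptic_decay(spec.params.tau_syn, scheme=scheme)
        self.scheme = scheme
        self._csr = None
        if self.pre_ids is not None and self.n_post * max(1, self.n_pre) > 512:
            # compressed sparse row (post x pre) view of the edge list for
            # fast per-step accumulation; duplicates sum as required
            from scipy import sparse

            conv = self.pre_ids.shape[1]
            rows = np.repeat(np.arange(self.n_post), conv)
            self._csr = sparse.csr_matrix(
                (self.w.ravel(), (rows, self.pre_ids.ravel())),
                shape=(self.n_post, self.n_pre),
            )

    def _csr_matvec(self, x: np.ndarray) -> np.ndarray:
        """Low-overhead sparse matvec (bypasses scipy's dispatch layer)."""
        from scipy.sparse import _sparsetools

        M = self._csr
        out = np.zeros(self.n_post)
        _sparsetools.csr_matvec(
            self.n_post, self.n_pre, M.indptr, M.indices, M.data, x, out
        )
        return out

    @property
    def edge_count(self) -> int:
        return int(np.prod(self.w.shape))

    def jump_from(self, delta_pre: np.ndarray) -> np.ndarray:
        """Summed weight of last step's presynaptic impulses per target [nS]."""
        if not delta_pre.any():
            return 0.0
        if self.pre_ids is None:
            return self.w @ delta_pre
        if self._csr is not None:
            return self._csr.dot(delta_pre.astype(np.float64))
        return (self.w * delta_pre[self.pre_ids]).sum(axis=1)

    def step(self, delta_pre: np.ndarray, arith: ArithmeticContext | None, site: str):
        self.g = dyn.step_conductance(
            self.g, self.jump_from(delta_pre), self.spec.params.tau_syn,
            scheme=self.scheme, arith=arith, site=site,
        )

    def edges(self):
        """Yield (pre_id, post_id, weight_pS) rows, post-major."""
        if self.pre_ids is None:
            for m in range(self.n_post):
                for n in range(self.n_pre):
                    yield n, m, self.w[m, n] * 1e3
        else:
            for m in range(self.n_post):
                for k in range(self.pre_ids.shape[1]):
                    yield int(self.pre_ids[m, k]), m, self.w[m, k] * 1e3


class Hemisphere:
    """Populations, projections and plasticity state of one hemisphere."""

    def __init__(
        self,
        label: str,
        seed_table: SeedTable,
        counts: dict[str, int] | None = None,
        convergence: dict[tuple[str, str], int | str] | None = None,
        weight_cv: float = 0.1,
        scheme: str = "exponential",
        plasticity_params: PlasticityParams | None = None,
        arith: ArithmeticContext | None = None,
        seed_prefix: str | None = None,
    ):
        self.label = label
        self.counts = dict(counts or DEFAULT_POPULATION_COUNTS)
        self.convergence = {
            (_canon(a), _canon(b)): v
            for (a, b), v in (convergence or DEFAULT_CONVERGENCE).items()
        }
        self.scheme = scheme
        self.arith = arith
        self.plasticity = plasticity_params or PlasticityParams()
        prefix = seed_prefix if seed_prefix is not None else label
        self._prefix = prefix

        # populations
        self.params: dict[str, NeuronParams] = {p: NEURON_PARAMS[p] for p in self.counts}
        self.v: dict[str, np.ndarray] = {
            p: np.full(self.counts[p], self.params[p].E_L) for p in self.counts
        }
        self.delta: dict[str, np.ndarray] = {
            p: np.zeros(self.counts[p], dtype=bool) for p in self.counts
        }
        # one pooled lane bank for all spontaneous-discharge draws (a lane
        # per neuron with I_spont > 0), sliced per population each step
        self._spont_slices: dict[str, slice] = {}
        off = 0
        for p in self.counts:
            if self.params[p].I_spont > 0.0 and self.counts[p] > 0:
                self._spont_slices[p] = slice(off, off + self.counts[p])
                off += self.counts[p]
        self._spont_bank: LFSRStream | None = (
            seed_table.stream(f"{prefix}:spont", lanes=off) if off else None
        )

        # projections (conductance synapses); CF pairs with PkC without one
        self.projections: dict[tuple[str, str], ProjectionGroup] = {}
        for (post, pre), conv in self.convergence.items():
            spec = ProjectionSpec(post, pre, conv, SYNAPSE_PARAMS[(post, pre)])
            if self.counts[post] == 0 or self.counts[pre] == 0:
                continue
            wiring = seed_table.stream(f"{prefix}:wiring:{post}<-{pre}")
            weights = seed_table.stream(f"{prefix}:weights:{post}<-{pre}")
            self.projections[(post, pre)] = ProjectionGroup(
                spec, self.counts, wiring, weights, weight_cv, scheme
            )

        # plastic parallel-fibre weights, stored as fractions of 1 uS.
        # kept GrC-major (n_GrC, n_PkC) so the common LTP update touches
        # contiguous rows; the (n_PkC, n_GrC) view is exposed as a property.
        self._w_pf_t = np.zeros((self.counts["GrC"], self.counts["PkC"]))
        self._w_bound = 0.0  # running upper bound on any plastic weight
        self.q_grc = np.zeros(self.counts["GrC"])

        # precomputed per-population membrane constants for the float path
        self._mem = {}
        for pop, p in self.params.items():
            beta = dyn.membrane_decay(p, scheme=scheme)
            self._mem[pop] = (beta, (1.0 - beta) * p.E_L, dyn.DT_MS / p.C)
        self._kd = None  # lazily built numba kernel data

    @property
    def w_pf_pkc(self) -> np.ndarray:
        """(n_PkC, n_GrC) view of the plastic parallel-fibre weights."""
        return self._w_pf_t.T

    @w_pf_pkc.setter
    def w_pf_pkc(self, value):
        self._w_pf_t = np.ascontiguousarray(np.asarray(value).T)
        self._w_bound = float(self._w_pf_t.max()) if self._w_pf_t.size else 0.0

    # -- counts ----------------------------------------------------------

    @property
    def neuron_count(self) -> int:
        return sum(self.counts.values())

    @property
    def synapse_count(self) -> int:
        return sum(p.edge_count for p in self.projections.values())

    # -- accelerated path -------------------------------------------------

    def _build_kernel_data(self):
        """Flatten state into the layout the numba kernel consumes.

        Population membrane/impulse dict entries become views into single
        flat arrays, so both code paths always see the same state.
        """
        pops = list(self.counts)
        off = np.zeros(len(pops) + 1, dtype=np.int64)
        for i, p in enumerate(pops):
            off[i + 1] = off[i] + self.counts[p]
        v_all = np.empty(off[-1])
        d_all = np.zeros(off[-1], dtype=bool)
        for i, p in enumerate(pops):
            v_all[off[i]:off[i + 1]] = self.v[p]
            d_all[off[i]:off[i + 1]] = self.delta[p]
            self.v[p] = v_all[off[i]:off[i + 1]]
            self.delta[p] = d_all[off[i]:off[i + 1]]
        pidx = {p: i for i, p in enumerate(pops)}

        projs = list(self.projections.items())
        P = len(projs)
        goff = np.zeros(P + 1, dtype=np.int64)
        beta = np.empty(P)
        E = np.empty(P)
        plastic = np.zeros(P, dtype=np.int8)
        ppre = np.empty(P, dtype=np.int64)
        ppost = np.empty(P, dtype=np.int64)
        iptr_blocks, epost_blocks, ew_blocks = [], [], []
        iptr_off = np.zeros(P, dtype=np.int64)
        edge_off = np.zeros(P, dtype=np.int64)
        g_views = []
        for k, ((post, pre), proj) in enumerate(projs):
            goff[k + 1] = goff[k] + proj.n_post
            beta[k] = proj.beta
            E[k] = proj.spec.params.E
            ppre[k] = pidx[pre]
            ppost[k] = pidx[post]
            if proj.spec.params.plastic:
                plastic[k] = 1
                iptr = np.zeros(proj.n_pre + 1, dtype=np.int64)
                eposts = np.zeros(0, dtype=np.int32)
                ew = np.zeros(0)
            else:
                flat_pre = proj.pre_ids.ravel()
                posts = np.repeat(
                    np.arange(proj.n_post, dtype=np.int32), proj.pre_ids.shape[1]
                )
                order = np.argsort(flat_pre, kind="stable")
                eposts = posts[order]
                ew = proj.w.ravel()[order]
                counts = np.bincount(flat_pre, minlength=proj.n_pre)
                iptr = np.zeros(proj.n_pre + 1, dtype=np.int64)
                np.cumsum(counts, out=iptr[1:])
            iptr_off[k] = sum(len(b) for b in iptr_blocks)
            edge_off[k] = sum(len(b) for b in ew_blocks)
            iptr_blocks.append(iptr)
            epost_blocks.append(eposts)
            ew_blocks.append(ew)
        g_all = np.empty(goff[-1])
        for k, (_key, proj) in enumerate(projs):
            g_all[goff[k]:goff[k + 1]] = proj.g
            proj.g = g_all[goff[k]:goff[k + 1]]
            g_views.append(proj.g)

        mem = np.array([self._mem[p] for p in pops])  # (n_pops, 3)
        self._kd = {
            "pops": pops,
            "pop_off": off,
            "v_all": v_all,
            "d_all": d_all,
            "beta_m": np.ascontiguousarray(mem[:, 0]),
            "c1": np.ascontiguousarray(mem[:, 1]),
            "a_over_C": np.ascontiguousarray(mem[:, 2]),
            "vth": np.array([self.params[p].V_th for p in pops]),
            "vr_shift": np.array([self.params[p].V_r - self.params[p].V_th for p in pops]),
            "g_all": g_all,
            "proj_pre": ppre,
            "proj_post": ppost,
            "proj_goff": goff,
            "proj_beta": beta,
            "proj_E": E,
            "proj_plastic": plastic,
            "indptr_all": np.concatenate(iptr_blocks) if iptr_blocks else np.zeros(0, dtype=np.int64),
            "proj_iptr_off": iptr_off,
            "edge_post_all": np.concatenate(epost_blocks) if epost_blocks else np.zeros(0, dtype=np.int32),
            "edge_w_all": np.concatenate(ew_blocks) if ew_blocks else np.zeros(0),
            "proj_edge_off": edge_off,
            "i_acc": np.empty(off[-1]),
            "fired": np.zeros(off[-1], dtype=bool),
        }

    def _step_kernel(self, mf_drive, cf_drive, plasticity: bool) -> dict[str, np.ndarray]:
        from . import _kernels

        if self._kd is None:
            self._build_kernel_data()
        kd = self._kd
        pops = kd["pops"]
        off = kd["pop_off"]
        i_acc = kd["i_acc"]
        i_acc[:] = 0.0
        spont_u = self._spont_bank.uniform() if self._spont_bank is not None else None
        for i, p in enumerate(pops):
            if p in self._spont_slices:
                i_acc[off[i]:off[i + 1]] = (
                    2.0 * self.params[p].I_spont * spont_u[self._spont_slices[p]]
                )
            if p == "MF":
                i_acc[off[i]:off[i + 1]] += mf_drive
            elif p == "CF":
                i_acc[off[i]:off[i + 1]] += cf_drive
        _kernels.hemi_step_kernel(
            kd["v_all"], kd["d_all"], off,
            kd["beta_m"], kd["c1"], kd["a_over_C"], kd["vth"], kd["vr_shift"],
            kd["g_all"], kd["proj_pre"], kd["proj_post"], kd["proj_goff"],
            kd["proj_beta"], kd["proj_E"], kd["proj_plastic"],
            kd["indptr_all"], kd["proj_iptr_off"],
            kd["edge_post_all"], kd["edge_w_all"], kd["proj_edge_off"],
            self._w_pf_t, self.plasticity.w_scale_nS,
            i_acc, kd["fired"],
        )
        kd["d_all"][:] = kd["fired"]
        if not np.isfinite(kd["v_all"].sum()):
            raise FloatingPointError("non-finite membrane state in network step")
        new_delta = self.delta  # views into d_all, already updated
        if self.counts["GrC"] and plasticity and self.counts["PkC"]:
            pp = self.plasticity
            gi = pops.index("GrC")
            ci = pops.index("CF")
            _kernels.plasticity_kernel(
                self._w_pf_t, self.q_grc,
                kd["d_all"][off[gi]:off[gi + 1]], kd["d_all"][off[ci]:off[ci + 1]],
                pp.gamma_ltp, pp.gamma_ltd,
                1.0 - dyn.DT_MS / pp.tau_ltd, 1000.0 / pp.tau_ltd,
            )
            self._w_bound += pp.gamma_ltp
            if self._w_bound >= pp.w_max:
                np.minimum(self._w_pf_t, pp.w_max, out=self._w_pf_t)
                self._w_bound = float(self._w_pf_t.max()) + pp.gamma_ltp
        elif self.counts["GrC"]:
            pp = self.plasticity
            gi = pops.index("GrC")
            q = self.q_grc
            q *= 1.0 - dyn.DT_MS / pp.tau_ltd
            gd = kd["d_all"][off[gi]:off[gi + 1]]
            if gd.any():
                q[gd] += 1000.0 / pp.tau_ltd
        return new_delta

    # -- stepping --------------------------------------------------------

    def step(self, mf_drive=0.0, cf_drive=0.0, plasticity: bool = True) -> dict[str, np.ndarray]:
        """Advance the hemisphere one 1 ms tick.

        Order: (1) conductance decay + jumps from the *previous* step's
        impulses, (2) synaptic currents, (3) membrane update with threshold
        and reset, (4) rate trace and plasticity from this step's GrC/CF
        impulses.  Returns the new impulse flags per population (in the
        accelerated path these are views valid until the next step; copy
        them to keep a history).
        """
        arith = self.arith
        fast = arith is None or arith.is_float
        if fast:
            from . import _kernels

            if _kernels.HAVE_NUMBA:
                return self._step_kernel(mf_drive, cf_drive, plasticity)
        delta_prev = self.delta
        active = {pop: bool(delta_prev[pop].any()) for pop in delta_prev}
        fdelta: dict[str, np.ndarray] = {}  # float view of previous impulses

        def fprev(pop):
            if pop not in fdelta:
                fdelta[pop] = delta_prev[pop].astype(np.float64)
            return fdelta[pop]

        # (1) conductances from registered impulses
        for (post, pre), proj in self.projections.items():
            if proj.spec.params.plastic:
                # plastic class: weights come from the learning matrix (uS fractions)
                dp = delta_prev[pre]
                if active[pre]:
                    jump = self._w_pf_t[dp].sum(axis=0) * self.plasticity.w_scale_nS
                else:
                    jump = None
            elif active[pre]:
                if proj._csr is not None:
                    jump = proj._csr_matvec(fprev(pre))
                elif proj.pre_ids is None:
                    jump = proj.w @ fprev(pre)
                else:
                    jump = (proj.w * fprev(pre)[proj.pre_ids]).sum(axis=1)
            else:
                jump = None
            if fast:
                g = proj.g
                g *= proj.beta
                if jump is not None:
                    g += jump
                if proj.scheme == "euler":
                    np.maximum(g, 0.0, out=g)
            else:
                proj.g = dyn.step_conductance(
                    proj.g, 0.0 if jump is None else jump, proj.spec.params.tau_syn,
                    scheme=self.scheme, arith=arith,
                    site=f"{self._prefix}:g:{post}<-{pre}",
                )

        # (2)+(3) synaptic currents and membrane updates
        new_delta: dict[str, np.ndarray] = {}
        spont_u = self._spont_bank.uniform() if self._spont_bank is not None else None
        for pop in self.counts:
            n = self.counts[pop]
            if n == 0:
                new_delta[pop] = np.zeros(0, dtype=bool)
                continue
            p = self.params[pop]
            v = self.v[pop]
            i = np.zeros(n)
            for (post, _pre), proj in self.projections.items():
                if post != pop:
                    continue
                E = proj.spec.params.E
                if E == 0.0:
                    i -= proj.g * v
                else:
                    i -= proj.g * (v - E)
            if pop in self._spont_slices:
                i += 2.0 * p.I_spont * spont_u[self._spont_slices[pop]]
            if pop == "MF":
                i += mf_drive
            elif pop == "CF":
                i += cf_drive
            if fast:
                beta, c1, a = self._mem[pop]
                v_new = v * beta
                v_new += c1
                i *= a
                v_new += i
                fired = v_new > p.V_th
                if fired.any():
                    v_new[fired] += p.V_r - p.V_th
                self.v[pop] = v_new
                new_delta[pop] = fired
            else:
                self.v[pop], new_delta[pop] = dyn.step_membrane(
                    v, i, 0.0, p,
                    scheme=self.scheme, arith=arith,
                    site=f"{self._prefix}:v:{pop}",
                )
        check = 0.0
        for pop in self.counts:
            if self.counts[pop]:
                check += float(self.v[pop].sum())
        if not np.isfinite(check):
            raise FloatingPointError("non-finite membrane state in network step")
        self.delta = new_delta

        # (4) rate trace and parallel-fibre plasticity
        if self.counts["GrC"]:
            if fast:
                pp = self.plasticity
                q = self.q_grc
                q *= 1.0 - dyn.DT_MS / pp.tau_ltd
                gd = new_delta["GrC"]
                if gd.any():
                    q[gd] += 1000.0 / pp.tau_ltd
            else:
                self.q_grc = dyn.step_grc_trace(
                    self.q_grc, new_delta["GrC"], self.plasticity,
                    arith=arith, site=f"{self._prefix}:q",
                )
            if plasticity and self.counts["PkC"]:
                self._apply_plasticity(new_delta["GrC"], new_delta["CF"])
        return new_delta

    def _apply_plasticity(self, grc_delta: np.ndarray, cf_delta: np.ndarray):
        pp = self.plasticity
        arith = self.arith
        if arith is not None and not arith.is_float:
            self.w_pf_pkc = dyn.apply_plasticity(
                self.w_pf_pkc, self.q_grc, grc_delta, cf_delta, pp,
                arith=arith, site=f"{self._prefix}:w",
            )
            return
        # float64 fast path: touch only active rows/columns.
        # weights are GrC-major, so the common case (LTP on the spiking
        # granule cells, no CF spike) updates contiguous rows.
        # No synapse receives LTD and LTP in the same step (the CF impulse
        # gates them disjointly per PkC row), so the two updates commute with
        # the [0, w_max] clip.  The upper clip is skipped while a running
        # upper bound (each step can raise any weight by at most gamma_LTP)
        # certifies no weight can have reached w_max.
        wt = self._w_pf_t
        if grc_delta.any():
            if cf_delta.any():
                block = wt[grc_delta]
                block[:, ~cf_delta] += pp.gamma_ltp
                wt[grc_delta] = block
            else:
                wt[grc_delta] += pp.gamma_ltp
            self._w_bound += pp.gamma_ltp
            if self._w_bound >= pp.w_max:
                np.minimum(wt, pp.w_max, out=wt)
                self._w_bound = float(wt.max()) + pp.gamma_ltp
        if cf_delta.any():
            for m in np.flatnonzero(cf_delta):
                col = wt[:, m]
                col -= pp.gamma_ltd * self.q_grc
                np.maximum(col, 0.0, out=col)

    def purkinje_impulses(self) -> np.ndarray:
        return self.delta["PkC"]


class CerebellumTopology:
    """Two independently wired hemispheres sharing parameters."""

    def __init__(self, left: Hemisphere, right: Hemisphere):
        self.hemispheres = {"L": left, "R": right}

    @property
    def neuron_count(self) -> int:
        return sum(h.neuron_count for h in self.hemispheres.values())

    @property
    def synapse_count(self) -> int:
        return sum(h.synapse_count for h in self.hemispheres.values())

    def count_summary(self) -> dict:
        h = self.hemispheres["L"]
        return {
            "neurons_total": self.neuron_count,
            "synapses_total": self.synapse_count,
            "per_hemisphere": dict(h.counts),
            "edges_per_projection": {
                f"{post}<-{pre}": proj.edge_count
                for (post, pre), proj in h.projections.items()
            },
        }

    def step(self, mf_drive_L=0.0, mf_drive_R=0.0, cf_drive_L=0.0, cf_drive_R=0.0,
             plasticity: bool = True) -> dict[str, dict[str, np.ndarray]]:
        return {
            "L": self.hemispheres["L"].step(mf_drive_L, cf_drive_L, plasticity),
            "R": self.hemispheres["R"].step(mf_drive_R, cf_drive_R, plasticity),
        }

    def write_edges(self, directory):
        """Dump each projection's edge list as columnar text (pre, post, pS)."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, hemi in self.hemispheres.items():
            for (post, pre), proj in hemi.projections.items():
                path = directory / f"{label}_{post}_from_{pre}.tsv"
                with open(path, "w") as fh:
                    fh.write("pre_id\tpost_id\tweight_pS\n")
                    for a, b, w in proj.edges():
                        fh.write(f"{a}\t{b}\t{w:.6g}\n")


def build_cerebellum(
    master_seed: int = 1,
    counts: dict[str, int] | None = None,
    convergence: dict[tuple[str, str], int | str] | None = None,
    weight_cv: float = 0.1,
    scheme: str = "exponential",
    plasticity_params: PlasticityParams | None = None,
    arith: ArithmeticContext | None = None,
    mirror_seeds: bool = False,
    seed_table: SeedTable | None = None,
) -> CerebellumTopology:
    """Build the two-hemisphere network from a master seed.

    Hemispheres share all parameters but draw wiring, weights and noise from
    disjoint seed streams (``mirror_seeds=True`` forces identical streams,
    used for symmetry diagnostics).  With the default counts and convergence
    table the build is checked against the reference totals (9,504 neurons,
    240,484 synapses).
    """
    table = seed_table or SeedTable(master_seed)
    counts = dict(counts or DEFAULT_POPULATION_COUNTS)
    conv = convergence or DEFAULT_CONVERGENCE
    bad = [k for k in counts if k not in NEURON_PARAMS]
    if bad:
        raise ValueError(f"unknown population name(s) in config: {bad}")
    kw = dict(
        counts=counts, convergence=conv, weight_cv=weight_cv, scheme=scheme,
        plasticity_params=plasticity_params, arith=arith,
    )
    left = Hemisphere("L", table, seed_prefix="L", **kw)
    right = Hemisphere("R", table, seed_prefix="L" if mirror_seeds else "R", **kw)
    topo = CerebellumTopology(left, right)
    if counts == DEFAULT_POPULATION_COUNTS and dict(conv) == DEFAULT_CONVERGENCE:
        if topo.neuron_count != REFERENCE_NEURON_TOTAL or (
            topo.synapse_count != REFERENCE_SYNAPSE_TOTAL
        ):
            raise AssertionError(
                "default build does not reproduce the reference totals: "
                f"{topo.neuron_count} neurons, {topo.synapse_count} synapses"
            )
    return topo


def step_network(topology: CerebellumTopology, mf_drive, cf_drive, **kw):
    """Functional wrapper over :meth:`CerebellumTopology.step`.

    ``mf_drive``/``cf_drive`` are (left, right) pairs of per-fibre injected
    currents [pA].
    """
    mL, mR = mf_drive if isinstance(mf_drive, tuple) else (mf_drive, mf_drive)
    cL, cR = cf_drive if isinstance(cf_drive, tuple) else (cf_drive, cf_drive)
    return topology.step(mL, mR, cL, cR, **kw)
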