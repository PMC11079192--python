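"""Topology construction, wiring statistics, and whole-network stepping.

The central check is a brute-force oracle: a pure-Python per-neuron,
per-edge reimplementation of the update order (conductance decay, jumps
from the previous step's impulses, currents, membrane threshold/reset,
rate trace, LTD/LTP) stepped alongside the vectorised network on a
miniature topology, spike for spike.
"""

import numpy as np
import pytest

from cerebsim import dynamics as dyn
from cerebsim.network import (
    DEFAULT_CONVERGENCE,
    DEFAULT_POPULATION_COUNTS,
    ProjectionSpec,
    build_cerebellum,
    draw_connections,
    init_weights,
)
from cerebsim.rng import LFSRStream, SeedTable

from conftest import MINI_CONVERGENCE, MINI_COUNTS, make_mini_hemisphere


class TestCounts:
    def test_default_build_reference_totals(self, default_topology):
        assert default_topology.neuron_count == 9504
        assert default_topology.synapse_count == 240484

    def test_per_hemisphere_composition(self, default_topology):
        h = default_topology.hemispheres["L"]
        assert h.counts == {"MF": 246, "CF": 8, "GrC": 4096, "GoC": 369,
                            "MLI": 25, "PkC": 8}
        assert h.neuron_count == 4752

    def test_fixed_convergence_projections(self, default_topology):
        h = default_topology.hemispheres["L"]
        assert h.projections[("GoC", "GrC")].edge_count == 36900
        assert h.projections[("PkC", "GrC")].edge_count == 32768

    def test_zero_size_build_is_empty(self):
        counts = {k: 0 for k in DEFAULT_POPULATION_COUNTS}
        topo = build_cerebellum(1, counts=counts)
        assert topo.neuron_count == 0
        assert topo.synapse_count == 0

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError, match="unknown population"):
            build_cerebellum(1, counts={"XX": 5})


class TestWiring:
    def test_full_fan_in_has_no_random_edges(self):
        s = LFSRStream(3)
        before = int(s.register)
        assert draw_connections(4096, 8, "all", s) is None
        assert int(s.register) == before  # stream untouched

    def test_convergence_shape_and_range(self):
        ids = draw_connections(50, 20, 7, LFSRStream(5))
        assert ids.shape == (20, 7)
        assert ids.min() >= 0 and ids.max() < 50

    def test_replacement_allows_convergence_above_pool(self):
        ids = draw_connections(3, 4, 10, LFSRStream(5))
        assert ids.shape == (4, 10)

    def test_nonpositive_convergence_rejected(self):
        with pytest.raises(ValueError):
            draw_connections(10, 5, 0, LFSRStream(1))

    def test_out_degree_matches_replacement_sampling(self):
        # each of `post*conv` draws hits a given source w.p. 1/pre: the mean
        # out-degree over rebuilds is binomial(post*conv, 1/pre)
        pre, post, conv = 40, 30, 8
        reps = 200
        deg = np.zeros(pre)
        for r in range(reps):
            ids = draw_connections(pre, post, conv, LFSRStream(1000 + r))
            deg += np.bincount(ids.ravel(), minlength=pre)
        mean_deg = deg / reps
        expected = post * conv / pre  # = 6
        sd = np.sqrt(post * conv * (1 / pre) * (1 - 1 / pre) / reps)
        assert np.all(np.abs(mean_deg - expected) < 6 * sd)

    def test_rebuild_same_seed_bit_identical(self):
        a = build_cerebellum(9, counts=MINI_COUNTS, convergence=MINI_CONVERGENCE)
        b = build_cerebellum(9, counts=MINI_COUNTS, convergence=MINI_CONVERGENCE)
        for key in a.hemispheres["L"].projections:
            pa = a.hemispheres["L"].projections[key]
            pb = b.hemispheres["L"].projections[key]
            if pa.pre_ids is not None:
                assert np.array_equal(pa.pre_ids, pb.pre_ids)
            assert np.array_equal(pa.w, pb.w)

    def test_different_seeds_differ_only_in_wiring(self):
        a = build_cerebellum(9, counts=MINI_COUNTS, convergence=MINI_CONVERGENCE)
        b = build_cerebellum(10, counts=MINI_COUNTS, convergence=MINI_CONVERGENCE)
        assert a.synapse_count == b.synapse_count
        pa = a.hemispheres["L"].projections[("GoC", "GrC")]
        pb = b.hemispheres["L"].projections[("GoC", "GrC")]
        assert not np.array_equal(pa.pre_ids, pb.pre_ids)


class TestInitWeights:
    def test_parallel_fibre_weights_start_at_zero(self, default_topology):
        h = default_topology.hemispheres["L"]
        assert np.all(h.w_pf_pkc == 0.0)

    def test_degenerate_cv_gives_exact_mean(self):
        spec = ProjectionSpec("GrC", "MF", 4, dyn.SYNAPSE_PARAMS[("GrC", "MF")])
        w = init_weights(spec, (100,), LFSRStream(2), cv=0.0)
        assert np.allclose(w, 19.5e-3)

    def test_sample_mean_matches_table(self, default_topology):
        # GrC<-MF weights ~ N(19.5 pS, (cv 19.5)^2): 32768 samples, 3 sigma
        w = default_topology.hemispheres["L"].projections[("GrC", "MF")].w
        sd = 0.1 * 19.5e-3
        assert abs(w.mean() - 19.5e-3) < 3 * sd / np.sqrt(w.size)

    def test_weights_nonnegative(self, default_topology):
        for proj in default_topology.hemispheres["L"].projections.values():
            assert np.all(proj.w >= 0.0)


# ---------------------------------------------------------------------------
# brute-force scalar oracle
# ---------------------------------------------------------------------------

def _oracle_run(hemi_seed, n_steps, mf_drive_fn, cf_drive_fn):
    """Per-neuron, per-edge pure-Python rerun of a mini hemisphere."""
    hemi = make_mini_hemisphere(hemi_seed)  # only to copy wiring/weights
    counts = hemi.counts
    pops = list(counts)
    params = {p: dyn.NEURON_PARAMS[p] for p in pops}
    scheme = "exponential"
    beta_m = {p: float(np.exp(-params[p].g_L / params[p].C)) for p in pops}
    projs = []
    for (post, pre), proj in hemi.projections.items():
        edges_by_pre = [[] for _ in range(counts[pre])]
        if proj.pre_ids is not None:
            for m in range(proj.n_post):
                for k in range(proj.pre_ids.shape[1]):
                    edges_by_pre[int(proj.pre_ids[m, k])].append(
                        (m, float(proj.w[m, k]))
                    )
        projs.append({
            "post": post, "pre": pre,
            "beta": float(proj.beta), "E": proj.spec.params.E,
            "plastic": proj.spec.params.plastic,
            "g": [0.0] * proj.n_post,
            "edges_by_pre": edges_by_pre,
        })
    pp = hemi.plasticity
    wT = [[0.0] * counts["PkC"] for _ in range(counts["GrC"])]
    q = [0.0] * counts["GrC"]
    v = {p: [params[p].E_L] * counts[p] for p in pops}
    delta = {p: [False] * counts[p] for p in pops}
    spont_order = [p for p in pops if params[p].I_spont > 0.0 and counts[p] > 0]
    lanes = sum(counts[p] for p in spont_order)
    spont = SeedTable(hemi_seed).stream("L:spont", lanes=lanes)

    spikes = []
    for t in range(n_steps):
        # conductance decay then jumps from previous impulses (pre-major)
        for pr in projs:
            pr["g"] = [g * pr["beta"] for g in pr["g"]]
        for pr in projs:
            if pr["plastic"]:
                for j in range(counts[pr["pre"]]):
                    if delta[pr["pre"]][j]:
                        for m in range(counts[pr["post"]]):
                            pr["g"][m] += wT[j][m] * pp.w_scale_nS
            else:
                for j in range(counts[pr["pre"]]):
                    if delta[pr["pre"]][j]:
                        for m, w in pr["edges_by_pre"][j]:
                            pr["g"][m] += w
        # external + spontaneous drive
        u = spont.uniform()
        i = {p: [0.0] * counts[p] for p in pops}
        off = 0
        for p in spont_order:
            for j in range(counts[p]):
                i[p][j] = 2.0 * params[p].I_spont * u[off + j]
            off += counts[p]
        for j in range(counts["MF"]):
            i["MF"][j] += mf_drive_fn(t, j)
        for j in range(counts["CF"]):
            i["CF"][j] += cf_drive_fn(t, j)
        # synaptic currents
        for pr in projs:
            post = pr["post"]
            for m in range(counts[post]):
                i[post][m] -= pr["g"][m] * (v[post][m] - pr["E"])
        # membranes
        new_delta = {}
        for p in pops:
            prm = params[p]
            nd = []
            for j in range(counts[p]):
                vn = v[p][j] * beta_m[p] + (1 - beta_m[p]) * prm.E_L + i[p][j] * (1.0 / prm.C)
                if vn > prm.V_th:
                    nd.append(True)
                    vn += prm.V_r - prm.V_th
                else:
                    nd.append(False)
                v[p][j] = vn
            new_delta[p] = nd
        delta = new_delta
        # rate trace and plasticity
        any_cf = any(delta["CF"])
        for j in range(counts["GrC"]):
            q[j] *= 1.0 - 1.0 / pp.tau_ltd
            if delta["GrC"][j]:
                q[j] += 1000.0 / pp.tau_ltd
                for m in range(counts["PkC"]):
                    if not delta["CF"][m]:
                        wT[j][m] += pp.gamma_ltp
        for m in range(counts["PkC"]):
            if delta["CF"][m]:
                for j in range(counts["GrC"]):
                    wT[j][m] = max(0.0, wT[j][m] - pp.gamma_ltd * q[j])
        spikes.append({p: list(delta[p]) for p in pops})
    return spikes, v, wT


def _drive_mf(t, j):
    return 12.0 + 10.0 * np.sin(2 * np.pi * t / 200.0) + 3.0 * j


def _drive_cf(t, j):
    return 6.0 if t % 97 < 3 else 0.0


class TestNetworkStep:
    def test_silent_network_stays_silent(self):
        counts = dict(MINI_COUNTS)
        hemi = make_mini_hemisphere(21)
        # zero all spontaneous drive by replacing parameters
        for p in list(hemi.params):
            prm = hemi.params[p]
            hemi.params[p] = dyn.NeuronParams(prm.C, prm.g_L, prm.E_L, 0.0,
                                              prm.V_r, prm.V_th)
        hemi._spont_slices = {}
        hemi._spont_bank = None
        hemi._mem = {p: (dyn.membrane_decay(hemi.params[p]),
                         (1 - dyn.membrane_decay(hemi.params[p])) * hemi.params[p].E_L,
                         1.0 / hemi.params[p].C) for p in hemi.params}
        for _ in range(50):
            delta = hemi.step(0.0, 0.0)
            assert not any(d.any() for d in delta.values())

    def test_one_step_transmission_delay(self):
        # an impulse emitted at step t must not move any postsynaptic
        # conductance until step t+1 (registered spike storage)
        hemi = make_mini_hemisphere(22)
        first_mf_spike = None
        for t in range(30):
            delta = hemi.step(mf_drive=2000.0, cf_drive=0.0, plasticity=False)
            g_grc_mf = hemi.projections[("GrC", "MF")].g
            if first_mf_spike is None and delta["MF"].any():
                first_mf_spike = t
                assert np.all(g_grc_mf == 0.0)  # same-step: not yet visible
            elif first_mf_spike is not None and t == first_mf_spike + 1:
                assert np.any(g_grc_mf > 0.0)   # next step: jump landed
        assert first_mf_spike is not None

    def test_matches_scalar_loop_oracle_spike_for_spike(self):
        n_steps = 1000
        hemi = make_mini_hemisphere(23)
        got = []
        for t in range(n_steps):
            mf = np.array([_drive_mf(t, j) for j in range(hemi.counts["MF"])])
            cf = np.array([_drive_cf(t, j) for j in range(hemi.counts["CF"])])
            delta = hemi.step(mf, cf)
            got.append({p: d.copy() for p, d in delta.items()})
        exp_spikes, exp_v, exp_w = _oracle_run(23, n_steps, _drive_mf, _drive_cf)
        total = 0
        for t in range(n_steps):
            for p in hemi.counts:
                assert np.array_equal(got[t][p], exp_spikes[t][p]), (t, p)
                total += int(np.sum(got[t][p]))
        assert total > 100  # the comparison exercised real activity
        for p in hemi.counts:
            assert np.allclose(hemi.v[p], exp_v[p], atol=1e-9)
        assert np.allclose(hemi.w_pf_pkc, np.array(exp_w).T, atol=1e-15)

    def test_numpy_and_accelerated_paths_agree(self, monkeypatch):
        def run(disable):
            if disable:
                from cerebsim import _kernels
                monkeypatch.setattr(_kernels, "HAVE_NUMBA", False)
            hemi = make_mini_hemisphere(24)
            out = []
            for t in range(400):
                mf = np.array([_drive_mf(t, j) for j in range(hemi.counts["MF"])])
                cf = np.array([_drive_cf(t, j) for j in range(hemi.counts["CF"])])
                delta = hemi.step(mf, cf)
                out.append({p: d.copy() for p, d in delta.items()})
            return out, hemi

        fast, h1 = run(False)
        slow, h2 = run(True)
        for t in range(len(fast)):
            for p in MINI_COUNTS:
                assert np.array_equal(fast[t][p], slow[t][p]), (t, p)
        for p in MINI_COUNTS:
            assert np.allclose(h1.v[p], h2.v[p], atol=1e-9)

    def test_inhibitory_projections_never_depolarize_above_reversal(self):
        hemi = make_mini_hemisphere(25)
        for t in range(300):
            hemi.step(mf_drive=30.0, cf_drive=0.0)
            for (post, pre), proj in hemi.projections.items():
                assert np.all(proj.g >= 0.0)
                if proj.spec.params.E == -70.0:
                    v = hemi.v[post]
                    i = -proj.g * (v - proj.spec.params.E)
                    assert np.all(i[v > -70.0] <= 0.0)

    def test_mirror_seeds_make_hemispheres_identical(self):
        topo = build_cerebellum(31, counts=MINI_COUNTS,
                                convergence=MINI_CONVERGENCE, mirror_seeds=True)
        for t in range(100):
            delta = topo.step(15.0, 15.0, 0.0, 0.0)
            for p in MINI_COUNTS:
                assert np.array_equal(delta["L"][p], delta["R"][p])


class TestEdgeDump:
    def test_columnar_text_roundtrip(self, tmp_path):
        topo = build_cerebellum(13, counts=MINI_COUNTS, convergence=MINI_CONVERGENCE)
        topo.write_edges(tmp_path)
        f = tmp_path / "L_GoC_from_GrC.tsv"
        lines = f.read_text().strip().splitlines()
        assert lines[0] == "pre_id\tpost_id\tweight_pS"
        assert len(lines) - 1 == MINI_COUNTS["GoC"] * MINI_CONVERGENCE[("GoC", "GrC")]


class TestFixedPointNetworkPath:
    @pytest.mark.parametrize("mode", ["half_up", "randomized"])
    def test_state_stays_on_storage_grid(self, mode):
        from cerebsim.fixedpoint import DEFAULT_FORMATS, ArithmeticContext, RoundingMode

        st = SeedTable(5)
        arith = ArithmeticContext(
            mode=RoundingMode.HALF_UP if mode == "half_up" else RoundingMode.RANDOMIZED,
            seed_table=st,
        )
        hemi = make_mini_hemisphere(5, arith=arith)
        for t in range(100):
            hemi.step(mf_drive=30.0, cf_drive=6.0 if t % 50 < 2 else 0.0)
        ulp_v = DEFAULT_FORMATS["voltage"].ulp
        for p in hemi.counts:
            k = hemi.v[p] / ulp_v
            assert np.allclose(k, np.round(k), atol=1e-6)
        ulp_g = DEFAULT_FORMATS["conductance"].ulp
        for proj in hemi.projections.values():
            k = proj.g / ulp_g
            assert np.allclose(k, np.round(k), atol=1e-6)
            assert np.all(proj.g >= 0.0)

    def test_randomized_mode_reproducible_from_seed(self):
        from cerebsim.fixedpoint import ArithmeticContext, RoundingMode

        def run():
            st = SeedTable(6)
            arith = ArithmeticContext(mode=RoundingMode.RANDOMIZED, seed_table=st)
            hemi = make_mini_hemisphere(6, arith=arith)
            for _ in range(80):
                hemi.step(mf_drive=25.0)
            return {p: hemi.v[p].copy() for p in hemi.counts}

        a, b = run(), run()
        for p in a:
            assert np.array_equal(a[p], b[p])
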