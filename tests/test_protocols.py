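"""Protocol engines: weight init, reproducibility, and an independent
step-by-step reference implementation built from the module-level operations."""

import math

import numpy as np
import pytest

import ca1plast.seeding as seeding
from ca1plast import (ExplorationProtocol, IOProtocol, ModelParams,
                      PlasticityConfig, ConnectivityConfig,
                      exc_hebbian_step, init_exc_weights, ou_trace,
                      pv_iltd_step, run_batch, run_exploration_batch,
                      run_exploration_trial, run_io_batch, run_io_trial,
                      sst_iltp_step, step_dendrite, step_soma, tuning_curves)

SHORT_SCHEDULE = (("A", 2), ("B", 1), ("A_prime", 2))


class TestInitWeights:
    def test_two_adjacent_seeded_entries(self, params):
        for seed in range(20):
            w = init_exc_weights(np.random.default_rng(seed), params)
            idx = np.flatnonzero(w == 0.6)
            assert len(idx) == 2
            assert (idx[1] - idx[0]) % params.n_sc in (1, params.n_sc - 1)
            assert np.all(w > 0)

    def test_unseeded_mean_matches_lognormal_moment(self, params):
        """E[0.1 * lognormal(0, 0.1)] = 0.1 * e^{0.005}."""
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(400):
            w = init_exc_weights(rng, params)
            vals.extend(w[w != 0.6])
        assert np.mean(vals) == pytest.approx(0.1 * math.exp(0.005),
                                              rel=2e-3)


def _reference_exploration(protocol: ExplorationProtocol, master_seed: int,
                           trial_index: int):
    """Step-by-step re-simulation from the module-level operations.

    Regenerates the identical per-trial noise substreams (same generation
    pattern as the batch engine: stationary init, then chunked traces) and
    integrates with step_dendrite / step_soma / plasticity functions.
    """
    p = protocol.params
    nsc = p.n_sc
    gen_sc = seeding.substream(master_seed, seeding.SC_NOISE, trial_index)
    gen_ta = seeding.substream(master_seed, seeding.TA_NOISE, trial_index)
    gen_w = seeding.substream(master_seed, seeding.INIT_WEIGHTS, trial_index)
    gen_p = seeding.substream(master_seed, seeding.PERMUTATION, trial_index)

    w_sc = init_exc_weights(gen_w, p)
    perm_b = gen_p.permutation(nsc)
    identity = np.arange(nsc)

    f32 = np.float32
    xi_sc_last = (np.sqrt(p.ou_var)
                  * gen_sc.standard_normal(nsc, dtype=f32)).astype(f32)
    xi_ta_last = f32(np.sqrt(p.ou_var) * float(gen_ta.standard_normal(dtype=f32)))

    spl = p.steps_per_lap
    chunk = min(4000, spl)
    centers = np.arange(nsc) * p.track_length / nsc
    pos_lap = (np.arange(1, spl + 1) * (p.speed * p.dt)) % p.track_length

    plast = protocol.plasticity
    exc = plast.exc_on and p.eta_sc > 0
    pv_on = plast.pv_on and p.eta_pv > 0
    sst_on = plast.sst_on and p.eta_sst > 0

    r_dend = r_soma = 0.0
    w_pv, w_sst = p.w_pv_init, p.w_sst_init
    soma_trace = []
    for lap, env in enumerate(protocol.lap_environments):
        perm = perm_b if env == "B" else identity
        for c0 in range(0, spl, chunk):
            xi_sc = ou_trace(chunk, p.dt, gen_sc, tau=p.ou_tau,
                             variance=p.ou_var, n_streams=nsc,
                             x0=xi_sc_last, dtype=f32)
            xi_ta = ou_trace(chunk, p.dt, gen_ta, tau=p.ou_tau,
                             variance=p.ou_var, x0=xi_ta_last, dtype=f32)
            xi_sc_last, xi_ta_last = xi_sc[-1].copy(), xi_ta[-1]
            tuning = tuning_curves(pos_lap[c0:c0 + chunk], centers, p)
            for t in range(chunk):
                ta = max(p.mu_ta + float(xi_ta[t]), 0.0)
                rates = np.maximum(tuning[t, perm] + xi_sc[t], 0.0)
                r_dend = float(step_dendrite(r_dend, ta, w_sst, 1.0, p))
                sc_drive = float(np.dot(w_sc, rates))
                r_soma = float(step_soma(r_soma, r_dend, sc_drive,
                                         w_pv, 1.0, p))
                if exc:
                    w_sc = exc_hebbian_step(w_sc, r_dend, r_soma, rates, p)
                if pv_on:
                    w_pv = float(pv_iltd_step(w_pv, 1.0, r_soma, p))
                if sst_on:
                    w_sst = float(sst_iltp_step(w_sst, 1.0, r_soma, p))
                soma_trace.append(r_soma)
    return np.array(soma_trace), w_sc, w_pv, w_sst


class TestEngineAgainstReference:
    def test_batch_engine_matches_module_operations(self):
        proto = ExplorationProtocol(lap_schedule=(("A", 1), ("B", 1)))
        rec = run_exploration_trial(proto, master_seed=11, trial_index=0)
        ref_soma, ref_w_sc, ref_w_pv, ref_w_sst = _reference_exploration(
            proto, 11, 0)
        # compare down-sampled soma trace and final weights
        rec_every = int(round(proto.record_every_ms / proto.params.dt))
        np.testing.assert_allclose(rec.r_soma,
                                   ref_soma[rec_every - 1::rec_every],
                                   rtol=0, atol=1e-9)
        np.testing.assert_allclose(rec.w_sc_laps[-1], ref_w_sc, atol=1e-9)
        assert rec.w_pv[-1] == pytest.approx(ref_w_pv, abs=1e-9)
        assert rec.w_sst[-1] == pytest.approx(ref_w_sst, abs=1e-9)


class TestReproducibility:
    def test_same_seed_identical_batches(self):
        proto = ExplorationProtocol(lap_schedule=(("A", 1),))
        r1 = run_exploration_batch(proto, 2, 5)
        r2 = run_exploration_batch(proto, 2, 5)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.r_soma, b.r_soma)
            np.testing.assert_array_equal(a.w_sc_laps, b.w_sc_laps)

    def test_trial_invariant_to_batch_size(self):
        proto = ExplorationProtocol(lap_schedule=(("A", 1),))
        small = run_exploration_batch(proto, 1, 5)[0]
        large = run_exploration_batch(proto, 3, 5)[0]
        np.testing.assert_array_equal(small.r_soma, large.r_soma)
        np.testing.assert_array_equal(small.w_sc_laps, large.w_sc_laps)

    def test_io_trial_matches_batch_slice(self):
        proto = IOProtocol(
            connectivity=ConnectivityConfig(mode="connectivity_driven",
                                            pv_alpha=1),
            pathway="SC", active_rule="PV_iLTD",
            baseline_ms=1000, induction_ms=2000, post_ms=1000)
        single = run_io_trial(proto, 9, trial_index=1)
        batch = run_io_batch(proto, 3, 9)[1]
        np.testing.assert_array_equal(single.r_soma, batch.r_soma)
        np.testing.assert_array_equal(single.w_pv, batch.w_pv)


class TestPlasticityToggles:
    def test_all_off_leaves_weights_untouched(self):
        proto = ExplorationProtocol(
            lap_schedule=(("A", 1),),
            plasticity=PlasticityConfig(exc_on=False, pv_on=False,
                                        sst_on=False))
        rec = run_exploration_trial(proto, 3)
        np.testing.assert_array_equal(rec.w_sc_laps[0], rec.w_sc_laps[-1])
        assert rec.w_pv[-1] == rec.w_pv[0] == 1.0
        assert rec.w_sst[-1] == rec.w_sst[0] == 1.0

    def test_off_equals_zero_learning_rate(self):
        """Disabling a rule is bit-identical to eta = 0."""
        base = dict(lap_schedule=(("A", 1),))
        off = ExplorationProtocol(
            plasticity=PlasticityConfig(exc_on=False, pv_on=False,
                                        sst_on=True), **base)
        zeroed = ExplorationProtocol(
            plasticity=PlasticityConfig(exc_on=True, pv_on=True,
                                        sst_on=True),
            params=ModelParams(eta_sc=0.0, eta_pv=0.0), **base)
        r_off = run_exploration_trial(off, 21)
        r_zero = run_exploration_trial(zeroed, 21)
        np.testing.assert_array_equal(r_off.w_sc_laps, r_zero.w_sc_laps)
        np.testing.assert_array_equal(r_off.w_pv, r_zero.w_pv)
        np.testing.assert_array_equal(r_off.r_soma, r_zero.r_soma)

    def test_inhibitory_weights_move_in_rule_direction(self):
        proto = ExplorationProtocol(lap_schedule=(("A", 2),))
        rec = run_exploration_trial(proto, 13)
        assert rec.w_sst[-1] >= rec.w_sst[0]
        assert rec.w_pv[-1] <= rec.w_pv[0]
        assert np.all(np.diff(rec.w_sst) >= 0)
        assert np.all(np.diff(rec.w_pv) <= 0)


class TestEnvironmentRestoration:
    def test_maps_match_with_plasticity_off(self):
        """A' inputs are identical to A's, so with frozen weights the
        time-averaged spatial maps agree within sampling error: the A-vs-A'
        agreement is as good as the lap-to-lap agreement within A itself."""
        from ca1plast.analysis import spatial_map, spatial_correlation
        proto = ExplorationProtocol(
            lap_schedule=(("A", 4), ("B", 1), ("A_prime", 4)),
            plasticity=PlasticityConfig(exc_on=False, pv_on=False,
                                        sst_on=False))
        rec = run_exploration_trial(proto, 17)
        m_a = spatial_map(rec, "A")
        m_ap = spatial_map(rec, "A_prime")
        cross = spatial_correlation(m_a, m_ap)
        within = spatial_correlation(
            spatial_map(rec, "A", laps=[0, 1]),
            spatial_map(rec, "A", laps=[2, 3]))
        assert cross > 0.8
        assert cross > within - 0.1  # no extra decorrelation beyond noise
        assert np.nanmean(np.abs(m_a.mean_rate - m_ap.mean_rate)) < 0.05


class TestIOProtocol:
    def test_epoch_structure_and_silent_pathway(self):
        proto = IOProtocol(
            connectivity=ConnectivityConfig(mode="connectivity_driven"),
            pathway="SC", active_rule="none",
            baseline_ms=1000, induction_ms=1000, post_ms=1000)
        rec = run_io_trial(proto, 2)
        epoch = rec.extras["epoch"]
        assert sorted(set(epoch)) == [0, 1, 2]
        # TA silent during measurement epochs, active during induction
        assert np.all(rec.extras["ta_input"][epoch != 1] == 0.0)
        assert rec.extras["ta_input"][epoch == 1].mean() > 1.0

    def test_no_rule_means_no_weight_change(self):
        proto = IOProtocol(
            connectivity=ConnectivityConfig(mode="connectivity_driven",
                                            pv_alpha=1, sst_gamma=1),
            pathway="both", active_rule="none",
            baseline_ms=1000, induction_ms=2000, post_ms=1000)
        rec = run_io_trial(proto, 4)
        assert np.all(rec.w_pv == rec.w_pv[0])
        assert np.all(rec.w_sst == rec.w_sst[0])

    def test_constant_rate_mode_rejected(self):
        proto = IOProtocol(connectivity=ConnectivityConfig(),
                           baseline_ms=100, induction_ms=100, post_ms=100)
        with pytest.raises(ValueError):
            run_io_trial(proto, 1)


def test_run_batch_dispatch():
    proto = ExplorationProtocol(lap_schedule=(("A", 1),))
    recs = run_batch(proto, 2, 1)
    assert len(recs) == 2 and recs[0].kind == "exploration"
    with pytest.raises(TypeError):
        run_batch(object(), 1, 1)


def test_trial_record_time_axis():
    proto = ExplorationProtocol(lap_schedule=(("A", 1),))
    rec = run_exploration_trial(proto, 1)
    # one lap = 20,000 ms at 10-ms down-sampling
    assert len(rec.time_ms) == 2000
    assert rec.time_ms[-1] == pytest.approx(20_000.0)
    assert rec.environment_of_sample()[0] == "A"
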