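"""Simulation protocols: input-output reprioritisation and environment switch.

Two in-silico experiments are implemented.

*Input-output protocol.* A single neuron receives artificial (untuned) SC
and/or TA stimulation with OU noise, interneuron rates driven by the chosen
feedforward/feedback connectivity. Somatic activity and input-output
correlations are measured in a baseline epoch (plasticity off), inhibitory
plasticity is induced with both pathways active, and the baseline
measurement is repeated. Excitatory plasticity is off throughout; the
single-channel SC weight is fixed.

*Environment-switch (exploration) protocol.* The animal runs laps on an
annular track through environments A (10 laps), B (15 laps) and back to
A-prime (10 laps). The switch to B shuffles the identity of the place-tuned
SC inputs; the return restores the original identity. Interneuron rates are
constant (r_PV = r_SST = 1); SC Hebbian plasticity and the enabled
inhibitory rules run throughout exploration.

Both protocols are simulated for whole batches at once (state arrays carry a
trial axis) while every trial consumes its own named RNG substreams, so a
single trial re-simulated in isolation is bit-identical to its slice of the
batch. Per-step update order: inputs; interneuron rates from the
previous step's somatic activity; dendrite; soma; plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels, seeding
from .inputs import ou_trace, tuning_curves
from .model import ConnectivityConfig
from .params import ModelParams
from .plasticity import PlasticityConfig

__all__ = [
    "IOProtocol",
    "ExplorationProtocol",
    "TrialRecord",
    "init_exc_weights",
    "run_io_trial",
    "run_exploration_trial",
    "run_batch",
    "run_io_batch",
    "run_exploration_batch",
]

DEFAULT_LAP_SCHEDULE = (("A", 10), ("B", 15), ("A_prime", 10))


@dataclass(frozen=True)
class IOProtocol:
    """Configuration of the input-output (artificial stimulation) experiment.

    ``pathway`` selects which input is stimulated during the measurement
    epochs ("SC", "TA" or "both"); the silent pathway contributes zero mean
    and zero noise. ``active_rule`` selects the inhibitory rule(s) active
    during induction ("PV_iLTD", "SST_iLTP", "both" or "none"). Durations
    are simulated milliseconds.
    """

    connectivity: ConnectivityConfig = field(
        default_factory=lambda: ConnectivityConfig(mode="connectivity_driven"))
    pathway: str = "both"
    active_rule: str = "both"
    baseline_ms: float = 10_000.0
    induction_ms: float = 60_000.0
    post_ms: float = 10_000.0
    record_every_ms: float = 10.0
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.pathway not in ("SC", "TA", "both"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.active_rule not in ("PV_iLTD", "SST_iLTP", "both", "none"):
            raise ValueError(f"unknown active_rule {self.active_rule!r}")
        for name in ("baseline_ms", "induction_ms", "post_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ExplorationProtocol:
    """Configuration of the A -> B -> A' environment-switch experiment."""

    lap_schedule: tuple = DEFAULT_LAP_SCHEDULE
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    record_every_ms: float = 10.0
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if not self.lap_schedule:
            raise ValueError("empty lap schedule")
        for env, laps in self.lap_schedule:
            if laps <= 0:
                raise ValueError(f"lap count for {env!r} must be positive")

    @property
    def lap_environments(self) -> list[str]:
        out: list[str] = []
        for env, laps in self.lap_schedule:
            out.extend([env] * laps)
        return out


@dataclass
class TrialRecord:
    """Down-sampled traces and weight snapshots of one simulated trial.

    ``time_ms`` marks the simulated time of each recorded sample (default
    every 10 ms). For exploration trials, ``position``/``lap_index`` locate
    each sample on the track and ``w_sc_laps`` holds the SC weight vector
    after every lap (row 0 = initial weights). For input-output trials,
    ``extras`` carries the stimulation traces and an epoch code per sample
    (0 baseline, 1 induction, 2 post).
    """

    kind: str
    params: ModelParams
    master_seed: int
    trial_index: int
    time_ms: np.ndarray
    r_dend: np.ndarray
    r_soma: np.ndarray
    w_pv: np.ndarray
    w_sst: np.ndarray
    position: np.ndarray | None = None
    lap_index: np.ndarray | None = None
    lap_environments: list[str] | None = None
    w_sc_laps: np.ndarray | None = None
    permutation_b: np.ndarray | None = None
    protocol: object | None = None
    extras: dict = field(default_factory=dict)

    def environment_of_sample(self) -> np.ndarray:
        """Environment label of every recorded sample (exploration only)."""
        if self.lap_index is None or self.lap_environments is None:
            raise ValueError("not an exploration record")
        labels = np.asarray(self.lap_environments, dtype=object)
        return labels[self.lap_index]


def init_exc_weights(rng: np.random.Generator,
                     params: ModelParams) -> np.ndarray:
    """Initial SC weights: scaled lognormal draws plus a seeded adjacent pair.

    Weights are drawn from a lognormal whose underlying normal has mean 0
    and sd 0.1, multiplied by 0.1; then a uniformly random input and its
    circular neighbour are set to 0.6, imposing a small structure that lets
    the inputs drive postsynaptic activity from the start.
    """
    w = rng.lognormal(mean=0.0, sigma=0.1, size=params.n_sc) * 0.1
    k = int(rng.integers(params.n_sc))
    w[k] = 0.6
    w[(k + 1) % params.n_sc] = 0.6
    return w


# ---------------------------------------------------------------------------
# exploration (environment switch) engine
# ---------------------------------------------------------------------------

def run_exploration_batch(protocol: ExplorationProtocol, n_trials: int,
                          master_seed: int,
                          trial_indices: Sequence[int] | None = None,
                          ) -> list[TrialRecord]:
    """Simulate ``n_trials`` exploration trials vectorized across trials."""
    p = protocol.params
    n = int(n_trials)
    if n < 1:
        raise ValueError("n_trials must be >= 1")
    idx = np.arange(n) if trial_indices is None else np.asarray(trial_indices)
    plast = protocol.plasticity

    lap_envs = protocol.lap_environments
    n_laps = len(lap_envs)
    spl = p.steps_per_lap
    total_steps = n_laps * spl
    rec_every = max(1, int(round(protocol.record_every_ms / p.dt)))
    n_rec = total_steps // rec_every

    dt, k_euler = p.dt, p.euler_factor
    centers = np.arange(p.n_sc) * p.track_length / p.n_sc
    nsc = p.n_sc

    # per-trial RNG streams
    gens_sc = [seeding.substream(master_seed, seeding.SC_NOISE, i) for i in idx]
    gens_ta = [seeding.substream(master_seed, seeding.TA_NOISE, i) for i in idx]

    # initial state
    w_sc = np.stack([
        init_exc_weights(seeding.substream(master_seed, seeding.INIT_WEIGHTS, i), p)
        for i in idx])
    perm_b = np.stack([
        seeding.substream(master_seed, seeding.PERMUTATION, i).permutation(nsc)
        for i in idx])
    w_pv = np.full(n, p.w_pv_init, dtype=float)
    w_sst = np.full(n, p.w_sst_init, dtype=float)
    r_dend = np.zeros(n)
    r_soma = np.zeros(n)

    # stationary initial OU values; noise runs in float32 (contractive
    # recursion, no error accumulation) to halve generation cost
    noise_dtype = np.float32
    xi_sc_last = np.stack([
        (np.sqrt(p.ou_var) * g.standard_normal(nsc, dtype=noise_dtype))
        for g in gens_sc]).astype(noise_dtype)
    xi_ta_last = np.array([
        np.sqrt(p.ou_var) * float(g.standard_normal(dtype=noise_dtype))
        for g in gens_ta], dtype=noise_dtype)

    # effective learning toggles (off is identical to eta = 0)
    exc_active = plast.exc_on and p.eta_sc > 0.0
    pv_active = plast.pv_on and p.eta_pv > 0.0
    sst_active = plast.sst_on and p.eta_sst > 0.0
    # constant interneuron rates (exploration uses constant-rate mode)
    r_inter = 1.0
    eta_pv_dt = p.eta_pv * dt * r_inter
    eta_sst_dt = p.eta_sst * dt * r_inter
    eta_sc_dt = p.eta_sc * dt
    g_gain, g_slope, thr = p.g_gain, p.g_slope, p.hebb_threshold
    w_min, w_max, norm_target = p.w_min, p.w_max, p.norm_target

    identity = np.broadcast_to(np.arange(nsc), (n, nsc)).copy()

    # recording buffers
    rec_r_dend = np.empty((n_rec, n))
    rec_r_soma = np.empty((n_rec, n))
    rec_w_pv = np.empty((n_rec, n))
    rec_w_sst = np.empty((n_rec, n))
    rec_pos = np.empty(n_rec)
    rec_lap = np.empty(n_rec, dtype=int)
    w_sc_laps = np.empty((n_laps + 1, n, nsc))
    w_sc_laps[0] = w_sc

    chunk = min(4000, spl)
    assert spl % chunk == 0
    step_in_lap_pos = (np.arange(1, spl + 1) * (p.speed * dt)) % p.track_length
    rec_i = 0

    for lap in range(n_laps):
        env = lap_envs[lap]
        perm = perm_b if env == "B" else identity
        for c0 in range(0, spl, chunk):
            pos_chunk = step_in_lap_pos[c0:c0 + chunk]
            tuning = tuning_curves(pos_chunk, centers, p)     # (C, nsc)
            # per-trial OU noise for the chunk, trial-major
            xi_sc = np.empty((n, chunk, nsc), dtype=noise_dtype)
            xi_ta = np.empty((n, chunk), dtype=noise_dtype)
            for i in range(n):
                xi_sc[i] = ou_trace(chunk, dt, gens_sc[i],
                                    tau=p.ou_tau, variance=p.ou_var,
                                    n_streams=nsc, x0=xi_sc_last[i],
                                    dtype=noise_dtype)
                xi_ta[i] = ou_trace(chunk, dt, gens_ta[i],
                                    tau=p.ou_tau, variance=p.ou_var,
                                    x0=xi_ta_last[i], dtype=noise_dtype)
            xi_sc_last = xi_sc[:, -1, :].copy()
            xi_ta_last = xi_ta[:, -1].copy()

            t_global = lap * spl + c0
            next_rec = _kernels.explore_chunk(
                tuning, perm, xi_sc, xi_ta, p.mu_ta,
                r_dend, r_soma, w_pv, w_sst, w_sc,
                k_euler, g_gain, g_slope, thr,
                eta_sc_dt, eta_pv_dt, eta_sst_dt,
                norm_target, w_min, w_max,
                exc_active, pv_active, sst_active,
                rec_every, t_global, rec_i,
                rec_r_dend, rec_r_soma, rec_w_pv, rec_w_sst)
            rec_t = np.arange(chunk)[(t_global + np.arange(chunk) + 1)
                                     % rec_every == 0]
            rec_pos[rec_i:next_rec] = pos_chunk[rec_t]
            rec_lap[rec_i:next_rec] = lap
            rec_i = next_rec
        w_sc_laps[lap + 1] = w_sc

    time_ms = np.arange(1, n_rec + 1) * rec_every * dt
    records = []
    for j, i in enumerate(idx):
        records.append(TrialRecord(
            kind="exploration", params=p, master_seed=int(master_seed),
            trial_index=int(i), time_ms=time_ms,
            r_dend=rec_r_dend[:, j].copy(), r_soma=rec_r_soma[:, j].copy(),
            w_pv=rec_w_pv[:, j].copy(), w_sst=rec_w_sst[:, j].copy(),
            position=rec_pos, lap_index=rec_lap,
            lap_environments=lap_envs,
            w_sc_laps=w_sc_laps[:, j].copy(),
            permutation_b=perm_b[j].copy(), protocol=protocol))
    return records


def run_exploration_trial(protocol: ExplorationProtocol, master_seed: int,
                          trial_index: int = 0) -> TrialRecord:
    """Simulate a single exploration trial (identical to its batch slice)."""
    return run_exploration_batch(protocol, 1, master_seed,
                                 trial_indices=[trial_index])[0]


# ---------------------------------------------------------------------------
# input-output (artificial stimulation) engine
# ---------------------------------------------------------------------------

def run_io_batch(protocol: IOProtocol, n_trials: int, master_seed: int,
                 trial_indices: Sequence[int] | None = None,
                 ) -> list[TrialRecord]:
    """Simulate ``n_trials`` input-output trials vectorized across trials."""
    p = protocol.params
    n = int(n_trials)
    if n < 1:
        raise ValueError("n_trials must be >= 1")
    idx = np.arange(n) if trial_indices is None else np.asarray(trial_indices)
    conn = protocol.connectivity

    dt, k_euler = p.dt, p.euler_factor
    n_base = int(round(protocol.baseline_ms / dt))
    n_ind = int(round(protocol.induction_ms / dt))
    n_post = int(round(protocol.post_ms / dt))
    # epoch code, SC/TA stimulation flags, plasticity flag per epoch
    sc_stim = protocol.pathway in ("SC", "both")
    ta_stim = protocol.pathway in ("TA", "both")
    epochs = [
        (0, sc_stim, ta_stim, False, n_base),
        (1, True, True, True, n_ind),
        (2, sc_stim, ta_stim, False, n_post),
    ]
    total_steps = n_base + n_ind + n_post
    rec_every = max(1, int(round(protocol.record_every_ms / dt)))
    n_rec = total_steps // rec_every

    pv_rule = protocol.active_rule in ("PV_iLTD", "both") and p.eta_pv > 0.0
    sst_rule = protocol.active_rule in ("SST_iLTP", "both") and p.eta_sst > 0.0

    gens_sc = [seeding.substream(master_seed, seeding.SC_NOISE, i) for i in idx]
    gens_ta = [seeding.substream(master_seed, seeding.TA_NOISE, i) for i in idx]
    xi_sc_last = np.array([np.sqrt(p.ou_var) * float(g.standard_normal())
                           for g in gens_sc])
    xi_ta_last = np.array([np.sqrt(p.ou_var) * float(g.standard_normal())
                           for g in gens_ta])

    r_dend = np.zeros(n)
    r_soma = np.zeros(n)
    w_pv = np.full(n, p.w_pv_init, dtype=float)
    w_sst = np.full(n, p.w_sst_init, dtype=float)
    w_sc = 1.0  # fixed single-channel SC weight; excitatory plasticity off

    rec = {name: np.empty((n_rec, n)) for name in
           ("r_dend", "r_soma", "w_pv", "w_sst", "sc_input", "ta_input")}
    rec_epoch = np.empty(n_rec, dtype=int)

    if conn.mode == "constant_rate":
        raise ValueError("the input-output protocol uses connectivity-driven "
                         "interneuron rates")
    sst_a = conn.sst_alpha * conn.sst_coeffs[0]
    sst_b = conn.sst_beta * conn.sst_coeffs[1]
    sst_g = conn.sst_gamma * conn.sst_coeffs[2]
    pv_a = conn.pv_alpha * conn.pv_coeffs[0]
    pv_b = conn.pv_beta * conn.pv_coeffs[1]
    pv_g = conn.pv_gamma * conn.pv_coeffs[2]

    rec_i = 0
    t_global = 0
    chunk = 4000

    for code, sc_on, ta_on, plast_on, n_steps in epochs:
        done = 0
        while done < n_steps:
            c = min(chunk, n_steps - done)
            xi_sc = np.empty((c, n))
            xi_ta = np.empty((c, n))
            for i in range(n):
                xi_sc[:, i] = ou_trace(c, dt, gens_sc[i], tau=p.ou_tau,
                                       variance=p.ou_var, x0=xi_sc_last[i])
                xi_ta[:, i] = ou_trace(c, dt, gens_ta[i], tau=p.ou_tau,
                                       variance=p.ou_var, x0=xi_ta_last[i])
            xi_sc_last = xi_sc[-1].copy()
            xi_ta_last = xi_ta[-1].copy()
            # silent pathway: zero mean and zero noise
            sc_in = np.maximum(p.mu_sc + xi_sc, 0.0) if sc_on \
                else np.zeros((c, n))
            ta_in = np.maximum(p.mu_ta + xi_ta, 0.0) if ta_on \
                else np.zeros((c, n))

            next_rec = _kernels.io_chunk(
                sc_in, ta_in, r_dend, r_soma, w_pv, w_sst, w_sc,
                k_euler, p.g_gain, p.g_slope,
                sst_a, sst_b, sst_g, pv_a, pv_b, pv_g,
                p.eta_pv * dt, p.eta_sst * dt, p.w_min, p.w_max,
                plast_on, pv_rule, sst_rule,
                rec_every, t_global, rec_i,
                rec["r_dend"], rec["r_soma"], rec["w_pv"], rec["w_sst"])
            rec_t = np.arange(c)[(t_global + np.arange(c) + 1)
                                 % rec_every == 0]
            rec["sc_input"][rec_i:next_rec] = sc_in[rec_t]
            rec["ta_input"][rec_i:next_rec] = ta_in[rec_t]
            rec_epoch[rec_i:next_rec] = code
            rec_i = next_rec
            done += c
            t_global += c

    time_ms = np.arange(1, n_rec + 1) * rec_every * dt
    records = []
    for j, i in enumerate(idx):
        records.append(TrialRecord(
            kind="io", params=p, master_seed=int(master_seed),
            trial_index=int(i), time_ms=time_ms,
            r_dend=rec["r_dend"][:, j].copy(),
            r_soma=rec["r_soma"][:, j].copy(),
            w_pv=rec["w_pv"][:, j].copy(), w_sst=rec["w_sst"][:, j].copy(),
            protocol=protocol,
            extras={
                "sc_input": rec["sc_input"][:, j].copy(),
                "ta_input": rec["ta_input"][:, j].copy(),
                "epoch": rec_epoch,
            }))
    return records


def run_io_trial(protocol: IOProtocol, master_seed: int,
                 trial_index: int = 0) -> TrialRecord:
    """Simulate a single input-output trial."""
    return run_io_batch(protocol, 1, master_seed,
                        trial_indices=[trial_index])[0]


def run_batch(protocol, n_trials: int, master_seed: int) -> list[TrialRecord]:
    """Run a batch of independent trials of either protocol.

    Trials use disjoint RNG substreams keyed by (master_seed, trial index),
    so the collection is reproducible and trial i does not change when
    ``n_trials`` grows.
    """
    if isinstance(protocol, ExplorationProtocol):
        return run_exploration_batch(protocol, n_trials, master_seed)
    if isinstance(protocol, IOProtocol):
        return run_io_batch(protocol, n_trials, master_seed)
    raise TypeError(f"unknown protocol type {type(protocol).__name__}")
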