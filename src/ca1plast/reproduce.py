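"""End-to-end reproduction of the model's two experiments.

Runs the input-output protocol panels (pathway-specific stimulation with a
single inhibitory rule) at n = 10 seeds and the environment-switch protocol
under the four plasticity conditions at n = 100 seeds, and computes the
headline statistics: paired t-tests on somatic activity before vs after
induction, the Mann-Whitney comparisons of A-vs-A' spatial correlations
between conditions, the Friedman test across per-environment activities,
and the empirical stationary variance of the OU noise generator.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .inputs import ou_trace
from .model import ConnectivityConfig
from .params import ModelParams
from .plasticity import PlasticityConfig
from .protocols import (ExplorationProtocol, IOProtocol,
                        run_exploration_batch, run_io_batch)
from .seeding import substream, GENERIC

__all__ = ["io_panel", "exploration_condition", "ou_variance",
           "run_all_targets", "IO_PANELS"]

# the four pathway x rule panels of the input-output experiment
IO_PANELS = {
    "pv_sc": dict(conn=dict(pv_alpha=1), pathway="SC", active_rule="PV_iLTD"),
    "pv_ta": dict(conn=dict(pv_alpha=1), pathway="TA", active_rule="PV_iLTD"),
    "sst_sc": dict(conn=dict(sst_gamma=1), pathway="SC",
                   active_rule="SST_iLTP"),
    "sst_ta": dict(conn=dict(sst_gamma=1), pathway="TA",
                   active_rule="SST_iLTP"),
}


def io_panel(panel: str, seed: int, n_trials: int = 10,
             params: ModelParams | None = None) -> dict:
    """Run one input-output panel and its paired t-test.

    Returns per-trial baseline/post mean somatic activities, the paired
    two-tailed t-test on them, and the relative change.
    """
    panel_def = IO_PANELS[panel]
    conn = ConnectivityConfig(mode="connectivity_driven",
                              **panel_def["conn"])
    proto = IOProtocol(connectivity=conn, pathway=panel_def["pathway"],
                       active_rule=panel_def["active_rule"],
                       params=params or ModelParams())
    records = run_io_batch(proto, n_trials, seed)
    means = [analysis.io_epoch_means(r) for r in records]
    baseline = np.array([m["baseline"] for m in means])
    post = np.array([m["post"] for m in means])
    gc = analysis.compare_groups([baseline, post], "paired_t")
    return {
        "baseline": baseline, "post": post,
        "p_value": gc.p_value, "statistic": gc.statistic,
        "mean_change": float(post.mean() - baseline.mean()),
        "relative_change": float((post.mean() - baseline.mean())
                                 / baseline.mean()),
        "n": n_trials,
    }


def exploration_condition(iplas: str, seed: int, n_trials: int = 100,
                          params: ModelParams | None = None) -> dict:
    """Run one environment-switch condition and summarize each trial."""
    proto = ExplorationProtocol(plasticity=PlasticityConfig.from_name(iplas),
                                params=params or ModelParams())
    records = run_exploration_batch(proto, n_trials, seed)
    corrs = np.array([analysis.ab_a_prime_correlation(r) for r in records])
    means = [analysis.environment_summary(r) for r in records]
    peaks = [analysis.environment_peak_summary(r) for r in records]
    return {
        "spatial_corr": corrs,
        "mean_activity": {env: np.array([m[env] for m in means])
                          for env in ("A", "B", "A_prime")},
        "peak_activity": {env: np.array([m[env] for m in peaks])
                          for env in ("A", "B", "A_prime")},
        "n": n_trials,
    }


def ou_variance(seed: int, duration_ms: float = 500_000.0,
                dt: float = 0.5, params: ModelParams | None = None) -> float:
    """Empirical stationary variance of a single long OU trace."""
    p = params or ModelParams()
    rng = substream(seed, GENERIC, 0)
    trace = ou_trace(int(round(duration_ms / dt)), dt, rng,
                     tau=p.ou_tau, variance=p.ou_var)
    return float(np.var(trace))


def run_all_targets(seed: int, n_io: int = 10, n_exploration: int = 100,
                    verbose: bool = False) -> dict:
    """Compute every headline quantity from scratch.

    Returns a dict of short-named results; the values are the p-values /
    variances themselves plus the problem size that produced each.
    """
    def log(msg):
        if verbose:
            print(msg, flush=True)

    out: dict = {}

    log("input-output protocol: PV-iLTD, SC stimulation ...")
    pv_sc = io_panel("pv_sc", seed, n_io)
    out["io_pv_sc_pval"] = {"value": pv_sc["p_value"], "n": n_io}
    out["_io_pv_sc"] = pv_sc

    log("input-output protocol: SST-iLTP, TA stimulation ...")
    sst_ta = io_panel("sst_ta", seed, n_io)
    out["io_sst_ta_pval"] = {"value": sst_ta["p_value"], "n": n_io}
    out["_io_sst_ta"] = sst_ta

    conditions = {}
    for cond in ("on", "off", "sst-only", "pv-only"):
        log(f"environment-switch protocol: iPlas {cond} "
            f"({n_exploration} trials) ...")
        conditions[cond] = exploration_condition(cond, seed, n_exploration)
    out["_exploration"] = conditions

    gc = analysis.compare_groups(
        [conditions["on"]["spatial_corr"], conditions["off"]["spatial_corr"]],
        "mann_whitney")
    out["corr_on_vs_off_pval"] = {"value": gc.p_value, "n": n_exploration}

    act = conditions["on"]["mean_activity"]
    gf = analysis.compare_groups(
        [act["A"], act["B"], act["A_prime"]], "friedman_with_dunns")
    out["friedman_on_pval"] = {"value": gf.p_value, "n": n_exploration}
    out["_friedman_on"] = gf

    gi = analysis.compare_groups(
        [conditions["sst-only"]["spatial_corr"],
         conditions["pv-only"]["spatial_corr"]],
        "mann_whitney")
    out["corr_sst_vs_pv_pval"] = {"value": gi.p_value, "n": n_exploration}

    log("OU generator stationary variance ...")
    n_ou = 1_000_000
    out["ou_variance"] = {"value": ou_variance(seed, n_ou * 0.5, 0.5),
                          "n": n_ou}
    return out
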