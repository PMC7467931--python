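"""Two-compartment rate neuron: compartment dynamics and interneuron rates.

The pyramidal neuron is reduced to two coupled rate variables. The distal
(dendritic) compartment integrates temporoammonic (TA) excitation against
SST-interneuron inhibition,

    tau_0 dr_dend/dt = -r_dend + [TA - w_SST * r_SST]_+ ,

and the perisomatic compartment integrates dendritic drive, Schaffer-
collateral (SC) excitation and PV-interneuron inhibition through a
saturating nonlinearity,

    tau_0 dr_soma/dt = -r_soma + g(r_dend + w_SC . SC - w_PV * r_PV),
    g(x) = (4/3) [tanh(2x/5)]_+ .

Interneuron rates are either held constant (exploration protocol) or driven
by the circuit's inputs and output (input-output protocol):

    r_SST = [alpha * SC + 0.5 * beta * TA + 2 * gamma * r_soma]_+
    r_PV  = [0.2 * alpha * SC + 0.1 * beta * TA + 0.2 * gamma * r_soma]_+

with alpha/beta/gamma in {0, 1} selecting feedforward-SC, feedforward-TA and
feedback contributions. All functions accept scalars or numpy arrays and
broadcast, so a batch of trials can be stepped in one call.

Integration is forward Euler; closed-form steady states are provided for
verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "NeuronState",
    "ConnectivityConfig",
    "dendritic_nonlinearity",
    "step_dendrite",
    "step_soma",
    "interneuron_rates",
    "steady_state",
]


@dataclass
class NeuronState:
    """Instantaneous activities of the two compartments.

    ``r_dend`` stays non-negative along any trajectory started from a
    non-negative state (the dendritic drive is rectified); ``r_soma`` stays
    in [0, g_gain) because g is bounded.
    Either field may be a scalar or an array (one entry per trial).
    """

    r_dend: np.ndarray | float = 0.0
    r_soma: np.ndarray | float = 0.0

    def copy(self) -> "NeuronState":
        return NeuronState(np.copy(self.r_dend), np.copy(self.r_soma))


@dataclass(frozen=True)
class ConnectivityConfig:
    """How interneuron rates are generated.

    ``mode="constant_rate"`` fixes r_PV = r_SST = ``constant_rate_value``
    (the exploration protocol). ``mode="connectivity_driven"`` computes the
    rates from the circuit with per-interneuron feedforward/feedback toggles
    (the input-output protocol); each toggle is 0 or 1.

    ``sc_aggregate`` selects how the 40-dimensional SC input enters the
    interneuron formulas when place-tuned inputs are used: "mean" (default)
    or "sum" over input neurons. With a single artificial SC channel both
    reduce to the channel itself.
    """

    mode: str = "constant_rate"
    # SST toggles and fixed coefficients (ff-SC, ff-TA, feedback)
    sst_alpha: int = 0
    sst_beta: int = 0
    sst_gamma: int = 0
    sst_coeffs: tuple[float, float, float] = (1.0, 0.5, 2.0)
    # PV toggles and coefficients
    pv_alpha: int = 0
    pv_beta: int = 0
    pv_gamma: int = 0
    pv_coeffs: tuple[float, float, float] = (0.2, 0.1, 0.2)
    constant_rate_value: float = 1.0
    sc_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.mode not in ("constant_rate", "connectivity_driven"):
            raise ValueError(f"unknown connectivity mode {self.mode!r}")
        for name in ("sst_alpha", "sst_beta", "sst_gamma",
                     "pv_alpha", "pv_beta", "pv_gamma"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"toggle {name} must be 0 or 1")
        if self.sc_aggregate not in ("mean", "sum"):
            raise ValueError("sc_aggregate must be 'mean' or 'sum'")


def _check_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite {name}")
    return arr


def dendritic_nonlinearity(x, params: ModelParams | None = None):
    """Somatic transfer function g(x) = g_gain * [tanh(g_slope * x)]_+.

    Monotone non-decreasing, zero for x <= 0, bounded above by g_gain
    (4/3 at defaults). Raises on non-finite input.
    """
    p = params or ModelParams()
    arr = _check_finite(x, "drive")
    out = p.g_gain * np.maximum(np.tanh(p.g_slope * arr), 0.0)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def step_dendrite(r_dend, ta_input, w_sst, r_sst, params: ModelParams):
    """One forward-Euler step of the dendritic compartment.

    r <- r + (dt/tau_0) * (-r + [TA - w_SST * r_SST]_+)

    The result is non-negative whenever ``r_dend >= 0`` and dt <= tau_0
    (validated at parameter construction).
    """
    drive = np.maximum(np.asarray(ta_input, dtype=float)
                       - np.asarray(w_sst, dtype=float) * r_sst, 0.0)
    r = np.asarray(r_dend, dtype=float)
    return r + params.euler_factor * (drive - r)


def step_soma(r_soma, r_dend, sc_drive, w_pv, r_pv, params: ModelParams):
    """One forward-Euler step of the somatic compartment.

    ``sc_drive`` is the already-weighted total SC drive (w_SC . SC_input,
    a dot product over input neurons in place-field mode).
    """
    total = _check_finite(
        np.asarray(r_dend, dtype=float) + np.asarray(sc_drive, dtype=float)
        - np.asarray(w_pv, dtype=float) * r_pv,
        "somatic drive",
    )
    g = params.g_gain * np.maximum(np.tanh(params.g_slope * total), 0.0)
    r = np.asarray(r_soma, dtype=float)
    return r + params.euler_factor * (g - r)


def interneuron_rates(sc_agg, ta_input, r_soma, conn: ConnectivityConfig):
    """PV and SST firing rates for the current step.

    ``sc_agg`` is the aggregate instantaneous SC input (mean or sum over
    input neurons per ``conn.sc_aggregate``; the caller aggregates).
    Connectivity-driven rates are rectified at zero since the noisy linear
    combinations can go negative while firing rates cannot.

    Returns ``(r_pv, r_sst)``.
    """
    if conn.mode == "constant_rate":
        v = conn.constant_rate_value
        shape = np.shape(sc_agg)
        if shape:
            return np.full(shape, v), np.full(shape, v)
        return v, v
    sc = _check_finite(sc_agg, "SC aggregate")
    ta = _check_finite(ta_input, "TA input")
    rs = _check_finite(r_soma, "somatic rate")
    c_sst = conn.sst_coeffs
    c_pv = conn.pv_coeffs
    r_sst = (conn.sst_alpha * c_sst[0] * sc
             + conn.sst_beta * c_sst[1] * ta
             + conn.sst_gamma * c_sst[2] * rs)
    r_pv = (conn.pv_alpha * c_pv[0] * sc
            + conn.pv_beta * c_pv[1] * ta
            + conn.pv_gamma * c_pv[2] * rs)
    return np.maximum(r_pv, 0.0), np.maximum(r_sst, 0.0)


def steady_state(ta_input, sc_drive, w_sst, r_sst, w_pv, r_pv,
                 params: ModelParams | None = None):
    """Closed-form fixed point of both compartments under constant inputs.

    With all rates and weights held fixed (no noise, no plasticity) the two
    ODEs relax exponentially to

        r_dend* = [TA - w_SST * r_SST]_+
        r_soma* = g(r_dend* + sc_drive - w_PV * r_PV)

    Used as an independent oracle for the Euler integrator.
    """
    p = params or ModelParams()
    r_dend = np.maximum(np.asarray(ta_input, dtype=float)
                        - np.asarray(w_sst, dtype=float) * r_sst, 0.0)
    r_soma = p.g_gain * np.maximum(
        np.tanh(p.g_slope * (r_dend + sc_drive
                             - np.asarray(w_pv, dtype=float) * r_pv)), 0.0)
    return r_dend, r_soma
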