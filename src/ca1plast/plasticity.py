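"""Plasticity rules: Hebbian SC plasticity, PV-iLTD and SST-iLTP.

Excitatory SC weights follow a thresholded Hebbian rule whose postsynaptic
term is the product of dendritic and somatic activity,

    dw_j/dt = eta_SC * (r_dend * r_soma - 0.1)_+ * r_j ,

stabilized by subtractive normalization after every update: the mean weight
is subtracted, a constant is added (so mean(w) returns to ``norm_target``)
and negative weights are rectified to zero. Inhibitory weights follow
rate-based Hebbian rules of opposite sign,

    dw_PV/dt  = -eta_PV  * r_PV  * r_soma      (iLTD)
    dw_SST/dt = +eta_SST * r_SST * r_soma      (iLTP),

clipped to [w_min, w_max]. All update functions broadcast over a leading
trial axis. Disabling a rule is exactly equivalent to a zero learning rate
(for the excitatory rule this includes skipping normalization, which exists
only to stabilize learning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "SynapticState",
    "PlasticityConfig",
    "exc_hebbian_step",
    "normalize_exc_weights",
    "pv_iltd_step",
    "sst_iltp_step",
]


@dataclass
class SynapticState:
    """Excitatory weight vector plus scalar inhibitory weights.

    ``w_sc`` is a length-N_SC vector (or (n_trials, N_SC) batch, or a scalar
    in single-channel mode); ``w_pv`` and ``w_sst`` are scalars (or (n_trials,)
    arrays) bounded in [w_min, w_max].
    """

    w_sc: np.ndarray | float
    w_pv: np.ndarray | float = 1.0
    w_sst: np.ndarray | float = 1.0

    def copy(self) -> "SynapticState":
        return SynapticState(np.copy(self.w_sc), np.copy(self.w_pv),
                             np.copy(self.w_sst))


@dataclass(frozen=True)
class PlasticityConfig:
    """Which rules are active. Off is bit-identical to a zero learning rate."""

    exc_on: bool = True
    pv_on: bool = True
    sst_on: bool = True

    @classmethod
    def from_name(cls, name: str) -> "PlasticityConfig":
        """'on', 'off', 'pv-only' or 'sst-only' (inhibitory rules; the
        excitatory rule is controlled separately by the protocol)."""
        table = {
            "on": (True, True),
            "off": (False, False),
            "pv-only": (True, False),
            "sst-only": (False, True),
        }
        if name not in table:
            raise ValueError(f"unknown iPlas condition {name!r}")
        pv, sst = table[name]
        return cls(exc_on=True, pv_on=pv, sst_on=sst)


def exc_hebbian_step(w_sc, r_dend, r_soma, r_inputs, params: ModelParams,
                     dt: float | None = None, *, normalize: bool = True):
    """One Euler step of the Hebbian SC rule, then normalization.

    ``r_inputs`` has shape (..., N_SC) matching ``w_sc``. The postsynaptic
    factor (r_dend * r_soma - hebb_threshold) is rectified, so anti-Hebbian
    depression never occurs; stability comes from the subtractive
    normalization applied after the additive update.
    """
    dt = params.dt if dt is None else dt
    w = np.asarray(w_sc, dtype=float)
    if params.eta_sc == 0.0:
        return w
    post = np.maximum(
        np.asarray(r_dend, float) * np.asarray(r_soma, float)
        - params.hebb_threshold, 0.0)
    w = w + params.eta_sc * dt * np.expand_dims(post, -1) \
        * np.asarray(r_inputs, float)
    if normalize:
        w = normalize_exc_weights(w, params)
    return w


def normalize_exc_weights(w_sc, params: ModelParams) -> np.ndarray:
    """Subtractive normalization: w <- [w - mean(w) + norm_target]_+.

    When nothing is clipped the mean equals ``norm_target`` exactly; when
    clipping occurs the mean ends up above it by the clipped mass / N.
    """
    w = np.asarray(w_sc, dtype=float)
    if w.shape[-1:] == (0,):
        raise ValueError("empty weight vector")
    w = w - w.mean(axis=-1, keepdims=True) + params.norm_target
    return np.maximum(w, 0.0)


def pv_iltd_step(w_pv, r_pv, r_soma, params: ModelParams,
                 dt: float | None = None):
    """PV-iLTD: coactivation depresses; w_PV never increases.

    w_PV <- clip(w_PV - eta_PV * r_PV * r_soma * dt, w_min, w_max)
    """
    dt = params.dt if dt is None else dt
    w = np.asarray(w_pv, dtype=float) \
        - params.eta_pv * dt * np.asarray(r_pv, float) * np.asarray(r_soma, float)
    out = np.clip(w, params.w_min, params.w_max)
    return float(out) if np.ndim(out) == 0 else out


def sst_iltp_step(w_sst, r_sst, r_soma, params: ModelParams,
                  dt: float | None = None):
    """SST-iLTP: coactivation potentiates; w_SST never decreases.

    w_SST <- clip(w_SST + eta_SST * r_SST * r_soma * dt, w_min, w_max)
    """
    dt = params.dt if dt is None else dt
    w = np.asarray(w_sst, dtype=float) \
        + params.eta_sst * dt * np.asarray(r_sst, float) * np.asarray(r_soma, float)
    out = np.clip(w, params.w_min, params.w_max)
    return float(out) if np.ndim(out) == 0 else out
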