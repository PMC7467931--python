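"""Model parameters for the two-compartment CA1 circuit model.

All temporal quantities are in milliseconds; track geometry is in arbitrary
track units (the annular track has length ``track_length``); rates and
synaptic weights are dimensionless, as in the underlying rate model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the neuron dynamics, inputs and plasticity rules.

    Defaults are the published parameter set of the model: a membrane-like
    time constant ``tau_0`` = 1.25 ms shared by both compartments, a somatic
    nonlinearity g(x) = (4/3)[tanh(2x/5)]_+, 40 Schaffer-collateral (SC)
    inputs with Gaussian place tuning (amplitude 6.0, width 2.0) on an
    annular track of length 50 traversed at speed 2.5e-3 track-units/ms,
    temporoammonic (TA) drive of mean 2, Ornstein-Uhlenbeck input noise
    (tau = 50 ms, stationary variance 0.5), Hebbian excitatory plasticity
    with learning rate 2.5e-5 /ms and postsynaptic threshold 0.1, and
    inhibitory plasticity rates of 2.0e-4 /ms with weights bounded in
    [0, 10].

    Attributes
    ----------
    tau_0
        Time constant of both compartments' rate dynamics (ms).
    dt
        Forward-Euler integration step (ms). Must satisfy 0 < dt <= tau_0.
    g_gain, g_slope
        Amplitude (4/3) and argument scale (2/5) of the somatic
        nonlinearity g(x) = g_gain * [tanh(g_slope * x)]_+.
    mu_ta, mu_sc
        Mean TA drive and mean artificial SC drive used during direct
        pathway stimulation (rate units).
    hebb_threshold
        Threshold subtracted from the dendrite-soma activity product in the
        excitatory Hebbian rule.
    eta_sc, eta_pv, eta_sst
        Learning rates (1/ms) of the SC Hebbian rule, PV-iLTD and SST-iLTP.
    w_min, w_max
        Hard bounds on the inhibitory weights w_PV and w_SST.
    norm_target
        Post-normalization mean of the SC weight vector. The subtractive
        normalization step sets mean(w_SC) to this value before rectification.
        Default 2/N_SC = 0.05, i.e. the summed SC weight is held at 2.
    w_pv_init, w_sst_init
        Initial inhibitory weights (not prescribed by the model definition;
        mid-range default 1.0 leaves room for both iLTD and iLTP).
    n_sc
        Number of SC input neurons.
    a_sc, sigma_sc
        Amplitude and width of the presynaptic Gaussian place fields.
    track_length, speed
        Annular track length L (track units) and running speed v
        (track units / ms). One lap takes L / v = 20,000 ms at defaults.
    ou_tau, ou_var
        Time constant (ms) and stationary variance of the OU input noise.
    """

    tau_0: float = 1.25
    dt: float = 0.5
    g_gain: float = 4.0 / 3.0
    g_slope: float = 2.0 / 5.0
    mu_ta: float = 2.0
    mu_sc: float = 2.0
    hebb_threshold: float = 0.1
    eta_sc: float = 2.5e-5
    eta_pv: float = 2.0e-4
    eta_sst: float = 2.0e-4
    w_min: float = 0.0
    w_max: float = 10.0
    norm_target: float = 0.05
    w_pv_init: float = 1.0
    w_sst_init: float = 1.0
    n_sc: int = 40
    a_sc: float = 6.0
    sigma_sc: float = 2.0
    track_length: float = 50.0
    speed: float = 2.5e-3
    ou_tau: float = 50.0
    ou_var: float = 0.5

    def __post_init__(self) -> None:
        if not self.tau_0 > 0:
            raise ValueError(f"tau_0 must be positive, got {self.tau_0}")
        if not 0 < self.dt <= self.tau_0:
            raise ValueError(
                f"dt must satisfy 0 < dt <= tau_0 (Euler stability); "
                f"got dt={self.dt}, tau_0={self.tau_0}"
            )
        if self.w_min > self.w_max:
            raise ValueError(f"w_min={self.w_min} exceeds w_max={self.w_max}")
        for name in ("eta_sc", "eta_pv", "eta_sst", "ou_tau", "ou_var",
                     "a_sc", "sigma_sc", "track_length", "hebb_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ou_tau <= 0:
            raise ValueError("ou_tau must be positive")
        if self.n_sc < 2:
            raise ValueError("n_sc must be at least 2")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def euler_factor(self) -> float:
        """dt / tau_0, the per-step relaxation fraction."""
        return self.dt / self.tau_0

    @property
    def lap_duration(self) -> float:
        """Simulated time for one full lap, L / v (ms)."""
        return self.track_length / self.speed

    @property
    def steps_per_lap(self) -> int:
        return int(round(self.lap_duration / self.dt))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))
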