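"""Synthetic inputs: OU noise, track kinematics and place-tuned SC rates.

Each Schaffer-collateral (SC) input neuron is tuned to a position p0 on an
annular track of length L with a Gaussian tuning curve,

    SC_j(p) = A_SC * exp(-d(p, p0_j)^2 / (2 sigma_SC^2)) + xi_j ,

where d is the circular distance along the track and xi_j an independent
Ornstein-Uhlenbeck (OU) process (tau = 50 ms, mean 0, stationary variance
0.5). The temporoammonic (TA) pathway is spatially uniform, mu_TA + xi_TA,
with its own OU stream; during artificial stimulation SC inputs are likewise
untuned, mu_SC + xi_SC. Noisy rates are rectified at zero before entering
the dynamics (firing rates are non-negative; negative presynaptic rates
would invert the plasticity signs) — the rectification can be disabled.

The OU process is discretized exactly (not Euler-Maruyama):

    x <- m + (x - m) e^{-dt/tau} + sqrt(var (1 - e^{-2 dt/tau})) z ,

so samples follow the stationary law at every step when initialized from it;
``ou_trace`` generates long traces with the same recursion via a linear
filter along time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .params import ModelParams

__all__ = [
    "OUProcess",
    "EnvironmentTrack",
    "ou_step",
    "ou_trace",
    "advance_position",
    "circular_distance",
    "tuning_curves",
    "sc_place_rates",
    "ta_input",
    "constant_sc_input",
    "permute_inputs",
    "make_track",
]


@dataclass
class OUProcess:
    """State of one (or a vector of) Ornstein-Uhlenbeck noise stream(s).

    ``value`` may be a scalar or an array of independent streams sharing
    tau/mean/variance. ``variance`` is the stationary variance.
    """

    value: np.ndarray | float = 0.0
    tau: float = 50.0
    mean: float = 0.0
    variance: float = 0.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("OU time constant must be positive")
        if self.variance < 0:
            raise ValueError("OU variance must be non-negative")

    @classmethod
    def stationary(cls, rng: np.random.Generator, shape=(), *,
                   tau: float = 50.0, mean: float = 0.0,
                   variance: float = 0.5) -> "OUProcess":
        """Initialize from the stationary distribution (no burn-in needed)."""
        val = mean + np.sqrt(variance) * rng.standard_normal(shape)
        if shape == ():
            val = float(val)
        return cls(value=val, tau=tau, mean=mean, variance=variance)


def ou_step(proc: OUProcess, dt: float, rng: np.random.Generator):
    """Advance the OU state by dt using the exact discretization.

    Mutates and returns ``proc.value``. The update is distribution-exact:
    if the current value is stationary the next one is too, for any dt.
    """
    a = np.exp(-dt / proc.tau)
    b = np.sqrt(proc.variance * (1.0 - a * a))
    z = rng.standard_normal(np.shape(proc.value))
    proc.value = proc.mean + (np.asarray(proc.value) - proc.mean) * a + b * z
    if np.ndim(proc.value) == 0:
        proc.value = float(proc.value)
    return proc.value


def ou_trace(n_steps: int, dt: float, rng: np.random.Generator, *,
             tau: float = 50.0, mean: float = 0.0, variance: float = 0.5,
             n_streams: int | None = None, x0=None,
             dtype=np.float64) -> np.ndarray:
    """Generate an OU trace of ``n_steps`` samples after the initial value.

    Returns shape (n_steps,) or (n_steps, n_streams). The recursion
    x_t = a x_{t-1} + b z_t (in mean-deviation coordinates) is evaluated
    with a first-order linear filter along time, which is algebraically
    identical to iterating :func:`ou_step` with the same normal draws.
    ``x0`` defaults to a fresh stationary draw; the returned trace does not
    include x0 itself. ``dtype`` may be float32 for long batch simulations
    (the AR(1) recursion is contractive, so single precision does not
    accumulate error).
    """
    dtype = np.dtype(dtype)
    a = dtype.type(np.exp(-dt / tau))
    b = dtype.type(np.sqrt(variance * (1.0 - float(a) * float(a))))
    shape = (n_steps,) if n_streams is None else (n_steps, n_streams)
    z = rng.standard_normal(shape, dtype=dtype)
    if x0 is None:
        x0 = mean + np.sqrt(variance) * rng.standard_normal(shape[1:],
                                                            dtype=dtype)
    dev0 = np.asarray(x0, dtype=dtype) - dtype.type(mean)
    zi = np.broadcast_to(a * dev0, (1,) + shape[1:]).astype(dtype)
    coef_b = np.array([b], dtype=dtype)
    coef_a = np.array([1.0, -a], dtype=dtype)
    trace, _ = lfilter(coef_b, coef_a, z, axis=0, zi=zi)
    return trace + dtype.type(mean)


@dataclass
class EnvironmentTrack:
    """Annular track geometry, animal position and SC input identities.

    ``centers`` holds the N_SC place-field centers, evenly spaced over
    [0, L). ``permutation`` maps input-neuron index -> center index; the
    identity permutation defines environment A, and an environment switch
    shuffles it ("randomly shuffling the identity of the SC inputs").
    """

    length: float = 50.0
    speed: float = 2.5e-3
    position: float = 0.0
    lap: int = 0
    centers: np.ndarray = field(default_factory=lambda: np.arange(40) * 1.25)
    permutation: np.ndarray = field(default_factory=lambda: np.arange(40))
    environment_label: str = "A"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.permutation = np.asarray(self.permutation, dtype=int)
        if not 0 <= self.position < self.length:
            raise ValueError("position must lie in [0, L)")
        if sorted(self.permutation) != list(range(len(self.centers))):
            raise ValueError("permutation must be a bijection on input indices")

    @property
    def assigned_centers(self) -> np.ndarray:
        """Center of each input neuron under the current permutation."""
        return self.centers[self.permutation]


def make_track(params: ModelParams, label: str = "A") -> EnvironmentTrack:
    """Track with N_SC evenly spaced centers j * L / N_SC spanning [0, L)."""
    centers = np.arange(params.n_sc) * params.track_length / params.n_sc
    return EnvironmentTrack(
        length=params.track_length, speed=params.speed, centers=centers,
        permutation=np.arange(params.n_sc), environment_label=label)


def advance_position(track: EnvironmentTrack, dt: float) -> float:
    """Move the animal by v*dt along the annulus; wraps increment the lap."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = track.position + track.speed * dt
    if p >= track.length:
        track.lap += int(p // track.length)
        p = p % track.length
    track.position = p
    return p


def circular_distance(p, p0, length: float):
    """Shortest distance between positions along the annulus, in [0, L/2]."""
    delta = np.abs(np.asarray(p, dtype=float) - np.asarray(p0, dtype=float))
    return np.minimum(delta, length - delta)


def tuning_curves(positions, centers, params: ModelParams) -> np.ndarray:
    """Noise-free Gaussian place-field rates A_SC exp(-d^2 / 2 sigma^2).

    ``positions`` (T,) against ``centers`` (N,) -> (T, N); scalars allowed.
    """
    d = circular_distance(np.expand_dims(np.asarray(positions, float), -1),
                          centers, params.track_length)
    return params.a_sc * np.exp(-d * d / (2.0 * params.sigma_sc ** 2))


def sc_place_rates(track: EnvironmentTrack, noise, params: ModelParams,
                   *, rectify: bool = True) -> np.ndarray:
    """Instantaneous rates of all SC input neurons at the current position.

    ``noise`` is an :class:`OUProcess` with vector value, or a plain array
    of per-neuron noise values (one independent stream per input neuron).
    """
    xi = noise.value if isinstance(noise, OUProcess) else np.asarray(noise)
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (len(track.permutation),):
        raise ValueError(
            f"noise vector length {xi.shape} does not match "
            f"{len(track.permutation)} SC inputs")
    rates = tuning_curves(track.position, track.assigned_centers, params) + xi
    return np.maximum(rates, 0.0) if rectify else rates


def ta_input(noise, mu: float = 2.0, *, rectify: bool = True):
    """Temporoammonic drive mu_TA + xi_TA, rectified at zero."""
    xi = noise.value if isinstance(noise, OUProcess) else noise
    out = mu + np.asarray(xi, dtype=float)
    out = np.maximum(out, 0.0) if rectify else out
    return float(out) if np.ndim(out) == 0 else out


def constant_sc_input(noise, mu: float = 2.0, *, rectify: bool = True):
    """Artificial (untuned) SC stimulation mu_SC + xi_SC."""
    return ta_input(noise, mu, rectify=rectify)


def permute_inputs(track: EnvironmentTrack, permutation=None, *,
                   rng: np.random.Generator | None = None,
                   label: str | None = None) -> EnvironmentTrack:
    """Reassign input identities, composing with the current permutation.

    Pass an explicit ``permutation`` (a bijection on input indices) or an
    ``rng`` to draw a uniform random one. Applying a permutation and then
    its inverse (``np.argsort``) restores the original assignment exactly.
    Returns the (mutated) track.
    """
    n = len(track.permutation)
    if permutation is None:
        if rng is None:
            raise ValueError("provide a permutation or an rng")
        permutation = rng.permutation(n)
    permutation = np.asarray(permutation, dtype=int)
    if sorted(permutation) != list(range(n)):
        raise ValueError("mapping is not a bijection on input indices")
    track.permutation = track.permutation[permutation]
    if label is not None:
        track.environment_label = label
    return track
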