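# Methods

## Model

A single CA1 pyramidal neuron is reduced to two rate variables coupled in
series. The distal (dendritic) compartment integrates temporoammonic (TA)
excitation against inhibition from SST-expressing interneurons; the
perisomatic compartment integrates the dendritic output, Schaffer-
collateral (SC) excitation and inhibition from PV-expressing interneurons
through a saturating nonlinearity:

    tau_0 dr_dend/dt = -r_dend + [TA - w_SST r_SST]_+
    tau_0 dr_soma/dt = -r_soma + g(r_dend + w_SC . SC - w_PV r_PV)
    g(x) = (4/3) [tanh(2x/5)]_+

Both compartments share the time constant tau_0 = 1.25 ms. Activities are
dimensionless rates; r_dend >= 0 by construction and r_soma in [0, 4/3).
The model is deliberately minimal: no conductances, no spike timing, no
dendritic cable structure. The plasticity rules are rate-based abstractions
of pairing-induced inhibitory plasticity; they stand in for processes that
in vivo are organized by theta-timescale activity.

Interneuron rates are either constant, r_PV = r_SST = 1 (the exploration
protocol), or driven by the circuit with feedforward/feedback toggles
alpha, beta, gamma in {0, 1} (the stimulation protocol):

    r_SST = [alpha SC + 0.5 beta TA + 2 gamma r_soma]_+
    r_PV  = [0.2 alpha SC + 0.1 beta TA + 0.2 gamma r_soma]_+

Toggles are exposed per interneuron type (a superset of any single
experimental configuration), and the rates are computed from the noisy instantaneous
inputs of the current step and the somatic rate of the previous step, then
rectified at zero — noise can drive the linear combinations negative and
firing rates cannot be. When the SC input is the 40-dimensional
place-tuned vector, the scalar "SC" entering these formulas is its mean
across input neurons (configurable to the sum); in the single-channel
stimulation setting both reduce to the channel itself.

## Inputs

The simulated animal runs at constant speed v = 2.5e-3 track-units/ms
around an annular track of length L = 50 (lap duration L/v = 20,000 ms).
N_SC = 40 SC input neurons carry Gaussian place fields of amplitude
A_SC = 6.0 and width sigma_SC = 2.0, centered at j L / N_SC so they tile
the whole track; distance is measured circularly. TA input is spatially
uniform with mean mu_TA = 2. During artificial stimulation SC input is
likewise untuned with mean mu_SC = 2. Every input carries independent
Ornstein-Uhlenbeck noise with time constant 50 ms, mean 0 and stationary
variance 0.5 (one stream per SC input neuron, one for TA).

The OU update is the exact discretization
x <- m + (x - m) e^{-dt/tau} + sqrt(var (1 - e^{-2 dt/tau})) z, initialized
from the stationary law, so there is no burn-in and no discretization bias
at any dt; "variance" is the stationary variance, the only reading that
makes the parameter well-posed. Noisy input rates are rectified at zero
before entering the dynamics (negative presynaptic rates would invert the
plasticity signs); the rectification is toggleable. Position is continuous
— spatial bins exist only in the analysis.

## Plasticity

SC weights follow a thresholded Hebbian rule whose postsynaptic factor is
the product of dendritic and somatic activity,
dw_j/dt = eta_SC (r_dend r_soma - 0.1)_+ r_j, which captures the
requirement of coincident distal (TA-driven) and proximal (SC-driven)
activation for place-field formation. The rule is unstable on its own and
is stabilized by subtractive normalization after every update: subtract
the mean weight, add a constant, rectify negatives to zero.

The normalization constant deserves a note. Setting the post-update mean
weight to 2 would give a total SC drive of roughly 2 x 24 = 48 at every
position (24 being the summed tuning-curve value), deep in the saturation
of g — the neuron would fire at ceiling everywhere and no spatial tuning
could form or be expressed. The package therefore holds the *summed* SC
weight at 2 by default (`norm_target = 2 / N_SC = 0.05` per weight), which
keeps the background drive in the responsive range of g while the seeded
and learned weights produce a clear field. This is numerically equivalent
to a mean of 2 combined with averaging (rather than summing) the weighted
SC drive. The literal mean-2 reading remains reachable via
`norm_target: 2.0` in the configuration.

Normalization is applied together with the Hebbian update and only then:
a disabled excitatory rule (or eta_SC = 0) performs no normalization
either, so "rule off" is bit-identical to a zero learning rate — an
invariant the tests check exactly.

Inhibitory weights follow sign-definite rate rules, dw_PV/dt =
-eta_PV r_PV r_soma and dw_SST/dt = +eta_SST r_SST r_soma, hard-clipped to
[w_min, w_max] = [0, 10]. Initial inhibitory weights are not part of the
model definition; the default 1.0 sits far from both bounds so either rule
has room to act, and is configurable.

## Parameters

| symbol | default | meaning |
|---|---|---|
| tau_0 | 1.25 ms | compartment time constant |
| dt | 0.5 ms | Euler step (must satisfy dt <= tau_0) |
| mu_TA, mu_SC | 2 | mean uniform drives |
| eta_SC | 2.5e-5 /ms | SC Hebbian learning rate |
| eta_PV, eta_SST | 2.0e-4 /ms | inhibitory learning rates |
| w_min, w_max | 0, 10 | inhibitory weight bounds |
| norm_target | 0.05 | post-normalization mean SC weight (sum 2) |
| N_SC | 40 | SC input neurons |
| A_SC, sigma_SC | 6.0, 2.0 | place-field amplitude and width |
| L, v | 50, 2.5e-3 | track length, speed |
| ou_tau, ou_var | 50 ms, 0.5 | input-noise time constant and variance |

Integration is forward Euler for the compartments and all weights, the
simplest scheme consistent with a rate model; dt = 0.5 ms (tau_0 / 2.5) is
not part of the model definition and is configurable. Trajectories at dt
and dt/10 agree to O(dt), and simulated fixed points match the closed-form
steady states to 1e-3 (tested). Per step the update order is: inputs;
interneuron rates (from the previous step's somatic rate, avoiding an
algebraic loop in the feedback terms); dendrite; soma; plasticity.

## Protocols

**Input-output (stimulation) protocol.** A baseline epoch (10 s) measures
mean somatic activity and input-output correlations with only the selected
pathway stimulated (the silent pathway contributes zero mean and zero
noise); an induction epoch (60 s) activates both pathways and the selected
inhibitory rule(s); a post epoch repeats the baseline measurement.
Excitatory plasticity is off throughout and the single-channel SC weight
is fixed at 1. The pathway-specific panels use the connectivity that
carries each rule's effect (PV driven feedforward by SC, alpha = 1, for
the PV-iLTD panels; SST driven by somatic feedback, gamma = 1, for the
SST-iLTP panels), and the combined correlation experiment uses their
union — with stronger feedforward SST configurations the dendrite is
already silenced at baseline and there is no TA correlation left to
reprioritise. Epoch durations are design choices, not model constants:
60 s moves an inhibitory weight by order eta * r^2 * t ~ 1-10 at the
default learning rates, enough for the weight to traverse its range, while
10 s measurement epochs give epoch-mean standard errors well below the
effect sizes. "n = 10" trials are independent random seeds, the only
source of variability.

**Environment-switch protocol.** Laps A x10, B x15, A' x10. Initial SC
weights are lognormal(0, 0.1) draws scaled by 0.1, with one random
circularly-adjacent pair set to 0.6 to seed a weak spatial structure.
The switch to B shuffles the input-identity permutation uniformly at
random; the return to A' restores the identity exactly. Interneuron rates
are constant (1); excitatory and all enabled inhibitory rules run from the
first lap (no separate induction phase). Ablations toggle PV-iLTD /
SST-iLTP individually.

## Analysis

Spatial maps are occupancy-weighted means of somatic activity in 50 bins
(one per track unit). Place-field stability is the Pearson correlation
between the mean map of the last two A laps and the first two A' laps —
early A' laps isolate retention from re-learning. Per-environment activity
is summarized two ways:

- `environment_summary`: time-averaged somatic activity per environment
  (excluding the first A lap as the formation transient). This is the
  summary used for the Friedman test across A, B, A'.
- `environment_peak_summary`: the spatial-map peak per environment, i.e.
  the amplitude of the cell's place field. The track average is blind to
  whether drive is concentrated or scattered (with a concave somatic
  nonlinearity, scattering a fixed drive mass can only raise the spatial
  mean), so field dispersal in a novel environment shows up in the peak,
  which drops in B and recovers in A' when both inhibitory rules are
  active, and stays flat without them.

Group comparisons use the two-tailed paired t-test (stimulation
experiment), the two-sided Mann-Whitney U test (exact for small tie-free
samples, normal approximation with tie correction otherwise) and the
Friedman test with Dunn's multiple-comparison post hoc (implemented
in-package: within-block ranks, pairwise z statistics, Bonferroni
adjustment). Degenerate inputs (constant maps, zero-variance differences,
all-tied samples) yield flagged results with p = 1 rather than exceptions,
and undefined correlations are recorded as missing. "Unchanged" outcomes
are verified as near-zero effect sizes (|change| < 5% of baseline) rather
than as non-rejection of a null hypothesis, which at n = 10 would be a
coin flip under the null.

## Reproducibility and scale

A master seed feeds named substreams (weight initialization, per-trial SC
and TA noise, permutation) through `SeedSequence` spawn keys, so any trial
is reproducible in isolation and bit-identical to its slice of a batch of
any size. Batches are simulated with all trials advancing in lockstep
through compiled (numba) kernels; OU noise is pre-generated per trial in
float32 (the AR(1) recursion is contractive, so single precision does not
accumulate error) while all state variables remain float64. The
full-scale environment-switch batch — 100 trials x 35 laps x 40,000 Euler
steps per lap — runs in about 2.5 minutes per condition on one CPU.

## Known limitations

- 1-D annular track at constant speed; no 2-D arenas, variable running or
  theta-modulated inputs.
- A single pyramidal neuron; no recurrence, no population interactions, no
  replay/offline dynamics.
- The synthetic inputs capture the assumed statistical structure (Gaussian
  tuning, OU noise, identity shuffling) but none of the irregularities of
  real place-field data — passing tests demonstrate internal consistency
  of the model, not agreement with recordings.
- The exact induction durations of the stimulation experiment and the
  place-field detection criterion are not part of the model definition;
  both are configurable and the defaults are reported with every result.
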