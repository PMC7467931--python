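# ca1plast

Simulation pipeline for **interneuron-specific inhibitory plasticity in a
CA1 microcircuit model**: a rate-based, two-compartment pyramidal neuron
receiving temporoammonic (TA) input onto its distal dendrite (gated by SST
interneurons) and Schaffer-collateral (SC) input onto its perisomatic
compartment (gated by PV interneurons). Inhibitory synapses are plastic
with opposite signs — coactivation depresses PV synapses (PV-iLTD) and
potentiates SST synapses (SST-iLTP) — while SC synapses follow a
normalized Hebbian rule gated by the product of dendritic and somatic
activity.

The package is for computational neuroscientists who want to reproduce,
probe or extend the two in-silico experiments this circuit motif supports:

1. **Pathway reprioritisation** — how inducing PV-iLTD or SST-iLTP shifts
   the neuron's responsiveness from TA- toward SC-driven activity under
   artificial stimulation of either pathway.
2. **Place-field stability** — how inhibitory plasticity protects a place
   field formed in environment A while the animal explores a novel
   environment B and returns (A → B → A′), including ablations of either
   rule.

## Model

Dendritic and somatic activities evolve as

```
tau_0 dr_dend/dt = -r_dend + [TA - w_SST * r_SST]_+
tau_0 dr_soma/dt = -r_soma + g(r_dend + w_SC . SC - w_PV * r_PV)
g(x) = (4/3) [tanh(2x/5)]_+
```

with plasticity

```
dw_ij/dt  =  eta_SC  * (r_dend * r_soma - 0.1)_+ * r_j   (+ subtractive normalization)
dw_PV/dt  = -eta_PV  * r_PV  * r_soma                    (iLTD, clipped to [0, 10])
dw_SST/dt = +eta_SST * r_SST * r_soma                    (iLTP, clipped to [0, 10])
```

SC inputs are Gaussian place fields (amplitude 6.0, width 2.0) tiling an
annular track of length 50 traversed at 2.5e-3 track-units/ms; every input
carries independent Ornstein–Uhlenbeck noise (tau = 50 ms, variance 0.5).
Environment switches shuffle the identity of the SC inputs. See
`docs/methods.md` for assumptions, parameter table and numerical choices.

## Worked example

```python
import numpy as np
import ca1plast as cp

proto = cp.ExplorationProtocol(plasticity=cp.PlasticityConfig.from_name("on"))
records = cp.run_exploration_batch(proto, n_trials=10, master_seed=42)
corrs = [cp.ab_a_prime_correlation(r) for r in records]
peaks = [cp.environment_peak_summary(r) for r in records]
print(f"A-vs-A' spatial correlation: {np.mean(corrs):.3f}")
print(f"field amplitude A: {np.mean([p['A'] for p in peaks]):.3f}  "
      f"B: {np.mean([p['B'] for p in peaks]):.3f}  "
      f"A': {np.mean([p['A_prime'] for p in peaks]):.3f}")
```

prints

```
A-vs-A' spatial correlation: 0.986
field amplitude A: 1.309  B: 1.219  A': 1.308
```

i.e. with both inhibitory rules active the place field formed in A is
nearly perfectly retained after exposure to B (bin-wise Pearson r ≈ 0.99
between the late-A and early-A′ spatial maps), while the field amplitude
dips in the novel environment and recovers on return. Running the same
batch with `PlasticityConfig.from_name("off")` drops the spatial
correlation to ≈ 0.

The same workflows are available from the shell:

```bash
ca1plast simulate-environments --trials 10 --seed 42 --iplas on --out results/envs
ca1plast simulate-io --pathway sc --iplas pv-only --trials 10 --seed 1 --out results/io
ca1plast analyze results/envs
ca1plast reproduce-all --seed 1 --out results/reproduce
```

Each run directory contains per-trial trace CSVs, a per-trial summary
table, batch-level statistical tests, the resolved configuration and a
seed manifest sufficient to regenerate any single trial.

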