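# dynattractor

A simulator for dynamic memory representations in recurrent rate networks.
Classic attractor networks store memories as fixed cell assemblies; real
memories form, strengthen with repeated experience, and fade when
neglected. `dynattractor` models this by combining, in one network of N
rate neurons:

- an **online Hebbian (covariance) rule**
  τ_w dw_ij/dt = η (r_i − ⟨r_i⟩)(r_j − ⟨r_j⟩) − β w_ij with hard bounds
  [w_min, w_max], where ⟨r⟩ is a box-window running average of length T_LR
  and β gives exponential **forgetting** with time constant τ_w/β;
- **neural adaptation** via a moving threshold
  τ_θ dθ/dt = −θ + θ_0 + D_θ r inside the sigmoid f-I curve
  φ(h − θ) = r_max / (1 + e^{−b(h−θ)});
- **background activity** as per-step Gaussian noise C·ξ on the rates;
- two compensatory normalizations of the recurrent input,
  **synaptic** S_W = 1/(1 + α_w Σ w·H(w − w_thr)) and **divisive**
  S_R = 1/(1 + α_r (γ/N) Σ r), which limit the runaway dynamics of
  Hebbian learning and keep concurrently trained assemblies orthogonal.

Repeatedly stimulating a subset of neurons (rectangular pulse trains)
forms an assembly; noise-correlated outside neurons are gradually
recruited, so assembly size tracks stimulation frequency; unstimulated
assemblies decay and their neurons become available again. Membership is
read out with brief test pulses applied to a copy of the network with
learning and noise switched off (rate > 0.5 at 2 a.u. after the pulse).

The package is aimed at computational neuroscientists who want a tested,
scriptable implementation of this model family: every update equation is a
standalone function with oracle-backed tests, experiments are declarative
`Paradigm` objects, and each study ships as a named builder.

## Worked example

```python
import numpy as np
from dynattractor import paradigms, run, analysis

exp = paradigms.formation()          # 10 of 100 neurons, 10 pulses at f=1/30
rec = run(exp.paradigm, exp.params, seed=1, recording=exp.recording)

w = rec.dense_within["P1"]           # within-pattern mean weight, every step
t = rec.dense_weight_times
sat = t[np.flatnonzero(w >= exp.params.w_max - 1e-9)[0]]
print("weight ceiling reached at t =", sat, "a.u.")
for probe in rec.probes_for("P1")[:4]:
    print(f"probe at t={probe.time:4.0f}:",
          analysis.membership(probe).size, "members")
```

prints (seed 1):

```
weight ceiling reached at t = 134.0 a.u.
probe at t=   0: 0 members
probe at t=  30: 10 members
probe at t=  60: 10 members
probe at t=  90: 10 members
```

The mean weight among the stimulated neurons saturates during the 5th
pulse (onsets are 30 a.u. apart), and from the second probe onward a test
pulse re-ignites the whole 10-neuron assembly — the attractor has formed. The same workflow is available from the shell:

```sh
dynattractor list
dynattractor reproduce formation --seed 1 --out results/
dynattractor analyze results/formation_rep0.h5 --metrics sizes,weights
```

Records are HDF5 (parameters embedded, probes, weight statistics, final
state); derived tables are CSV. Other builders: `evolution` (7000-pulse
assembly growth), `two_patterns`, `reinforce_and_forget`,
`frequency_sweep`, `scalability_suite`, `multi_assembly`,
`ablation_suite`, `noise_demo`.

See `docs/methods.md` for the full model description, parameter table,
design choices and known limitations.

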