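# seizurepath

Model-based tracking of effective connectivity over epileptic seizures.

Intracranial EEG (ECoG) shows that a patient's seizures are strikingly
stereotyped, that some patients have two distinct seizure durations ("short"
and "long"), and that long and short events look identical at onset but end
differently.  `seizurepath` investigates these observations through the lens
of a neural mass model: it *inverts* a Jansen–Rit model against each ECoG
channel — estimating, at every sample, the hidden synaptic connectivity
parameters that best explain the recording — and then runs the statistical
pipeline that turns per-seizure parameter pathways into population-level
findings (duration bimodality, onset motifs, termination-linked
correlations).  Because clinical seizure archives of this kind are not
public, the package ships a first-class synthetic-data generator with known
ground truth, so every stage is testable end to end.

It is written for computational-neuroscience and epilepsy-modeling
researchers who want a transparent, fully seeded reference implementation of
assumed-density model inversion and its downstream seizure statistics.

## The model and the estimator

Each channel is an independent three-population neural mass (pyramidal `p`,
excitatory `e`, inhibitory `i`).  A synapse converts pre-synaptic firing to
a post-synaptic potential through a second-order kernel

dv/dt = z,  dz/dt = (α/τ)·φ(v_pre) − (2/τ)·z − v/τ²,

with the erf firing-rate sigmoid φ(v) = (erf((v − v0)/ς) + 1)/2
(v0 = 6 mV, ς = 3 mV) and fixed time constants (10 ms; 20 ms for i→p).  The
observed ECoG is the pyramidal potential v_p = v_ep − v_ip + u.  The five
estimated parameters θ = [u, α_ep, α_ip, α_pe, α_pi] (external input plus
four lumped connectivity gains, labels pre→post) are appended to the state
as a random walk, and a joint assumed-density (Kalman) filter tracks the
augmented Gaussian belief at full temporal resolution:

* prediction — the belief is propagated through the nonlinear model step
  with **exact closed-form Gaussian moments** (Stein identities plus
  bivariate-normal CDFs; no linearization, no sigma points);
* update — a Joseph-form linear Kalman correction against the ECoG sample.

In the linear limit the filter reduces to a textbook Kalman filter to
1e-10; in the nonlinear case its moments match 10⁶-sample Monte-Carlo
propagation to sampling accuracy.  See `docs/methods.md` for derivations,
parameter defaults and known limitations.

## Worked example

The numbered scripts under `analysis/` reproduce the synthetic study stage
by stage and write tidy tables under `results/`.  For instance, duration
bimodality detection:

```
$ python analysis/04_duration_bimodality.py
gap-criterion selection on 100 log durations:
  k=1: gap +0.055 (SE 0.095)
  k=2: gap +0.575 (SE 0.097)
  k=3: gap +0.140 (SE 0.087)
  k-means path -> k = 2; mixture path -> k = 2; agreement = True
  long/short boundary at 26.1 s (48 short, 52 long)
```

The gap statistic compares within-cluster dispersion against a uniform
reference; k = 2 wins on both clustering paths, recovering the generator's
two duration populations, and the boundary (26.1 s) separates the ~16 s and
~40 s modes.  Inverting one seizure:

```
$ python analysis/03_invert_example_seizure.py
seizure synthetic_sz0000: duration 47.9 s, filter valid=True, reconstruction MSE 5.94e-09 V^2 (0.01 mV^2 in millivolt units)
  u         ictal tracking RMSE 0.0007 (9.5% of truth scale)
  alpha_ep  ictal tracking RMSE 0.0652 (4.8% of truth scale)
  alpha_ip  ictal tracking RMSE 0.2898 (10.0% of truth scale)
  alpha_pe  ictal tracking RMSE 0.0284 (1.3% of truth scale)
  alpha_pi  ictal tracking RMSE 0.0163 (3.0% of truth scale)
  reconstruction vs measured ECoG, 1-s energy envelopes: r = 0.992
```

The filter reconstructs the measured signal to ~0.01 mV² mean squared error
and tracks the designed connectivity excursions within a few percent; a
deterministic forward simulation driven by the estimated θ̂(t) reproduces
the seizure's energy envelope (r = 0.992).  The full study
(`analysis/05_trajectories_and_correlations.py`) then shows the paper-style
findings on synthetic ground truth: pre-onset connectivity is uncorrelated
with duration (|r| < 0.06, none significant) while pre-offset excitatory
input correlates strongly (α_ep r = 0.96, Bonferroni-significant), and the
mean trajectory flags show the decrease-then-increase motif — a decrease
epoch locked to onset and an increase epoch locked to offset.

The same stages are available as a CLI over YAML configs:

```bash
seizurepath all --config my_run.yaml --seed 1
```

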