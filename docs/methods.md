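# Methods

## The model

Each ECoG channel is described by an independent Jansen–Rit neural mass: three
populations (pyramidal `p`, excitatory interneurons `e`, inhibitory
interneurons `i`) coupled through four synapses, `e→p`, `i→p`, `p→e`, `p→i`
(labels are pre→post throughout this package).  A synapse converts the
pre-synaptic population's normalized firing rate into a post-synaptic
potential through a critically damped second-order kernel,

    dv/dt = z,
    dz/dt = (α/τ) φ(v_pre) − (2/τ) z − v/τ²,

with lumped time constants τ = 10 ms for `e→p`, `p→e`, `p→i` and τ = 20 ms
for the slower inhibitory synapse `i→p`.  The firing-rate sigmoid is the
error function

    φ(v) = (erf((v − v0)/ς) + 1)/2,     v0 = 6 mV, ς = 3 mV,

so φ maps mean membrane potential to the fraction of the maximum population
rate; the maximum rate itself is absorbed into the gains α (volts), which are
the *effective connectivities* the filter estimates.  The pyramidal membrane
potential — also the observed ECoG —

    v_p = v_ep − v_ip + u

combines the excitatory and inhibitory PSPs with a lumped non-local input
`u`.  The minus sign of the inhibitory PSP is carried by the observation and
potential-assembly rows, so all four gains stay non-negative by convention.

The estimated parameter vector is θ = [u, α_ep, α_ip, α_pe, α_pi].  (Work
that writes synapse subscripts post←pre would print the same vector as
[u, α_pe, α_pi, α_ip, α_ep]; the physical quantities are identical, only the
label convention differs.)

All internal units are SI volts.  The model is exactly scale-equivariant: a
millivolt convention (v0 = 6, ς = 3, gains ×10³) rescales every signal by
10³, which the test suite verifies to 1e-12.

### Discretization

Both the generator and the filter's process model use explicit Euler at
dt = 1/fs with fs = 400 Hz, written in augmented matrix form
ξ' = Aξ + B g(ξ) + w with ξ = [x; θ], identity dynamics on the θ block, and
g carrying the per-synapse products θ_s·φ(c_sᵀξ).  Matching generator and
filter makes the discretization choice internally consistent; its one
visible artifact is an O(dt) bias of the limit-cycle frequency (about 1 Hz
at 400 Hz for the ~10 Hz reference oscillation).  The simulation tests
therefore check first-order self-convergence on a transient, and compare the
oscillation frequency against an adaptive-step integrator at a 10×
oversampled rate, where the bias is below one FFT bin.

### Reference parameter set

The reference gains map the classic Jansen–Rit constants (A = 3.25 mV,
B = 22 mV, C1 = 135, C2 = 0.8·C1, C3 = C4 = 0.25·C1, max rate 5 s⁻¹) into
the lumped form: α_ep = 1.755 V, α_ip = 3.7125 V, α_pe = 2.194 V,
α_pi = 0.548 V.  With u ≈ 9–12 mV the deterministic model sits on an
alpha-band (~10 Hz) limit cycle; near 5–6 mV it produces slower spike-like
oscillations, and below ~3.5 mV it rests at a fixed point.  The synthetic
studies use u = 9 mV as the baseline operating point.

## The assumed-density filter

The filter tracks the joint Gaussian belief over ξ (dimension 13) at every
sample.  The *update* against an observation is the standard linear Kalman
correction (the observation map H is linear), implemented in Joseph form,
which is algebraically identical to the (I−KH)P form but keeps the
covariance symmetric PSD in floating point.

The *prediction* pushes the Gaussian belief through the nonlinear step
exactly, in closed form:

* E[φ(v)] and E[φ′(v)] under a Gaussian have elementary closed forms because
  φ is itself a Gaussian CDF (mean v0, variance ς²/2);
* E[θφ(v)] and Cov(ξ, θφ(v)) follow from Stein's identity;
* the nonlinear–nonlinear block Cov(θ_sφ(v_s), θ_rφ(v_r)) expands by
  iterated Stein identities into terms requiring only E[φφ], E[φ′φ],
  E[φ′φ′], E[φ″φ] under a bivariate Gaussian — all elementary given the
  bivariate normal CDF, computed with the Genz/Drezner–Wesolowsky
  quadrature (absolute error ~1e-15).  The same-synapse variance terms are
  the degenerate pair case and need no special handling because the
  sigmoid's own width keeps the effective correlation strictly inside ±1.

No linearization, sigma points or sampling are involved; the only
approximation in the filter is the Gaussian projection itself.  The
propagation is verified against scrambled-Sobol Monte-Carlo at 10⁶ samples
per belief (componentwise agreement within 3 iid standard errors; quasi-MC
keeps the true sampling error well below that bound, so the check is
conservative).  In the linear-coupling limit the same code path reduces
exactly (to 1e-10 over 10⁴ steps) to a textbook Kalman filter.

### Noise configuration and initialization

Q is diagonal: process noise enters the z-states (the v-states are exact
integrals of z) and the θ block (random walk).  Defaults tie both scales to
the observation-noise SD (z: 10⁻²σ_obs, θ: 10⁻⁴σ_obs per step) so parameters
drift slowly relative to states; every scale is overridable, per parameter
for the θ block.  R defaults to the variance of the high-passed (100 Hz)
pre-ictal baseline — a proxy for observation noise — or an explicit
override.  The synthetic studies use a *matched* filter: the generator's
true process/observation noise levels.  The belief starts with zero state
mean, nominal θ (the reference set), small state variance and parameter SDs
of 20% of nominal.

Instability — non-finite estimates, a non-positive innovation variance, or a
covariance whose diagonal stays negative after one jitter repair of
10⁻¹²·tr(P)/13 — invalidates the trajectory from that sample onward;
downstream analyses drop invalid trajectories.  On the synthetic studies the
instability rate is zero at the default configuration.

### Identifiability

Two structural facts shape the validation studies:

* The inhibitory pair (α_ip, α_pi) is only jointly identifiable through
  fluctuations of the interneuron potentials across the sigmoid: if v_i
  barely moves, only the product α_ip·φ(v_i) is constrained, leaving a
  near-degenerate ridge (α_ip down, α_pi up).  The constant-parameter
  recovery study therefore drives the model with stronger endogenous
  fluctuation (process SD 5·10⁻³ V/s per step vs the seizure generator's
  10⁻³) and perturbs the truth by ±10%, which keeps the dynamics in the
  informative oscillatory band.  Under those conditions the reference
  suite recovers all five parameters within 10% on at least 9 of 10 seeds
  (90-s runs, final-third means).
* A step change in one gain can be absorbed by `u` if every parameter is
  given equal random-walk freedom.  The step-tracking study uses the matched
  configuration — random-walk noise only on the parameter that actually
  moves — and then tracks a 30% step in α_ep with a midpoint-crossing lag of
  well under 2 s.

## Preprocessing

Zero-phase (forward–backward) second-order Butterworth bandpass 1–180 Hz
plus a second-order bandstop at 48–52 Hz (the notch bandwidth is a package
choice; configurable).  Filter edge effects decay within ~1 s at 400 Hz, so
tone attenuation is characterized on the steady-state interior.  Segments
span 5 min before onset to 1 min after offset; segments with telemetry
dropouts (≥ 0.25 s of exactly repeated values on any channel, configurable)
or insufficient coverage are rejected with a recorded reason.  Energy is the
windowed sum of squares (1-s windows, 50% overlap, partial end windows
dropped so window centers align across seizures).

The synthetic estimation studies run on unfiltered generator output: the
generator produces exactly the model's observation process (no mains
interference or drift), and filtering would break the matched-model
assumption the studies are designed to test.  The filtering chain is
validated separately against reference tones.

## Statistics pipeline

* **Duration clustering.**  k-means and Gaussian-mixture fits on log
  durations for k = 1..3; the gap statistic (uniform reference over the
  observed log-duration range, 100 reference draws, first-max selection with
  a one-SE tolerance) picks k per method; patients require ≥ 20 seizures.
  With k = 2 the long/short boundary is the midpoint of the cluster means on
  the log scale.
* **Baseline normalization.**  Percent change from the pre-ictal mean
  (window −120 s to −60 s at full scale; −30 s to −10 s in the reduced-scale
  studies), dividing by |baseline| so direction is preserved for negative
  baselines; near-zero baselines are flagged unusable.
* **Trajectory summaries.**  Seizures are resampled on a common grid; past
  onset only seizures still ongoing contribute.  95% CIs are mean ± 1.96 SE;
  per-time two-sided one-sample t-tests at p < 0.05 flag increases and
  decreases.  These flags are a display statistic (no multiplicity
  correction), and ~5% false flags under the null are expected and observed.
  An offset-aligned variant lines termination epochs up, which is how the
  terminal increase of the decrease-then-increase motif is exposed without
  smearing across unequal durations.
* **Long/short contrast.**  Per-time Welch tests between the duration
  clusters, plus the overall mean difference per parameter.
* **Duration correlations.**  Pearson r between seizure duration and the
  channel-averaged mean parameter estimate over the 5-s window before onset
  (resp. before offset), with Bonferroni correction; the cohort divisor is
  patients × parameters (60 for a 12-patient, 5-parameter cohort).  A
  Spearman/log-duration option exists in the stats API.  The null
  calibration study corrects over the full family of comparisons each
  replicate performs (2 windows × 5 parameters) and measures a family-wise
  false-alarm rate of ~5% against a 10% bound.

## The synthetic generator

The generator emulates a chronically monitored focal-epilepsy patient:

* **Durations** from a one- or two-component lognormal; defaults are modes
  near 30 s and 90 s (log-SD 0.3), clearly separated on the log scale.
  A truncation floor (redraw below 15 s, then clamp) keeps every seizure
  long enough to hold the motif ramps.
* **Motifs**: piecewise half-cosine trajectories of the affected parameters
  (defaults: in-going pyramidal quantities u, α_ep, α_ip): `decrease`,
  `increase`, or `decrease_then_increase` (dip to −amplitude, terminal epoch
  at +overshoot, back to baseline at offset).  Long and short seizures must
  share their onset epoch; they may differ only in termination.
* **Offset link**: the terminal overshoot is `overshoot + link·z` percent of
  baseline with z the z-scored log duration, so a positive link makes longer
  seizures end with stronger in-going drive while pre-onset statistics stay
  duration-independent by construction.
* **ECoG** by simulating the model along each trajectory (process noise
  10⁻³ V/s on z-states, observation noise 10⁻⁴ V); focal structure via a
  configured subset of affected channels, others running baseline dynamics.

What the generator does *not* emulate: patient-specific waveform morphology,
artifacts, electrode drift, inter-channel coupling (each channel is an
independent neural mass, as in the estimation model), or model mismatch —
the data-generating model is the estimation model.  Passing studies
therefore demonstrate correctness and calibration of the inversion and
statistics machinery under matched conditions, not robustness to the
mismatch real ECoG carries.

### Reduced problem sizes

The reference studies run at a reduced per-seizure length so that a
100-seizure catalog with per-sample filtering stays tractable on a single
CPU: pre-onset context 35 s (baseline window −30 to −10 s), post-offset 5 s,
duration modes ~16 s and ~40 s (log-SD 0.2, floor 13 s), one affected
channel.  The statistical structure under test — bimodality, identical
onset epochs, a termination-linked excitation effect, 5-s analysis windows
— is unchanged from the full-scale design.  The trajectory-level surrogate
generator (ground truth plus slow AR(1) estimation noise, 2% of baseline,
50→20 Hz) backs the 200-replicate null calibration, where re-running the
full filter per replicate would add nothing to the property being measured
(calibration of the correlation test).

## Pipeline and reproducibility

`seizurepath synth|preprocess|estimate|analyze|all --config <yaml>` wraps the
stage functions in `seizurepath.pipeline`; unknown config keys are rejected
at every nesting level.  Every stage writes tidy CSVs plus a `manifest.json`
with a config hash, output file hashes, wall-clock and the per-seizure
validity ledger; all randomness derives from the single config seed through
fixed per-stage offsets, so stages rerun independently and bit-identically
(`--resume` skips already-computed estimates).  Estimate files store
per-sample posterior means and marginal variances (13 + 13 columns); full
covariances are not persisted.

## Known limitations

* Single-channel, uncoupled neural masses; no inter-channel inference.
* Synaptic time constants are fixed, not estimated.
* Explicit Euler at the operating rate biases limit-cycle frequency by
  O(dt); generator and filter share the discretization, so the studies are
  internally consistent, but comparisons against continuous-time solutions
  should use finer steps.
* The Gaussian projection can be confidently wrong near structural
  degeneracies (see Identifiability); posterior variances there understate
  the uncertainty along the degenerate ridge.
* EDF files can be read (through `mne`) but not written; the generator's
  native format is CSV with a JSON sidecar.
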