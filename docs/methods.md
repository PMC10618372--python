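# Methods

`pvntherm` couples two pieces of machinery: a single-channel kinetic
analysis pipeline for a thermosensitive Trpv4-like channel recorded
cell-attached on PVN (paraventricular nucleus) neurones, and a stochastic
conductance-based model of such a neurone that predicts how spontaneous
action-current frequency (ACf) changes with bath temperature.  This note
documents the models, the free parameters and their defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

Units throughout: time ms, rates 1/ms, potential mV, conductance pS
(nS in the neurone model), current pA, Ca²⁺ µM, temperature °C.

## 1. Channel kinetics (`markov_core`)

A channel is a continuous-time Markov chain with generator `Q` (off-diagonal
rates ≥ 0, zero row sums), each state labelled open or closed.  Standard
aggregated-Markov theory supplies everything downstream:

* **Equilibrium.** π solves πQ = 0, Σπ = 1.  Po = Σ_open π.  Mean class
  dwell times follow from renewal balance: mean sojourn = class occupancy /
  equilibrium exit flux.
* **Dwell-time mixtures.** Within a conductance class with sub-generator
  `Q_CC`, the dwell density is `φ exp(Q_CC t) u` with `u = −Q_CC·1` and φ
  the equilibrium entry distribution.  Eigen-decomposition gives an
  exponential mixture whose time constants are −1/eigenvalues.  Component
  weights of analytic mixtures can be negative for non-equilibrium entry;
  fitted mixtures are always proper.
* **Temperature.** Q10 scaling multiplies the designated forward
  (open-ward) rates by `q10^(ΔT/10)`.

### The default Trpv4-like channel

The channel is a 3-closed/3-open linear chain `C3–C2–C1–O1–O2–O3`, the
minimal uncoupled topology supporting three exponentials per class.  The
measured closed dwell mixtures at 22/32/37 °C are built in (taus
0.58/5.26/71.22 ms with areas 58/30/12 % at 22 °C, and the corresponding
32 and 37 °C columns; the 32 °C areas print as 65/27/7 and are normalised).
Unitary conductance 59.7 pS; cell-attached reversal −18.89 mV.

The open-side mixtures of the source measurements are not available, so the
defaults are package configuration values — chosen once so that mean open
time falls steeply on cooling while mean closed time shows no systematic
trend, reproducing the measured direction of the Po change
(Po 0.39 → 0.76 → 0.84 across 22/32/37 °C):

| T (°C) | open taus (ms) | open areas |
|--------|----------------|------------|
| 22     | 1.5, 6, 20     | .45/.35/.20 |
| 32     | 2, 10, 45      | .35/.35/.30 |
| 37     | 2.5, 12, 90    | .25/.30/.45 |

**Mixture → rates inversion.** For the linear chain the inversion
decouples: the closed-side rates are fully determined by the closed
mixture (entry and exit both pass through the gateway state C1), and
symmetrically for the open side.  Each side's five rates are found by
Levenberg–Marquardt least squares in log-rate space (residuals: log tau
ratios and area differences), with a moment-matched start plus 23 seeded
random restarts; the result must round-trip the target mixture to a
relative tau error ≤ 1e−4 and area error ≤ 1e−3, otherwise the fit fails
loudly.  Because tree-topology chains are reversible, the side
sub-generators are symmetrisable and all eigenvalues are real.

**Intermediate temperatures.** The three per-temperature fits anchor a
per-transition log-linear regression of rate against temperature (an
effective per-transition Q10, `trpv4_q10_profile`); schemes at
non-measured temperatures (e.g. 27 °C) interpolate through it.  Measured
temperatures return the exact per-temperature fit.

## 2. Synthetic recordings (`synthetic_data`)

Gating trajectories are exact: exponential waiting times and
embedded-chain jumps (initial state drawn from equilibrium), kept in
continuous time and only discretised when rendered, so ground truth is
exact for recovery tests.

Rendering emulates the acquisition chain of the recordings: unitary
current `i = g (V_drive − V_rev)` (ohmic; the cell-attached driving
potential collapses the unknown resting potential and pipette command
into one number, default −70 mV), within-sample integration of the
piecewise-constant conductance signal (anti-aliased sampling), a 4-pole
Bessel low-pass at 1 kHz, sampling at 5 kHz, then additive white Gaussian
noise.  Traces are stored as pipette current, inward openings negative.

**Noise default.** `noise_sd = 0.15 pA` rms.  A resistive-headstage
cell-attached patch filtered at 1 kHz typically shows 0.1–0.15 pA rms, and
a 3 pA channel then has SNR ≈ 20.  This matters: resolving events near a
0.3 ms dead time through a 1 kHz filter (rise time ≈ 0.34 ms) is only
physically possible at such noise levels, which is also implicit in the
source analysis choosing that dead time.

What the generator does *not* emulate: capacitance transients, baseline
drift, 50 Hz interference, filter-correlated (coloured) noise, open-channel
excess noise, and multi-channel stacking artefacts beyond simple
superposition.  Passing recovery tests therefore demonstrate correctness
of the analysis chain under idealised stationary recording conditions, not
robustness to every artefact of real records.

## 3. Idealization (`idealization`)

Two-Gaussian amplitude model fitted by EM to the all-points amplitudes;
levels refined as medians of confidently assigned samples because filter
ramps between levels drag plain means inward.  SKM then alternates a
2-state Viterbi pass (Gaussian emissions) with re-estimation of levels,
noise SDs and switching probability from the assignment; within-class SDs
use the median absolute deviation, since undetected brief events are
exactly the outliers a plain SD would absorb.  Iteration caps at 50 or
< 0.1 % of samples changing class.

Event boundaries are interpolated at the half-amplitude crossing, giving
continuous durations.  Two refinements address the analogue filter:

* **Brief-event duration correction.**  A pulse shorter than ~2 filter
  rise times is attenuated, so its measured half-amplitude duration
  underestimates the true width.  The measured↔true map is computed
  numerically for the exact acquisition chain (phase-averaged over the
  sampling comb) and inverted for dwells below the 1 %-error width.
* **Flicker recovery (excess-area).**  Events whose filtered peak never
  reaches half amplitude (flickers inside bursts) are invisible to any
  two-level assignment, but a linear filter conserves area: a run of
  fractional deviation toward the opposite level (peak ≥ 25 % of the
  amplitude and ≥ 5 within-class SDs, away from existing boundaries) is
  replaced by an inserted opposite-class event whose duration is the
  deviation area.  Without this step the fastest closed time constant of
  the 22 °C experiment is overestimated by ~16 %; with it the recovery
  matches the perfect-idealization limit (~6 %, which is the irreducible
  dead-time merging bias shared by the source analysis).

Dead-time imposition erases dwells shorter than 0.3 ms and concatenates
their flanking dwells (duration conserved; a censored boundary dwell
merges into its single neighbour).  The printed source value 0.3 ms is
used even though "three sample intervals" at 5 kHz would be 0.6 ms.

## 4. Dwell statistics (`dwell_analysis`)

Log-binned (Sigworth–Sine) histograms are display-only.  Fitting is ML on
the unbinned dwells with left truncation at the dead time: a left-truncated
exponential keeps its time constant under shifting, so the truncated
mixture is fitted by EM on `t − t_d` and the mixing fractions mapped back
through the truncation weights `exp(−t_d/τ)` — avoiding binning bias
entirely.  Restarts use the short-run strategy (pilot EMs on ≤ 8000 dwells
pick the basin; one full-data EM polishes).  Component count is chosen by
a log-likelihood ratio ladder at the 0.95 confidence level with 2 degrees
of freedom per added component (one tau, one area; the source states only
the confidence level).  Po and mean dwell times exclude the
duration-censored first and last dwells.

## 5. Rate estimation (`rate_estimation`)

The interval likelihood of the alternating dwell sequence uses matrix
exponentials of the class sub-generators, with a first-order missed-event
correction: apparent dwells evolve under
`Q̃_AA = Q_AA + Q_AB (e^{Q_BB t_d} − I) Q_BB^{−1} Q_BA`
(sojourns in the opposite class shorter than the dead time are treated as
unobserved, their duration accruing to the apparent dwell), and each
observed dwell of length t contributes
`e^{Q̃_AA (t−t_d)} e^{Q_AA t_d} Q_AB`.  At `t_d = 0` this reduces exactly
to the uncorrected likelihood.  The forward pass runs in the spectral
basis (complex-safe) with per-dwell scaling.  Optimisation is L-BFGS-B
over log rates bounded to [1e−6, 1e3] /ms; the default initialisation
inverts per-class mixture fits through `scheme_from_mixtures`.  The
equivalence of the correction is asserted against this package's own
simulator: on dead-time-imposed 2-state data the uncorrected fast time
constant is biased high by > 2 SE and the corrected one is unbiased
within 2 SE.

## 6. The stochastic neurone (`neuron_sim`)

Single compartment, C = 20 pF, fixed step 0.025 ms, explicit Euler.
Deterministic Hodgkin–Huxley fast Na⁺/K⁺ conductances generate spikes
(their parameters are not reported for these cells; spiking machinery is
deliberately generic).  Stochastic populations update by per-state
binomial transition draws each step (counts conserved by construction):

* **Kv**: 5-state chain equivalent to an n⁴ delayed rectifier (100 × 10 pS).
* **Trpv4-like**: the measured 6-state scheme at the run temperature
  (8 × 59.7 pS, reversal 0 mV — the nonselective-cation value; the
  −18.89 mV cell-attached number lives in pipette coordinates with an
  unknown resting-potential offset).
* **Trpm2-like**: 2 states, base rates are free parameters
  (0.05/0.1 ms⁻¹ at 37 °C → Po ≈ 0.33), Q10 = 15.6 on the opening rate,
  30 × 60 pS.
* **SK**: 2 states with Moczydlowski–Latorre-form Ca- and V-dependent
  rates.  The literal ML (BK) constants — mM-range Ca affinity with
  strong voltage dependence — would give zero open probability at −60 mV
  and µM Ca, so the form is kept but the half-saturation constants are
  µM-range (K1 = 0.5, K2 = 0.4 µM, weak voltage dependence δ = 0.1) with
  a steep Ca dependence (exponent 4, the Hill coefficient measured for
  SK channels).  600 × 20 pS.

**Microdomain.**  The Ca²⁺ fraction of each TRP current (GHK flux ratio
at the instantaneous potential, with PCa/PNa = 6 for Trpv4 and 0.7 for
Trpm2) feeds a buffered nanodomain (0.5 µm³, buffer capacity 20) that
exchanges with a large buffered bulk (τ = 0.5 ms); the bulk relaxes to a
0.1 µM rest.  SK reads the nanodomain.  Bulk Ca²⁺ stays within 2× rest in
all simulations while nanodomain transients are several-fold — local
coupling without global Ca²⁺ changes.

**Coupling efficiencies.**  Each TRP type deposits only a fraction of its
Ca²⁺ into the SK nanodomain: 0.15 for Trpv4, 1.0 for Trpm2.  This is the
model's reading of the pharmacology: econazole (Trpm2 block) raises
firing at 37 °C ten-fold while gadolinium (Trpv4 block) barely moves it,
which in any conductance-based model requires the Trpm2–SK coupling to
dominate the 37 °C brake; tight Trpm2–SK co-clustering with looser Trpv4
coupling realises that.

**Drive.**  Excitatory Poisson train (210 Hz, 1 nS, τ 3 ms) plus a
threshold-linear inhibitory interneurone (input 400 Hz, threshold 100 Hz,
gain 0.5 → IPSPs of 0.6 nS, τ 8 ms, −75 mV); per-run lognormal jitter
(σ = 0.2) of the mean rates.  Spikes are upward 0 mV crossings with a
3 ms lockout; a separate adaptive-threshold detector (running median
baseline + k·MAD, refractory grouping) serves the experimental
action-current observable.

**Calibration.**  Densities, drive and microdomain constants were
calibrated once against the prescribed operating points — drug-free ACf
< 1 Hz at 37 °C, a several-fold monotone rise through 32/27/22 °C, and
the drug/knockout directions — then frozen as the defaults above.  The
mechanism, not the tuning, carries the directions: cooling closes Trpv4
(Po 0.84 → 0.39) and effectively removes Trpm2 (Q10 15.6), the nanodomain
collapses from ~0.5 to ~0.2 µM, the steep SK curve turns a large
hyperpolarising conductance off, and firing rises despite the loss of
depolarising TRP current.

**Known limitations.**  The model predicts that gadolinium *increases*
firing at 37 °C (the Trpv4-coupled share of nanodomain Ca²⁺ is still
substantial there), whereas the recordings saw no change — reproducing
that would need even stronger Trpm2 dominance of the 37 °C brake.
Absolute ACf magnitudes are not fitted to data (the cold-end rates here
are higher than recorded ones); only the <1 Hz 37 °C operating point and
the directions are calibrated.  Single compartment only; no network; no
osmosensitivity.

## 7. Problem sizes and determinism

Every stochastic element takes an explicit seed; a (seed, config) pair is
bit-reproducible, and sweep runs pair seeds across temperatures so
contrasts are within-run.  The recovery experiments simulate ~5×10⁴
closed dwells (≈ 15 min of 22 °C recording, ≈ 44 min at 37 °C); the
direction suite uses 5 × 60 s runs per condition; the analytic-vs-Monte-
Carlo oracle checks use 10⁵ dwells per scheme.  These sizes put the
Monte-Carlo error of each checked quantity well inside its assertion
tolerance.
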