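# Methods

This note documents the models implemented in `neurolsm`, the parameter
choices that matter, what the synthetic data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Functional brain network construction

Regional BOLD series (rows of a `RegionalBoldMatrix`, sampling interval
defaulting to a 1.5 s repetition time) are correlated with Pearson's r; an
undirected edge joins regions i and j when `|R_ij| > X_th`.  The absolute
value is used because a strong negative coupling is still a functional
connection; a signed mode (`use_absolute=False`) is provided for analyses
that exclude anticorrelations.  `X_th = 0.3` is the default because, over
the threshold sweep (step 0.05), it keeps graph density within the
empirical range for biological brain networks (3.6–39.3%) with the
smallest between-subject spread.

The small-world index `δ = (C/C_rand)/(L/L_rand)` references 20 uniform
random graphs with matched node and edge counts (disconnected reference
draws are resampled with a bounded retry budget; the input graph itself
must be connected, and callers analysing fragmented graphs should pass the
largest connected component).  The degree exponent `γ` is the discrete
maximum-likelihood estimate with a Hurwitz-zeta likelihood; the lower
cut-off `x_min` defaults to the smallest positive degree, with a
KS-minimizing automatic choice and an explicit override available.  A fit
whose likelihood runs into the optimizer's upper bound is flagged
undefined — that happens precisely when the degree distribution decays
faster than any power law, e.g. for the peaked degrees of a dense modular
graph.  Note that a preferential-attachment graph follows
`P(k) ∝ 1/(k(k+1)(k+2))`, which only approaches `k^-3` in the tail, so the
asymptotic exponent 3 is recovered with a tail cut-off (`x_min ≈ 10` at
n = 5000) rather than from the full distribution.

The Watts-Strogatz generator rewires each ring-lattice edge (u, v) with
probability p to (u, w), keeping the source endpoint, avoiding self-loops
and duplicates, and conserving the edge count nk/2 exactly.  The
Barabási-Albert generator grows from a complete seed graph with
degree-proportional attachment.  Both are deterministic given a seed.

## Reservoir

Every undirected edge becomes a reciprocal pair of directed synapses.
Neurons are labelled excitatory (80% by default, Dale-consistent: all
outgoing synapses inherit the label).  Conduction delays are sampled from
Poisson(10 ms), floored at 0.1 ms and clipped at 40 ms.

LIF parameters are τ_m = 20 ms, V_rest = −65 mV, V_th = −50 mV,
V_reset = −70 mV, R_m = 1 MΩ, τ_ref = 2 ms; integration is forward Euler
at dt = 0.1 ms (convergence-checked), with dt = 0.5 ms used for the large
classification experiments — halving dt changes a run's total spike count
by under 5%.

Synaptic transmission follows a receptor-binding scheme: the bound
fraction obeys `dr_g/dt = αH(1 − r_g) − βr_g` (excitatory α = 2, β = 1;
inhibitory α = 0.9, β = 0.1, per ms), and the current is
`I = syn_gain · g · r_g · (E_syn − V_post)` with E_ex = 0 mV and
E_in = −70 mV.  Two interpretation choices deserve emphasis:

- **Transmitter gate.**  H is a logistic function of the *delayed*
  presynaptic membrane potential, `H = 1/(1 + exp(−V_pre(t−d)/5 mV))`.
  Because a LIF membrane never rises above threshold (−50 mV), where
  H ≈ 0, a presynaptic spike is represented in the delay buffer as a
  +30 mV action-potential pulse lasting 1 ms — the event the gate is meant
  to detect and that point-neuron models abstract away.
- **Current scale.**  The product `g_max · 65 mV ≈ 1` is dimensionally
  ambiguous; read as nA against R_m = 1 MΩ it perturbs the membrane by
  ~1 mV, reducing the recurrent network to a feed-forward relay.
  `syn_gain` (default 20 nA per unit drive) sets the conversion; the
  default keeps the network sparsely active and input-driven — raising it
  toward ~400 produces strong recurrent amplification but measurably
  degrades the class-separability of the liquid state, so restraint is the
  better regime for classification.

STDP uses the exponential windows `w(Δt<0) = A₊ e^{Δt/τ₊}`,
`w(Δt≥0) = −A₋ e^{−Δt/τ₋}` for excitatory synapses (signs mirrored for
inhibitory ones), Δt = t_pre − t_post, with A₊ = 0.1, A₋ = 0.105,
B₊ = 0.02, B₋ = 0.03, τ± = 20 ms, and weights clipped to
[0, g_max = 0.015].  Weight decay is **event-driven**: at each presynaptic
spike, a synapse whose postsynaptic neuron has fired since the previous
presynaptic spike receives the pairing update, while one whose last
transmission elicited no response decays by `exp(−Δt_interval/τ)`
(τ_ex = 3 ms, τ_in = 5 ms).  Applying that decay continuously in wall-clock
time would drive every weight to zero within ~10 ms and silence the
network permanently, which is inconsistent with the sustained reservoir
firing the architecture is designed to produce; conditioning decay on
transmission failure keeps the synapse table dynamic (ineffective pathways
are pruned, coincident ones reinforced) without that pathology.

Input spikes are injected as rectangular current pulses of 400 nA × 1 ms
into 39 randomly chosen reservoir neurons (one per encoder channel).  The
amplitude is chosen so a single input spike is reliably suprathreshold:
with τ_m = 20 ms a 1 ms pulse delivers `R·I·(1 − e^{−1/20}) ≈ 0.049·R·I`
of depolarization, so crossing the 15 mV gap needs ≳ 310 nA.

## Sparse spike encoding

Features: 25 ms Hamming-windowed frames at a 10 ms step, pre-emphasis
0.97, 512-point FFT magnitudes, 26 triangular mel filters, log, orthogonal
DCT-II keeping 13 cepstra (c0 retained); Δ and ΔΔ rows use the
central-difference estimator with context N = 2 and replicate padding.
Utterances are aligned to the median training frame count by dynamic time
warping against a uniform time-stretch of themselves (three-predecessor
recurrence, Euclidean local distance, no slope weighting); output frame j
averages the source frames mapped onto it, and the aligned matrix keeps
the nominal 10 ms step so all utterances share one time base.  Layer
normalization standardizes each frame across its 39 features
(ε = 1e−8).

The Sigma-Delta modulator runs per channel:
`e[n] = x[n] − y[n−1]`, `s[n] = (1−α)s[n−1] + e[n]`, spike iff
`s[n] ≥ θ`.  α defaults to 0 (pure accumulator; α > 0 adds an integrator
leak for stability experiments).  The bare modulator's reference threshold
is θ = 1, at which a constant input x ∈ [0, θ] is reproduced with long-run
spike rate x/θ.  The *encoder pipeline* default is θ = 8: per-frame layer
normalization leaves sustained per-channel offsets of up to ~3σ (the
energy cepstrum c0 especially), and a level-tracking modulator fires at
rate |level|/θ on those, so a unit threshold would emit dense,
uninformative spike trains (sparsity ~0.82).  At θ = 8 sustained levels
stay subthreshold and only strong feature transitions accumulate to
events, yielding sparsity ≈ 0.93 and ~120 spikes per utterance — an
order of magnitude below the one-spike-per-cell dense bound, and the
transient-driven raster structure this encoding aims for.  Negative
normalized excursions simply emit nothing (the sparsity mechanism); an
optional per-channel min-max rescale to [0, 1] is provided.

## Readout and training

One output LIF neuron per class receives current
`400 nA · Σ_j W_jk · pulse_j(t)` where each reservoir spike opens a 5 ms
pulse; the pulse width gives the output membrane a usable integration
window over the sparse liquid events.  Desired spike templates default to
the **activity-contrast** construction: each class's mean population
firing histogram (Gaussian-smoothed, σ = 10 ms) minus the mean of the
other classes', with the 8 largest peaks (≥ 40 ms apart) becoming desired
spike times.  Anchoring targets where a class's activity specifically
exceeds the others' makes them both reachable and selective; fixed
phase-shifted periodic templates are available (`template_mode =
"periodic"`) but are uncorrelated with when the liquid can fire and train
to chance accuracy.

The remote supervised rule is evaluated discretely: every desired spike
adds `e_H + Σ A₊ e^{−Δ/τ₊}` (over that channel's preceding spikes) to each
incoming weight, every actual output spike subtracts the same quantity;
e_H = 0.25, and the window reuses the reservoir's A₊/τ₊.  Updates are
accumulated over the training set within a cycle (batch mode; a
per-utterance sequential mode exists but is ~20× slower with no measured
accuracy benefit) and applied with learning rate 0.05 decayed as
`1/(1 + cycle/40)` — without the decay the output layer enters a
fire-everything/collapse limit cycle instead of settling at the
rate-matching equilibrium.  Weights are clipped to [−1, 1].
Classification runs the reservoir and output layer and returns the class
whose neuron's spike train has the smallest van Rossum distance
(τ = 20 ms, closed-form kernel evaluation) to its own template, ties going
to the lowest class index.  Reservoir plasticity acts within each
utterance's response (each run starts from the same initial state) but
reservoir weights are not carried across utterances, so readout learning
is isolated from reservoir drift.

## Firing and graph analytics

Separability of class-evoked firing uses a one-way fixed-effects ANOVA on
population spike counts per 1 ms bin, one group per stimulus class, pooled
over all available liquid responses (the diagnostic is a property of the
reservoir, not of the train/test split).  Degenerate inputs (zero pooled
within-group variance) are flagged rather than reported as infinite F.

Information-transmission metrics operate on the symmetrized weighted
synapse graph (undirected weight = mean of the two directed weights):
synaptic density (non-zero synapses per neuron), the weighted clustering
coefficient `C_w` (ordered-neighbour-pair convention, which reduces
exactly to the binary clustering coefficient under uniform weights), and
the weighted shortest path length `L_w` with edge length `1/g`, averaged
over ordered reachable pairs with the reachable fraction reported.

## Synthetic data

The BOLD generator emulates the *correlation structure* of parcellated
resting-state data, not hemodynamics: 90 regions in 6 modules, each region
a mixture `√r_b·global + √(r_w−r_b)·module + √(1−r_w)·noise` of
unit-variance AR(1) processes (φ = 0.3), with targets r_within = 0.55 and
r_between = 0.15 chosen so the thresholded graph is modular, mostly
connected, and lands mid-range in the biological density band; 200 samples
at TR = 1.5 s correspond to a five-minute scan.  There is no HRF
convolution, physiological noise or motion artefact, so passing tests
validate the correlation-to-graph pipeline, not fMRI preprocessing.

The audio generator produces 300–600 ms utterances at 12.5 kHz: each class
sweeps a distinct pair of formant trajectories (class-specific start/end
frequencies, ±3% speaker jitter), under a raised-cosine onset/offset
envelope with 5% white noise.  Classes are separable (a leave-one-out
nearest-centroid classifier on mean MFCC vectors scores well above
chance), but the utterances lack syllable structure, coarticulation and
speaker variety, so accuracies here do not predict accuracies on real
speech corpora.

All generators are pure functions of configuration and seed; the
documented experiment seed is 20260426.

## Scaled experiment and limitations

The standard desk-scale experiment uses 10 classes × (20 train + 10 test)
utterances, a functional graph from one synthetic BOLD subject at
X_th = 0.3, dt = 0.5 ms, and 240 training cycles; it completes in about a
minute on one CPU.  Under these conditions the firing-activity ANOVA is
highly significant (F ≈ 5–6, p < 1e−5) and test accuracy is typically
0.27–0.35 — roughly 3× the 10% chance level and overwhelmingly significant
against it, but well short of what the liquid state itself supports: a
nearest-centroid readout on per-channel spike counts reaches ~0.73 and
logistic regression ~0.87 on the same rasters.

The gap is a property of the decision architecture, not of the learning
rule's implementation: one threshold neuron per class, compared only
against its own few-spike template by a count-sensitive metric, needs an
own-versus-other firing ratio far larger than the instantaneous
discriminability of the liquid provides (planting near-ideal
logistic-regression weights into the output layer scores *worse* than the
trained ReSuMe weights, because any extra firing inflates the van Rossum
distance).  ReSuMe's rate-matching equilibrium — sparse, template-proximal
firing — is the best operating point of this architecture, and is what
training converges to.  Larger output layers, population readouts or
margin-based decision rules would close the gap but are outside this
package's scope.

Other known limitations: the transmitter gate and the event-driven
decay are interpretations of an underdetermined model description
(documented above); the synthetic FBN is modular rather than
scale-free, so its degree-exponent fit is flagged undefined; and absolute
recognition accuracies on licensed speech corpora are not reproducible
here by construction.
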