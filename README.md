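# neurolsm

A toolkit for building and analysing **brain-network-constrained spiking
liquid state machines (LSMs)** for spoken-digit recognition.

Conventional spiking neural networks use algorithmically generated wiring
(regular, random, small-world, scale-free).  This package instead derives
the recurrent reservoir's topology from a **functional brain network
(FBN)**: regional BOLD fMRI time series are correlated (Pearson), the
correlation matrix is thresholded into a binary graph, and that graph is
wired into a 90-neuron leaky integrate-and-fire (LIF) reservoir with
receptor-kinetic synapses, spike-timing-dependent plasticity (STDP) and
Poisson-distributed conduction delays.  Speech is converted into sparse
binary spike rasters by an **enhanced-MFCC Sigma-Delta encoder**, and a
readout layer trained with the **remote supervised method (ReSuMe)**
classifies utterances from the reservoir's firing patterns.

Audience: computational-neuroscience and neuromorphic-computing researchers
who want a desk-scale, fully synthetic-testable implementation of this
pipeline — no access to fMRI archives or licensed speech corpora required.

## The model

**Functional graph.** For regional BOLD series `x_i(t)`, edges are placed
where the Pearson correlation satisfies `|R_ij| > X_th` (default
`X_th = 0.3`, which puts graph density inside the biological range
3.6–39.3%).  Graphs are characterized by density, the small-world index
`δ = (C/C_rand)/(L/L_rand)` and the degree power-law exponent `γ` (discrete
maximum likelihood).

**Reservoir.** LIF membranes `τ_m dV/dt = −(V − V_rest) + R_m I_syn`
(τ_m = 20 ms, V_rest = −65 mV, V_th = −50 mV, V_reset = −70 mV,
τ_ref = 2 ms); synaptic current `I = g · r_g · (E_syn − V_post)` with
receptor binding `dr_g/dt = αH(1−r_g) − βr_g`, where H is a logistic gate
on the delayed presynaptic potential; STDP with exponential windows
(A₊ = 0.1, A₋ = 0.105, τ± = 20 ms) and weights clipped to [0, g_max = 0.015];
conduction delays Poisson-distributed in [0.1, 40] ms.

**Encoder.** 13 static MFCCs + 13 Δ + 13 ΔΔ (central-difference, context 2)
→ DTW alignment to a common frame count → per-frame layer normalization
`(x − μ)/(σ + ε)` → first-order Sigma-Delta modulation
(`e[n] = x[n] − y[n−1]`, `s[n] = (1−α)s[n−1] + e[n]`, spike iff `s[n] ≥ θ`)
giving a 39-channel binary raster with sparsity ≳ 0.93.

**Readout.** One output LIF neuron per class; weights trained with
`dw ∝ [S_d(t) − S_a(t)] (e_H + ∫ w(s) S_in(t−s) ds)` (e_H = 0.25); desired
templates anchored at each class's firing-activity contrast peaks;
classification by van Rossum distance between each output neuron's spike
train and its own template.

## Worked example

```python
import neurolsm as nl
from neurolsm.model import SpokenDigitLSM

# synthetic inputs: modular BOLD series and formant-swept utterances
dataset = nl.gen_audio_dataset(nl.AudioGenConfig(n_classes=4, per_class=9,
                                                 seed=nl.DEFAULT_SEED))
bold = nl.gen_bold(nl.BoldGenConfig(seed=nl.DEFAULT_SEED, n_subjects=1))[0]
top = nl.build_functional_graph(nl.compute_correlation_matrix(bold), x_th=0.3)
print("density:", round(nl.network_density(top), 3))

model = SpokenDigitLSM.from_dataset(dataset, top, seed=7)
results = model.fit(cycles=240)
print(results.summary())
```

prints

```
density: 0.165
Spoken-digit LSM results
================================================
reservoir neurons:      90
reservoir edges:        662
classes:                4
train / test size:      24 / 12
readout cycles:         240
test accuracy:          0.500
firing ANOVA:           F=3.96, p=0.00784
vR distance (first):    3.933
vR distance (final):    2.064
------------------------------------------------
per-class accuracy:
  class 0: 0.667
  class 1: 0.333
  class 2: 0.667
  class 3: 0.333
```

The functional graph lands at density 0.165 (inside the biological band);
the one-way ANOVA on per-millisecond population firing counts shows the
four classes evoke significantly different reservoir activity; the mean van
Rossum distance between actual and desired output trains roughly halves
over 240 ReSuMe cycles; and the trained readout classifies held-out
utterances well above the 25% chance level.  `results.plot_raster()` and
`results.plot_convergence()` visualize the liquid response and the training
curve.

A command-line interface mirrors the library:
`neurolsm fbn-build`, `neurolsm topo ws|ba`, `neurolsm topo-metrics`,
`neurolsm encode`, `neurolsm simulate`, `neurolsm train`,
`neurolsm analyze-graph`, `neurolsm synth bold|audio`.

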