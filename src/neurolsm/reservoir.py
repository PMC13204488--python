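"""Spiking reservoir: LIF neurons, kinetic synapses, STDP, conduction delays.

The reservoir wires an undirected topology (typically a functional brain
network over 90 regions) into a recurrent spiking network: every undirected
edge becomes a reciprocal pair of directed synapses, each neuron is labelled
excitatory or inhibitory (all of its outgoing synapses inherit the label),
and conduction delays are Poisson-distributed in [0.1, 40] ms.

Membrane dynamics follow the leaky integrate-and-fire equation
``tau_m dV/dt = -(V - V_rest) + R_m I_syn`` with threshold/reset and an
absolute refractory period.  Synaptic currents use a receptor-binding
kinetic model: ``I = g r_g (E_syn - V_post)`` where the bound-receptor
fraction r_g relaxes as ``dr_g/dt = alpha H (1 - r_g) - beta r_g`` and H is
a logistic gate on the *delayed* presynaptic potential.  Because a LIF
membrane never exceeds threshold, a presynaptic spike is represented in the
delay buffer as a brief +30 mV action-potential pulse (1 ms), which is what
actually opens the gate.  Synaptic weights are modulated by an exponential
STDP window on successful pre/post pairings, decay exponentially on failed
transmissions, and stay clipped to [0, g_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .encoding import SpikeRaster
from .fbn import Topology

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "Synapse",
    "SynapseTable",
    "ReservoirState",
    "SimulationResult",
    "initialize_reservoir",
    "lif_step",
    "synapse_gate",
    "stdp_update",
    "run_reservoir",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane parameters (defaults: 20 ms / -65 / -50 / -70 mV, 1 MOhm, 2 ms)."""

    tau_m: float = 20.0  # ms
    v_rest: float = -65.0  # mV
    v_th: float = -50.0  # mV
    v_reset: float = -70.0  # mV
    r_m: float = 1.0  # MOhm (so R*I is in mV when I is in nA)
    tau_ref: float = 2.0  # ms

    def __post_init__(self):
        if not (self.v_reset <= self.v_rest < self.v_th):
            raise ValueError("require v_reset <= v_rest < v_th")
        if self.tau_m <= 0 or self.tau_ref <= 0 or self.r_m <= 0:
            raise ValueError("time constants and resistance must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic-synapse, STDP, and delay parameters.

    Rate constants alpha/beta are per ms; reversal potentials in mV; decay
    and STDP window constants in ms; g_max is the dimensionless weight cap.
    """

    e_syn_ex: float = 0.0
    e_syn_in: float = -70.0
    alpha_ex: float = 2.0
    alpha_in: float = 0.9
    beta_ex: float = 1.0
    beta_in: float = 0.1
    tau_ex: float = 3.0
    tau_in: float = 5.0
    g_max: float = 0.015
    a_plus: float = 0.1
    a_minus: float = 0.105
    b_plus: float = 0.02
    b_minus: float = 0.03
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    delay_range: Tuple[float, float] = (0.1, 40.0)
    delay_mean: float = 10.0
    # conversion from the dimensionless conductance drive g*r_g*(E-V) to
    # injected current (nA): the printed constants leave the current scale
    # ambiguous (g_max*65 mV is ~1 nA, a ~1 mV perturbation at Rm=1 MOhm,
    # which would reduce the reservoir to a feed-forward relay); the default
    # puts the recurrent network in a sparsely active, non-epileptic regime
    syn_gain: float = 20.0
    v_scale: float = 5.0  # mV, steepness of the transmitter gate
    spike_peak: float = 30.0  # mV recorded during the presynaptic pulse
    spike_pulse_width: float = 1.0  # ms

    def __post_init__(self):
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        lo, hi = self.delay_range
        if not (0 < lo < hi):
            raise ValueError("delay_range must satisfy 0 < lo < hi")
        for name in ("a_plus", "a_minus", "b_plus", "b_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Synapse:
    """Single directed synapse (scalar mirror of one SynapseTable row)."""

    pre: int
    post: int
    kind: str  # "excitatory" | "inhibitory"
    g: float
    delay: float  # ms
    r_g: float = 0.0
    last_pre_spike: Optional[float] = None
    last_post_spike: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError("kind must be excitatory or inhibitory")
        if not (0.0 <= self.r_g <= 1.0):
            raise ValueError("r_g must lie in [0, 1]")


@dataclass
class SynapseTable:
    """Vectorized table of directed synapses (one entry per array index)."""

    pre: np.ndarray  # int
    post: np.ndarray  # int
    excitatory: np.ndarray  # bool, label of the presynaptic neuron
    g: np.ndarray  # float
    delay_ms: np.ndarray  # float
    r_g: np.ndarray  # float
    last_pre: np.ndarray  # float, -inf when never spiked
    last_post: np.ndarray  # float

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def copy(self) -> "SynapseTable":
        return SynapseTable(
            pre=self.pre.copy(),
            post=self.post.copy(),
            excitatory=self.excitatory.copy(),
            g=self.g.copy(),
            delay_ms=self.delay_ms.copy(),
            r_g=self.r_g.copy(),
            last_pre=self.last_pre.copy(),
            last_post=self.last_post.copy(),
        )

    def as_synapse(self, i: int) -> Synapse:
        return Synapse(
            pre=int(self.pre[i]),
            post=int(self.post[i]),
            kind="excitatory" if self.excitatory[i] else "inhibitory",
            g=float(self.g[i]),
            delay=float(self.delay_ms[i]),
            r_g=float(self.r_g[i]),
            last_pre_spike=None if np.isneginf(self.last_pre[i]) else float(self.last_pre[i]),
            last_post_spike=None if np.isneginf(self.last_post[i]) else float(self.last_post[i]),
        )


@dataclass
class ReservoirState:
    """Full mutable simulation state of the reservoir."""

    v: np.ndarray  # membrane potentials, mV
    refractory: np.ndarray  # remaining refractory time, ms
    synapses: SynapseTable
    neuron_excitatory: np.ndarray  # bool per neuron
    nparams: NeuronParams
    sparams: SynapseParams
    clock: float = 0.0  # ms
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.v.size

    def copy(self) -> "ReservoirState":
        return ReservoirState(
            v=self.v.copy(),
            refractory=self.refractory.copy(),
            synapses=self.synapses.copy(),
            neuron_excitatory=self.neuron_excitatory.copy(),
            nparams=self.nparams,
            sparams=self.sparams,
            clock=self.clock,
            seed=self.seed,
        )


@dataclass
class SimulationResult:
    """Reservoir raster plus optional weight trajectory and final synapse table."""

    raster: SpikeRaster
    weight_trace: Optional[np.ndarray] = None  # mean g per step
    final_synapses: Optional[SynapseTable] = None
    dt: float = 0.1  # ms per raster column


def initialize_reservoir(
    top: Topology,
    nparams: Optional[NeuronParams] = None,
    sparams: Optional[SynapseParams] = None,
    excitatory_fraction: float = 0.8,
    seed: int = 0,
) -> ReservoirState:
    """Wire a topology into a reservoir.

    Each undirected edge yields two directed synapses; neurons are labelled
    excitatory with probability ``excitatory_fraction`` (their outgoing
    synapses inherit the label); delays ~ Poisson(delay_mean) clipped to
    [0.1, 40] ms; initial weights uniform in (0, g_max]; r_g starts at 0 and
    membranes at rest.  Deterministic for a given seed.
    """
    nparams = nparams or NeuronParams()
    sparams = sparams or SynapseParams()
    if top.n_edges == 0:
        raise ValueError("topology has no edges")
    if not (0.0 < excitatory_fraction < 1.0):
        raise ValueError("excitatory_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = top.n_nodes
    neuron_exc = rng.random(n) < excitatory_fraction
    pairs = sorted(top.edges)
    pre = np.array([u for u, v in pairs] + [v for u, v in pairs], dtype=np.int64)
    post = np.array([v for u, v in pairs] + [u for u, v in pairs], dtype=np.int64)
    m = pre.size
    lo, hi = sparams.delay_range
    delays = rng.poisson(sparams.delay_mean, size=m).astype(float)
    delays = np.clip(delays + lo, lo, hi)
    g0 = sparams.g_max * (1.0 - rng.random(m))  # uniform in (0, g_max]
    table = SynapseTable(
        pre=pre,
        post=post,
        excitatory=neuron_exc[pre],
        g=g0,
        delay_ms=delays,
        r_g=np.zeros(m),
        last_pre=np.full(m, -np.inf),
        last_post=np.full(m, -np.inf),
    )
    return ReservoirState(
        v=np.full(n, nparams.v_rest),
        refractory=np.zeros(n),
        synapses=table,
        neuron_excitatory=neuron_exc,
        nparams=nparams,
        sparams=sparams,
        clock=0.0,
        seed=seed,
    )


def lif_step(
    state: ReservoirState, injected_current: np.ndarray, dt: float
) -> Tuple[ReservoirState, np.ndarray]:
    """One forward-Euler LIF step; returns (state, boolean spike flags).

    Neurons inside their refractory period stay clamped at v_reset and
    ignore input.  A neuron crossing v_th emits a spike, resets, and starts
    a tau_ref refractory hold.
    """
    p = state.nparams
    if dt <= 0 or dt > p.tau_ref:
        raise ValueError("require 0 < dt <= tau_ref")
    injected_current = np.asarray(injected_current, dtype=float)
    if not np.all(np.isfinite(injected_current)):
        raise ValueError("injected current must be finite")
    v = state.v
    refr = state.refractory
    active = refr <= 0
    dv = (dt / p.tau_m) * (-(v - p.v_rest) + p.r_m * injected_current)
    v = np.where(active, v + dv, p.v_reset)
    spikes = active & (v >= p.v_th)
    v = np.where(spikes, p.v_reset, v)
    refr = np.where(spikes, p.tau_ref, np.maximum(refr - dt, 0.0))
    state.v = v
    state.refractory = refr
    state.clock += dt
    return state, spikes


def transmitter_gate(v_pre_delayed, sparams: SynapseParams):
    """Logistic transmitter-concentration gate H on the delayed presynaptic V."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v_pre_delayed, dtype=float) / sparams.v_scale))


def synapse_gate(
    syn: Synapse,
    v_pre_delayed: float,
    v_post: float,
    sparams: Optional[SynapseParams] = None,
    dt: float = 0.1,
) -> Tuple[float, float]:
    """Advance one synapse's receptor state and return (r_g, current).

    ``r_g`` is advanced by Euler on ``dr_g/dt = alpha H (1 - r_g) - beta r_g``
    (clipped to [0, 1]); the current contribution is
    ``g * r_g * (E_syn - v_post)`` evaluated at the entry value of r_g (so a
    fully unbound synapse passes no current this step).
    """
    sparams = sparams or SynapseParams()
    exc = syn.kind == "excitatory"
    alpha = sparams.alpha_ex if exc else sparams.alpha_in
    beta = sparams.beta_ex if exc else sparams.beta_in
    e_syn = sparams.e_syn_ex if exc else sparams.e_syn_in
    current = sparams.syn_gain * syn.g * syn.r_g * (e_syn - v_post)
    h = float(transmitter_gate(v_pre_delayed, sparams))
    r = syn.r_g + dt * (alpha * h * (1.0 - syn.r_g) - beta * syn.r_g)
    r = min(max(r, 0.0), 1.0)
    return r, current


def stdp_update(
    syn: Synapse,
    event: str,
    t: Optional[float] = None,
    dt_elapsed: Optional[float] = None,
    sparams: Optional[SynapseParams] = None,
) -> Synapse:
    """Apply one plasticity event to a synapse and return the updated copy.

    ``event`` is one of:

    - ``"decay"``: multiply g by exp(-dt_elapsed / tau) with tau = tau_ex
      (excitatory) or tau_in (inhibitory).
    - ``"pre-spike"``: presynaptic spike at time t; pairs against the last
      postsynaptic spike with dt = t_pre - t_post >= 0 (depression branch
      for excitatory synapses).
    - ``"post-spike"``: postsynaptic spike at time t; pairs against the last
      presynaptic spike with dt = t_pre - t_post < 0 (potentiation branch
      for excitatory synapses).

    Resulting weights are clipped to [0, g_max].
    """
    sparams = sparams or SynapseParams()
    exc = syn.kind == "excitatory"
    g = syn.g
    out = replace(syn)
    if event == "decay":
        if dt_elapsed is None or dt_elapsed < 0:
            raise ValueError("decay requires dt_elapsed >= 0")
        tau = sparams.tau_ex if exc else sparams.tau_in
        g = g * np.exp(-dt_elapsed / tau)
    elif event == "pre-spike":
        if t is None:
            raise ValueError("pre-spike requires t")
        if syn.last_post_spike is not None:
            delta = t - syn.last_post_spike  # >= 0
            if exc:
                g += -sparams.a_minus * np.exp(-delta / sparams.tau_minus) * sparams.g_max
            else:
                g += sparams.b_minus * np.exp(-delta / sparams.tau_minus) * sparams.g_max
        out.last_pre_spike = t
    elif event == "post-spike":
        if t is None:
            raise ValueError("post-spike requires t")
        if syn.last_pre_spike is not None:
            delta = syn.last_pre_spike - t  # < 0
            if exc:
                g += sparams.a_plus * np.exp(delta / sparams.tau_plus) * sparams.g_max
            else:
                g += -sparams.b_plus * np.exp(delta / sparams.tau_plus) * sparams.g_max
        out.last_post_spike = t
    else:
        raise ValueError(f"unknown event {event!r}")
    out.g = float(np.clip(g, 0.0, sparams.g_max))
    return out


def _input_current_series(
    input_raster: SpikeRaster,
    input_map: Sequence[int],
    input_amplitude: float,
    pulse_width: float,
    n_neurons: int,
    n_steps: int,
    dt: float,
) -> np.ndarray:
    """Dense (n_steps, n_neurons) injected-current array from an event raster.

    Each input spike becomes a rectangular pulse of ``input_amplitude`` nA
    lasting ``pulse_width`` ms, injected into the mapped neuron.
    """
    input_map = np.asarray(input_map, dtype=int)
    if input_map.size != input_raster.n_channels:
        raise ValueError("input_map length must equal raster channel count")
    if np.unique(input_map).size != input_map.size:
        raise ValueError("mapped neurons must be distinct")
    current = np.zeros((n_steps, n_neurons))
    raster_dt_ms = input_raster.dt * 1000.0
    pulse_steps = max(1, int(round(pulse_width / dt)))
    ch, ts = np.nonzero(input_raster.values)
    for c, s in zip(ch, ts):
        start = int(round(s * raster_dt_ms / dt))
        if start >= n_steps:
            continue
        current[start : start + pulse_steps, input_map[c]] += input_amplitude
    return current


def run_reservoir(
    state: ReservoirState,
    input_raster: SpikeRaster,
    input_map: Sequence[int],
    input_amplitude: float = 400.0,
    pulse_width: float = 1.0,
    duration: Optional[float] = None,
    dt: float = 0.1,
    seed: int = 0,
    plasticity: bool = True,
    record_weights: bool = False,
) -> SimulationResult:
    """Drive the reservoir with an input spike raster and record its spikes.

    The event loop per step: read delayed presynaptic potentials from a ring
    buffer, advance receptor gates and accumulate synaptic currents, add the
    injected input pulses, step all LIF neurons, then apply STDP pairings on
    the spikes and exponential weight decay everywhere.  The state is
    mutated in place; pass ``state.copy()`` to preserve the original.
    """
    sp = state.sparams
    np_params = state.nparams
    n = state.n_neurons
    raster_span_ms = input_raster.n_timesteps * input_raster.dt * 1000.0
    if duration is None:
        duration = raster_span_ms
    if duration + 1e-9 < raster_span_ms:
        raise ValueError("duration must cover the input raster span")
    n_steps = int(round(duration / dt))
    current_in = _input_current_series(
        input_raster, input_map, input_amplitude, pulse_width, n, n_steps, dt
    )
    tab = state.synapses
    m = tab.n_synapses
    exc = tab.excitatory
    alpha = np.where(exc, sp.alpha_ex, sp.alpha_in)
    beta = np.where(exc, sp.beta_ex, sp.beta_in)
    e_syn = np.where(exc, sp.e_syn_ex, sp.e_syn_in)
    delay_steps = np.maximum(1, np.round(tab.delay_ms / dt).astype(int))
    buf_len = int(delay_steps.max()) + 1
    vbuf = np.full((buf_len, n), np_params.v_rest)
    peak_steps = max(1, int(round(sp.spike_pulse_width / dt)))
    peak_timer = np.zeros(n)  # remaining steps at spike peak in the buffer
    # per-neuron synapse index lists for STDP event application
    syn_by_pre = [np.flatnonzero(tab.pre == i) for i in range(n)]
    syn_by_post = [np.flatnonzero(tab.post == i) for i in range(n)]
    raster = np.zeros((n, n_steps), dtype=np.uint8)
    weight_trace = np.empty(n_steps) if record_weights else None
    for step in range(n_steps):
        t = state.clock
        # delayed presynaptic potentials per synapse
        read_idx = (step - delay_steps) % buf_len
        v_pre_del = vbuf[read_idx, tab.pre]
        h = 1.0 / (1.0 + np.exp(-v_pre_del / sp.v_scale))
        tab.r_g += dt * (alpha * h * (1.0 - tab.r_g) - beta * tab.r_g)
        np.clip(tab.r_g, 0.0, 1.0, out=tab.r_g)
        i_syn_terms = sp.syn_gain * tab.g * tab.r_g * (e_syn - state.v[tab.post])
        i_total = np.zeros(n)
        np.add.at(i_total, tab.post, i_syn_terms)
        i_total += current_in[step]
        state, spikes = lif_step(state, i_total, dt)
        raster[:, step] = spikes
        if plasticity:
            spiking = np.flatnonzero(spikes)
            for neuron in spiking:
                # outgoing: this neuron is pre.  A recent postsynaptic spike
                # means successful transmission -> STDP pairing (dt >= 0
                # branch); otherwise the transmission failed and the weight
                # decays by the time elapsed since the last presynaptic event.
                idx = syn_by_pre[neuron]
                if idx.size:
                    last_pre = tab.last_pre[idx]
                    last_post = tab.last_post[idx]
                    # success: the postsynaptic neuron fired since the
                    # previous presynaptic spike -> STDP pairing (dt >= 0)
                    paired = np.isfinite(last_post) & (last_post > last_pre)
                    sel = idx[paired]
                    if sel.size:
                        delta = t - tab.last_post[sel]  # >= 0
                        win = np.exp(-delta / sp.tau_minus)
                        inc = np.where(
                            tab.excitatory[sel],
                            -sp.a_minus * win,
                            sp.b_minus * win,
                        )
                        tab.g[sel] += inc * sp.g_max
                    # failure: a previous presynaptic spike elicited no
                    # postsynaptic response -> exponential decay over the
                    # inter-spike interval
                    fail = idx[np.isfinite(last_pre) & ~paired]
                    if fail.size:
                        elapsed = t - tab.last_pre[fail]
                        tau_decay = np.where(
                            tab.excitatory[fail], sp.tau_ex, sp.tau_in
                        )
                        tab.g[fail] *= np.exp(-elapsed / tau_decay)
                    tab.last_pre[idx] = t
                # incoming: this neuron is post; pair with last pre spike
                idx = syn_by_post[neuron]
                if idx.size:
                    has_pre = ~np.isneginf(tab.last_pre[idx])
                    sel = idx[has_pre]
                    if sel.size:
                        delta = tab.last_pre[sel] - t  # <= 0
                        win = np.exp(delta / sp.tau_plus)
                        inc = np.where(
                            tab.excitatory[sel],
                            sp.a_plus * win,
                            -sp.b_plus * win,
                        )
                        tab.g[sel] += inc * sp.g_max
                    tab.last_post[idx] = t
            np.clip(tab.g, 0.0, sp.g_max, out=tab.g)
        if record_weights:
            weight_trace[step] = tab.g.mean()
        # write membrane record (spike peak during the action-potential pulse)
        peak_timer = np.where(spikes, peak_steps, np.maximum(peak_timer - 1, 0))
        v_record = np.where(peak_timer > 0, sp.spike_peak, state.v)
        vbuf[step % buf_len] = v_record
    return SimulationResult(
        raster=SpikeRaster(values=raster, dt=dt / 1000.0),
        weight_trace=weight_trace,
        final_synapses=tab,
        dt=dt,
    )
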