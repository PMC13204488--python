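"""LSM readout layer: ReSuMe-trained output neurons over the reservoir.

One output LIF neuron per class.  Each class owns a desired spike-train
template (by default anchored at the class's firing-activity contrast
peaks); training nudges the
reservoir-to-output weights with the remote supervised rule

    dw ~ [S_d(t) - S_a(t)] * (e_H + integral w(dt) S_in(t - dt) d dt)

evaluated discretely: every desired output spike potentiates each incoming
weight by ``e_H`` plus an STDP-window sum over that reservoir neuron's
preceding spikes, and every actual output spike depresses it by the same
quantity.  Classification picks the class whose output neuron's spike train
is closest (van Rossum distance) to its own template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import SpikeRaster
from .reservoir import (
    NeuronParams,
    ReservoirState,
    SimulationResult,
    SynapseParams,
    run_reservoir,
)

__all__ = [
    "LabeledSpikeSet",
    "ReadoutConfig",
    "ReadoutModel",
    "make_templates",
    "van_rossum_distance",
    "resume_step",
    "train_readout",
    "classify",
]


@dataclass
class LabeledSpikeSet:
    """Spike rasters with class labels (the readout's training currency)."""

    items: List[Tuple[SpikeRaster, int]]
    classes: Tuple[int, ...]

    def __post_init__(self):
        if not self.items:
            raise ValueError("labeled set must be non-empty")
        labels = {label for _, label in self.items}
        if not labels.issubset(set(self.classes)):
            raise ValueError("labels must be drawn from the class set")


@dataclass(frozen=True)
class ReadoutConfig:
    """Readout hyper-parameters.

    e_h is the anti-Hebbian offset of the remote supervised rule; the
    learning window reuses the reservoir's STDP potentiation constants
    (a_plus, tau_plus).  ``batch_update`` accumulates weight deltas over the
    training set within a cycle before applying them (the sequential
    per-utterance mode is available but much slower).
    """

    e_h: float = 0.25
    a_plus: float = 0.1
    tau_plus: float = 20.0  # ms
    learning_rate: float = 0.05
    lr_decay_tau: float = 40.0  # cycles; lr_c = lr / (1 + c/tau); 0 disables
    weight_cap: float = 1.0
    init_weight_scale: float = 0.1
    output_gain: float = 400.0  # nA injected per unit weight per reservoir spike
    pulse_width: float = 5.0  # ms, reservoir-spike pulse seen by the output layer
    tau_vr: float = 20.0  # ms, van Rossum kernel
    template_mode: str = "activity"  # "activity" | "periodic"
    template_rate: float = 10.0  # Hz
    template_phase_step: float = 8.0  # ms
    template_spikes: int = 8  # spikes per activity-driven template
    batch_update: bool = True

    def __post_init__(self):
        if self.e_h < 0:
            raise ValueError("e_h must be >= 0")


@dataclass
class ReadoutModel:
    """Trained readout: weights, templates, and the parameters that made them."""

    weights: np.ndarray  # (n_reservoir, n_classes)
    classes: Tuple[int, ...]
    templates: Dict[int, np.ndarray]  # class -> desired spike times (ms)
    duration: float  # ms
    dt: float  # ms
    config: ReadoutConfig
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    input_map: Optional[np.ndarray] = None
    history: Optional[dict] = None


def make_templates(
    classes: Sequence[int],
    duration: float,
    base_rate: float = 10.0,
    phase_step: float = 8.0,
) -> Dict[int, np.ndarray]:
    """Phase-shifted periodic desired spike trains, one per class.

    Class k spikes at ``k * phase_step + i * (1000 / base_rate)`` ms for all
    i with the time inside [0, duration).  Templates are pairwise distinct
    as long as phase_step is not a multiple of the period.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    period = 1000.0 / base_rate
    if duration < 2 * period:
        raise ValueError("duration must allow at least 2 template spikes")
    templates: Dict[int, np.ndarray] = {}
    for rank, c in enumerate(classes):
        offset = (rank * phase_step) % period
        times = np.arange(offset, duration, period)
        templates[int(c)] = times
    keys = list(templates)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = templates[keys[i]], templates[keys[j]]
            if a.size == b.size and np.allclose(a, b):
                raise ValueError(
                    "template parameters yield identical trains for classes "
                    f"{keys[i]} and {keys[j]}"
                )
    return templates


def make_activity_templates(
    train_set: "LabeledSpikeSet",
    duration: float,
    dt: float = 0.5,
    n_spikes: int = 5,
    sigma_ms: float = 10.0,
    min_sep_ms: float = 40.0,
) -> Dict[int, np.ndarray]:
    """Desired spike trains derived from class-specific firing activity.

    For each class, the class-mean population firing histogram is contrasted
    against the mean histogram of all other classes; the ``n_spikes``
    largest peaks of the smoothed difference (kept at least ``min_sep_ms``
    apart) become the desired spike times.  Anchoring the targets where the
    class's liquid activity specifically exceeds the others' makes them both
    reachable (the neuron is driven there) and class-selective (competing
    classes rarely drive firing at those times).
    """
    from scipy.ndimage import gaussian_filter1d

    n_steps = int(round(duration / dt))
    classes = sorted(set(train_set.classes))
    psths = {c: np.zeros(n_steps) for c in classes}
    counts = {c: 0 for c in classes}
    for raster, label in train_set.items:
        dt_raster_ms = raster.dt * 1000.0
        per_step = raster.values.sum(axis=0)
        steps = np.minimum(
            np.round(np.arange(raster.n_timesteps) * dt_raster_ms / dt).astype(int),
            n_steps - 1,
        )
        np.add.at(psths[label], steps, per_step)
        counts[label] += 1
    smoothed = {
        c: gaussian_filter1d(psths[c] / max(counts[c], 1), sigma_ms / dt)
        for c in classes
    }
    templates: Dict[int, np.ndarray] = {}
    for c in classes:
        rest = [smoothed[o] for o in classes if o != c]
        contrast = smoothed[c] - (np.mean(rest, axis=0) if rest else 0.0)
        chosen: list = []
        for idx in np.argsort(contrast)[::-1]:
            t = idx * dt
            if all(abs(t - u) >= min_sep_ms for u in chosen):
                chosen.append(t)
            if len(chosen) == n_spikes:
                break
        templates[int(c)] = np.sort(np.asarray(chosen, dtype=float))
    return templates


def van_rossum_distance(
    times_a: np.ndarray, times_b: np.ndarray, tau: float = 20.0
) -> float:
    """van Rossum distance between two spike-time arrays (ms), kernel tau (ms).

    Uses the closed form D^2 = (1/2) [K(a,a) + K(b,b) - 2 K(a,b)] with
    K(x,y) = sum_ij exp(-|x_i - y_j| / tau), i.e. the L2 distance between
    the exponentially filtered trains (filter normalized so one isolated
    spike has norm 1/sqrt(2)... the conventional unitless form).
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)

    def kernel(x, y):
        if x.size == 0 or y.size == 0:
            return 0.0
        return float(np.exp(-np.abs(x[:, None] - y[None, :]) / tau).sum())

    d2 = 0.5 * (kernel(a, a) + kernel(b, b) - 2.0 * kernel(a, b))
    return float(np.sqrt(max(d2, 0.0)))


def _window_sum(t: float, input_times: np.ndarray, a_plus: float, tau_plus: float) -> float:
    """Causal STDP-window sum over input spikes at or before t."""
    prior = input_times[input_times <= t]
    if prior.size == 0:
        return 0.0
    return float(a_plus * np.exp(-(t - prior) / tau_plus).sum())


def resume_step(
    w: float,
    s_in: np.ndarray,
    s_a: np.ndarray,
    s_d: np.ndarray,
    e_h: float = 0.25,
    a_plus: float = 0.1,
    tau_plus: float = 20.0,
) -> float:
    """Weight delta of the remote supervised rule for one synapse.

    ``s_in``, ``s_a``, ``s_d`` are spike-time arrays (ms) for the input
    (reservoir) neuron, the actual output train, and the desired output
    train.  Returns

        dw = sum_{t in s_d} [e_h + W(t)] - sum_{t in s_a} [e_h + W(t)]

    with W(t) the causal exponential window sum over s_in.  Antisymmetric
    under swapping s_a and s_d.
    """
    s_in = np.asarray(s_in, dtype=float)
    delta = 0.0
    for t in np.asarray(s_d, dtype=float):
        delta += e_h + _window_sum(t, s_in, a_plus, tau_plus)
    for t in np.asarray(s_a, dtype=float):
        delta -= e_h + _window_sum(t, s_in, a_plus, tau_plus)
    return delta


def _dilate_raster(raster: np.ndarray, width_steps: int) -> np.ndarray:
    """Extend each spike into a rectangular pulse of width_steps steps."""
    out = raster.astype(bool).copy()
    for shift in range(1, width_steps):
        out[:, shift:] |= raster[:, : raster.shape[1] - shift].astype(bool)
    return out


def _input_trace(raster: np.ndarray, dt: float, a_plus: float, tau_plus: float) -> np.ndarray:
    """Exponential STDP trace of each reservoir neuron, (n_steps, n_neurons).

    trace[t, j] = a_plus * sum over spikes of j at steps s <= t of
    exp(-(t-s) dt / tau_plus); evaluated recursively.
    """
    n_neurons, n_steps = raster.shape
    decay = np.exp(-dt / tau_plus)
    trace = np.zeros((n_steps, n_neurons), dtype=np.float32)
    cur = np.zeros(n_neurons, dtype=np.float32)
    for t in range(n_steps):
        cur = cur * decay + a_plus * raster[:, t]
        trace[t] = cur
    return trace


def _simulate_outputs(
    weights: np.ndarray,
    pulses: np.ndarray,  # (n_steps, n_utts, n_reservoir) or (n_steps, n_reservoir)
    nparams: NeuronParams,
    dt: float,
    gain: float,
) -> List:
    """LIF simulation of the output layer; returns per-(utt, class) spike steps.

    ``pulses`` may be batched over utterances.  Output spikes are returned
    as a list indexed [utt][class] of step arrays (or [class] when
    unbatched).
    """
    batched = pulses.ndim == 3
    if not batched:
        pulses = pulses[:, None, :]
    n_steps, n_utts, _ = pulses.shape
    n_out = weights.shape[1]
    v = np.full((n_utts, n_out), nparams.v_rest)
    refr = np.zeros((n_utts, n_out))
    spike_steps: List[List[list]] = [
        [[] for _ in range(n_out)] for _ in range(n_utts)
    ]
    for t in range(n_steps):
        current = gain * (pulses[t] @ weights)  # (n_utts, n_out)
        active = refr <= 0
        dv = (dt / nparams.tau_m) * (-(v - nparams.v_rest) + nparams.r_m * current)
        v = np.where(active, v + dv, nparams.v_reset)
        spikes = active & (v >= nparams.v_th)
        v = np.where(spikes, nparams.v_reset, v)
        refr = np.where(spikes, nparams.tau_ref, np.maximum(refr - dt, 0.0))
        for u, k in zip(*np.nonzero(spikes)):
            spike_steps[u][k].append(t)
    result = [
        [np.asarray(s, dtype=int) for s in per_utt] for per_utt in spike_steps
    ]
    return result if batched else result[0]


def train_readout(
    train_set: LabeledSpikeSet,
    cycles: int = 240,
    config: Optional[ReadoutConfig] = None,
    neuron_params: Optional[NeuronParams] = None,
    seed: int = 0,
    duration: Optional[float] = None,
    dt: float = 0.5,
    eval_every: int = 40,
    templates: Optional[Dict[int, np.ndarray]] = None,
) -> ReadoutModel:
    """Train reservoir->output weights with the remote supervised rule.

    ``train_set`` holds *reservoir* rasters (the liquid responses), one per
    utterance.  Per cycle, output LIF neurons are driven through the current
    weights and each output neuron's weights receive the ReSuMe delta with
    desired train = its class template when the utterance matches its class
    and the empty train otherwise.  Records a van Rossum convergence curve
    every ``eval_every`` cycles in ``model.history``.
    """
    config = config or ReadoutConfig()
    neuron_params = neuron_params or NeuronParams()
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    classes = tuple(sorted(set(train_set.classes)))
    n_classes = len(classes)
    class_rank = {c: i for i, c in enumerate(classes)}
    rasters = [item[0] for item in train_set.items]
    labels = [item[1] for item in train_set.items]
    n_reservoir = rasters[0].n_channels
    dt_raster_ms = rasters[0].dt * 1000.0
    max_span = max(r.n_timesteps for r in rasters) * dt_raster_ms
    if duration is None:
        duration = max_span
    n_steps = int(round(duration / dt))
    if templates is None:
        if config.template_mode == "activity":
            templates = make_activity_templates(
                train_set, duration, dt, n_spikes=config.template_spikes
            )
        else:
            templates = make_templates(
                classes, duration, config.template_rate, config.template_phase_step
            )
    template_steps = {
        c: np.minimum(np.round(t / dt).astype(int), n_steps - 1)
        for c, t in templates.items()
    }
    rng = np.random.default_rng(seed)
    weights = config.init_weight_scale * rng.random((n_reservoir, n_classes))
    width_steps = max(1, int(round(config.pulse_width / dt)))
    n_utts = len(rasters)
    pulses = np.zeros((n_steps, n_utts, n_reservoir), dtype=np.float32)
    traces = np.zeros((n_steps, n_utts, n_reservoir), dtype=np.float32)
    desired_term = np.zeros((n_utts, n_reservoir, n_classes), dtype=np.float64)
    for u, r in enumerate(rasters):
        # resample the reservoir raster onto the simulation grid
        grid = np.zeros((n_reservoir, n_steps), dtype=np.uint8)
        ch, ts = np.nonzero(r.values)
        steps = np.minimum(np.round(ts * dt_raster_ms / dt).astype(int), n_steps - 1)
        grid[ch, steps] = 1
        pulses[:, u, :] = _dilate_raster(grid, width_steps).T
        traces[:, u, :] = _input_trace(grid, dt, config.a_plus, config.tau_plus)
        k = class_rank[labels[u]]
        t_d = template_steps[labels[u]]
        desired_term[u, :, k] = (config.e_h + traces[t_d, u, :]).sum(axis=0)
    history = {"cycle": [], "mean_vr_distance": []}

    def record(cycle, actual):
        dists = []
        for u in range(n_utts):
            k = class_rank[labels[u]]
            a_times = actual[u][k] * dt
            d_times = template_steps[labels[u]] * dt
            dists.append(van_rossum_distance(a_times, d_times, config.tau_vr))
        history["cycle"].append(cycle)
        history["mean_vr_distance"].append(float(np.mean(dists)))

    for cycle in range(1, cycles + 1):
        if config.lr_decay_tau > 0:
            lr = config.learning_rate / (1.0 + cycle / config.lr_decay_tau)
        else:
            lr = config.learning_rate
        if config.batch_update:
            actual = _simulate_outputs(
                weights, pulses, neuron_params, dt, config.output_gain
            )
            delta = desired_term.sum(axis=0)
            for u in range(n_utts):
                for k in range(n_classes):
                    steps = actual[u][k]
                    if steps.size:
                        delta[:, k] -= (
                            config.e_h + traces[steps, u, :]
                        ).sum(axis=0)
            weights = weights + lr * delta / n_utts
        else:
            actual = []
            for u in range(n_utts):
                acts = _simulate_outputs(
                    weights, pulses[:, u, :], neuron_params, dt, config.output_gain
                )
                actual.append(acts)
                delta = desired_term[u].copy()
                for k in range(n_classes):
                    steps = acts[k]
                    if steps.size:
                        delta[:, k] -= (config.e_h + traces[steps, u, :]).sum(axis=0)
                weights = weights + lr * delta
                np.clip(weights, -config.weight_cap, config.weight_cap, out=weights)
        np.clip(weights, -config.weight_cap, config.weight_cap, out=weights)
        if cycle == 1 or cycle % eval_every == 0 or cycle == cycles:
            record(cycle, actual)
    return ReadoutModel(
        weights=weights,
        classes=classes,
        templates=templates,
        duration=duration,
        dt=dt,
        config=config,
        neuron_params=neuron_params,
        history=history,
    )


def output_spike_times(model: ReadoutModel, reservoir_raster: SpikeRaster) -> Dict[int, np.ndarray]:
    """Actual output-layer spike times (ms) for one reservoir response."""
    cfg = model.config
    dt = model.dt
    n_steps = int(round(model.duration / dt))
    n_reservoir = reservoir_raster.n_channels
    dt_raster_ms = reservoir_raster.dt * 1000.0
    grid = np.zeros((n_reservoir, n_steps), dtype=np.uint8)
    ch, ts = np.nonzero(reservoir_raster.values)
    steps = np.minimum(np.round(ts * dt_raster_ms / dt).astype(int), n_steps - 1)
    grid[ch, steps] = 1
    width_steps = max(1, int(round(cfg.pulse_width / dt)))
    pulses = _dilate_raster(grid, width_steps).T.astype(np.float32)
    acts = _simulate_outputs(
        model.weights, pulses, model.neuron_params, dt, cfg.output_gain
    )
    return {
        c: acts[i] * dt for i, c in enumerate(model.classes)
    }


def classify(model: ReadoutModel, reservoir_raster: SpikeRaster) -> int:
    """Class whose output neuron best reproduces its own template.

    Ties break toward the lowest class index.
    """
    if model.weights is None:
        raise ValueError("model is untrained")
    actual = output_spike_times(model, reservoir_raster)
    best_class, best_dist = None, np.inf
    for c in model.classes:  # sorted ascending, so ties keep the lowest
        d = van_rossum_distance(actual[c], model.templates[c], model.config.tau_vr)
        if d < best_dist:
            best_class, best_dist = c, d
    return int(best_class)
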