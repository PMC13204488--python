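"""Firing-pattern and information-transmission analytics.

Separability of class-evoked firing is quantified with a one-way ANOVA on
per-timebin population spike counts (one group per stimulus class).
Information-transmission structure of the weighted synapse graph is
summarized by synaptic density (non-zero synapses per neuron), the weighted
clustering coefficient C_w, and the weighted shortest path length L_w
(edge length = 1 / weight).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path

from .encoding import SpikeRaster
from .reservoir import SimulationResult, SynapseTable

__all__ = [
    "AnovaResult",
    "WeightedGraphView",
    "firing_counts",
    "oneway_anova",
    "synaptic_density",
    "weighted_cc",
    "weighted_spl",
    "SplResult",
    "symmetrize_synapses",
]


class AnovaResult(NamedTuple):
    f_value: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


class SplResult(NamedTuple):
    l_w: Optional[float]
    reachable_fraction: float
    defined: bool


@dataclass(frozen=True)
class WeightedGraphView:
    """Symmetric non-negative weight matrix with implied binary adjacency."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        a = self.weights > 0
        np.fill_diagonal(a, False)
        return a


def firing_counts(result, bin_ms: float = 1.0) -> np.ndarray:
    """Population spike count per time bin, summed over neurons.

    ``result`` may be a SimulationResult or a SpikeRaster.
    """
    raster = result.raster if isinstance(result, SimulationResult) else result
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    dt_ms = raster.dt * 1000.0
    duration = raster.n_timesteps * dt_ms
    if bin_ms > duration:
        raise ValueError("bin exceeds raster duration")
    per_step = raster.values.sum(axis=0)
    steps_per_bin = bin_ms / dt_ms
    n_bins = int(np.floor(raster.n_timesteps / steps_per_bin + 1e-9))
    edges = np.round(np.arange(n_bins + 1) * steps_per_bin).astype(int)
    return np.array(
        [per_step[edges[i] : edges[i + 1]].sum() for i in range(n_bins)],
        dtype=float,
    )


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degenerate inputs (zero pooled within-group variance) are flagged
    rather than returning a silent infinity.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        return AnovaResult(
            f_value=np.nan,
            p_value=np.nan,
            df_between=df_between,
            df_within=df_within,
            degenerate=True,
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_value=float(f),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        degenerate=False,
    )


def synaptic_density(synapses: SynapseTable, n_neurons: int) -> float:
    """Active (non-zero-weight) synapses per neuron."""
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    return float((synapses.g > 0).sum()) / n_neurons


def symmetrize_synapses(synapses: SynapseTable, n_neurons: int) -> WeightedGraphView:
    """Directed synapse table -> undirected weighted graph view.

    The undirected weight of {i, j} is the mean of the two directed weights
    (a missing direction counts as 0).
    """
    w = np.zeros((n_neurons, n_neurons))
    np.add.at(w, (synapses.pre, synapses.post), synapses.g)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraphView(weights=w)


def weighted_cc(g: WeightedGraphView) -> float:
    """Weighted clustering coefficient C_w.

    Node term: 1 / (s_i (D_i - 1)) * sum over ordered neighbour pairs
    (j, k), j != k, of ((g_ij + g_ik) / 2) a_ij a_jk a_ki; C_w is the mean
    over nodes (degree < 2 nodes contribute 0).  With uniform weights this
    reduces exactly to the binary clustering coefficient.
    """
    w = g.weights
    a = g.adjacency.astype(float)
    n = g.n_nodes
    strength = (w * a).sum(axis=1)
    degree = a.sum(axis=1)
    terms = np.zeros(n)
    for i in range(n):
        if degree[i] < 2:
            continue
        nbrs = np.flatnonzero(a[i])
        acc = 0.0
        for j in nbrs:
            for k in nbrs:
                if j == k or a[j, k] == 0:
                    continue
                acc += (w[i, j] + w[i, k]) / 2.0
        terms[i] = acc / (strength[i] * (degree[i] - 1))
    return float(terms.mean())


def weighted_spl(g: WeightedGraphView) -> SplResult:
    """Weighted shortest path length L_w with edge length 1 / g_mn.

    Averages the shortest-path distances over ordered reachable node pairs;
    unreachable pairs are excluded and reported through
    ``reachable_fraction``.  For a connected graph this equals the
    1/(N(N-1)) normalized pair sum.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    a = g.adjacency
    if not a.any():
        return SplResult(l_w=None, reachable_fraction=0.0, defined=False)
    lengths = np.zeros_like(g.weights)
    lengths[a] = 1.0 / g.weights[a]
    dist = shortest_path(sparse.csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(dist) & off
    frac = reachable.sum() / off.sum()
    if not reachable.any():
        return SplResult(l_w=None, reachable_fraction=0.0, defined=False)
    return SplResult(
        l_w=float(dist[reachable].mean()),
        reachable_fraction=float(frac),
        defined=True,
    )
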