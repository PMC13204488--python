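"""Functional brain network construction and characterization.

Nodes are parcellated brain regions, edges are supra-threshold Pearson
correlations between regional BOLD time series.  The module also provides
the algorithmic comparison topologies (Watts-Strogatz ring/small-world/random
and Barabasi-Albert scale-free graphs) and the two graph-level summary
statistics used to characterize them: the small-world index (delta) and the
power-law degree exponent (gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import optimize, special

__all__ = [
    "RegionalBoldMatrix",
    "CorrelationMatrix",
    "Topology",
    "GraphMetrics",
    "GammaFit",
    "compute_correlation_matrix",
    "build_functional_graph",
    "network_density",
    "threshold_density_sweep",
    "small_world_index",
    "scale_free_exponent",
    "generate_ws_topology",
    "generate_ba_topology",
]

#: Default correlation threshold for declaring a functional edge.
DEFAULT_X_TH = 0.3
#: Default threshold increment for density sweeps.
DEFAULT_SWEEP_STEP = 0.05
#: Density range reported for biological brain networks.
BIOLOGICAL_DENSITY_RANGE = (0.036, 0.393)


@dataclass(frozen=True)
class RegionalBoldMatrix:
    """Regional BOLD time series: one row per brain region.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_samples)
        Mean BOLD signal per region (arbitrary units).
    region_labels : sequence of str
        One identifier per region (e.g. AAL region names).
    sampling_interval : float
        Seconds per sample (the scanner repetition time).
    """

    values: np.ndarray
    region_labels: tuple
    sampling_interval: float = 1.5

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if values.ndim != 2:
            raise ValueError("BOLD matrix must be 2-D (regions x samples)")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if values.shape[1] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(values)):
            raise ValueError("BOLD values must be finite")
        if len(self.region_labels) != values.shape[0]:
            raise ValueError("one label per region required")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Region-by-region Pearson correlation matrix."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(values) > 1.0 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Topology:
    """Undirected simple graph used as a reservoir wiring scaffold."""

    n_nodes: int
    edges: frozenset
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        edges = frozenset(
            tuple(sorted((int(u), int(v)))) for (u, v) in self.edges
        )
        object.__setattr__(self, "edges", edges)
        for u, v in edges:
            if u == v:
                raise ValueError("self-loops not allowed")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError("node index out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for u, v in self.edges:
            a[u, v] = a[v, u] = True
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


class GraphMetrics(NamedTuple):
    """Density plus (possibly undefined) small-world and scale-free indices."""

    density: float
    delta: Optional[float]
    gamma: Optional[float]


class GammaFit(NamedTuple):
    """Discrete power-law exponent fit for a degree distribution."""

    gamma: Optional[float]
    defined: bool
    x_min: Optional[int]
    n_tail: int


def compute_correlation_matrix(bold: RegionalBoldMatrix) -> CorrelationMatrix:
    """Pearson correlation between every pair of regional BOLD series.

    Raises
    ------
    ValueError
        If any region's time series has zero variance (the correlation is
        undefined there); the error message names the offending region.
    """
    x = bold.values
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        label = bold.region_labels[zero[0]]
        raise ValueError(
            f"region {label!r} (index {zero[0]}) has zero variance; "
            "correlation undefined"
        )
    r = np.corrcoef(x)
    # guard tiny numerical overshoot so the invariants hold exactly
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=(r + r.T) / 2.0)


def build_functional_graph(
    corr: CorrelationMatrix,
    x_th: float = DEFAULT_X_TH,
    use_absolute: bool = True,
) -> Topology:
    """Threshold a correlation matrix into a binary functional graph.

    An edge (i, j) exists iff ``|R_ij| > x_th`` (strict).  With
    ``use_absolute=False``, the signed value ``R_ij > x_th`` is used instead,
    i.e. negative correlations never produce edges.
    """
    if not (0.0 <= x_th <= 1.0):
        raise ValueError("x_th must lie in [0, 1]")
    r = corr.values
    n = corr.n_regions
    strength = np.abs(r) if use_absolute else r
    iu, ju = np.triu_indices(n, k=1)
    mask = strength[iu, ju] > x_th
    edges = frozenset(zip(iu[mask].tolist(), ju[mask].tolist()))
    meta = {
        "generator": "functional_graph",
        "x_th": float(x_th),
        "use_absolute": use_absolute,
    }
    return Topology(n_nodes=n, edges=edges, meta=meta)


def network_density(top: Topology) -> float:
    """Edges as a fraction of the n(n-1)/2 possible edges."""
    if top.n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    max_edges = top.n_nodes * (top.n_nodes - 1) / 2
    return top.n_edges / max_edges


def threshold_density_sweep(
    corrs: Sequence[CorrelationMatrix],
    step: float = DEFAULT_SWEEP_STEP,
    use_absolute: bool = True,
):
    """Mean and SD of graph density over subjects at each threshold.

    Thresholds run over {0, step, 2*step, ..., 1}.  Returns a dict with
    keys ``thresholds``, ``mean_density``, ``sd_density`` (each an ndarray).
    """
    if len(corrs) == 0:
        raise ValueError("need at least one correlation matrix")
    if not (0.0 < step <= 1.0):
        raise ValueError("step must lie in (0, 1]")
    n_steps = int(np.floor(1.0 / step + 1e-9)) + 1
    thresholds = np.minimum(np.arange(n_steps) * step, 1.0)
    if thresholds[-1] < 1.0:
        thresholds = np.append(thresholds, 1.0)
    dens = np.empty((len(corrs), thresholds.size))
    for i, c in enumerate(corrs):
        for j, th in enumerate(thresholds):
            g = build_functional_graph(c, th, use_absolute=use_absolute)
            dens[i, j] = network_density(g)
    return {
        "thresholds": thresholds,
        "mean_density": dens.mean(axis=0),
        "sd_density": dens.std(axis=0),
    }


def _binary_clustering_and_path(g: nx.Graph):
    c = nx.average_clustering(g)
    length = nx.average_shortest_path_length(g)
    return c, length


def small_world_index(
    top: Topology,
    n_reference: int = 20,
    seed: int = 0,
    max_retries: int = 50,
) -> float:
    """Small-world index delta = (C/C_rand) / (L/L_rand).

    C and L are the binary clustering coefficient and characteristic path
    length; C_rand and L_rand are averages over ``n_reference`` uniform
    random graphs with the same node and edge counts.  A graph is considered
    small-world when delta > 1.
    """
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    g = top.to_networkx()
    if top.n_nodes < 3:
        raise ValueError("small-world index needs at least 3 nodes")
    if not nx.is_connected(g):
        raise ValueError("small-world index requires a connected graph")
    c, length = _binary_clustering_and_path(g)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    attempts = 0
    while len(c_rand) < n_reference:
        attempts += 1
        if attempts > n_reference + max_retries:
            raise RuntimeError(
                "could not sample enough connected reference graphs"
            )
        ref = nx.gnm_random_graph(
            top.n_nodes, top.n_edges, seed=int(rng.integers(2**31))
        )
        if not nx.is_connected(ref):
            continue  # L undefined; resample
        cr, lr = _binary_clustering_and_path(ref)
        if cr == 0:
            continue
        c_rand.append(cr)
        l_rand.append(lr)
    c_rand = float(np.mean(c_rand))
    l_rand = float(np.mean(l_rand))
    return (c / c_rand) / (length / l_rand)


def _powerlaw_mle(degrees: np.ndarray, x_min: int) -> float:
    """Discrete MLE for P(k) ~ k^-gamma, k >= x_min (Hurwitz-zeta likelihood)."""
    tail = degrees[degrees >= x_min].astype(float)
    log_sum = np.log(tail).sum()
    n = tail.size

    def nll(gamma):
        return n * np.log(special.zeta(gamma, x_min)) + gamma * log_sum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


_GAMMA_UPPER = 8.0 - 1e-3  # MLE at the search bound means no power-law tail


def _ks_distance(degrees: np.ndarray, x_min: int, gamma: float) -> float:
    tail = np.sort(degrees[degrees >= x_min])
    ks = np.arange(x_min, tail.max() + 1)
    pmf = ks ** (-gamma) / special.zeta(gamma, x_min)
    cdf_model = np.cumsum(pmf)
    cdf_emp = np.searchsorted(tail, ks, side="right") / tail.size
    return float(np.max(np.abs(cdf_emp - cdf_model)))


def scale_free_exponent(top_or_degrees, x_min="min") -> GammaFit:
    """Fit the degree-distribution power-law exponent gamma by discrete MLE.

    Parameters
    ----------
    top_or_degrees : Topology or array-like of int
        Graph, or a raw degree sequence.
    x_min : "min", "auto", or int
        Lower cut-off of the fitted tail.  ``"min"`` (default) uses the
        smallest positive degree; ``"auto"`` selects the cut-off minimizing
        the Kolmogorov-Smirnov distance between the fitted model and the
        empirical tail (Clauset-style); an int fixes it explicitly.

    Returns
    -------
    GammaFit
        ``defined`` is False (and gamma None) for degenerate degree
        distributions with fewer than 3 distinct positive values.
    """
    if isinstance(top_or_degrees, Topology):
        degrees = top_or_degrees.degrees()
    else:
        degrees = np.asarray(top_or_degrees, dtype=int)
    degrees = degrees[degrees > 0]
    if np.unique(degrees).size < 3:
        return GammaFit(gamma=None, defined=False, x_min=None, n_tail=0)
    if x_min == "min":
        xm = int(degrees.min())
    elif x_min == "auto":
        candidates = np.unique(degrees)
        # keep at least 10 tail points and cap candidate count for speed
        candidates = [
            int(x) for x in candidates if (degrees >= x).sum() >= 10
        ][:50]
        best, best_ks = None, np.inf
        for cand in candidates:
            if np.unique(degrees[degrees >= cand]).size < 3:
                continue
            gam = _powerlaw_mle(degrees, cand)
            ks = _ks_distance(degrees, cand, gam)
            if ks < best_ks:
                best, best_ks = cand, ks
        if best is None:
            return GammaFit(gamma=None, defined=False, x_min=None, n_tail=0)
        xm = best
    else:
        xm = int(x_min)
    gamma = _powerlaw_mle(degrees, xm)
    if gamma >= _GAMMA_UPPER:
        # likelihood pushed to the boundary: the degree distribution decays
        # faster than any power law (e.g. the peaked degrees of a dense
        # modular graph); flag rather than report the bound
        return GammaFit(gamma=None, defined=False, x_min=xm, n_tail=0)
    return GammaFit(
        gamma=gamma, defined=True, x_min=xm, n_tail=int((degrees >= xm).sum())
    )


def graph_metrics(
    top: Topology, n_reference: int = 20, seed: int = 0
) -> GraphMetrics:
    """Density plus delta and gamma, flagging either as None when undefined."""
    density = network_density(top)
    try:
        delta = small_world_index(top, n_reference=n_reference, seed=seed)
    except (ValueError, RuntimeError):
        delta = None
    fit = scale_free_exponent(top)
    gamma = fit.gamma if fit.defined else None
    return GraphMetrics(density=density, delta=delta, gamma=gamma)


def generate_ws_topology(n: int, k: int, p: float, seed: int = 0) -> Topology:
    """Watts-Strogatz graph: ring lattice with probabilistic rewiring.

    Starts from a ring where each node connects to its k/2 nearest
    neighbours on each side, then rewires each original edge (u, v) with
    probability p to (u, w) for a uniformly random w, avoiding self-loops
    and duplicates.  Edge count nk/2 is conserved for every p.
    """
    if not (n > k >= 2):
        raise ValueError("require n > k >= 2")
    if k % 2 != 0:
        raise ValueError("k must be even")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = set()
    for u in range(n):
        for offset in range(1, k // 2 + 1):
            v = (u + offset) % n
            edges.add(tuple(sorted((u, v))))
    if p > 0:
        for u, v in sorted(edges):
            if rng.random() < p:
                # rewire keeping endpoint u
                candidates = [
                    w
                    for w in range(n)
                    if w != u and tuple(sorted((u, w))) not in edges
                ]
                if not candidates:
                    continue
                w = candidates[rng.integers(len(candidates))]
                edges.discard((u, v))
                edges.add(tuple(sorted((u, w))))
    meta = {"generator": "watts_strogatz", "n": n, "k": k, "p": p, "seed": seed}
    return Topology(n_nodes=n, edges=frozenset(edges), meta=meta)


def generate_ba_topology(m0: int, me: int, n: int, seed: int = 0) -> Topology:
    """Barabasi-Albert graph grown from a complete seed graph.

    Each new node attaches ``me`` edges to existing nodes chosen with
    probability proportional to current degree (no duplicates/self-loops).
    """
    if not (1 <= me <= m0 <= n):
        raise ValueError("require 1 <= me <= m0 <= n")
    rng = np.random.default_rng(seed)
    edges = set()
    degree = np.zeros(n, dtype=np.int64)
    for u in range(m0):
        for v in range(u + 1, m0):
            edges.add((u, v))
            degree[u] += 1
            degree[v] += 1
    for new in range(m0, n):
        targets: set = set()
        while len(targets) < me:
            existing = degree[:new].astype(float)
            probs = existing / existing.sum()
            t = int(rng.choice(new, p=probs))
            targets.add(t)
        for t in targets:
            edges.add(tuple(sorted((new, t))))
            degree[new] += 1
            degree[t] += 1
    meta = {
        "generator": "barabasi_albert",
        "m0": m0,
        "me": me,
        "n": n,
        "seed": seed,
    }
    return Topology(n_nodes=n, edges=frozenset(edges), meta=meta)
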