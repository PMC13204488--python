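"""Functional-graph construction, characterization and generators."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurolsm import (
    CorrelationMatrix,
    RegionalBoldMatrix,
    Topology,
    build_functional_graph,
    compute_correlation_matrix,
    generate_ba_topology,
    generate_ws_topology,
    network_density,
    scale_free_exponent,
    small_world_index,
    threshold_density_sweep,
)
from neurolsm.fbn import BIOLOGICAL_DENSITY_RANGE


def pearson_oracle(x, y):
    """Direct element-wise evaluation of the correlation formula."""
    xm, ym = x.mean(), y.mean()
    num = ((x - xm) * (y - ym)).sum()
    den = np.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
    return num / den


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, bold_small):
        corr = compute_correlation_matrix(bold_small)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(8)
        bold = RegionalBoldMatrix(
            values=np.vstack([row, -row]),
            region_labels=["a", "b"],
            sampling_interval=1.0,
        )
        corr = compute_correlation_matrix(bold)
        assert corr.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((3, 5))
        bold = RegionalBoldMatrix(
            values=x, region_labels=["a", "b", "c"], sampling_interval=1.0
        )
        corr = compute_correlation_matrix(bold)
        for i in range(3):
            for j in range(3):
                assert corr.values[i, j] == pytest.approx(
                    pearson_oracle(x[i], x[j]), abs=1e-12
                )

    def test_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.standard_normal((5, 10))
            bold = RegionalBoldMatrix(
                values=x,
                region_labels=[f"r{i}" for i in range(5)],
                sampling_interval=1.0,
            )
            corr = compute_correlation_matrix(bold)
            for i in range(5):
                for j in range(5):
                    assert corr.values[i, j] == pytest.approx(
                        pearson_oracle(x[i], x[j]), abs=1e-12
                    )

    def test_zero_variance_region_rejected(self):
        bold = RegionalBoldMatrix(
            values=np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]),
            region_labels=["flat", "ok"],
            sampling_interval=1.0,
        )
        with pytest.raises(ValueError, match="flat"):
            compute_correlation_matrix(bold)


def corr_from_upper(n, entries):
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = entries
    m = m + m.T - np.diag(np.diag(m)) + np.eye(n) - np.eye(n)
    np.fill_diagonal(m, 1.0)
    return CorrelationMatrix(values=m)


class TestFunctionalGraph:
    def test_threshold_above_max_gives_empty_graph(self, bold_small):
        corr = compute_correlation_matrix(bold_small)
        off = np.abs(corr.values[np.triu_indices(5, k=1)]).max()
        top = build_functional_graph(corr, min(1.0, off + 1e-6))
        assert top.n_edges == 0

    def test_zero_threshold_gives_complete_graph(self, bold_small):
        corr = compute_correlation_matrix(bold_small)
        top = build_functional_graph(corr, 0.0)
        assert top.n_edges == 5 * 4 // 2

    def test_exact_threshold_selection(self):
        entries = [0.2, 0.25, 0.31, 0.4, 0.5, 0.29]
        corr = corr_from_upper(4, entries)
        top = build_functional_graph(corr, 0.3)
        iu = np.array(np.triu_indices(4, k=1)).T
        expected = {
            tuple(pair) for pair, e in zip(map(tuple, iu), entries) if e > 0.3
        }
        assert top.edges == frozenset(expected)
        assert top.n_edges == 3
        assert top.meta["x_th"] == 0.3

    def test_monotone_in_threshold(self, bold_subjects):
        corr = compute_correlation_matrix(bold_subjects[0])
        prev = None
        for th in np.linspace(0, 1, 11):
            edges = build_functional_graph(corr, th).edges
            if prev is not None:
                assert edges.issubset(prev)
            prev = edges

    def test_signed_mode_drops_negative_correlations(self):
        corr = corr_from_upper(3, [-0.9, 0.5, 0.1])
        top = build_functional_graph(corr, 0.3, use_absolute=False)
        assert top.edges == frozenset({(0, 2)})


class TestDensity:
    def test_toy_fixture_densities(self, fixtures):
        assert network_density(fixtures["complete5"]["value"]) == 1.0
        ring = fixtures["ring6"]["value"]
        assert network_density(ring) == pytest.approx(
            fixtures["ring6"]["expected_density"]
        )
        assert network_density(Topology(n_nodes=4, edges=frozenset())) == 0.0

    def test_synthetic_fbn_density_in_biological_range(self, bold_subjects):
        lo, hi = BIOLOGICAL_DENSITY_RANGE
        for bold in bold_subjects:
            corr = compute_correlation_matrix(bold)
            d = network_density(build_functional_graph(corr, 0.3))
            assert lo <= d <= hi


class TestDensitySweep:
    def test_single_matrix_has_zero_sd(self, bold_subjects):
        corr = compute_correlation_matrix(bold_subjects[0])
        res = threshold_density_sweep([corr])
        assert np.all(res["sd_density"] == 0.0)

    def test_zero_threshold_counts_nonzero_pairs(self, bold_subjects):
        corr = compute_correlation_matrix(bold_subjects[0])
        res = threshold_density_sweep([corr])
        n = corr.n_regions
        iu = np.triu_indices(n, k=1)
        frac = (np.abs(corr.values[iu]) > 0).mean()
        assert res["mean_density"][0] == pytest.approx(frac)

    def test_curve_matches_compositional_recompute(self, bold_subjects):
        corrs = [compute_correlation_matrix(b) for b in bold_subjects]
        res = threshold_density_sweep(corrs, step=0.25)
        for j, th in enumerate(res["thresholds"]):
            dens = [
                network_density(build_functional_graph(c, th)) for c in corrs
            ]
            assert res["mean_density"][j] == pytest.approx(np.mean(dens))
            assert res["sd_density"][j] == pytest.approx(np.std(dens))

    def test_mean_curve_non_increasing(self, bold_subjects):
        corrs = [compute_correlation_matrix(b) for b in bold_subjects]
        res = threshold_density_sweep(corrs)
        assert np.all(np.diff(res["mean_density"]) <= 1e-12)
        # no off-diagonal |R| reaches 1, so the curve ends at zero
        assert res["mean_density"][-1] == 0.0


class TestSmallWorldIndex:
    def test_random_graph_delta_near_one(self):
        g = nx.gnm_random_graph(90, 400, seed=5)
        assert nx.is_connected(g)
        top = Topology(n_nodes=90, edges=frozenset(g.edges()))
        delta = small_world_index(top, n_reference=20, seed=1)
        assert delta == pytest.approx(1.0, abs=0.15)

    def test_ws_graph_is_small_world(self):
        top = generate_ws_topology(90, 8, 0.1, seed=2)
        delta = small_world_index(top, n_reference=20, seed=1)
        assert delta > 1.0

    def test_disconnected_graph_rejected(self):
        top = Topology(n_nodes=4, edges=frozenset({(0, 1), (2, 3)}))
        with pytest.raises(ValueError, match="connected"):
            small_world_index(top)

    def test_deterministic_given_seed(self):
        top = generate_ws_topology(60, 6, 0.2, seed=3)
        d1 = small_world_index(top, n_reference=5, seed=9)
        d2 = small_world_index(top, n_reference=5, seed=9)
        assert d1 == d2


class TestScaleFreeExponent:
    def test_recovers_planted_exponent(self):
        rng = np.random.default_rng(7)
        gamma = 2.5
        ks = np.arange(1, 2000)
        pmf = ks ** (-gamma)
        pmf /= pmf.sum()
        degrees = rng.choice(ks, size=2000, p=pmf)
        fit = scale_free_exponent(degrees)
        assert fit.defined
        assert fit.gamma == pytest.approx(gamma, abs=0.15)

    def test_ba_graph_exponent_near_three(self):
        # preferential attachment is k^-3 only asymptotically; the exact
        # degree law ~ 1/(k(k+1)(k+2)) bends below 3 at small k, so the
        # asymptotic exponent is recovered from the tail (x_min = 10)
        top = generate_ba_topology(m0=3, me=3, n=5000, seed=4)
        fit = scale_free_exponent(top, x_min=10)
        assert fit.defined
        assert fit.gamma == pytest.approx(3.0, abs=0.25)

    def test_regular_graph_flagged_undefined(self):
        ring = generate_ws_topology(20, 4, 0.0, seed=0)
        fit = scale_free_exponent(ring)
        assert not fit.defined
        assert fit.gamma is None


class TestGenerators:
    def test_ring_lattice_closed_form_clustering(self):
        top = generate_ws_topology(10, 4, 0.0, seed=0)
        assert all(d == 4 for d in top.degrees())
        cc = nx.average_clustering(top.to_networkx())
        k = 4
        assert cc == pytest.approx(3 * (k - 2) / (4 * (k - 1)))  # = 0.5
        assert top.n_edges == 10 * 4 // 2

    @given(p=st.floats(0.0, 1.0), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_ws_edge_count_conserved(self, p, seed):
        top = generate_ws_topology(30, 6, p, seed=seed)
        assert top.n_edges == 30 * 6 // 2
        assert all(u != v for u, v in top.edges)

    def test_ws_full_rewiring_stays_simple(self):
        top = generate_ws_topology(50, 6, 1.0, seed=1)
        assert top.n_edges == 150
        assert all(u != v for u, v in top.edges)

    def test_ba_complete_seed(self):
        top = generate_ba_topology(m0=5, me=2, n=5, seed=0)
        assert top.n_edges == 10

    def test_ba_edge_count_closed_form(self):
        top = generate_ba_topology(m0=5, me=2, n=50, seed=0)
        assert top.n_edges == 10 + 2 * 45

    def test_ba_new_nodes_have_min_degree(self):
        top = generate_ba_topology(m0=5, me=3, n=60, seed=2)
        deg = top.degrees()
        assert np.all(deg[5:] >= 3)

    def test_generators_deterministic(self):
        a = generate_ws_topology(40, 4, 0.3, seed=8)
        b = generate_ws_topology(40, 4, 0.3, seed=8)
        assert a.edges == b.edges
        a = generate_ba_topology(4, 2, 40, seed=8)
        b = generate_ba_topology(4, 2, 40, seed=8)
        assert a.edges == b.edges

    @pytest.mark.parametrize(
        "call",
        [
            lambda: generate_ws_topology(10, 11, 0.1),
            lambda: generate_ws_topology(10, 3, 0.1),
            lambda: generate_ws_topology(10, 4, 1.5),
            lambda: generate_ba_topology(2, 3, 10),
        ],
    )
    def test_generator_parameter_validation(self, call):
        with pytest.raises(ValueError):
            call()
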