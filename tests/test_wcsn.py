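"""Per-cell network construction: windows, statistic, edges, transforms.

The optimized builder is checked bit-for-bit against a brute-force oracle
that sorts distances explicitly, counts joint window membership with a
double loop, and evaluates the statistic arithmetic directly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcsgnet.simulate import simulate_independent_pair
from wcsgnet.wcsn import (
    WcsnConfig,
    build_cell_network,
    build_test_network,
    build_training_networks,
    critical_value,
    pair_statistic,
    transform_weights,
    window_members,
    window_size,
)


def brute_force_network(E0, k, box=0.1, alpha=0.01):
    """Independent oracle: explicit sorting and double-loop counting."""
    n, p = E0.shape
    m = max(1, round(box * n))
    z = critical_value(alpha)
    windows = {}
    for u in range(p):
        if E0[k, u] <= 0:
            continue
        d = np.abs(E0[:, u] - E0[k, u])
        order = sorted(range(n), key=lambda i: (d[i], i))
        windows[u] = set(order[:m])
    edges = []
    for u in sorted(windows):
        for v in sorted(windows):
            if v <= u:
                continue
            n_uv = len(windows[u] & windows[v])
            rho = (
                math.sqrt(n - 1)
                * (n * n_uv - m * m)
                / math.sqrt(m * m * (n - m) * (n - m))
            )
            if rho > z:
                edges.append((u, v, rho))
    return edges


class TestWindowMembers:
    def test_contiguous_window_on_grid(self):
        values = np.arange(1.0, 101.0)
        members = window_members(values, 49, 0.1)
        assert len(members) == 10
        assert 49 in members
        span = values[members]
        assert span.max() - span.min() == 9  # contiguous run of values

    def test_m_equal_one_returns_anchor(self):
        values = np.arange(1.0, 21.0)
        assert list(window_members(values, 5, 0.049)) == [5]

    def test_containment_and_cardinality(self, rng):
        values = rng.normal(size=50) ** 2 + 0.1
        for k in [0, 7, 49]:
            members = window_members(values, k, 0.2)
            assert k in members
            assert len(members) == window_size(50, 0.2)

    def test_zero_anchor_rejected(self):
        values = np.ones(20)
        values[3] = 0.0
        with pytest.raises(ValueError):
            window_members(values, 3, 0.1)


class TestPairStatistic:
    def test_independence_point_is_zero(self):
        assert pair_statistic(100, 10, 10, 1).rho_norm == 0.0

    def test_perfect_cooccurrence(self):
        s = pair_statistic(100, 10, 10, 10)
        assert s.rho_norm == pytest.approx(math.sqrt(99), rel=1e-12)

    def test_worked_value_exceeds_critical(self):
        s = pair_statistic(200, 20, 20, 5)
        assert s.rho_norm == pytest.approx(math.sqrt(199) * 600 / 3600, rel=1e-12)
        assert s.rho_norm > critical_value(0.01)

    def test_rho_norm_consistent_with_rho_over_sigma(self):
        s = pair_statistic(150, 15, 20, 8)
        assert s.rho_norm == pytest.approx(s.rho / s.sigma, rel=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_symmetry_and_bounds(self, data):
        n = data.draw(st.integers(min_value=10, max_value=300))
        n_u = data.draw(st.integers(min_value=1, max_value=n - 1))
        n_v = data.draw(st.integers(min_value=1, max_value=n - 1))
        n_uv = data.draw(st.integers(min_value=0, max_value=min(n_u, n_v)))
        a = pair_statistic(n, n_u, n_v, n_uv)
        b = pair_statistic(n, n_v, n_u, n_uv)
        assert a.rho_norm == pytest.approx(b.rho_norm, rel=1e-12)
        assert a.sigma > 0

    def test_degenerate_windows_rejected(self):
        with pytest.raises(ValueError):
            pair_statistic(100, 0, 10, 0)
        with pytest.raises(ValueError):
            pair_statistic(100, 100, 10, 10)


class TestCriticalValue:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.5, 0.0), (0.01, 2.3263478740408408), (0.025, 1.959963984540054)],
    )
    def test_quantiles(self, alpha, expected):
        assert critical_value(alpha) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range(self):
        for bad in (0.0, -0.1, 0.7):
            with pytest.raises(ValueError):
                critical_value(bad)


class TestBuildCellNetwork:
    def test_zero_expression_gene_has_no_edges(self, rng):
        E0 = rng.lognormal(size=(60, 5))
        E0[10, 2] = 0.0
        net = build_cell_network(E0, 10)
        assert 2 not in set(net.u.tolist()) | set(net.v.tolist())

    def test_duplicated_gene_gives_sqrt_n_minus_1(self, rng):
        """Identical columns share windows: n_uv = n_u = n_v = m, so the
        statistic collapses to sqrt(n-1), significant for any n >= 7."""
        for n in (7, 30, 100):
            x = rng.permutation(np.arange(1.0, n + 1))
            E0 = np.column_stack([x, x])
            net = build_cell_network(E0, 0)
            assert net.n_edges == 1
            assert net.weight[0] == pytest.approx(math.sqrt(n - 1), rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(10, 61))
            p = int(rng.integers(2, 9))
            E0 = rng.lognormal(size=(n, p))
            E0[rng.random((n, p)) < 0.2] = 0.0
            k = int(rng.integers(n))
            net = build_cell_network(E0, k)
            mine = [
                (int(u), int(v), float(w))
                for u, v, w in zip(net.u, net.v, net.weight)
            ]
            assert mine == brute_force_network(E0, k)

    def test_column_swap_symmetry(self, rng):
        E0 = rng.lognormal(size=(40, 4))
        a = build_cell_network(E0, 5)
        b = build_cell_network(E0[:, [1, 0, 2, 3]], 5)
        w_a = {(min(u, v), max(u, v)): w for u, v, w in a.edges}
        swap = {0: 1, 1: 0, 2: 2, 3: 3}
        w_b = {
            (min(swap[u], swap[v]), max(swap[u], swap[v])): w for u, v, w in b.edges
        }
        assert w_a == w_b

    def test_out_of_range_cell(self, rng):
        with pytest.raises(IndexError):
            build_cell_network(rng.lognormal(size=(20, 3)), 20)


class TestCalibrationAndPower:
    def test_null_edge_rate_near_nominal(self):
        """Independent genes: per-cell rejection rate at alpha=0.01 stays
        within [0.001, 0.05] under the normal approximation."""
        n = 1000
        m = window_size(n, 0.1)
        z = critical_value(0.01)
        hits = total = 0
        for rep in range(40):
            x, y = simulate_independent_pair(n, seed=900 + rep)

            def membership(col):
                order = np.argsort(
                    np.abs(col[:, None] - col[None, :]), axis=1, kind="stable"
                )[:, :m]
                B = np.zeros((n, n), dtype=bool)
                B[np.arange(n)[:, None], order] = True
                return B

            n_uv = (membership(x) & membership(y)).sum(axis=1)
            rho = math.sqrt(n - 1) * (n * n_uv - m * m) / (m * (n - m))
            hits += int((rho > z).sum())
            total += n
        assert 0.001 <= hits / total <= 0.05

    def test_power_against_near_duplicate(self):
        """y = x + 1% noise is detected in almost every cell."""
        x, _ = simulate_independent_pair(1000, seed=5)
        noise = np.random.default_rng(6).normal(0, 0.01 * x.std(), 1000)
        y = np.abs(x + noise)
        E0 = np.column_stack([x, y])
        nets = build_training_networks(E0)
        rate = np.mean([net.n_edges for net in nets])
        assert rate > 0.9


class TestTrainingAndTestNetworks:
    def test_training_networks_deterministic(self, rng):
        E0 = rng.lognormal(size=(30, 4))
        a = build_training_networks(E0)
        b = build_training_networks(E0)
        for x, y in zip(a, b):
            assert np.array_equal(x.u, y.u)
            assert np.array_equal(x.weight, y.weight)

    def test_training_pool_isolated_from_test_data(self, rng):
        """Training networks are byte-identical with or without test cells."""
        E0 = rng.lognormal(size=(40, 5))
        nets = build_training_networks(E0)
        _ = build_test_network(E0, rng.lognormal(size=5))
        nets_after = build_training_networks(E0)
        for x, y in zip(nets, nets_after):
            assert np.array_equal(x.u, y.u) and np.array_equal(x.weight, y.weight)

    def test_block_edges_enriched_within_type(self, default_dataset):
        """Cells carry more edges inside their type's dependence block."""
        from wcsgnet.preprocess import cpm_normalize, log_transform

        ds = default_dataset
        E0 = log_transform(cpm_normalize(ds), 0.0)[:, :100]
        rows = np.flatnonzero(ds.labels == "type_0")[:40]
        in_rate = out_rate = 0.0
        for k in rows:
            net = build_cell_network(E0, int(k))
            inb = np.sum((net.u < 20) & (net.v < 20))
            outb = np.sum((net.u >= 60) & (net.v >= 60))
            in_rate += inb / (20 * 19 / 2)
            out_rate += outb / (40 * 39 / 2)
        assert in_rate > out_rate

    def test_test_network_matches_duplicate_training_cell(self, rng):
        """Inserting a copy of training cell r reproduces r's network under
        the (n+1)-cell pool, computed independently by the oracle."""
        from tests.test_wcsn import brute_force_network

        E0 = rng.lognormal(size=(30, 4))
        r = 11
        net = build_test_network(E0, E0[r])
        pool = np.vstack([E0, E0[r][None, :]])
        oracle = brute_force_network(pool, 30)
        mine = [(int(u), int(v), float(w)) for u, v, w in zip(net.u, net.v, net.weight)]
        assert mine == oracle

    def test_all_zero_test_cell_has_empty_network(self, rng):
        E0 = rng.lognormal(size=(30, 4))
        net = build_test_network(E0, np.zeros(4))
        assert net.n_edges == 0

    def test_test_insertions_order_independent(self, rng):
        E0 = rng.lognormal(size=(30, 4))
        a, b = rng.lognormal(size=4), rng.lognormal(size=4)
        na1 = build_test_network(E0, a)
        nb1 = build_test_network(E0, b)
        nb2 = build_test_network(E0, b)
        na2 = build_test_network(E0, a)
        assert np.array_equal(na1.weight, na2.weight)
        assert np.array_equal(nb1.weight, nb2.weight)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            build_test_network(rng.lognormal(size=(30, 4)), np.ones(5))


class TestTransformWeights:
    def _net(self, rng):
        E0 = rng.lognormal(size=(40, 5))
        return build_cell_network(E0, 3)

    def test_log1p_values_and_order(self, rng):
        net = self._net(rng)
        out = transform_weights(net, "log1p")
        assert np.allclose(out.weight, np.log1p(net.weight))
        assert np.array_equal(np.argsort(out.weight), np.argsort(net.weight))

    def test_log1p_of_e_minus_one(self):
        import wcsgnet.wcsn as wc

        net = wc.CellNetwork(
            0, np.array([0]), np.array([1]), np.array([math.e - 1]), 3
        )
        assert transform_weights(net, "log1p").weight[0] == pytest.approx(1.0)

    def test_binary_all_ones_same_edges(self, rng):
        net = self._net(rng)
        out = transform_weights(net, "binary")
        assert np.all(out.weight == 1.0)
        assert np.array_equal(out.u, net.u) and np.array_equal(out.v, net.v)

    def test_raw_identity_and_unknown_mode(self, rng):
        net = self._net(rng)
        assert transform_weights(net, "raw") is net
        with pytest.raises(ValueError):
            transform_weights(net, "sqrt")

    def test_raw_weights_exceed_critical_value(self, rng):
        net = self._net(rng)
        assert np.all(net.weight > critical_value(0.01))
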