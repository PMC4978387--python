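"""Global/local model-fit measures, grid search, and graph metrics."""

import itertools

import numpy as np
import pytest

import sfm
from sfm.evaluation import node_error


def sym(vec, n):
    """Symmetric matrix with given strict-upper-triangle vector."""
    M = np.zeros((n, n))
    M[np.triu_indices(n, 1)] = vec
    return M + M.T


class TestGlobalPerformance:
    def test_identical_gives_one(self):
        rng = np.random.default_rng(0)
        M = sym(rng.random(6), 4)
        assert sfm.global_performance(M, M) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        M = sym(rng.random(10), 5)
        assert sfm.global_performance(2.5 * M + 3.0, M) == pytest.approx(1.0)
        assert sfm.global_performance(M, 0.1 * M - 7.0) == pytest.approx(1.0)

    def test_hand_computed_four_by_four(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 1.0, 4.0, 3.0, 7.0, 5.0]
        # scalar covariance arithmetic, no numpy
        ma, mb = sum(a) / 6, sum(b) / 6
        cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / 6
        va = sum((x - ma) ** 2 for x in a) / 6
        vb = sum((y - mb) ** 2 for y in b) / 6
        expected = cov / (va * vb) ** 0.5
        assert sfm.global_performance(sym(a, 4), sym(b, 4)) == pytest.approx(expected)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero variance"):
            sfm.global_performance(sym(np.ones(6), 4), sym(np.arange(6.0), 4))


class TestVarianceArithmetic:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.4833, 23.4), (0.674, 45.4), (0.735, 54.0), (0.7377, 54.4), (0.0, 0.0)],
    )
    def test_variance_explained(self, r, expected):
        assert round(sfm.variance_explained(r), 1) == expected

    @pytest.mark.parametrize(
        "r_model, r_sc, expected", [(0.674, 0.4833, 28.8), (0.735, 0.4833, 40.0)]
    )
    def test_additional_variance(self, r_model, r_sc, expected):
        assert round(sfm.additional_variance(r_model, r_sc), 1) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sfm.variance_explained(1.2)
        with pytest.raises(ValueError):
            sfm.additional_variance(0.5, 1.0)


def tls_oracle(x, y, n_angles=200_000):
    """Brute-force TLS line: scan angles, minimize orthogonal SSE."""
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    best = None
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        nvec = np.array([-np.sin(theta), np.cos(theta)])
        res = x * nvec[0] + y * nvec[1]
        sse = np.sum(res**2)
        if best is None or sse < best[0]:
            best = (sse, nvec)
    nvec = best[1]
    if nvec[1] < 0:
        nvec = -nvec
    return x * nvec[0] + y * nvec[1]


class TestLocalError:
    def test_identical_matrices_zero_residuals(self):
        rng = np.random.default_rng(2)
        M = sym(rng.random(10), 5)
        np.testing.assert_allclose(sfm.local_error(M, M), 0.0, atol=1e-12)

    def test_matches_angle_scan_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.random(15)
        y = 0.8 * x + 0.2 * rng.random(15)
        res = sfm.local_error(sym(x, 6), sym(y, 6))
        np.testing.assert_allclose(res, tls_oracle(x, y), atol=1e-4)

    def test_signed_residuals_sum_to_zero_and_sign_convention(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0, 0.0, 0.0])
        y = np.array([-2.0, -1.0, 1.0, 2.0, 1.0, -1.0])
        res = sfm.local_error(sym(x, 4), sym(y, 4))
        assert np.sum(res) == pytest.approx(0.0, abs=1e-12)
        # point 4 has empirical above the TLS line -> positive residual
        assert res[4] > 0 and res[5] < 0

    def test_constant_input_reported(self):
        with pytest.raises(ValueError, match="constant"):
            sfm.local_error(sym(np.ones(6), 4), sym(np.arange(6.0), 4))


class TestErrorVsDistance:
    def test_exponential_decay_gives_minus_one(self):
        d = np.linspace(10, 100, 28)
        res = np.exp(-d)
        r, p, n = sfm.error_vs_edge_distance(res, d)
        assert r == pytest.approx(-1.0)
        assert n == 28

    def test_zero_residuals_excluded_with_count(self):
        d = np.linspace(1, 10, 10)
        res = np.exp(-d)
        res[:3] = 0.0
        with pytest.warns(UserWarning, match="3 zero-residual"):
            r, p, n = sfm.error_vs_edge_distance(res, d)
        assert n == 7

    def test_independent_residuals_null(self):
        rs, ps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = rng.uniform(10, 100, 300)
            res = rng.lognormal(size=300)
            r, p, _ = sfm.error_vs_edge_distance(res, d)
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.05
        assert np.median(ps) > 0.05


class TestPartialCorrelation:
    def test_orthogonal_regressor_keeps_plain_r(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(210)
        y = 0.5 * x + rng.standard_normal(210)
        d = rng.standard_normal(210)  # independent of both
        plain = sfm.global_performance(sym(x, 21), sym(y, 21))
        partial = sfm.partial_global_performance(sym(x, 21), sym(y, 21), d)
        assert partial == pytest.approx(plain, abs=0.05)

    def test_constant_distance_warns_and_equals_plain(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 15))
        with pytest.warns(UserWarning, match="constant distance"):
            partial = sfm.partial_global_performance(
                sym(x, 6), sym(y, 6), np.ones(15)
            )
        assert partial == pytest.approx(sfm.global_performance(sym(x, 6), sym(y, 6)))

    def test_trivariate_gaussian_recovers_closed_form(self):
        """Sampled partial correlation matches the closed-form value."""
        r_xy, r_xd, r_yd = 0.6, 0.5, 0.4
        cov = np.array([[1.0, r_xy, r_xd], [r_xy, 1.0, r_yd], [r_xd, r_yd, 1.0]])
        rng = np.random.default_rng(6)
        x, y, d = (np.linalg.cholesky(cov) @ rng.standard_normal((3, 2145)))
        expected = (r_xy - r_xd * r_yd) / np.sqrt((1 - r_xd**2) * (1 - r_yd**2))
        got = sfm.partial_global_performance(sym(x, 66), sym(y, 66), d)
        assert got == pytest.approx(expected, abs=0.02)


# ------------------------------------------------------------ graph oracle
def brute_force_metrics(S):
    """Path-enumeration betweenness + direct Onnela clustering, N <= 7."""
    n = S.shape[0]
    edges = {(i, j): S[i, j] for i in range(n) for j in range(n) if i != j and S[i, j] > 0}

    def all_paths(s, t):
        paths = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                paths.append((length, path))
                continue
            for nxt in range(n):
                if (node, nxt) in edges and nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / edges[(node, nxt)]))
        return paths

    btw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        dmin = min(p[0] for p in paths)
        shortest = [p[1] for p in paths if abs(p[0] - dmin) < 1e-12]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            btw[v] += through / len(shortest)
    btw /= (n - 1) * (n - 2) / 2

    wmax = max(edges.values()) if edges else 1.0
    clust = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if (i, j) in edges]
        k = len(nbrs)
        if k < 2:
            continue
        tot = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if (j, h) in edges:
                tot += (S[i, j] / wmax * S[i, h] / wmax * S[j, h] / wmax) ** (1 / 3)
        clust[i] = 2 * tot / (k * (k - 1))
    return btw, clust


def random_graph(n, seed, density=0.7):
    rng = np.random.default_rng(seed)
    S = rng.random((n, n)) * (rng.random((n, n)) < density)
    S = np.triu(S, 1)
    return S + S.T


class TestNodeMetrics:
    def test_star_graph_betweenness(self):
        n = 6
        S = np.zeros((n, n))
        S[0, 1:] = S[1:, 0] = 1.0
        m = sfm.node_metrics(S)
        assert m["betweenness"][0] == pytest.approx(1.0)  # all paths via center
        np.testing.assert_allclose(m["betweenness"][1:], 0.0)
        np.testing.assert_allclose(m["strength"], [5.0] + [1.0] * 5)

    def test_complete_graph(self):
        S = np.ones((5, 5)) - np.eye(5)
        m = sfm.node_metrics(S)
        np.testing.assert_allclose(m["betweenness"], 0.0, atol=1e-12)
        np.testing.assert_allclose(m["clustering"], 1.0)
        np.testing.assert_allclose(m["eigenvector_centrality"], 1 / np.sqrt(5))

    def test_triangle_with_pendant_matches_brute_force(self):
        S = np.array(
            [
                [0.0, 2.0, 1.0, 0.0],
                [2.0, 0.0, 4.0, 0.0],
                [1.0, 4.0, 0.0, 0.5],
                [0.0, 0.0, 0.5, 0.0],
            ]
        )
        m = sfm.node_metrics(S)
        btw, clust = brute_force_metrics(S)
        np.testing.assert_allclose(m["betweenness"], btw, atol=1e-10)
        np.testing.assert_allclose(m["clustering"], clust, atol=1e-10)
        np.testing.assert_allclose(m["strength"], S.sum(1))

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, n, seed):
        S = random_graph(n, seed)
        m = sfm.node_metrics(S)
        btw, clust = brute_force_metrics(S)
        np.testing.assert_allclose(m["betweenness"], btw, atol=1e-10)
        np.testing.assert_allclose(m["clustering"], clust, atol=1e-10)
        # eigenvector centrality: Perron vector oracle via power iteration
        v = np.ones(n)
        for _ in range(2000):
            v = S @ v + 1e-12
            v /= np.linalg.norm(v)
        np.testing.assert_allclose(m["eigenvector_centrality"], v, atol=1e-6)

    def test_node_error_averages_incident_edges(self):
        res = np.array([1.0, -2.0, 3.0])  # edges (0,1), (0,2), (1,2) of a triangle
        np.testing.assert_allclose(node_error(res, 3), [1.5, 2.0, 2.5])


class TestGridSearch:
    def test_single_point_grid(self, toy_raw, toy_geometry):
        sc = sfm.build_structural_connectome(toy_raw, toy_geometry, h=0.1)
        fc_emp = sfm.fc_from_sar(sfm.sar_correlation(sc, sfm.SARParams(k=0.4)).correlation)
        result = sfm.grid_search(
            {"model": "sar"}, toy_raw, toy_geometry, fc_emp, {"k": [0.4], "h": [0.1]}
        )
        assert result.best_params == {"k": 0.4, "h": 0.1}
        assert result.best_r == pytest.approx(1.0)

    def test_exact_recovery_on_noiseless_sar(self, geometry66):
        """The argmax lands exactly on the generating parameters."""
        raw = sfm.generate_connectome(geometry66, seed=9)
        sc = sfm.build_structural_connectome(raw, geometry66, h=0.1)
        fc_emp = sfm.fc_from_sar(sfm.sar_correlation(sc, sfm.SARParams(k=0.65)).correlation)
        result = sfm.grid_search(
            {"model": "sar"},
            raw,
            geometry66,
            fc_emp,
            {"k": np.arange(0.05, 1.0, 0.05), "h": [0.0, 0.05, 0.1, 0.15, 0.2]},
        )
        assert result.best_params["k"] == pytest.approx(0.65)
        assert result.best_params["h"] == pytest.approx(0.1)
        assert result.best_r == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_surface(self, toy_raw, toy_geometry):
        fc_emp = sym([0.1, 0.5, 0.2, 0.4, 0.3, 0.6], 4)
        grid = {"k": [0.2, 0.5, 0.8], "h": [0.0, 0.1]}
        r1 = sfm.grid_search({"model": "sar"}, toy_raw, toy_geometry, fc_emp, grid)
        r2 = sfm.grid_search({"model": "sar"}, toy_raw, toy_geometry, fc_emp, grid)
        np.testing.assert_array_equal(r1.performance, r2.performance)
        assert r1.best_params == r2.best_params

    def test_unstable_points_flagged_and_empty_grid_rejected(self, toy_raw, toy_geometry):
        fc_emp = sym([0.1, 0.5, 0.2, 0.4, 0.3, 0.6], 4)
        # input-normalized S has spectral radius 1, so k >= 1 is unstable
        result = sfm.grid_search(
            {"model": "sar"}, toy_raw, toy_geometry, fc_emp, {"k": [0.5, 1.2], "h": [0.1]}
        )
        assert result.n_unstable == 1
        assert np.isnan(result.performance[1, 0])
        with pytest.raises(ValueError, match="empty"):
            sfm.grid_search({"model": "sar"}, toy_raw, toy_geometry, fc_emp, {"k": [], "h": [0.1]})

    def test_tie_broken_toward_smallest_parameters(self, toy_raw, toy_geometry):
        sc = sfm.build_structural_connectome(toy_raw, toy_geometry, h=0.0, input_norm=True)
        fc_emp = sfm.fc_from_sar(sfm.sar_correlation(sc, sfm.SARParams(k=0.3)).correlation)
        # two identical h values produce an exact tie in h; smallest k wins ties in k
        est = sfm.StructureFunctionModel(
            raw=toy_raw, geometry=toy_geometry, grid={"k": [0.3, 0.3], "h": [0.0]}
        ).fit(fc_emp)
        assert est.best_params_ == {"k": 0.3, "h": 0.0}
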