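"""Affinity construction, Laplacian spectra and the VB index itself."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vbgradient as vb
from vbgradient.graph_core import ZERO_TOL

from conftest import make_series_with_correlation


def complete_affinity(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return vb.AffinityMatrix(w)


def path_affinity(n, weight=1.0):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return vb.AffinityMatrix(w)


def two_triangles():
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return vb.AffinityMatrix(w)


def random_affinity(n, seed):
    return vb.uniform_affinity(n, seed)


# --- containers ---------------------------------------------------------------


class TestContainers:
    def test_time_series_rejects_bad_input(self):
        with pytest.raises(vb.InputError):
            vb.TimeSeriesMatrix(np.ones((1, 5)))          # m < 2
        with pytest.raises(vb.InputError):
            vb.TimeSeriesMatrix(np.ones((3, 1)))          # k < 2
        bad = np.ones((3, 5))
        bad[1, 2] = np.nan
        with pytest.raises(vb.InputError):
            vb.TimeSeriesMatrix(bad)                      # missing values

    def test_affinity_rejects_violated_invariants(self):
        with pytest.raises(vb.InputError):
            vb.AffinityMatrix(np.array([[0.0, 0.3], [0.2, 0.0]]))  # asymmetric
        with pytest.raises(vb.InputError):
            vb.AffinityMatrix(np.array([[0.5, 0.3], [0.3, 0.0]]))  # diagonal
        with pytest.raises(vb.InputError):
            vb.AffinityMatrix(np.array([[0.0, 1.3], [1.3, 0.0]]))  # out of range

    def test_affinity_tsv_roundtrip(self, tmp_path):
        A = random_affinity(7, seed=3)
        p = tmp_path / "a.tsv"
        A.to_tsv(p)
        B = vb.AffinityMatrix.from_tsv(p)
        np.testing.assert_allclose(B.weights, A.weights, atol=1e-15)
        assert B.vertex_ids == A.vertex_ids

    def test_affinity_npy_roundtrip(self, tmp_path):
        A = random_affinity(5, seed=4)
        p = tmp_path / "a.npy"
        A.to_npy(p)
        B = vb.AffinityMatrix.from_npy(p, vertex_ids=A.vertex_ids)
        np.testing.assert_array_equal(B.weights, A.weights)


# --- build_affinity -----------------------------------------------------------


class TestBuildAffinity:
    @pytest.mark.parametrize("corr, expected", [
        (1.0, 1.0),                      # identical series
        (0.0, 0.0),                      # orthogonal mean-centred series
        (np.cos(np.pi / 4), 0.5),        # 45-degree pair: linear, not cosine
        (-1.0, 0.0),                     # anti-correlated, clamped from -1
    ])
    def test_weight_calibration(self, corr, expected):
        ts = make_series_with_correlation(corr)
        A = vb.build_affinity(ts)
        assert A.weights[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_identical_series_weight_one(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(20)
        A = vb.build_affinity(vb.TimeSeriesMatrix(np.vstack([s, s])))
        assert A.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_series_warns_and_zeroes(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((4, 30))
        values[2] = 3.14  # flat series
        with pytest.warns(UserWarning, match="zero-variance"):
            A = vb.build_affinity(vb.TimeSeriesMatrix(values))
        assert np.all(A.weights[2] == 0.0)
        assert np.all(A.weights[:, 2] == 0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_output_is_valid_affinity(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 12)
        ts = vb.TimeSeriesMatrix(rng.standard_normal((m, 15)))
        A = vb.build_affinity(ts)  # construction revalidates all invariants
        assert A.n == m
        assert np.array_equal(A.weights, A.weights.T)


# --- graph_laplacian ----------------------------------------------------------


class TestLaplacian:
    def test_complete_three_vertices(self):
        pair = vb.graph_laplacian(complete_affinity(3))
        expected = np.array([[2.0, -1.0, -1.0], [-1.0, 2.0, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_array_equal(pair.laplacian, expected)

    def test_zero_affinity_gives_zero_laplacian(self):
        pair = vb.graph_laplacian(vb.AffinityMatrix(np.zeros((4, 4))))
        assert not pair.laplacian.any()
        assert not pair.degrees.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_row_sums_zero_and_degrees(self, seed):
        A = random_affinity(8, seed)
        pair = vb.graph_laplacian(A)
        np.testing.assert_allclose(pair.laplacian.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(pair.degrees, A.weights.sum(axis=1))
        evals = np.linalg.eigvalsh(pair.laplacian)
        assert evals[0] >= -1e-10  # positive semi-definite


# --- spectrum -----------------------------------------------------------------


class TestSpectrum:
    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_complete_graph_lambda2_equals_n(self, n):
        res = vb.spectrum(vb.graph_laplacian(complete_affinity(n)))
        assert res.lambda2 == pytest.approx(n, abs=1e-8)

    @pytest.mark.parametrize("mode", ["standard", "geig"])
    def test_disconnected_graph_lambda2_zero(self, mode):
        res = vb.spectrum(vb.graph_laplacian(two_triangles()), mode=mode)
        assert res.lambda2 == 0.0

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_complete_graph_geig_lambda2(self, n):
        pair = vb.graph_laplacian(complete_affinity(n))
        res = vb.spectrum(pair, mode="geig")
        assert res.lambda2 == pytest.approx(n / (n - 1), abs=1e-8)
        # the same value is the mean of the non-smallest standard eigenvalues
        # divided by the common degree n - 1
        std = vb.spectrum(pair).eigenvalues
        assert res.lambda2 == pytest.approx(std[1:].mean() / (n - 1), abs=1e-8)

    def test_path3_eigenvalues(self):
        res = vb.spectrum(vb.graph_laplacian(path_affinity(3)))
        np.testing.assert_allclose(res.eigenvalues, [0.0, 1.0, 3.0], atol=1e-8)

    def test_geig_zero_degree_vertex_error_names_vertex(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5  # vertex 2 isolated
        with pytest.raises(vb.DegenerateGraphError, match="vertex 2"):
            vb.spectrum(vb.graph_laplacian(vb.AffinityMatrix(w)), mode="geig")

    @pytest.mark.parametrize("seed", range(10))
    def test_standard_mode_invariants(self, seed):
        res = vb.spectrum(vb.graph_laplacian(random_affinity(9, seed)))
        assert abs(res.eigenvalues[0]) <= 1e-8
        assert np.all(np.diff(res.eigenvalues) >= 0.0)
        gram = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-8)
        assert abs(res.fiedler_vector.sum()) < 1e-8  # orthogonal to all-ones

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_independent_eigensolver(self, seed):
        """networkx Laplacian + numpy eigvalsh as the independent oracle."""
        nx = pytest.importorskip("networkx")
        A = random_affinity(7, seed)
        ours = vb.spectrum(vb.graph_laplacian(A)).eigenvalues
        G = nx.from_numpy_array(A.weights)
        theirs = np.sort(np.linalg.eigvalsh(
            nx.laplacian_matrix(G).toarray().astype(float)))
        np.testing.assert_allclose(ours, np.maximum(theirs, 0.0), atol=1e-8)


# --- rayleigh_quotient --------------------------------------------------------


class TestRayleigh:
    def test_fiedler_vector_attains_lambda2(self):
        A = random_affinity(8, seed=0)
        pair = vb.graph_laplacian(A)
        res = vb.spectrum(pair)
        rq = vb.rayleigh_quotient(pair, res.fiedler_vector)
        assert rq == pytest.approx(res.lambda2, abs=1e-8)

    def test_all_ones_vector_gives_zero(self):
        pair = vb.graph_laplacian(random_affinity(6, seed=1))
        assert vb.rayleigh_quotient(pair, np.ones(6)) == pytest.approx(0.0, abs=1e-10)

    def test_zero_vector_rejected(self):
        pair = vb.graph_laplacian(random_affinity(4, seed=2))
        with pytest.raises(vb.InputError):
            vb.rayleigh_quotient(pair, np.zeros(4))

    def test_one_orthogonal_vectors_bounded_below_by_lambda2(self):
        """Any vector orthogonal to the all-ones vector scores >= lambda2."""
        rng = np.random.default_rng(123)
        A = random_affinity(9, seed=3)
        pair = vb.graph_laplacian(A)
        lam2 = vb.spectrum(pair).lambda2
        for _ in range(150):
            x = rng.standard_normal(9)
            x -= x.mean()
            assert vb.rayleigh_quotient(pair, x) >= lam2 - 1e-8

    def test_quadratic_form_identity_many_random_pairs(self):
        """x^T L x equals the half-sum of weighted squared differences; the
        implementation asserts this internally, so 1000 calls without an
        AssertionError certify the identity."""
        rng = np.random.default_rng(99)
        for i in range(1000):
            n = int(rng.integers(2, 11))
            A = random_affinity(n, seed=i)
            x = rng.standard_normal(n)
            pair = vb.graph_laplacian(A)
            rq = vb.rayleigh_quotient(pair, x)
            assert np.isfinite(rq) and rq >= -1e-10


# --- vb_index -----------------------------------------------------------------


class TestVBIndex:
    def test_complete_unit_graph_scores_one(self):
        for norm in ("unnorm", "geig"):
            assert vb.vb_index(complete_affinity(6), norm).value == pytest.approx(1.0, abs=1e-8)

    def test_disconnected_graph_scores_zero(self):
        assert vb.vb_index(two_triangles()).value == 0.0

    def test_path3_scores_one_third(self):
        assert vb.vb_index(path_affinity(3)).value == pytest.approx(1.0 / 3.0, abs=1e-8)

    @pytest.mark.parametrize("norm", ["unnorm", "geig"])
    @pytest.mark.parametrize("seed", range(20))
    def test_bounded_in_unit_interval(self, norm, seed):
        A = random_affinity(int(np.random.default_rng(seed).integers(3, 12)), seed)
        v = vb.vb_index(A, norm)
        assert 0.0 <= v.value <= 1.0

    def test_zero_iff_disconnected(self):
        # connected random graphs score > 0; cutting them to pieces scores 0
        for seed in range(20):
            A = random_affinity(8, seed)
            assert vb.vb_index(A).value > 0.0
            w = A.weights.copy()
            w[:4, 4:] = 0.0
            w[4:, :4] = 0.0
            assert vb.vb_index(vb.AffinityMatrix(w)).value == 0.0

    @pytest.mark.parametrize("c", [0.1, 0.25, 0.5, 0.9, 1.0])
    def test_uniform_weight_scaling_scales_lambda2(self, c):
        A = random_affinity(9, seed=5)
        lam2 = vb.vb_index(A).lambda2
        scaled = vb.vb_index(vb.AffinityMatrix(c * A.weights)).lambda2
        assert scaled == pytest.approx(c * lam2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        A = random_affinity(8, seed)
        perm = rng.permutation(8)
        B = vb.AffinityMatrix(A.weights[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            vb.spectrum(vb.graph_laplacian(A)).eigenvalues,
            vb.spectrum(vb.graph_laplacian(B)).eigenvalues, atol=1e-8)
        assert vb.vb_index(B).value == pytest.approx(vb.vb_index(A).value, abs=1e-8)

    def test_geig_matches_standard_on_regular_graphs(self):
        # all degrees equal: D = d I, so geig eigenvalues are standard / d
        A = complete_affinity(7, weight=0.6)
        d = 6 * 0.6
        std = vb.spectrum(vb.graph_laplacian(A)).eigenvalues
        gen = vb.spectrum(vb.graph_laplacian(A), mode="geig").eigenvalues
        np.testing.assert_allclose(gen, std / d, atol=1e-8)


# --- hypothesis property: any valid series matrix yields a valid VB value -----


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), m=st.integers(2, 10), k=st.integers(3, 30))
def test_vb_index_in_unit_interval_for_arbitrary_series(seed, m, k):
    rng = np.random.default_rng(seed)
    ts = vb.TimeSeriesMatrix(rng.standard_normal((m, k)))
    value = vb.vb_index(vb.build_affinity(ts)).value
    assert 0.0 <= value <= 1.0
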