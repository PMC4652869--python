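"""Unit, oracle and property tests for the cross-mapping statistics."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossembed.crossmap import (
    EmbeddednessProfile,
    ForecastSpec,
    analyze_pair,
    complexity_from_profile,
    convergence_profile,
    directionality,
    embeddedness_profile,
    knn_forecast,
    relative_embeddedness,
)
from crossembed.embedding import EmbeddingConfig
from crossembed.simulators import RosslerParams, simulate_coupled_rossler
from helpers import brute_force_forecast


def random_instance(seed, tie_heavy=False):
    """One random forecasting instance within the oracle-check envelope."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 201))
    d = int(rng.integers(1, 6))
    k = int(rng.integers(1, min(8, n - 1) + 1))
    nq = int(rng.integers(1, 21))
    if tie_heavy:
        # values on a coarse grid so exact distance ties actually occur
        lib = rng.integers(0, 3, (n, d)).astype(float)
        q = rng.integers(0, 3, (nq, d)).astype(float)
    else:
        lib = rng.normal(size=(n, d))
        q = rng.normal(size=(nq, d))
    y = rng.normal(size=n)
    return lib, y, q, k


class TestForecastSpecValidation:
    def test_rejects_bad_k(self):
        with pytest.raises(ValueError, match="k"):
            ForecastSpec(k=0)

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            ForecastSpec(threshold=0.0)
        with pytest.raises(ValueError, match="threshold"):
            ForecastSpec(threshold=1.2)

    def test_rejects_small_n_queries(self):
        with pytest.raises(ValueError, match="n_queries"):
            ForecastSpec(k=4, n_queries=4)

    def test_rejects_unknown_folds(self):
        with pytest.raises(ValueError, match="folds"):
            ForecastSpec(folds="threefold")

    def test_rejects_bad_d_fixed(self):
        with pytest.raises(ValueError, match="d_fixed"):
            ForecastSpec(d_fixed=0)


class TestKnnForecast:
    def test_equal_targets_give_constant_forecast(self):
        lib = np.array([[0.0], [1.0], [2.0], [5.0], [9.0]])
        y = np.full(5, 3.0)
        out = knn_forecast(lib, y, np.array([[0.7]]), ForecastSpec(k=4))
        assert out.forecasts[0] == pytest.approx(3.0, abs=1e-12)

    def test_equidistant_neighbors_average(self):
        # four library points at identical distance 1 from the origin query
        lib = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = knn_forecast(lib, y, np.array([[0.0, 0.0]]), ForecastSpec(k=4))
        assert np.all(out.weights[0] == 0.25)
        assert out.forecasts[0] == 2.5

    def test_1d_library_example_matches_oracle(self):
        lib = np.array([[0.1], [0.2], [0.3], [0.4], [1.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        q = np.array([[0.0]])
        out = knn_forecast(lib, y, q, ForecastSpec(k=4))
        assert set(out.neighbor_indices[0]) == {0, 1, 2, 3}
        _, _, w, fc = brute_force_forecast(lib, y, q, 4)
        assert out.forecasts[0] == fc[0]
        assert out.weights[0].tolist() == w[0]

    def test_k_larger_than_library_rejected(self):
        lib = np.zeros((4, 2))
        with pytest.raises(ValueError, match="k"):
            knn_forecast(lib, np.zeros(4), np.zeros((1, 2)), ForecastSpec(k=5))

    def test_k_equal_to_library_size_uses_all_rows(self):
        lib = np.array([[0.0], [1.0], [2.0], [3.0]])
        out = knn_forecast(
            lib, np.arange(4.0), np.array([[1.9]]), ForecastSpec(k=4)
        )
        assert sorted(out.neighbor_indices[0].tolist()) == [0, 1, 2, 3]

    def test_non_finite_query_rejected(self):
        lib = np.zeros((10, 2))
        q = np.array([[np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            knn_forecast(lib, np.zeros(10), q, ForecastSpec(k=2))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            knn_forecast(np.zeros((10, 2)), np.zeros(10), np.zeros((1, 3)))

    def test_target_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            knn_forecast(np.zeros((10, 2)), np.zeros(9), np.zeros((1, 2)))

    def test_ties_break_to_lower_library_index(self):
        # two library rows exactly coincide; the lower index must be chosen
        lib = np.array([[5.0], [1.0], [1.0], [1.0], [1.0], [1.0]])
        out = knn_forecast(
            lib, np.arange(6.0), np.array([[1.0]]), ForecastSpec(k=4)
        )
        assert out.neighbor_indices[0].tolist() == [1, 2, 3, 4]

    def test_all_zero_distances_give_uniform_weights(self):
        lib = np.ones((6, 3))
        out = knn_forecast(
            lib, np.arange(6.0), np.ones((2, 3)), ForecastSpec(k=4)
        )
        assert np.all(out.weights == 0.25)
        assert out.neighbor_indices[0].tolist() == [0, 1, 2, 3]

    @given(seed=st.integers(0, 300), tie_heavy=st.booleans())
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_weights_sum_to_one_and_forecast_bounded(self, seed, tie_heavy):
        lib, y, q, k = random_instance(seed, tie_heavy)
        out = knn_forecast(lib, y, q, ForecastSpec(k=k, n_queries=k + 1))
        assert np.allclose(out.weights.sum(axis=1), 1.0, atol=1e-12)
        ny = y[out.neighbor_indices]
        assert np.all(out.forecasts <= ny.max(axis=1) + 1e-12)
        assert np.all(out.forecasts >= ny.min(axis=1) - 1e-12)
        # squared distances are ascending per row
        assert np.all(np.diff(out.squared_distances, axis=1) >= 0)

    @given(seed=st.integers(0, 500), tie_heavy=st.booleans())
    @settings(deadline=None, derandomize=True, max_examples=120)
    def test_matches_brute_force_oracle_bitwise(self, seed, tie_heavy):
        lib, y, q, k = random_instance(seed, tie_heavy)
        out = knn_forecast(lib, y, q, ForecastSpec(k=k, n_queries=k + 1))
        idx, sq, w, fc = brute_force_forecast(lib, y, q, k)
        assert out.neighbor_indices.tolist() == idx
        assert out.squared_distances.tolist() == sq
        assert out.weights.tolist() == w
        assert out.forecasts.tolist() == fc


@pytest.fixture(scope="module")
def rossler_4000():
    """Coupled pair with 4000 subsampled points for mid-length checks."""
    traj = simulate_coupled_rossler(
        RosslerParams(seed=0, duration=500.0, transient=100.0)
    )
    return traj.observables[:, 0], traj.observables[:, 1]


class TestEmbeddednessProfile:
    def test_constant_series_rho_zero_with_warning(self, caplog):
        x = np.ones(200)
        y = np.ones(200)
        with caplog.at_level(logging.WARNING, logger="crossembed.crossmap"):
            p = embeddedness_profile(
                x, y, EmbeddingConfig(tau=1, d_max=3), ForecastSpec(n_queries=5)
            )
        assert np.all(p.rho == 0.0)
        assert "degenerate" in caplog.text

    def test_white_noise_null(self):
        # independent white noise: |rho| < 0.1 at every d in >= 18/20 seeds
        emb_kw = dict(tau=1, d_max=10)
        ok = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            x = rng.standard_normal(3000)
            y = rng.standard_normal(3000)
            p = embeddedness_profile(
                x, y, EmbeddingConfig(seed=s, **emb_kw),
                ForecastSpec(query_seed=s),
            )
            ok += bool(np.all(np.abs(p.rho) < 0.1))
        assert ok >= 18

    def test_rossler_asymmetry(self, rossler_4000):
        x, y = rossler_4000
        emb = EmbeddingConfig(tau=4, d_max=20, seed=0)
        spec = ForecastSpec(query_seed=0)
        up_by_down = embeddedness_profile(x, y, emb, spec)
        down_by_up = embeddedness_profile(y, x, emb, spec)
        assert up_by_down.optimal > down_by_up.optimal
        assert directionality(up_by_down, down_by_up) > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            embeddedness_profile(
                np.zeros(100), np.zeros(99), EmbeddingConfig(tau=1, d_max=2)
            )

    def test_d_fixed_profile(self, rossler_4000):
        x, y = rossler_4000
        emb = EmbeddingConfig(tau=4, d_max=20, seed=0)
        full = embeddedness_profile(x, y, emb, ForecastSpec(query_seed=0))
        fixed = embeddedness_profile(
            x, y, emb, ForecastSpec(query_seed=0, d_fixed=5)
        )
        assert fixed.dims.tolist() == [5]
        assert fixed.rho[0] == pytest.approx(full.at(5), abs=1e-12)

    def test_d_fixed_beyond_dmax_rejected(self, rossler_4000):
        x, y = rossler_4000
        with pytest.raises(ValueError, match="d_fixed"):
            embeddedness_profile(
                x, y, EmbeddingConfig(tau=4, d_max=20),
                ForecastSpec(d_fixed=21),
            )

    def test_scale_invariance(self, short_rossler):
        # Multiplying both series by a positive constant leaves rho, d* and
        # directionality unchanged when internal normalisation is on.
        x, y = short_rossler
        emb = EmbeddingConfig(tau=4, d_max=10, seed=0)
        spec = ForecastSpec(query_seed=0)
        base_f = embeddedness_profile(x, y, emb, spec)
        base_r = embeddedness_profile(y, x, emb, spec)
        for a in (0.01, 7.3, 1e4):
            pf = embeddedness_profile(a * x, a * y, emb, spec)
            pr = embeddedness_profile(a * y, a * x, emb, spec)
            assert np.allclose(pf.rho, base_f.rho, rtol=1e-9, atol=1e-11)
            assert complexity_from_profile(pf) == complexity_from_profile(base_f)
            assert directionality(pf, pr) == pytest.approx(
                directionality(base_f, base_r), abs=1e-9
            )

    def test_n_effective_counts_queries(self, short_rossler):
        x, y = short_rossler
        p = embeddedness_profile(
            x, y, EmbeddingConfig(tau=4, d_max=5),
            ForecastSpec(n_queries=100, folds="both"),
        )
        assert p.n_effective == 200
        p1 = embeddedness_profile(
            x, y, EmbeddingConfig(tau=4, d_max=5),
            ForecastSpec(n_queries=100, folds="printed"),
        )
        assert p1.n_effective == 100

    def test_profile_at_missing_dim_rejected(self):
        p = EmbeddednessProfile(rho=np.array([0.5]), dims=np.array([3]))
        assert p.at(3) == 0.5
        with pytest.raises(ValueError, match="d=4"):
            p.at(4)


class TestComplexityFromProfile:
    def make(self, rho):
        rho = np.asarray(rho, dtype=float)
        return EmbeddednessProfile(
            rho=rho, dims=np.arange(1, rho.size + 1)
        )

    def test_threshold_example(self):
        assert complexity_from_profile(
            self.make([0.50, 0.80, 0.95, 0.96]), 0.95
        ) == 3

    def test_constant_profile(self):
        assert complexity_from_profile(self.make([0.7, 0.7, 0.7]), 0.95) == 1

    def test_uninformative_profile_returns_one_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="crossembed.crossmap"):
            assert complexity_from_profile(self.make([-0.2, -0.1, 0.0])) == 1
        assert "uninformative" in caplog.text

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            complexity_from_profile(self.make([]))

    def test_peaked_profile_picks_near_peak(self):
        assert complexity_from_profile(
            self.make([0.2, 0.5, 0.9, 0.8, 0.6]), 0.95
        ) == 3

    def test_threshold_one_requires_maximum(self):
        assert complexity_from_profile(
            self.make([0.50, 0.80, 0.95, 0.96]), 1.0
        ) == 4


class TestDirectionality:
    def make(self, rho):
        rho = np.asarray(rho, dtype=float)
        return EmbeddednessProfile(rho=rho, dims=np.arange(1, rho.size + 1))

    def test_identical_profiles_zero(self):
        p = self.make([0.2, 0.6])
        assert directionality(p, p) == 0.0

    @given(
        a=st.lists(st.floats(-1, 1), min_size=1, max_size=6),
        b=st.lists(st.floats(-1, 1), min_size=1, max_size=6),
    )
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry_exact(self, a, b):
        pa, pb = self.make(a), self.make(b)
        assert directionality(pa, pb) == -directionality(pb, pa)


class TestRelativeEmbeddedness:
    def test_flat_profile_zero(self):
        p = EmbeddednessProfile(
            rho=np.array([0.4, 0.3, 0.4]), dims=np.array([1, 2, 3])
        )
        assert relative_embeddedness(p, 3) == 0.0

    def test_arithmetic_example(self):
        p = EmbeddednessProfile(
            rho=np.array([0.2, 0.6, 0.9]), dims=np.array([1, 2, 3])
        )
        assert relative_embeddedness(p, 3) == pytest.approx(0.7)


class TestConvergenceProfile:
    def test_single_length_matches_profile_maximum(self, short_rossler):
        x, y = short_rossler
        emb = EmbeddingConfig(tau=4, d_max=10, seed=0)
        spec = ForecastSpec(query_seed=0, folds="printed", n_queries=500)
        p = embeddedness_profile(x, y, emb, spec)
        half = (len(x) - (emb.d_max - 1) * emb.tau) // 2
        lengths, vals = convergence_profile(x, y, emb, spec, [half])
        assert lengths.tolist() == [half]
        assert vals[0] == pytest.approx(p.optimal, abs=1e-12)

    def test_excessive_length_rejected(self, short_rossler):
        x, y = short_rossler
        with pytest.raises(ValueError, match="exceeds"):
            convergence_profile(
                x, y, EmbeddingConfig(tau=4, d_max=10),
                ForecastSpec(), [100000],
            )

    def test_below_minimum_skipped_with_warning(self, short_rossler, caplog):
        x, y = short_rossler
        with caplog.at_level(logging.WARNING, logger="crossembed.crossmap"):
            lengths, vals = convergence_profile(
                x, y, EmbeddingConfig(tau=4, d_max=10),
                ForecastSpec(n_queries=200), [3, 600],
            )
        assert lengths.tolist() == [600]
        assert "skipped" in caplog.text

    def test_lengths_returned_sorted_with_values(self, short_rossler):
        x, y = short_rossler
        lengths, vals = convergence_profile(
            x, y, EmbeddingConfig(tau=4, d_max=10, seed=0),
            ForecastSpec(query_seed=0, n_queries=300), [800, 200, 400],
        )
        assert lengths.tolist() == [200, 400, 800]
        assert vals.shape == (3,)
        assert np.all(np.isfinite(vals))


class TestAnalyzePair:
    def test_summary_consistent_with_profiles(self, rossler_4000):
        x, y = rossler_4000
        emb = EmbeddingConfig(tau=4, d_max=20, seed=0)
        spec = ForecastSpec(query_seed=0)
        res = analyze_pair(y, x, emb, spec, labels=("up", "down"))
        p_main = embeddedness_profile(x, y, emb, spec)
        p_rev = embeddedness_profile(y, x, emb, spec)
        assert res.source == "up" and res.target == "down"
        assert res.optimal_embeddedness == p_main.optimal
        assert res.complexity == complexity_from_profile(p_main, spec.threshold)
        assert res.directionality == directionality(p_main, p_rev)

    def test_directionality_antisymmetric_between_orientations(
        self, short_rossler
    ):
        x, y = short_rossler
        emb = EmbeddingConfig(tau=4, d_max=8, seed=1)
        spec = ForecastSpec(query_seed=1, n_queries=300)
        fwd = analyze_pair(y, x, emb, spec, labels=("up", "down"))
        rev = analyze_pair(x, y, emb, spec, labels=("down", "up"))
        assert fwd.directionality == -rev.directionality
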