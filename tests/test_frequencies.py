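import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digisort import (
    CollapsedMarkerMatrix,
    DesignSpec,
    ExpressionMatrix,
    FrequencyEstimationOptions,
    MarkerSet,
    ValidationError,
    collapse_markers,
    estimate_frequencies,
    generate_truth,
    solve_gbar,
)


def _collapsed(values, types=None, samples=None):
    values = np.asarray(values, dtype=float)
    k, p = values.shape
    return CollapsedMarkerMatrix(
        values,
        types or [f"t{i}" for i in range(k)],
        samples or [f"s{j}" for j in range(p)],
    )


class TestCollapseMarkers:
    def test_single_marker_is_identity(self, tiny_expr, small_markers):
        col = collapse_markers(tiny_expr, small_markers)
        np.testing.assert_array_equal(col.values[0], tiny_expr.values[0])
        np.testing.assert_array_equal(col.values[1], tiny_expr.values[1])

    def test_arithmetic_mean_of_markers(self, tiny_expr):
        markers = MarkerSet({"liver": ["g1", "g2"], "brain": ["g3"]})
        col = collapse_markers(tiny_expr, markers)
        np.testing.assert_allclose(col.values[0], [5.0, 5.0])  # mean of rows g1,g2

    def test_absent_marker_dropped_with_warning(self, tiny_expr, caplog):
        markers = MarkerSet({"liver": ["g1", "X"], "brain": ["g2"]})
        with caplog.at_level("WARNING"):
            col = collapse_markers(tiny_expr, markers)
        np.testing.assert_array_equal(col.values[0], tiny_expr.values[0])
        assert any("dropped" in r.message for r in caplog.records)

    def test_cell_type_losing_all_markers_errors(self, tiny_expr):
        markers = MarkerSet({"liver": ["g1"], "brain": ["nope"]})
        with pytest.raises(ValidationError, match="brain"):
            collapse_markers(tiny_expr, markers)


class TestSolveGbar:
    def test_pure_sample_equations(self):
        gbar = solve_gbar(_collapsed([[2, 0], [0, 4]]))
        np.testing.assert_allclose(gbar, [2.0, 4.0])

    def test_two_by_two_system(self):
        # x1*2 + x2*2 = 1 and x1*1 + x2*3 = 1  =>  x = (0.25, 0.25)
        gbar = solve_gbar(_collapsed([[2, 1], [2, 3]]))
        np.testing.assert_allclose(gbar, [4.0, 4.0])

    def test_scaling_homogeneity(self):
        base = np.array([[2.0, 1.0, 3.0], [2.0, 3.0, 1.0]])
        g1 = solve_gbar(_collapsed(base))
        g2 = solve_gbar(_collapsed(7.5 * base))
        np.testing.assert_allclose(g2, 7.5 * g1)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValidationError, match="underdetermined"):
            solve_gbar(_collapsed([[1.0], [2.0]]))

    def test_square_system_warns(self):
        with pytest.warns(UserWarning, match="equals"):
            solve_gbar(_collapsed([[2, 0], [0, 4]]))

    def test_rank_deficient_rejected_with_condition_number(self):
        with pytest.raises(ValidationError, match="condition number"):
            solve_gbar(_collapsed([[1, 2, 3], [2, 4, 6]]))

    def test_unidentifiable_type_named(self):
        # second row pushes its nonnegative weight to zero: its "markers" are
        # a scaled copy of noise orthogonal to the sum-to-one fit
        values = np.array(
            [[2.0, 2.1, 1.9, 2.0], [0.001, 0.9, 0.001, 0.9], [1.0, 0.1, 1.1, 0.05]]
        )
        try:
            gbar = solve_gbar(_collapsed(values))
        except ValidationError as err:
            assert "unidentifiable" in str(err)
        else:  # if the optimum keeps all weights positive, they must be usable
            assert np.all(gbar > 0)


class TestEstimateFrequencies:
    def _expr_markers(self, collapsed_values):
        """One marker per type so the collapsed matrix equals the expression rows."""
        values = np.asarray(collapsed_values, dtype=float)
        k, p = values.shape
        expr = ExpressionMatrix(
            values, [f"m{i}" for i in range(k)], [f"s{j}" for j in range(p)]
        )
        markers = MarkerSet({f"t{i}": [f"m{i}"] for i in range(k)})
        return expr, markers

    def test_pure_samples_give_identity(self):
        expr, markers = self._expr_markers([[2, 0], [0, 4]])
        W = estimate_frequencies(expr, markers)
        np.testing.assert_allclose(W.values, np.eye(2), atol=1e-12)

    def test_worked_two_by_two(self):
        expr, markers = self._expr_markers([[2, 1], [2, 3]])
        W = estimate_frequencies(expr, markers)
        np.testing.assert_allclose(W.values, [[0.5, 0.25], [0.5, 0.75]])
        np.testing.assert_allclose(W.gbar, [4.0, 4.0])

    def test_exact_recovery_with_ideal_markers(self, ideal_truth):
        W = estimate_frequencies(ideal_truth.observed, ideal_truth.markers)
        np.testing.assert_allclose(
            W.values, ideal_truth.frequencies.values, atol=1e-6
        )

    def test_columns_on_simplex(self, noisy_truth):
        W = estimate_frequencies(noisy_truth.observed, noisy_truth.markers)
        np.testing.assert_allclose(W.values.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(W.values >= 0) and np.all(W.values <= 1)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        spec = DesignSpec(
            design="three_tissue", n_genes=60, markers_per_type=3,
            marker_fold=100.0, noise_sd=0.05, seed=2,
        )
        truth = generate_truth(spec)
        W1 = estimate_frequencies(truth.observed, truth.markers)
        scaled = ExpressionMatrix(
            scale * truth.observed.values,
            truth.observed.gene_ids,
            truth.observed.sample_ids,
        )
        W2 = estimate_frequencies(scaled, truth.markers)
        np.testing.assert_allclose(W2.values, W1.values, rtol=1e-8, atol=1e-10)

    def test_permutation_equivariance(self, noisy_truth):
        markers = noisy_truth.markers
        W1 = estimate_frequencies(noisy_truth.observed, markers)
        order = list(reversed(markers.cell_type_order))
        permuted = MarkerSet({ct: markers.assignments[ct] for ct in order}, order)
        W2 = estimate_frequencies(noisy_truth.observed, permuted)
        np.testing.assert_allclose(W2.values, W1.values[::-1], rtol=1e-10)
        assert W2.cell_type_order == order

    def test_marker_count_robustness_small_scale(self):
        """More markers per type must not degrade W accuracy (smoke-scale
        version of the 100-seed sweep in the acceptance suite)."""
        from digisort import subsample_markers

        counts = [1, 5, 20]
        mae = np.zeros((10, len(counts)))
        for i, seed in enumerate(range(30, 40)):
            spec = DesignSpec(
                design="three_tissue", n_genes=120, markers_per_type=20,
                marker_fold=100.0, noise_sd=0.1, seed=seed,
            )
            truth = generate_truth(spec)
            for j, m in enumerate(counts):
                sub = subsample_markers(truth, m, seed=seed * 10 + j)
                W = estimate_frequencies(truth.observed, sub)
                mae[i, j] = np.abs(W.values - truth.frequencies.values).mean()
        means = mae.mean(axis=0)
        assert np.all(means[1:] <= 1.10 * means[:-1])
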