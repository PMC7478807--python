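"""kNN entropy and mutual information: closed-form oracles and invariants."""

import numpy as np
import pytest

from nfkbinfo.infotheory import (
    EmbeddedResponses,
    embed_timepoints,
    equispaced_timepoints,
    knn_entropy,
    conditional_entropy,
    mi_dimension_convergence,
    mi_samplesize_bias,
    mutual_information,
)
from nfkbinfo.synthetic_nfkb import TrajectoryEnsemble

from conftest import separated_classes

LN2 = np.log(2.0)


class TestEquispacedTimepoints:
    def test_single_dimension_is_frame_center(self):
        assert equispaced_timepoints(1) == pytest.approx([240.5])

    def test_two_dimensions_are_thirds(self):
        expected = np.linspace(1.0, 480.0, 4)[1:-1]
        assert equispaced_timepoints(2) == pytest.approx(expected)
        assert expected == pytest.approx([160.667, 320.333], abs=1e-3)

    def test_full_resolution_recovers_interior_grid(self):
        tp = equispaced_timepoints(478)
        assert tp == pytest.approx(np.arange(2.0, 480.0))

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            equispaced_timepoints(0)


class TestEmbedding:
    def test_exact_grid_times_extract_columns(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.arange(8.0).reshape(2, 4)
        ens = TrajectoryEnsemble(times, vals, np.array(["A", "B"]))
        emb = embed_timepoints(ens, [2.0, 4.0])
        assert np.array_equal(emb.points, vals[:, [1, 3]])

    def test_half_integer_time_interpolates(self):
        times = np.array([240.0, 241.0])
        ens = TrajectoryEnsemble(times, [[1.0, 3.0]], np.array(["A"]))
        emb = embed_timepoints(ens, [240.5])
        assert emb.points[0, 0] == pytest.approx(2.0)

    def test_shape_is_cells_by_timepoints(self, nfkb_cv25):
        emb = embed_timepoints(nfkb_cv25)
        assert emb.points.shape == (nfkb_cv25.n_cells, 5)

    def test_time_outside_grid_rejected(self):
        ens = TrajectoryEnsemble([1.0, 2.0], [[0.0, 1.0]], np.array(["A"]))
        with pytest.raises(ValueError, match="outside"):
            embed_timepoints(ens, [3.0])


class TestKnnEntropy:
    def test_gaussian_1d_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5000, 1))
        expected = 0.5 * np.log(2 * np.pi * np.e)
        assert knn_entropy(x, k=10) == pytest.approx(expected, abs=0.03)

    def test_uniform_1d_zero_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.random((5000, 1))
        assert knn_entropy(x, k=10) == pytest.approx(0.0, abs=0.03)

    def test_multivariate_gaussian_closed_form(self):
        # replicate-averaged to measure estimator bias rather than noise
        rng = np.random.default_rng(2)
        d = 3
        expected = 0.5 * np.log((2 * np.pi * np.e) ** d)
        ests = [knn_entropy(rng.standard_normal((5000, d)), k=10) for _ in range(4)]
        assert np.mean(ests) == pytest.approx(expected, abs=0.05)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 3))
        assert knn_entropy(x + 7.5, k=5) == pytest.approx(knn_entropy(x, k=5), abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            knn_entropy(np.zeros((5, 2)) + np.arange(5)[:, None], k=10)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            knn_entropy(np.ones((50, 2)), k=3)

    def test_duplicates_floored_not_crashed(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((100, 1))
        x[:30] = x[0]  # heavy duplication, eps=0 for some points
        assert np.isfinite(knn_entropy(x, k=3))


class TestConditionalEntropy:
    def test_degenerate_weights_select_one_class(self):
        pts, labels = separated_classes(n_per_class=200, d=2, m=2, seed=5)
        emb = EmbeddedResponses(pts, labels, np.array([1.0, 2.0]))
        h = conditional_entropy(emb, k=5, q=np.array([1.0, 0.0]))
        assert h == pytest.approx(knn_entropy(pts[labels == "class0"], k=5))

    def test_identical_classes_average_to_class_entropy(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((400, 2))
        pts = np.vstack([a, a + 1e-9])
        labels = np.array(["A"] * 400 + ["B"] * 400)
        emb = EmbeddedResponses(pts, labels, np.array([1.0, 2.0]))
        h = conditional_entropy(emb, k=5)
        assert h == pytest.approx(knn_entropy(a, k=5), abs=1e-6)

    def test_single_distribution_conditional_matches_marginal(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((4000, 2))
        labels = np.array(["A", "B"] * 2000)
        emb = EmbeddedResponses(pts, labels, np.array([1.0, 2.0]))
        assert conditional_entropy(emb, k=10) == pytest.approx(
            knn_entropy(pts, k=10), abs=0.05
        )

    def test_small_class_error_names_class(self):
        pts = np.random.default_rng(8).standard_normal((15, 2))
        labels = np.array(["big"] * 12 + ["tiny"] * 3)
        emb = EmbeddedResponses(pts, labels, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="tiny"):
            conditional_entropy(emb, k=5)


class TestMutualInformation:
    def test_permuted_labels_give_zero_smooth_distribution(self):
        # for a smooth unimodal cloud the raw estimate is unbiased both ways
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((5000, 5))
        labels = np.repeat([f"c{i}" for i in range(5)], 1000)
        est = mutual_information(EmbeddedResponses(pts, rng.permutation(labels), np.arange(5.0)))
        assert abs(est.mi_bits_raw) <= 0.05

    def test_permuted_labels_no_spurious_information(self):
        # clustered mixtures: the null raw estimate is biased negative (the
        # per-class and pooled entropies resolve the clusters at different
        # sample sizes), so shuffling must never yield positive information
        pts, labels = separated_classes(n_per_class=1000, d=5, m=5, seed=9)
        rng = np.random.default_rng(10)
        shuffled = rng.permutation(labels)
        est = mutual_information(EmbeddedResponses(pts, shuffled, np.arange(5.0)))
        assert est.mi_bits_raw <= 0.05
        assert est.mi_bits <= 0.05

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_separated_classes_reach_discrete_limit(self, m):
        pts, labels = separated_classes(n_per_class=1000, d=3, m=m, seed=11)
        est = mutual_information(EmbeddedResponses(pts, labels, np.arange(3.0)))
        assert est.mi_bits == pytest.approx(np.log2(m), abs=0.05)

    def test_bounded_by_log2_class_count(self, nfkb_cv25):
        est = mutual_information(embed_timepoints(nfkb_cv25))
        assert est.mi_bits_raw <= np.log2(5) + 0.05
        assert est.mi_bits >= 0

    def test_affine_map_cancels_exactly(self):
        pts, labels = separated_classes(n_per_class=300, d=4, m=3, seed=12)
        emb = EmbeddedResponses(pts, labels, np.arange(4.0))
        emb2 = EmbeddedResponses(3.7 * pts + 11.0, labels, np.arange(4.0))
        a, b = mutual_information(emb, k=5), mutual_information(emb2, k=5)
        assert b.mi_bits_raw == pytest.approx(a.mi_bits_raw, abs=1e-10)
        # the entropies themselves shift by d*log2(3.7)
        assert b.h_marginal_bits - a.h_marginal_bits == pytest.approx(
            4 * np.log2(3.7), abs=1e-10
        )

    def test_mi_grows_with_class_separation(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal((600, 2))
        labels = np.array(["A"] * 300 + ["B"] * 300)
        mis = []
        for sep in (0.0, 1.0, 3.0, 10.0):
            pts = base.copy()
            pts[300:, 0] += sep
            mis.append(
                mutual_information(EmbeddedResponses(pts, labels, np.arange(2.0))).mi_bits
            )
        assert np.all(np.diff(mis) >= -0.02)

    def test_component_entropies_consistent(self, nfkb_cv25):
        est = mutual_information(embed_timepoints(nfkb_cv25))
        assert est.mi_bits_raw == pytest.approx(
            est.h_marginal_bits - est.h_conditional_bits
        )
        assert est.q == pytest.approx(np.full(5, 0.2))
        assert all(n == 300 for n in est.n_per_class.values())

    def test_single_class_rejected(self):
        pts = np.random.default_rng(14).standard_normal((100, 2))
        emb = EmbeddedResponses(pts, np.array(["A"] * 100), np.arange(2.0))
        with pytest.raises(ValueError, match="2 ligand classes"):
            mutual_information(emb)


class TestDimensionConvergence:
    def test_converges_for_separated_ensemble(self, nfkb_cv10):
        table = mi_dimension_convergence(nfkb_cv10, V_max=8)
        assert list(table["V"]) == list(range(1, 9))
        tail = table["mi_bits"].to_numpy()[3:]  # V >= 4
        assert tail.max() - tail.min() <= 0.1

    def test_single_row_table(self, nfkb_cv25):
        assert len(mi_dimension_convergence(nfkb_cv25, V_max=1)) == 1

    def test_single_ligand_rejected(self):
        ens = TrajectoryEnsemble(
            np.arange(1.0, 481.0),
            np.random.default_rng(15).random((20, 480)),
            np.array(["A"] * 20),
        )
        with pytest.raises(ValueError):
            mi_dimension_convergence(ens)


class TestSampleSizeBias:
    def test_full_fraction_equals_full_ensemble_mi(self, nfkb_cv25):
        table = mi_samplesize_bias(nfkb_cv25, fractions=(1.0,), rng=0)
        full = mutual_information(embed_timepoints(nfkb_cv25)).mi_bits
        assert table["mi_mean_bits"].iloc[0] == full
        assert table["mi_sd_bits"].iloc[0] == 0.0

    def test_bias_line_nearly_flat(self, nfkb_cv10):
        table = mi_samplesize_bias(nfkb_cv10, fractions=(0.25, 0.5, 1.0), reps=3, rng=1)
        slope = np.polyfit(table["inv_N"], table["mi_mean_bits"], 1)[0]
        inv_range = table["inv_N"].max() - table["inv_N"].min()
        assert abs(slope) * inv_range < 0.1

    def test_reproducible_for_fixed_seed(self, nfkb_cv25):
        a = mi_samplesize_bias(nfkb_cv25, fractions=(0.5, 1.0), reps=2, rng=2)
        b = mi_samplesize_bias(nfkb_cv25, fractions=(0.5, 1.0), reps=2, rng=2)
        assert a.equals(b)

    def test_too_small_fraction_rejected(self, nfkb_cv25):
        with pytest.raises(ValueError):
            mi_samplesize_bias(nfkb_cv25, fractions=(0.01,), rng=3)
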