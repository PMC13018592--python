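"""Monte-Carlo dropout, normalized entropy, and the rejection machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trustnet as tn
from trustnet.errors import DataError, ParameterError, StateError
from conftest import labels_of


class TestNormalizedEntropy:
    @pytest.mark.parametrize("probs,expected,tol", [
        ((0.5, 0.5), 1.0, 1e-12),       # complete uncertainty
        ((1.0, 0.0), 0.0, 1e-12),       # complete certainty
        ((0.9, 0.1), 0.4690, 1e-4),     # -(0.9 log2 0.9 + 0.1 log2 0.1)
    ])
    def test_reference_values(self, probs, expected, tol):
        assert tn.normalized_entropy(probs) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", [(0.5, 0.4), (-0.1, 1.1), (2.0,)])
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(ParameterError):
            tn.normalized_entropy(bad)

    @settings(derandomize=True, max_examples=500, deadline=None)
    @given(raw=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6))
    def test_bounds_and_uniform_maximum(self, raw):
        p = np.array(raw) / np.sum(raw)
        p = p / p.sum()
        h = tn.normalized_entropy(p)
        assert 0.0 <= h <= 1.0
        if h == 1.0:  # only the uniform vector reaches the top
            assert np.allclose(p, 1.0 / p.size, atol=1e-9)


class TestMCPredict:
    def test_mean_is_arithmetic_mean_of_passes(self, trained_net, easy_dataset):
        img = easy_dataset.split("test")[0]
        pred = tn.mc_predict(trained_net, img, n_passes=7, p=0.2, seed=3)
        assert np.allclose(pred.mean_probs, pred.per_pass_probs.mean(axis=0))
        assert pred.predicted_index == int(pred.mean_probs.argmax())
        # mean commutes with relabeling of passes
        perm = np.random.default_rng(0).permutation(7)
        assert np.allclose(pred.per_pass_probs[perm].mean(axis=0), pred.mean_probs)

    def test_zero_dropout_equals_deterministic(self, trained_net, easy_dataset):
        img = easy_dataset.split("test")[0]
        pred = tn.mc_predict(trained_net, img, n_passes=5, p=0.0, seed=0)
        det = tn.predict_deterministic(trained_net, img)
        for row in pred.per_pass_probs:
            assert np.array_equal(row, det)

    def test_single_pass_mean_is_the_pass(self, trained_net, easy_dataset):
        pred = tn.mc_predict(trained_net, easy_dataset.split("test")[1],
                             n_passes=1, p=0.3, seed=1)
        assert np.array_equal(pred.mean_probs, pred.per_pass_probs[0])

    def test_seeded_determinism(self, trained_net, easy_dataset):
        img = easy_dataset.split("test")[2]
        a = tn.mc_predict(trained_net, img, n_passes=4, p=0.2, seed=9)
        b = tn.mc_predict(trained_net, img, n_passes=4, p=0.2, seed=9)
        assert np.array_equal(a.per_pass_probs, b.per_pass_probs)

    def test_untrained_state_rejected(self, easy_dataset):
        from conftest import small_config
        net = tn.build_network(small_config())
        with pytest.raises(StateError):
            tn.mc_predict(net, easy_dataset.split("test")[0])


class TestSweepForwardPasses:
    def test_single_pass_row_matches_one_pass_accuracy(self, trained_net, easy_dataset):
        images = easy_dataset.split("test")[:12]
        table = tn.sweep_forward_passes(trained_net, images, n_grid=(1, 4),
                                        p=0.3, seed=5)
        y = labels_of(images)
        singles = [tn.mc_predict(trained_net, img, n_passes=1, p=0.3, seed=5,
                                 image_index=i).predicted_index
                   for i, img in enumerate(images)]
        expected = float(np.mean(np.array(singles) == y))
        assert table.set_index("n_passes").accuracy[1] == expected

    def test_zero_dropout_gives_constant_accuracy(self, trained_net, easy_dataset):
        table = tn.sweep_forward_passes(trained_net, easy_dataset.split("test")[:10],
                                        n_grid=(1, 3, 8), p=0.0, seed=0)
        assert table.accuracy.nunique() == 1

    def test_accuracy_saturates_with_ensemble_size(self, trained_net):
        # |acc(20) - acc(10)| <= |acc(10) - acc(1)| on mixed phantoms,
        # majority over 5 seeds: the cost-accuracy plateau.
        votes = 0
        for seed in range(5):
            ds = tn.generate_dataset(n=80, seed=20 + seed, image_size=48)
            images = ds.split("train")
            t = tn.sweep_forward_passes(trained_net, images, n_grid=(1, 10, 20),
                                        p=0.1, seed=seed).set_index("n_passes")
            if abs(t.accuracy[20] - t.accuracy[10]) <= abs(t.accuracy[10] - t.accuracy[1]):
                votes += 1
        assert votes >= 3

    def test_empty_set_rejected(self, trained_net):
        with pytest.raises(DataError):
            tn.sweep_forward_passes(trained_net, [], n_grid=(1,))


class TestSeparationAndCalibration:
    def test_separation_equals_brute_force_pairwise(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            hc = rng.random(rng.integers(1, 20))
            hm = rng.random(rng.integers(1, 20))
            brute = np.mean([(m > c) + 0.5 * (m == c) for m in hm for c in hc])
            assert tn.separation_score(hc, hm) == pytest.approx(float(brute))

    def test_perfect_separation_case(self):
        assert tn.separation_score([0.1, 0.2], [0.8, 0.9]) == 1.0

    def test_calibrate_selects_best_separating_rate(self, trained_net, mixed_dataset):
        cal = tn.calibrate_dropout(trained_net, mixed_dataset.split("validation"),
                                   p_grid=(0.01, 0.1, 0.3), n_passes=8, seed=0)
        assert cal.p_star in cal.grid
        defined = {p: s for p, s in cal.separation.items() if not np.isnan(s)}
        if defined:
            assert cal.separation[cal.p_star] == max(defined.values())

    def test_all_correct_falls_back_to_smallest_p(self, trained_net, easy_dataset):
        # Confident subset of obvious phantoms: typically zero mistakes.
        easy = easy_dataset.split("test")[:8]
        cal = tn.calibrate_dropout(trained_net, easy, p_grid=(0.05, 0.01),
                                   n_passes=4, seed=0)
        if all(np.isnan(s) for s in cal.separation.values()):
            assert cal.p_star == 0.01
            assert cal.warning is not None


class TestAlphaAndFilter:
    @pytest.mark.parametrize("values,expected", [
        ([0.2, 0.4], 0.3), ([0.7], 0.7), ([0.0, 0.0, 0.0], 0.0),
    ])
    def test_alpha_is_the_mean(self, values, expected):
        assert tn.compute_alpha(values).alpha == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            tn.compute_alpha([])

    def test_threshold_is_inclusive(self):
        pred = tn.MCPrediction(
            per_pass_probs=np.array([[0.6, 0.4]]), mean_probs=np.array([0.6, 0.4]),
            predicted_index=0, entropy=0.4, n_passes=1, dropout_rate=0.1)
        assert tn.uq_filter(pred, tn.UncertaintyThreshold(alpha=0.4)) == "reliable"
        pred.entropy = 0.4 + 1e-9
        assert tn.uq_filter(pred, tn.UncertaintyThreshold(alpha=0.4)) == "flagged"
        pred.entropy = 1.0
        assert tn.uq_filter(pred, tn.UncertaintyThreshold(alpha=1.0)) == "reliable"


class TestUQSafety:
    def test_retained_accuracy_not_below_full_accuracy(self, trained_net):
        # Directional claim: rejecting high-entropy cases never hurts
        # accuracy on the retained subset (majority over 5 seeds).
        votes = 0
        for seed in range(5):
            ds = tn.generate_dataset(n=80, seed=50 + seed, image_size=48)
            images = ds.split("train")
            y = labels_of(images)
            preds = tn.mc_predict_dataset(trained_net, images, n_passes=10,
                                          p=0.1, seed=seed)
            h = np.array([p.entropy for p in preds])
            yhat = np.array([p.predicted_index for p in preds])
            alpha = h.mean()
            keep = h <= alpha
            if keep.any() and (yhat == y)[keep].mean() >= (yhat == y).mean():
                votes += 1
        assert votes >= 3
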