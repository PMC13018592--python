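"""Metrics, Wilson intervals, MoRF/AUPC, calibration, risk-coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trustnet as tn
from trustnet.errors import CalibrationError, DataError, ParameterError
from trustnet.evaluation import ConfusionCounts, metrics_from_counts
from conftest import labels_of


class TestWilson:
    def test_printed_degenerate_bounds(self):
        lo, hi = tn.wilson_ci(100, 100)
        assert lo == pytest.approx(0.9630, abs=5e-4) and hi == 1.0
        lo93, hi93 = tn.wilson_ci(93, 93)
        assert lo93 == pytest.approx(0.9603, abs=5e-4) and hi93 == 1.0

    def test_zero_successes_symmetry(self):
        lo, hi = tn.wilson_ci(0, 100)
        assert lo == 0.0 and hi == pytest.approx(0.0370, abs=5e-4)

    def test_half_proportion(self):
        lo, hi = tn.wilson_ci(50, 100)
        assert lo == pytest.approx(0.4038, abs=1e-3)
        assert hi == pytest.approx(0.5962, abs=1e-3)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for s, n in [(3, 10), (93, 100), (1, 7), (40, 41)]:
            lo, hi = tn.wilson_ci(s, n)
            elo, ehi = proportion_confint(s, n, method="wilson")
            assert lo == pytest.approx(elo, abs=1e-10)
            assert hi == pytest.approx(ehi, abs=1e-10)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(n=st.integers(1, 500), data=st.data())
    def test_interval_contains_point_estimate(self, n, data):
        s = data.draw(st.integers(0, n))
        lo, hi = tn.wilson_ci(s, n)
        assert lo <= s / n <= hi
        assert 0.0 <= lo <= hi <= 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ParameterError):
            tn.wilson_ci(0, 0)


class TestConfusionMetrics:
    def test_imagewise_baseline_counts(self):
        # 100 stroke + 100 normal, 7 FN, 0 FP.
        rep = metrics_from_counts(ConfusionCounts(tp=93, fn=7, tn=100, fp=0))
        assert rep.accuracy.percent == pytest.approx(96.5)
        assert rep.sensitivity.percent == pytest.approx(93.0)
        assert rep.specificity.percent == pytest.approx(100.0)
        assert rep.precision.percent == pytest.approx(100.0)
        assert rep.specificity.ci_low == pytest.approx(96.30, abs=0.05)
        assert rep.precision.ci_low == pytest.approx(96.03, abs=0.05)

    def test_f1_from_precision_and_sensitivity(self):
        # sens 83.08% with prec 100% -> F1 90.76%
        rep = metrics_from_counts(ConfusionCounts(tp=108, fn=22, tn=100, fp=0))
        sens, prec = rep.sensitivity.percent, rep.precision.percent
        f1_harmonic = 2 * prec * sens / (prec + sens)
        assert rep.f1.percent == pytest.approx(f1_harmonic)
        assert rep.f1.percent == pytest.approx(90.76, abs=0.01)
        assert metrics_from_counts(
            ConfusionCounts(tp=540, fn=110, tn=0, fp=0)
        ).sensitivity.percent == pytest.approx(83.08, abs=0.01)

    def test_f1_harmonic_equals_count_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fn, fp = rng.integers(1, 50, 3)
            rep = metrics_from_counts(ConfusionCounts(tp=tp, fn=fn, tn=5, fp=fp))
            assert rep.f1.percent == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))

    def test_all_correct(self):
        counts, rep = tn.confusion_and_metrics(
            [tn.STROKE, tn.NORMAL], [tn.STROKE, tn.NORMAL])
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)
        assert rep.accuracy.percent == 100.0

    def test_abstentions_excluded_but_tallied(self):
        counts, rep = tn.confusion_and_metrics(
            [tn.STROKE, tn.STROKE, tn.NORMAL], [tn.STROKE, None, tn.NORMAL])
        assert counts.abstained == 1 and counts.total == 2
        assert rep.accuracy.percent == 100.0

    def test_zero_denominator_is_nan_not_zero(self):
        rep = metrics_from_counts(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert np.isnan(rep.sensitivity.percent)
        assert np.isnan(rep.precision.percent)


@pytest.fixture(scope="module")
def morf_inputs(trained_net, easy_dataset):
    images = easy_dataset.split("test")[:6]
    maps = [tn.saliency_map(trained_net, img, method="gradcam")
            for img in images]
    return images, maps


class TestMoRF:
    def test_zero_fraction_equals_unperturbed_confidence(self, trained_net,
                                                         morf_inputs):
        images, maps = morf_inputs
        curve = tn.morf_curve(trained_net, images, maps)
        confs = []
        for img in images:
            probs = tn.predict_deterministic(trained_net, img)
            confs.append(probs.max())
        assert curve.mean_confidence[0] == pytest.approx(np.mean(confs), abs=1e-12)
        assert curve.fractions[0] == 0.0

    def test_full_replacement_endpoint(self, trained_net, morf_inputs):
        images, maps = morf_inputs
        curve = tn.morf_curve(trained_net, images, maps, replacement=0.0)
        endpoint = []
        for img in images:
            cls = int(tn.predict_deterministic(trained_net, img).argmax())
            blank = tn.predict_deterministic(trained_net,
                                             np.zeros_like(img.pixels))
            endpoint.append(blank[cls])
        assert curve.mean_confidence[-1] == pytest.approx(np.mean(endpoint))

    def test_shape_mismatch_rejected(self, trained_net, easy_dataset):
        img = easy_dataset.split("test")[0]
        with pytest.raises(DataError):
            tn.morf_curve(trained_net, [img], [np.zeros((3, 3))])

    def test_saliency_ordering_beats_random(self, trained_net, easy_dataset):
        # Faithfulness: removing saliency-ranked pixels first degrades
        # confidence faster than a random ranking (paired, >= 50 strokes).
        strokes = [i for i in easy_dataset.images.values()
                   if i.label == tn.STROKE][:50]
        assert len(strokes) == 50
        maps = [tn.saliency_map(trained_net, img, method="gradcam")
                for img in strokes]
        rng = np.random.default_rng(0)
        rand_maps = [rng.random(img.pixels.shape) for img in strokes]
        aupc_sal = tn.morf_curve(trained_net, strokes, maps, step=0.1).aupc
        aupc_rand = tn.morf_curve(trained_net, strokes, rand_maps, step=0.1).aupc
        assert aupc_sal < aupc_rand


class TestAUPC:
    def _flat_curve(self, value):
        f = np.arange(0, 1.01, 0.05)
        c = np.full_like(f, value)
        return tn.PerturbationCurve(fractions=f, mean_confidence=c,
                                    ci_low=c, ci_high=c,
                                    aupc=float(np.trapezoid(c, f)),
                                    aupc_stepsum=float(c.sum()), n_images=1)

    def test_unit_square_extremes(self):
        assert self._flat_curve(1.0).aupc == pytest.approx(1.0)
        f = np.arange(0, 1.01, 0.05)
        c = 1.0 - f
        linear = tn.PerturbationCurve(fractions=f, mean_confidence=c,
                                      ci_low=c, ci_high=c,
                                      aupc=float(np.trapezoid(c, f)),
                                      aupc_stepsum=float(c.sum()), n_images=1)
        assert linear.aupc == pytest.approx(0.5)

    def test_selection_is_argmin_with_gradcam_ties(self):
        curves = {"gradcam": self._flat_curve(0.4),
                  "gradcam_pp": self._flat_curve(0.4),
                  "scorecam": self._flat_curve(0.6)}
        aupcs, selected = tn.aupc_and_select(curves)
        assert selected == "gradcam"
        assert aupcs["scorecam"] == pytest.approx(0.6)

    def test_mismatched_grids_rejected(self):
        a = self._flat_curve(0.5)
        f = np.arange(0, 1.01, 0.1)
        c = np.full_like(f, 0.5)
        b = tn.PerturbationCurve(fractions=f, mean_confidence=c, ci_low=c,
                                 ci_high=c, aupc=0.5, aupc_stepsum=float(c.sum()),
                                 n_images=1)
        with pytest.raises(DataError):
            tn.aupc_and_select({"gradcam": a, "scorecam": b})


class TestCalibration:
    def test_perfect_predictions_are_perfectly_calibrated(self):
        rep = tn.calibration_metrics([1.0] * 5, [True] * 5, [1.0] * 5, [1] * 5)
        assert rep.ece == 0.0 and rep.mce == 0.0 and rep.brier == 0.0

    def test_single_sample_gap(self):
        rep = tn.calibration_metrics([0.7], [True], [0.7], [1])
        assert rep.ece == pytest.approx(0.3) and rep.mce == pytest.approx(0.3)

    def test_brier_contribution(self):
        rep = tn.calibration_metrics([0.5], [False], [0.5], [1])
        assert rep.brier == pytest.approx(0.25)

    def test_ece_never_exceeds_mce(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 100))
            conf = rng.random(n)
            corr = rng.random(n) < conf
            rep = tn.calibration_metrics(conf, corr, conf, corr.astype(int))
            assert rep.ece <= rep.mce + 1e-12


class TestTemperature:
    def _calibrated_logits(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 2, size=n)
        p = 1 / (1 + np.exp(-z))
        y = (rng.random(n) < p).astype(int)
        logits = np.column_stack([np.zeros(n), z])  # class-1 logit = z
        return logits, y

    def test_already_optimal_logits_give_unit_temperature(self):
        logits, y = self._calibrated_logits()
        assert tn.fit_temperature(logits, y) == pytest.approx(1.0, abs=0.02)

    def test_recovers_known_scaling(self):
        logits, y = self._calibrated_logits()
        t = tn.fit_temperature(3.0 * logits, y)
        assert t == pytest.approx(3.0, rel=0.05)

    def test_scaling_preserves_predictions(self):
        logits, y = self._calibrated_logits(n=200)
        t = tn.fit_temperature(logits, y)
        assert np.array_equal((logits / t).argmax(axis=1), logits.argmax(axis=1))

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            tn.fit_temperature(np.zeros((5, 2)), [1, 1, 1, 1, 1])

    def test_full_report_on_trained_model(self, trained_net, mixed_dataset):
        val = mixed_dataset.split("validation")
        tst = mixed_dataset.split("test")
        rep = tn.calibration_with_temperature(
            tn.predict_logits_batch(trained_net, val), labels_of(val),
            tn.predict_logits_batch(trained_net, tst), labels_of(tst))
        assert 0 <= rep.ece <= rep.mce <= 1
        assert 0 <= rep.brier <= 1
        assert rep.temperature > 0


class TestRiskCoverage:
    def test_all_correct_gives_zero_risk(self):
        curve = tn.risk_coverage_curve([0.1, 0.5, 0.9], [True, True, True])
        covered = curve[curve.coverage > 0]
        assert (covered.risk == 0).all()

    def test_full_coverage_risk_is_error_rate(self):
        curve = tn.risk_coverage_curve([0.2, 0.4, 0.6, 0.8],
                                       [True, True, False, True])
        last = curve.iloc[-1]
        assert last.threshold == 1.0 and last.coverage == 1.0
        assert last.risk == pytest.approx(0.25)

    def test_perfectly_ordered_errors_give_monotone_risk(self):
        # Brute-force 10-sample case: wrong predictions carry the highest
        # entropies, so risk is non-increasing as coverage decreases.
        h = np.arange(10) / 10.0
        correct = h < 0.7
        curve = tn.risk_coverage_curve(h, correct)
        risks = curve[curve.coverage > 0].sort_values("coverage").risk.values
        assert all(a <= b + 1e-12 for a, b in zip(risks, risks[1:]))
        # brute-force check of each point
        for _, row in curve.iterrows():
            covered = h <= row.threshold
            if covered.any():
                assert row.risk == pytest.approx(1 - correct[covered].mean())

    def test_coverage_nondecreasing(self):
        rng = np.random.default_rng(5)
        h = rng.random(30)
        c = rng.random(30) < 0.8
        curve = tn.risk_coverage_curve(h, c)
        assert (np.diff(curve.coverage) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            tn.risk_coverage_curve([], [])
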