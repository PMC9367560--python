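"""Training schedule, metrics against brute-force oracles, reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import toy_series
from vista.model import ViSTAClassifier
from vista.traineval import (RADIOLOGIST_REFERENCE, TrainConfig, auc,
                             best_youden_cutoff, compare_report, cosine_lr,
                             evaluate_scorer, fit_network, thresholded_metrics)


# -- independent oracles -----------------------------------------------------

def pairwise_concordance(scores, labels):
    """AUC as the probability a positive outscores a negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best J over every threshold, scanning a dense candidate grid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    candidates = np.concatenate([[-np.inf, np.inf], np.unique(scores),
                                 np.unique(scores) - 1e-9,
                                 np.unique(scores) + 1e-9])
    best_j, best_t = -np.inf, None
    for t in np.sort(candidates):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        spec = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_j


class TestCosineSchedule:
    CFG = TrainConfig(epochs=100)

    def test_endpoints(self):
        assert cosine_lr(0, self.CFG) == pytest.approx(1e-3)
        assert cosine_lr(100, self.CFG) == pytest.approx(1e-6)
        # final trained epoch is within one step of the closed-form minimum
        assert cosine_lr(99, self.CFG) < cosine_lr(98, self.CFG) < 1e-5

    def test_midpoint(self):
        mid = cosine_lr(50, self.CFG)
        assert mid == pytest.approx(1e-6 + (1e-3 - 1e-6) / 2, rel=1e-9)
        assert mid == pytest.approx(5.005e-4, rel=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_max=1e-6, lr_min=1e-3)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestAUC:
    def test_perfect_and_uninformative(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_documented_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_matches_pairwise_concordance(self, data):
        n = data.draw(st.integers(4, 50))
        # draw from a small discrete grid to force ties
        scores = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(
            pairwise_concordance(scores, labels), abs=1e-12)


class TestThresholdedMetrics:
    def test_confusion_counts(self):
        rep = thresholded_metrics([0.1, 0.6, 0.7, 0.2], [0, 1, 0, 1], 0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (1, 1, 1, 1)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(0.5)

    @pytest.mark.parametrize("tp,fp,fn,tn,f1_expected", [
        (29, 10, 3, 27, 0.817),    # precision .744, sensitivity .906
        (5, 2, 27, 35, 0.256),     # precision .714, sensitivity .156
    ])
    def test_f1_from_observer_style_counts(self, tp, fp, fn, tn, f1_expected):
        scores = np.concatenate([np.ones(tp), np.ones(fp),
                                 np.zeros(fn), np.zeros(tn)])
        labels = np.concatenate([np.ones(tp), np.zeros(fp),
                                 np.ones(fn), np.zeros(tn)])
        rep = thresholded_metrics(scores, labels, 0.5)
        assert rep.f1 == pytest.approx(f1_expected, abs=5e-4)

    def test_f1_harmonic_identity(self):
        # precision == sensitivity == 0.75 -> f1 == 0.75
        rep = thresholded_metrics([1, 1, 1, 1, 0, 0], [1, 1, 1, 0, 1, 0], 0.5)
        assert rep.precision == rep.sensitivity == rep.f1 == pytest.approx(0.75)

    def test_undefined_metrics_reported_as_none(self):
        rep = thresholded_metrics([0.1, 0.2], [0, 1], threshold=0.9)
        assert rep.precision is None       # no positive predictions
        assert rep.f1 is None
        assert rep.sensitivity == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_internal_consistency(self, data):
        n = data.draw(st.integers(4, 40))
        scores = np.array(data.draw(st.lists(st.floats(0, 1), min_size=n,
                                             max_size=n)))
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n,
                                             max_size=n)))
        rep = thresholded_metrics(scores, labels, 0.5)
        assert rep.tp + rep.fp + rep.tn + rep.fn == n
        if rep.accuracy is not None:
            assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / n)
        if rep.f1 is not None:
            p, r = rep.precision, rep.sensitivity
            assert rep.f1 == pytest.approx(2 * p * r / (p + r))


class TestYoudenCutoff:
    def test_all_equal_scores(self):
        rule = best_youden_cutoff([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1])
        assert rule.youden == pytest.approx(0.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            best_youden_cutoff([0.1, 0.2], [0, 0])

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_matches_exhaustive_search(self, data):
        n = data.draw(st.integers(4, 50))
        scores = np.array(data.draw(st.lists(st.integers(0, 8), min_size=n,
                                             max_size=n)), dtype=float)
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n,
                                             max_size=n)))
        if len(set(labels.tolist())) < 2:
            labels[0], labels[1] = 0, 1
        rule = best_youden_cutoff(scores, labels)
        assert rule.youden == pytest.approx(exhaustive_youden(scores, labels),
                                            abs=1e-9)


class TestTrainingLoop:
    def _samples(self, n, rng):
        from vista.traineval import SeriesSample

        out = []
        for i in range(n):
            s = toy_series(rng, n_steps=3, patch=16)
            out.append(SeriesSample(s.patches, s.times, i % 2))
        return out

    def test_loss_decreases_on_smoke_run(self, rng):
        from conftest import tiny_network

        net = tiny_network(np.random.default_rng(0))
        samples = self._samples(8, rng)
        cfg = TrainConfig(epochs=5, seed=0, batch_size=4, augment=False)
        history = fit_network(net, samples, None, cfg)
        assert len(history) == 5
        assert history[-1].train_loss < history[0].train_loss

    def test_empty_split_rejected(self):
        from conftest import tiny_network

        with pytest.raises(ValueError, match="empty training split"):
            fit_network(tiny_network(), [], None, TrainConfig(epochs=1))

    def test_full_pipeline_determinism(self, tiny_cohort):
        y = np.array([1 if s.label == "IA" else 0 for s in tiny_cohort])

        def run():
            clf = ViSTAClassifier(dim=8, channels=(4, 8, 8, 8), epochs=3,
                                  random_state=5, validation_fraction=0.2)
            clf.fit(tiny_cohort[:40], y[:40])
            return clf.decision_function(tiny_cohort[40:]), clf.history_

        s1, h1 = run()
        s2, h2 = run()
        assert np.array_equal(s1, s2)
        assert [r.train_loss for r in h1] == [r.train_loss for r in h2]
        assert [r.val_auc for r in h1] == [r.val_auc for r in h2]


class TestCompareReport:
    def test_radiologist_reference_rows(self, tmp_path):
        rep = evaluate_scorer([0.2, 0.4, 0.6, 0.9], [0, 0, 1, 1], threshold=0.5)
        table = compare_report({"ViSTA": rep}, RADIOLOGIST_REFERENCE,
                               out_dir=tmp_path)
        senior = table[table["method"] == "Senior"].iloc[0]
        assert senior["reference"]
        assert senior["accuracy"] == pytest.approx(0.855)
        assert senior["precision"] == pytest.approx(0.824)
        assert senior["sensitivity"] == pytest.approx(0.875)
        assert senior["f1"] == pytest.approx(0.848)
        assert (tmp_path / "comparison.csv").exists()
        assert (tmp_path / "roc.png").exists()

    def test_model_only_table(self):
        rep = evaluate_scorer([0.2, 0.9], [0, 1])
        table = compare_report({"m": rep}, radiologists={})
        assert len(table) == 1
        assert not table["reference"].any()

    def test_perfect_scorer_roc_through_corner(self):
        rep = evaluate_scorer([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert rep.auc == 1.0
        assert (0.0, 1.0) in [(f, t) for f, t in rep.roc]
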