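"""VDT arithmetic and policies; static CNN and CNN+LSTM baseline contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import TINY_BACKBONE, TINY_PATCH, toy_series
from vista.baselines import (CNNLSTMClassifier, CNNLSTMNetwork,
                             CNNStaticClassifier, VDTClassifier, compute_vdt,
                             vdt_classify, vdt_score_series)
from vista.model import BackboneConfig, count_params
from vista.preprocess import FollowUpSeries, series_from_synthetic
from vista.synth import GrowthParams, sample_series, simulate_cohort
from vista.traineval import CutoffRule, auc, best_youden_cutoff


class TestComputeVDT:
    def test_doubling_identity(self):
        assert compute_vdt(100.0, 200.0, 100.0).vdt_days == pytest.approx(100.0)

    def test_no_growth_conventions(self):
        res = compute_vdt(150.0, 150.0, 200.0)
        assert res.inv_vdt == 0.0
        assert res.vdt_days == np.inf

    def test_precise_value(self):
        # 365 * ln 2 / ln 1.5
        res = compute_vdt(100.0, 150.0, 365.0)
        assert res.vdt_days == pytest.approx(365.0 * np.log(2) / np.log(1.5),
                                             rel=1e-12)
        assert res.vdt_days == pytest.approx(624.0, abs=0.1)

    def test_invalid_inputs(self):
        for bad in [(0.0, 100.0, 10.0), (100.0, -5.0, 10.0), (100.0, 100.0, 0.0)]:
            with pytest.raises(ValueError):
                compute_vdt(*bad)

    @settings(deadline=None, max_examples=100)
    @given(v1=st.floats(1.0, 1e5), v2=st.floats(1.0, 1e5),
           dt=st.floats(1.0, 3000.0))
    def test_antisymmetric_under_volume_swap(self, v1, v2, dt):
        a = compute_vdt(v1, v2, dt).inv_vdt
        b = compute_vdt(v2, v1, dt).inv_vdt
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-15)


class TestVDTSeries:
    def test_recovers_simulator_doubling_time(self):
        p = GrowthParams(v0=200.0, dt_double=200.0, noise_sd=0.0)
        syn = sample_series(p, np.random.default_rng(17))
        series = series_from_synthetic(syn)
        res = vdt_score_series(series)
        assert res.vdt_days == pytest.approx(200.0, rel=0.10)

    def test_static_series_zero_score(self):
        p = GrowthParams(v0=400.0, dt_double=np.inf, noise_sd=0.0)
        syn = sample_series(p, np.random.default_rng(18))
        series = series_from_synthetic(syn)
        assert vdt_score_series(series).inv_vdt == 0.0

    def test_shrinkage_negative_score(self):
        series = FollowUpSeries("S", np.array([0.0, 100.0]),
                                np.zeros((2, 4, 4, 4)),
                                np.array([300.0, 200.0]), None)
        assert vdt_score_series(series).inv_vdt < 0.0

    def test_single_point_rejected(self):
        series = FollowUpSeries("S", np.array([0.0]), np.zeros((1, 4, 4, 4)),
                                np.array([100.0]), None)
        with pytest.raises(ValueError):
            vdt_score_series(series)


class TestVDTClassify:
    FIXED = CutoffRule(threshold=1 / 400.0, origin="fixed_400_days")

    def test_fast_grower_positive_under_400_rule(self):
        assert vdt_classify(compute_vdt(100.0, 200.0, 399.0), self.FIXED) \
            == "positive"
        assert vdt_classify(compute_vdt(100.0, 200.0, 401.0), self.FIXED) \
            == "negative"

    def test_static_negative_under_both_rules(self):
        res = compute_vdt(100.0, 100.0, 365.0)
        youden = CutoffRule(threshold=0.001, origin="best_youden")
        assert vdt_classify(res, self.FIXED) == "negative"
        assert vdt_classify(res, youden) == "negative"

    def test_youden_cutoff_separates_separable_set(self):
        scores = np.array([-0.01, -0.005, 0.0, 0.002, 0.004, 0.008])
        labels = np.array([0, 0, 0, 1, 1, 1])
        rule = best_youden_cutoff(scores, labels)
        pred = scores >= rule.threshold
        assert np.array_equal(pred.astype(int), labels)
        assert rule.youden == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_cohort():
    cohort = simulate_cohort(40, seed=23)
    return [series_from_synthetic(s, patch_size=TINY_PATCH) for s in cohort]


class TestVDTClassifierEstimator:

    def test_fixed_rule(self, small_cohort):
        small = small_cohort
        clf = VDTClassifier(cutoff="fixed").fit(small)
        assert clf.rule_.origin == "fixed_400_days"
        preds = clf.predict(small)
        assert set(preds) <= {0, 1}

    def test_youden_calibration_and_table(self, small_cohort):
        small = small_cohort
        clf = VDTClassifier(cutoff="youden").fit(small)
        table = clf.results_table(small)
        assert list(table.columns) == ["series_id", "v1", "v2", "dt_days",
                                       "vdt_days", "inv_vdt", "pred"]
        assert len(table) == len(small)
        assert clf.get_params()["cutoff"] == "youden"


class TestCNNLSTM:
    def test_interval_blind_by_construction(self, rng):
        net = CNNLSTMNetwork(BackboneConfig(**TINY_BACKBONE), hidden_dim=8,
                             rng=rng).eval()
        series = toy_series(np.random.default_rng(3), n_steps=4)
        feats = net.encode(series.patches)
        from vista._autodiff import no_grad
        with no_grad():
            a = net.temporal_logit(feats, series.times).data
            b = net.temporal_logit(feats, series.times * 7.3).data
        assert a == b

    def test_single_step_defined(self, rng):
        net = CNNLSTMNetwork(BackboneConfig(**TINY_BACKBONE), hidden_dim=8,
                             rng=rng).eval()
        series = toy_series(np.random.default_rng(4), n_steps=1)
        from vista._autodiff import no_grad
        with no_grad():
            logit = net.temporal_logit(net.encode(series.patches), series.times)
        p = 1 / (1 + np.exp(-float(logit.data)))
        assert 0.0 <= p <= 1.0

    def test_lstm_module_larger_than_simta(self):
        from vista.model import SimTAConfig, ViSTANetwork

        cfg = BackboneConfig(**TINY_BACKBONE)
        lstm = CNNLSTMNetwork(cfg, hidden_dim=cfg.dim,
                              rng=np.random.default_rng(0))
        vista = ViSTANetwork(cfg, SimTAConfig(dim=cfg.dim),
                             np.random.default_rng(0))
        lstm_part = count_params(lstm.cell) + count_params(lstm.head)
        simta_part = sum(count_params(l) for l in vista.layers) \
            + count_params(vista.head)
        assert lstm_part > simta_part


class TestCNNStaticPolicies:
    def test_sample_selection(self, tiny_cohort):
        y = np.ones(len(tiny_cohort), dtype=int)
        total_scans = sum(len(s) for s in tiny_cohort)
        all_points = CNNStaticClassifier(train_policy="all_points")
        assert len(all_points._train_samples(tiny_cohort, y)) == total_scans
        first = CNNStaticClassifier(train_policy="first_only")
        samples = first._train_samples(tiny_cohort, y)
        assert len(samples) == len(tiny_cohort)
        assert all(s.patches.shape[0] == 1 for s in samples)

    def test_policy_constrains_training_not_applicability(self, tiny_cohort):
        clf = CNNStaticClassifier(train_policy="first_only", eval_policy="last",
                                  dim=8, channels=(4, 8, 8, 8), epochs=1,
                                  validation_fraction=0.0, random_state=0)
        clf.fit(tiny_cohort[:20])
        probs = clf.predict_proba(tiny_cohort[20:24])
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_unknown_policy_rejected(self, tiny_cohort):
        clf = CNNStaticClassifier(train_policy="median_only")
        with pytest.raises(ValueError):
            clf._train_samples(tiny_cohort, np.ones(len(tiny_cohort), dtype=int))


def test_last_scan_beats_first_scan_on_growth_labels():
    """Median over 5 seeds: last-scan CNN >= first-scan CNN in test AUC.

    Baseline size and density are drawn independently of the label, so the
    first scan is nearly uninformative while the last scan reflects the
    realized growth and solid transformation.
    """
    cohort = [series_from_synthetic(s, patch_size=TINY_PATCH)
              for s in simulate_cohort(150, seed=19)]
    y = np.array([1 if s.label == "IA" else 0 for s in cohort])
    train, test = cohort[:90], cohort[90:]
    ytr, yte = y[:90], y[90:]
    diffs = []
    for seed in range(5):
        aucs = {}
        for policy in ("last", "first"):
            clf = CNNStaticClassifier(train_policy=f"{policy}_only",
                                      eval_policy=policy, dim=8,
                                      channels=(4, 8, 8, 8), epochs=10,
                                      validation_fraction=0.0,
                                      random_state=seed)
            clf.fit(train, ytr)
            aucs[policy] = auc(clf.decision_function(test), yte)
        diffs.append(aucs["last"] - aucs["first"])
    assert np.median(diffs) >= 0.0
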