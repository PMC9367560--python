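"""Scaled-down study pipeline: simulate a cohort, train all methods, compare.

The default conditions mirror the study design: 351 follow-up series with an
IA prevalence of 160/351, a nodule-level 245/37/69 train/validation/test
split, 32 mm cubic patches, and a 20-epoch training budget per model — a
desk-scale protocol that one CPU completes in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import CNNLSTMClassifier, CNNStaticClassifier, VDTClassifier
from .model import ViSTAClassifier
from .preprocess import FollowUpSeries, series_from_synthetic
from .synth import assign_splits, simulate_cohort
from .traineval import (MetricsReport, as_binary_labels, best_youden_cutoff,
                        evaluate_scorer)

DEFAULT_N_SERIES = 351
DEFAULT_IA_FRACTION = 160.0 / 351.0
DEFAULT_SPLIT = (245 / 351, 37 / 351, 69 / 351)
DEFAULT_EPOCHS = 20


@dataclass
class SplitData:
    train: list[FollowUpSeries]
    val: list[FollowUpSeries]
    test: list[FollowUpSeries]

    def labels(self, which: str) -> np.ndarray:
        return as_binary_labels([s.label for s in getattr(self, which)])


def make_benchmark_data(dataset_seed: int = 42,
                        n_series: int = DEFAULT_N_SERIES,
                        ia_fraction: float = DEFAULT_IA_FRACTION,
                        split: tuple = DEFAULT_SPLIT,
                        patch_size: int = 32) -> SplitData:
    """Simulate and preprocess the default cohort, split at nodule level."""
    rng = np.random.default_rng(dataset_seed)
    cohort = simulate_cohort(n_series, ia_fraction, rng)
    splits = assign_splits([s.label for s in cohort], split, rng)
    data = SplitData([], [], [])
    for syn, sp in zip(cohort, splits):
        series = series_from_synthetic(syn, patch_size=patch_size)
        getattr(data, {"train": "train", "val": "val", "test": "test"}[sp]).append(series)
    return data


def _net_kwargs(epochs, seed):
    return dict(epochs=epochs, random_state=seed, validation_fraction=0.0)


def build_methods(epochs: int = DEFAULT_EPOCHS, seed: int = 0) -> dict:
    """The evaluated scorers, keyed by their conventional names."""
    return {
        "ViSTA": ViSTAClassifier(**_net_kwargs(epochs, seed)),
        "CNN+LSTM": CNNLSTMClassifier(**_net_kwargs(epochs, seed)),
        "CNN-last": CNNStaticClassifier(train_policy="last_only",
                                        eval_policy="last",
                                        **_net_kwargs(epochs, seed)),
        "1/VDT": VDTClassifier(cutoff="youden"),
    }


def run_benchmark(data: SplitData | None = None, dataset_seed: int = 42,
                  train_seed: int = 0, epochs: int = DEFAULT_EPOCHS,
                  methods: dict | None = None,
                  ) -> dict[str, MetricsReport]:
    """Fit every method on the train split and evaluate on the test split.

    Network checkpoints are selected by validation AUC; decision thresholds
    come from the best Youden index on the validation split, applied to the
    test split.
    """
    if data is None:
        data = make_benchmark_data(dataset_seed)
    methods = methods if methods is not None else build_methods(epochs, train_seed)
    y_val, y_test = data.labels("val"), data.labels("test")
    reports: dict[str, MetricsReport] = {}
    for name, clf in methods.items():
        if isinstance(clf, VDTClassifier):
            clf.fit(data.val, y_val)
        else:
            clf.fit(data.train, data.labels("train"),
                    validation_data=(data.val, y_val))
        val_scores = clf.decision_function(data.val)
        rule = best_youden_cutoff(val_scores, y_val)
        test_scores = clf.decision_function(data.test)
        reports[name] = evaluate_scorer(test_scores, y_test, rule.threshold)
    return reports
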