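"""Evaluation summaries for decomposition and classification runs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import PhenotypeResults, accuracy
from .decomposition import DecompositionResult, overlap_score, random_baseline
from .io import FeatureMatrix
from .simulate import SyntheticTruth


@dataclass
class DecompositionEvaluation:
    """Mean top-k overlap with annotations, per-dish detail, and a null mean."""

    mean_overlap: float
    per_dish: pd.DataFrame  # dish, annotated, predicted, overlap
    baseline_mean: float | None = None

    def summary(self) -> str:
        lines = [
            "Decomposition evaluation",
            f"  dishes: {len(self.per_dish)}   mean overlap: {self.mean_overlap:.3f}",
        ]
        if self.baseline_mean is not None:
            lines.append(f"  random-baseline mean overlap: {self.baseline_mean:.3f}")
        return "\n".join(lines)


def evaluate_decomposition(
    results: Sequence[DecompositionResult],
    truths: Sequence[SyntheticTruth | set | list],
    library: FeatureMatrix | None = None,
    n_baseline: int = 200,
    seed: int = 0,
) -> DecompositionEvaluation:
    """Score predicted ingredient sets against annotated ones.

    The null reference, when a ``library`` is given, is the mean overlap of a
    uniform random k-subset predictor over ``n_baseline`` seeded draws
    (analytically k·m/n for annotation size m and library size n).
    """
    if len(results) != len(truths):
        raise ValueError(
            f"{len(results)} results vs {len(truths)} truth records"
        )
    if not results:
        raise ValueError("empty result list")
    rows = []
    for i, (res, truth) in enumerate(zip(results, truths)):
        annotated = (
            truth.true_ingredients if isinstance(truth, SyntheticTruth) else truth
        )
        ov = overlap_score(res.selected, annotated) if res.selected else 0
        rows.append(
            {
                "dish": f"dish{i:04d}",
                "annotated": ";".join(sorted(annotated)),
                "predicted": ";".join(res.selected),
                "overlap": ov,
            }
        )
    per_dish = pd.DataFrame(rows)
    baseline_mean = None
    if library is not None:
        k = max((len(r.selected) for r in results), default=0) or 5
        draws = []
        rng = np.random.default_rng(seed)
        for res, truth in zip(results, truths):
            annotated = set(
                truth.true_ingredients if isinstance(truth, SyntheticTruth) else truth
            )
            for _ in range(max(1, n_baseline // len(results))):
                pred = random_baseline(library, k=k, seed=int(rng.integers(2**31)))
                draws.append(len(pred & annotated))
        baseline_mean = float(np.mean(draws))
    return DecompositionEvaluation(
        mean_overlap=float(per_dish["overlap"].mean()),
        per_dish=per_dish,
        baseline_mean=baseline_mean,
    )


@dataclass
class ClassificationEvaluation:
    """Overall accuracy plus a truth-rows × prediction-columns confusion matrix."""

    accuracy: float
    confusion: pd.DataFrame

    def summary(self) -> str:
        return (
            f"Classification evaluation\n  accuracy: {self.accuracy:.4f}\n"
            f"{self.confusion.to_string()}"
        )


def evaluate_classification(
    results: PhenotypeResults,
    X_test: FeatureMatrix,
    y_test,
) -> ClassificationEvaluation:
    """Accuracy and confusion matrix of a fitted model on held-out samples.

    ``y_test`` may be a PhenotypeTable or a plain label vector ordered like
    the columns of ``X_test``.  Confusion rows are truth, columns are
    prediction; every test sample is counted exactly once, so row sums equal
    class sizes.
    """
    if hasattr(y_test, "labels") and hasattr(y_test, "sample_ids"):
        X_test = X_test.reorder_samples(y_test.sample_ids)
        truth = np.asarray(y_test.labels, dtype=str)
    else:
        truth = np.asarray(y_test, dtype=str)
    pred = results.predict(X_test).astype(str)
    classes = sorted(set(truth) | set(pred) | set(results.class_labels))
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        confusion.loc[t, p] += 1
    confusion.index.name = "truth"
    confusion.columns.name = "predicted"
    return ClassificationEvaluation(
        accuracy=accuracy(pred, truth), confusion=confusion
    )
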