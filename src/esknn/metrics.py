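"""Performance measures for two-class probabilistic classifiers:
misclassification rate and the Brier score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalResult", "misclassification_rate", "brier_score", "evaluate"]


@dataclass(frozen=True)
class EvalResult:
    """Misclassification rate and Brier score on a test set."""

    misclassification_rate: float
    brier_score: float
    n_points: int


def misclassification_rate(y_true, y_pred) -> float:
    """Fraction of positions where predicted and true labels differ."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must share a nonzero length")
    return float(np.mean(y_true != y_pred))


def brier_score(y_true, probs) -> float:
    """Mean squared difference between 0/1 outcomes and predicted
    class-1 probabilities: (1/n) * sum_i (y_i - p_i)^2.  Lower is
    better; a perfectly calibrated, perfectly sharp predictor scores 0.
    """
    y_true = np.asarray(y_true, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if y_true.shape != probs.shape or y_true.size == 0:
        raise ValueError("outcome and probability vectors must share a nonzero length")
    if np.any((probs < 0.0) | (probs > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((y_true - probs) ** 2))


def evaluate(y_true, probs, threshold: float = 0.5) -> EvalResult:
    """Both scores at once, classifying by strict threshold on the
    class-1 probability."""
    y_true = np.asarray(y_true)
    pred = (np.asarray(probs) > threshold).astype(int)
    return EvalResult(
        misclassification_rate=misclassification_rate(y_true, pred),
        brier_score=brier_score(y_true, probs),
        n_points=int(y_true.size),
    )
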