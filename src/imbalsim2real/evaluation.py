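"""Metrics: validation scores, success rates, multi-run statistics.

Note on naming: the benchmark "validation MSE" reported by this package is a
*sum* of squared errors per partition, not a mean — the paired and unpaired
partition scores add up to the total.  The name is kept for continuity with
the field's usage but :class:`ValidationReport` documents the convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import ImbalancedDataset


@dataclass(frozen=True)
class ValidationReport:
    """Sum-of-squared-error scores of the sim->real mapping vs analytic truth.

    ``score_total = score_paired + score_unpaired`` by construction; the
    partition follows the dataset's paired/unpaired source split.
    """

    score_paired: float
    score_unpaired: float
    residuals_paired: np.ndarray
    residuals_unpaired: np.ndarray

    @property
    def score_total(self) -> float:
        return self.score_paired + self.score_unpaired


def validation_score(
    predict_fn: Callable,
    dataset: ImbalancedDataset,
    truth_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> ValidationReport:
    """Score a sim->real response mapping over all source covariate points.

    ``predict_fn(covariates, y1)`` maps raw-unit source samples to predicted
    target responses; ``truth_fn(x1, x2)`` (or ``truth_fn(*covariate
    columns)``) gives the analytic target response.  Scores are sums of
    squared errors per partition.
    """
    src = dataset.source_samples()
    if not src:
        raise ValueError("dataset has no source samples")
    cov = np.array([s.covariates for s in src])
    y1 = np.array([s.response for s in src])
    pred = np.asarray(predict_fn(cov, y1), dtype=float).ravel()
    truth = np.asarray(truth_fn(*(cov[:, j] for j in range(cov.shape[1])))).ravel()
    resid = pred - truth
    npair = dataset.n_paired
    rp, ru = resid[:npair], resid[npair:]
    return ValidationReport(
        score_paired=float(np.sum(rp**2)),
        score_unpaired=float(np.sum(ru**2)),
        residuals_paired=rp,
        residuals_unpaired=ru,
    )


def success_rate(predicted_angles, true_angles, tolerance: float = 0.10) -> float:
    """Percentage of predictions within ``tolerance`` (relative) of truth.

    The band is relative to the true value, so zero-truth rows (e.g.
    zero-pressure angles) must be excluded upstream.
    """
    pred = np.asarray(predicted_angles, dtype=float).ravel()
    true = np.asarray(true_angles, dtype=float).ravel()
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predicted and true angles must be equal-length, non-empty")
    if np.any(true == 0):
        raise ValueError(
            "true angles contain zeros; exclude zero-pressure rows before scoring"
        )
    ok = np.abs(pred - true) <= tolerance * np.abs(true)
    return float(100.0 * np.count_nonzero(ok) / pred.size)


def convergence_success_index(run_scores: Sequence[float], threshold: float = 150.0) -> float:
    """Percentage of runs whose final validation score is below ``threshold``."""
    scores = np.asarray(run_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("run_scores must be non-empty")
    return float(100.0 * np.count_nonzero(scores < threshold) / scores.size)


def multi_run_stats(run_scores: Sequence[float]) -> tuple[float, float]:
    """(mean, sample variance) across independent runs; needs n >= 2."""
    scores = np.asarray(run_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("variance requires at least 2 runs")
    return float(scores.mean()), float(scores.var(ddof=1))


def stiffness_report(
    predict_fn: Callable,
    validation_sets: Mapping[float, Mapping[str, np.ndarray]],
) -> dict:
    """Per-stiffness estimation summary plus total and average MSE.

    ``validation_sets`` maps true stiffness -> {"pressure", "angle_real"}
    arrays.  For each group the estimator predicts stiffness from (pressure,
    real-world angle); the report gives the prediction mean and STD per
    group, the total (summed) squared error over all points, and the
    average squared error per point.
    """
    per_stiffness: dict[float, tuple[float, float]] = {}
    total, count = 0.0, 0
    for k, grids in validation_sets.items():
        P = np.asarray(grids["pressure"], dtype=float)
        theta = np.asarray(grids["angle_real"], dtype=float)
        if P.size == 0:
            raise ValueError(f"empty validation group for stiffness {k}")
        pred = np.asarray(predict_fn(P, theta), dtype=float).ravel()
        per_stiffness[float(k)] = (float(pred.mean()), float(pred.std()))
        total += float(np.sum((pred - k) ** 2))
        count += pred.size
    return {
        "per_stiffness": per_stiffness,
        "total_mse": total,
        "average_mse": total / count,
        "n_points": count,
    }
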