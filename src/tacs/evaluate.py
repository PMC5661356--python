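"""Evaluation metrics: centroid matching, precision/recall/success, spike timing, SNR.

Detected ROIs are matched one-to-one to ground-truth cells when their
centroids lie within 5 pixels; spike estimates match ground-truth spikes
within 0.22 s.  Precision is the percentage of estimates that match,
recall the percentage of truths that are found, fall-out the complement of
precision, and the success rate is the harmonic mean of precision and
recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "EvalReport",
    "mask_centroids",
    "match_rois",
    "precision_recall_fallout",
    "success_rate",
    "table_percent",
    "match_spikes",
    "snr_db",
    "snr_power",
]

#: Matching thresholds: 5 px between ROI centroids, 0.22 s between spikes.
ROI_MATCH_DIST_PX = 5.0
SPIKE_MATCH_WINDOW_S = 0.22


@dataclass
class MatchResult:
    """One-to-one pairing between estimate and truth sets."""

    pairs: list[tuple[int, int, float]]  # (estimate id, truth id, distance)
    unmatched_estimates: list[int]
    unmatched_truths: list[int]

    @property
    def n_estimates(self) -> int:
        return len(self.pairs) + len(self.unmatched_estimates)

    @property
    def n_truths(self) -> int:
        return len(self.pairs) + len(self.unmatched_truths)


@dataclass
class EvalReport:
    """Percentages (1 d.p. on display) plus optional spike-timing errors."""

    precision: float
    recall: float
    fallout: float
    success: float
    rmse: float | None = None
    mae: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"precision": round(self.precision, 1), "recall": round(self.recall, 1),
             "fallout": round(self.fallout, 1), "success": round(self.success, 1)}
        if self.rmse is not None:
            d["rmse_s"] = self.rmse
        if self.mae is not None:
            d["mae_s"] = self.mae
        return d


def mask_centroids(masks) -> np.ndarray:
    """``(n, 2)`` array of (row, col) centroids of boolean masks."""
    out = [ndimage.center_of_mass(np.asarray(m, bool)) for m in masks]
    return np.asarray(out, dtype=np.float64).reshape(-1, 2)


def _assign(cost: np.ndarray, max_dist: float) -> MatchResult:
    n_est, n_truth = cost.shape
    if n_est == 0 or n_truth == 0:
        return MatchResult([], list(range(n_est)), list(range(n_truth)))
    # Infeasible pairs get a cost that dwarfs any feasible total, so the
    # assignment first maximises the number of within-threshold matches and
    # then minimises their total distance.
    big = max_dist * (n_est + n_truth + 1) * 1e6 + 1.0
    padded = np.where(cost <= max_dist, cost, big)
    rows, cols = linear_sum_assignment(padded)
    pairs = [(int(r), int(c), float(cost[r, c]))
             for r, c in zip(rows, cols) if cost[r, c] <= max_dist]
    matched_e = {p[0] for p in pairs}
    matched_t = {p[1] for p in pairs}
    return MatchResult(pairs,
                       [i for i in range(n_est) if i not in matched_e],
                       [j for j in range(n_truth) if j not in matched_t])


def match_rois(est_centroids, truth_centroids, max_dist: float = ROI_MATCH_DIST_PX) -> MatchResult:
    """Optimal one-to-one centroid matching within ``max_dist`` pixels."""
    est = np.asarray(est_centroids, np.float64).reshape(-1, 2)
    truth = np.asarray(truth_centroids, np.float64).reshape(-1, 2)
    if est.size and truth.size:
        cost = np.linalg.norm(est[:, None, :] - truth[None, :, :], axis=2)
    else:
        cost = np.zeros((len(est), len(truth)))
    return _assign(cost, max_dist)


def precision_recall_fallout(match: MatchResult) -> EvalReport:
    """Precision/recall/fall-out/success (all %) from a matching."""
    flags = []
    n_matched = len(match.pairs)
    if match.n_estimates == 0:
        precision = 0.0
        flags.append("no_estimates")
    else:
        precision = 100.0 * n_matched / match.n_estimates
    if match.n_truths == 0:
        recall = 0.0
        flags.append("no_truths")
    else:
        recall = 100.0 * n_matched / match.n_truths
    return EvalReport(precision=precision, recall=recall, fallout=100.0 - precision,
                      success=success_rate(precision, recall), flags=flags)


def success_rate(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (both %); 0 when both are 0."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision and recall must lie in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def table_percent(value: float) -> float:
    """Format a percentage for a comparison table: truncate to one decimal.

    Truncation (not rounding to nearest) is the convention under which a
    table's harmonic-mean column is reproducible from its own printed
    precision and recall columns, so it is what we use when quoting scores
    alongside published tables.
    """
    return np.trunc(value * 10.0) / 10.0


def match_spikes(est_times, truth_times,
                 window: float = SPIKE_MATCH_WINDOW_S) -> tuple[MatchResult, EvalReport]:
    """One-to-one spike matching within ``window`` seconds, plus timing errors.

    Returns the matching and a report whose ``rmse``/``mae`` are the
    root-mean-square and mean absolute timing errors (s) over matched pairs.
    """
    est = np.sort(np.asarray(est_times, np.float64).ravel())
    truth = np.sort(np.asarray(truth_times, np.float64).ravel())
    if est.size and truth.size:
        cost = np.abs(est[:, None] - truth[None, :])
    else:
        cost = np.zeros((est.size, truth.size))
    match = _assign(cost, window)
    report = precision_recall_fallout(match)
    if match.pairs:
        errors = np.array([d for _, _, d in match.pairs])
        report.rmse = float(np.sqrt(np.mean(errors ** 2)))
        report.mae = float(np.mean(errors))
    return match, report


def snr_db(signal_power: float, noise_power: float) -> float:
    """``10 log10(signal power / noise power)`` in dB."""
    if signal_power <= 0 or noise_power <= 0:
        raise ValueError("powers must be positive")
    return 10.0 * np.log10(signal_power / noise_power)


def snr_power(snr_in_db: float) -> float:
    """Inverse of :func:`snr_db`: the power ratio for a given dB value."""
    return float(10.0 ** (snr_in_db / 10.0))
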