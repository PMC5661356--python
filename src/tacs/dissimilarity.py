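"""Dissimilarity metrics between a pixel time course and a region feature.

Two metrics are supported.  The Euclidean metric compares both the pattern
and the magnitude of temporal activity and suits data in which baseline
brightness is informative (e.g. synthetic dyes).  The correlation metric,
``1 - Pearson``, compares only the pattern of activity, which suits
indicators with uneven expression where pixels of one cell share a common
activity pattern at different magnitudes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "METRICS",
    "euclidean_dissimilarity",
    "correlation_dissimilarity",
    "dissimilarity_many",
]

#: Valid metric names; the Euclidean metric is the default.
METRICS = ("euclidean", "correlation")


def _check_lengths(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"time courses must be 1-D and equal length; got {a.shape} vs {b.shape}")
    return a, b


def euclidean_dissimilarity(i_x: np.ndarray, f: np.ndarray) -> float:
    """``||I(x) - f||_2``: zero iff the two time courses are identical."""
    a, b = _check_lengths(i_x, f)
    return float(np.linalg.norm(a - b))


def correlation_dissimilarity(i_x: np.ndarray, f: np.ndarray) -> float:
    """``1 - corr(I(x), f)`` in ``[0, 2]``.

    A zero-variance argument has no activity pattern to compare; its
    correlation is taken as 0 so the dissimilarity falls back to the
    neutral value 1.
    """
    a, b = _check_lengths(i_x, f)
    if a.size < 2:
        raise ValueError("correlation requires at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        return 1.0
    return float(1.0 - np.dot(da, db) / (na * nb))


def dissimilarity_many(traces: np.ndarray, feature: np.ndarray, metric: str) -> np.ndarray:
    """Vectorised dissimilarity of ``(T, n)`` pixel traces against features.

    ``feature`` may be a single length-``T`` vector (broadcast against all
    columns) or a ``(T, n)`` matrix of per-pixel targets.  Used by the
    evolution engine, where thousands of band pixels are scored per sweep.
    """
    traces = np.asarray(traces, np.float64)
    feature = np.asarray(feature, np.float64)
    if feature.ndim == 1:
        feature = feature[:, None]
    if metric == "euclidean":
        return np.linalg.norm(traces - feature, axis=0)
    if metric == "correlation":
        dt = traces - traces.mean(axis=0)
        df = feature - feature.mean(axis=0)
        nt = np.linalg.norm(dt, axis=0)
        nf = np.linalg.norm(df, axis=0)
        denom = nt * nf
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, np.einsum("tn,tn->n", dt, np.broadcast_to(df, dt.shape)) / denom, 0.0)
        return 1.0 - corr
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
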