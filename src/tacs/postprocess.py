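"""Trace extraction and neuropil correction.

Segmentation yields, as a by-product, everything needed for neuropil
correction: each ROI's raw interior trace and the local background
(narrowband) trace.  The correction itself — subtracting a user-weighted
background trace — is deliberately left as an explicit postprocessing step
because the appropriate weight depends on the imaging setup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Segmentation

__all__ = ["TraceMatrix", "extract_timecourses", "neuropil_correct"]


@dataclass
class TraceMatrix:
    """``(M, T)`` matrix of per-ROI traces with their identifiers."""

    values: np.ndarray
    roi_ids: list[int]
    kind: str  # {raw, neuropil, corrected}

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, np.float64))
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("row count must match the number of ROI ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        """Rows = ROI id, columns = frame index."""
        return pd.DataFrame(self.values, index=pd.Index(self.roi_ids, name="roi"),
                            columns=pd.RangeIndex(self.values.shape[1], name="frame"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def extract_timecourses(video, seg: Segmentation) -> tuple[TraceMatrix, TraceMatrix]:
    """Raw interior and local-background traces for every surviving ROI.

    Raw row i = mean time course over the ROI's interior (all interior
    pixels: an ROI's raw trace never depends on other ROIs).  Neuropil row
    i = mean over the ROI's narrowband pixels outside every interior — the
    same local background feature that guides the contour.
    """
    states = seg.surviving_states()
    if not states:
        raise ValueError("segmentation has no surviving ROIs")
    any_int = seg.any_interior()
    raw, nb, ids = [], [], []
    for state in states:
        raw.append(video.data[:, state.interior].mean(axis=1))
        nb_free = state.narrowband & ~any_int
        if not nb_free.any():
            nb_free = state.narrowband
        nb.append(video.data[:, nb_free].mean(axis=1))
        ids.append(state.label)
    return (TraceMatrix(np.stack(raw), ids, "raw"),
            TraceMatrix(np.stack(nb), ids, "neuropil"))


def neuropil_correct(raw: np.ndarray, neuropil: np.ndarray, weight: float) -> np.ndarray:
    """``corrected = raw - weight * neuropil``, elementwise.

    ``weight`` is user-supplied (commonly ~0.7, but setup-dependent) and is
    never estimated here.
    """
    raw = np.asarray(raw, np.float64)
    neuropil = np.asarray(neuropil, np.float64)
    if raw.shape != neuropil.shape:
        raise ValueError("raw and neuropil traces must have equal shape")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("neuropil weight must lie in [0, 1]")
    return raw - weight * neuropil
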