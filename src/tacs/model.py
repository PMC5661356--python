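"""Model/Results interface over the segmentation engine.

``ActivityContourModel`` is constructed from a video plus the two
parameters a user must set for a new dataset (expected cell radius and the
data-term weight); ``fit()`` runs initialisation, coupled level-set
evolution, pruning and merging, and returns a ``SegmentationResults``
object carrying the ROI masks, their traces, per-ROI diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import engine, initialize, postprocess
from .engine import AlgorithmParams, Segmentation
from .io import VideoStack, downsample_time, read_video, summary_images

__all__ = ["ActivityContourModel", "SegmentationResults"]


class ActivityContourModel:
    """Coupled active-contour segmentation model for a calcium imaging video.

    Parameters
    ----------
    video
        The ``VideoStack`` to segment.
    radius
        Expected cell radius in pixels.
    lam
        Weight of the data (external) term relative to the regulariser.
    metric
        ``"euclidean"`` (pattern + magnitude; default) or ``"correlation"``
        (pattern only, for indicators with uneven brightness).
    params
        Full :class:`~tacs.engine.AlgorithmParams`; overrides the other
        keyword arguments when given.
    """

    def __init__(self, video: VideoStack, radius: float, lam: float = 3.0,
                 metric: str = "euclidean", params: AlgorithmParams | None = None,
                 **param_overrides):
        self.video = video
        if params is None:
            params = AlgorithmParams(r=radius, lam=lam, metric=metric, **param_overrides)
        self.params = params

    @classmethod
    def from_file(cls, path, radius: float, lam: float = 3.0, dataset: str | None = None,
                  frame_rate: float | None = None, **kwargs) -> "ActivityContourModel":
        """Build the model straight from a TIFF or HDF5 video file."""
        return cls(read_video(path, dataset=dataset, frame_rate=frame_rate),
                   radius, lam=lam, **kwargs)

    def fit(self, init: str = "auto", alpha: float | None = None,
            grid_spacing: float | None = None, grid_radius: float | None = None,
            init_masks: np.ndarray | None = None,
            exclusion: np.ndarray | None = None,
            downsample: int = 1) -> "SegmentationResults":
        """Seed, evolve and return the converged segmentation.

        ``init`` selects the seeding strategy: ``"auto"`` (peaks of the
        correlation and mean images, selectivity ``alpha``), ``"grid"``
        (discs on a lattice; ``grid_spacing`` defaults to ``1.5r``,
        ``grid_radius`` to ``2r/3``) or ``"masks"`` (user masks, one per
        page of ``init_masks``).  ``downsample`` averages that many
        consecutive frames before segmenting, trading temporal resolution
        for SNR.
        """
        video = downsample_time(self.video, downsample) if downsample > 1 else self.video
        p = self.params
        if init == "auto":
            a = p.alpha if alpha is None else alpha
            summaries = summary_images(video)
            candidates = initialize.candidate_rois(summaries, a, p.r, exclusion=exclusion)
        elif init == "grid":
            spacing = grid_spacing if grid_spacing is not None else 1.5 * p.r
            radius = grid_radius if grid_radius is not None else max(2.0 * p.r / 3.0, 1.5)
            candidates = initialize.grid_init(video.frame_shape, spacing, radius)
            if exclusion is not None:
                excl = np.asarray(exclusion, bool)
                candidates = [c for c in candidates if not (c.mask & excl).any()]
        elif init == "masks":
            if init_masks is None:
                raise ValueError("init='masks' requires init_masks")
            candidates = [initialize.CandidateROI(m, "user") for m in np.asarray(init_masks, bool)]
        else:
            raise ValueError("init must be 'auto', 'grid' or 'masks'")
        if not candidates:
            raise ValueError("initialization produced no candidate ROIs")
        seg = engine.segment(video, candidates, p)
        return SegmentationResults(self, video, seg)


class SegmentationResults:
    """Fitted segmentation: ROI masks, traces, diagnostics and summaries."""

    def __init__(self, model: ActivityContourModel, video: VideoStack, seg: Segmentation):
        self.model = model
        self.video = video
        self.segmentation = seg
        self.states = seg.surviving_states()
        if self.states:
            raw, neuropil = postprocess.extract_timecourses(video, seg)
        else:
            raw = neuropil = None
        self.raw_traces = raw
        self.neuropil_traces = neuropil

    @property
    def n_rois(self) -> int:
        return len(self.states)

    @property
    def masks(self) -> np.ndarray:
        """``(M, H, W)`` boolean interiors of the surviving ROIs."""
        if not self.states:
            return np.zeros((0,) + self.video.frame_shape, bool)
        return np.stack([s.interior for s in self.states])

    def centroids(self) -> np.ndarray:
        return np.asarray([s.centroid() for s in self.states], np.float64).reshape(-1, 2)

    def neuropil_corrected(self, weight: float = 0.7) -> postprocess.TraceMatrix:
        """Raw traces minus ``weight`` times the local background traces.

        The 0.7 default is a common convention only; the right value is
        setup-dependent and should be chosen by the user.
        """
        if self.raw_traces is None:
            raise ValueError("no surviving ROIs")
        values = postprocess.neuropil_correct(self.raw_traces.values,
                                              self.neuropil_traces.values, weight)
        return postprocess.TraceMatrix(values, self.raw_traces.roi_ids, "corrected")

    def summary(self) -> pd.DataFrame:
        """One row per surviving ROI: id, status, area, centroid, sweeps used."""
        rows = []
        for s in self.states:
            cy, cx = s.centroid()
            rows.append({"roi": s.label, "status": s.status, "area": s.area,
                         "centroid_row": round(cy, 2), "centroid_col": round(cx, 2),
                         "sweeps": s.n_sweeps})
        return pd.DataFrame(rows, columns=["roi", "status", "area", "centroid_row",
                                           "centroid_col", "sweeps"])

    def roi_index(self) -> list[dict]:
        """JSON-ready index of the surviving ROIs."""
        out = []
        for s in self.states:
            cy, cx = s.centroid()
            out.append({"id": int(s.label), "centroid": [cy, cx],
                        "area": s.area, "status": s.status})
        return out

    def save(self, out_dir) -> None:
        """Write masks (multi-page TIFF), ROI index (JSON), traces (CSV), config (YAML)."""
        import pathlib

        import tifffile
        import yaml

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.n_rois:
            tifffile.imwrite(out / "roi_masks.tif", self.masks.astype(np.uint8))
            self.raw_traces.to_csv(out / "traces_raw.csv")
            self.neuropil_traces.to_csv(out / "traces_neuropil.csv")
        (out / "roi_index.json").write_text(json.dumps(self.roi_index(), indent=1))
        cfg = dataclasses.asdict(self.model.params)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg))

    def plot_contours(self, image: np.ndarray | None = None, ax=None):
        """Draw ROI outlines over a background image (default: mean image)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if image is None:
            image = self.video.data.mean(axis=0)
        ax.imshow(image, cmap="gray")
        for s in self.states:
            ax.contour(s.phi, levels=[0.0], colors=["tab:red"], linewidths=1.0)
        ax.set_axis_off()
        return ax

    def __repr__(self) -> str:
        return (f"<SegmentationResults: {self.n_rois} ROIs after "
                f"{self.segmentation.n_sweeps_run} sweeps>")
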