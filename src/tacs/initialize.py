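"""Candidate ROI seeding and level-set initialisation.

Seeds come from connected regions of peak local correlation or peak mean
intensity (extended-maxima transform of the summary images), from a fixed
grid of discs, or from user-supplied masks.  Each seed becomes a
signed-distance level set whose interior is the seed mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction

from .engine import LevelSetState, signed_distance, _narrowband_from_interior
from .io import SummaryImages

__all__ = ["CandidateROI", "candidate_rois", "grid_init", "init_level_set", "disc_mask"]

logger = logging.getLogger(__name__)


@dataclass
class CandidateROI:
    """A single connected seed region and where it came from."""

    mask: np.ndarray
    source: str  # {correlation_peak, mean_peak, grid, user}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("candidate mask is empty")
        _, n = ndimage.label(self.mask, structure=np.ones((3, 3)))
        if n != 1:
            raise ValueError(f"candidate mask must be one 8-connected component; got {n}")

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc of given radius (pixels within ``radius`` of the centre)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _extended_maxima(image: np.ndarray, h: float) -> np.ndarray:
    """Regional maxima of the h-maxima reconstruction (extended-maxima transform)."""
    image = np.asarray(image, np.float64)
    rec = reconstruction(image - h, image, method="dilation")
    return local_maxima(rec, connectivity=2)


def _components(mask: np.ndarray, source: str) -> list[CandidateROI]:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return [CandidateROI(labels == k, source) for k in range(1, n + 1)]


def candidate_rois(summaries: SummaryImages, alpha: float, r: float,
                   exclusion: np.ndarray | None = None) -> list[CandidateROI]:
    """Automatic seeding from peaks of the correlation and mean images.

    For each summary image, peaks whose relative height is below
    ``alpha * SD(image)`` are suppressed (extended-maxima transform with
    ``h = alpha * SD``); each surviving connected component seeds one
    candidate.  Low ``alpha`` (0.2–0.8) deliberately over-seeds: redundant
    contours shrink and are pruned during evolution.  Mean-image candidates
    whose centroid falls within ``r`` pixels of a correlation-image
    candidate are dropped as duplicates; candidates touching the exclusion
    mask are discarded; candidates larger than the maximum-area prune
    threshold are replaced by a disc of radius ``r`` at their centroid.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out: list[CandidateROI] = []
    corr_candidates: list[CandidateROI] = []
    for image, source in ((summaries.correlation_image, "correlation_peak"),
                          (summaries.mean_image, "mean_peak")):
        if image is None:
            continue
        sd = float(np.std(image))
        if sd == 0.0:
            continue
        found = _components(_extended_maxima(image, alpha * sd), source)
        if source == "correlation_peak":
            corr_candidates = found
            out.extend(found)
        else:
            kept = []
            for cand in found:
                cy, cx = cand.centroid()
                dup = any(math.hypot(cy - oy, cx - ox) < r
                          for oy, ox in (c.centroid() for c in corr_candidates))
                if not dup:
                    kept.append(cand)
            out.extend(kept)
    if exclusion is not None:
        exclusion = np.asarray(exclusion, bool)
        out = [c for c in out if not (c.mask & exclusion).any()]
    max_area = 3.0 * math.pi * r ** 2
    shaped = []
    for cand in out:
        if cand.mask.sum() > max_area:
            disc = disc_mask(cand.mask.shape, cand.centroid(), r)
            if exclusion is not None:
                disc = disc & ~exclusion
            if disc.any():
                cand = CandidateROI(disc, cand.source)
            else:
                continue
        shaped.append(cand)
    if not shaped:
        logger.warning("automatic initialization produced no candidates (alpha=%.3g)", alpha)
    return shaped


def grid_init(shape: tuple[int, int], spacing: float, disc_radius: float) -> list[CandidateROI]:
    """Discs of ``disc_radius`` on a regular lattice with the given spacing.

    An initialization-agnostic fallback: with seeds everywhere, contours in
    cells grow onto the cell and background seeds shrink and are pruned.
    """
    if spacing <= 2 * disc_radius:
        raise ValueError("spacing must exceed the disc diameter")
    h, w = shape

    def centers(dim: int) -> np.ndarray:
        c = np.arange(spacing / 2.0, dim, spacing)
        return c if c.size else np.array([dim / 2.0])

    out = []
    for cy in centers(h):
        for cx in centers(w):
            mask = disc_mask(shape, (cy, cx), disc_radius)
            if mask.any():
                out.append(CandidateROI(mask, "grid"))
    return out


def init_level_set(candidate: CandidateROI, r: float,
                   narrowband_width: float | None = None) -> LevelSetState:
    """Signed-distance level set from a candidate: positive inside, negative out.

    The narrowband — the exterior annulus supplying the local background
    feature — extends ``2r`` (by default) beyond the interior.
    """
    width = 2.0 * r if narrowband_width is None else narrowband_width
    mask = candidate.mask
    state = LevelSetState(phi=signed_distance(mask), interior=mask.copy(),
                          narrowband=_narrowband_from_interior(mask, width))
    return state
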