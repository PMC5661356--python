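"""Seeded synthetic calcium-imaging video generator with full ground truth.

The generator emulates the features that make real two-photon data hard to
segment: donut-shaped cells (nucleus-excluded indicator) whose brightness
falls off from boundary to centre, mutually independent Poisson spike
trains convolved with a stereotyped calcium transient on top of a uniform
random baseline, summed contributions wherever cells overlap, a spatially
and temporally varying background that is independent of the cells, and
additive white Gaussian noise of configurable SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import VideoStack

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "poisson_spike_train",
    "calcium_transient_kernel",
    "donut_profile",
    "place_cells",
    "simulate_video",
    "demix25_spec",
]


@dataclass
class SyntheticSpec:
    """Generative parameters of one synthetic video.

    Defaults describe a moderate-noise recording: 100x100 px field at
    10 Hz, radius-6 donut cells, 0.5 Hz Poisson spiking, transients of peak
    amplitude 100 a.u. decaying with a 1 s time constant, baselines drawn
    uniformly from [40, 120] a.u., and noise SD in the same arbitrary
    intensity units as the transient amplitude.
    """

    height: int = 100
    width: int = 100
    n_frames: int = 150
    frame_rate: float = 10.0
    n_cells: int = 10
    cell_radius: float = 6.0
    overlap_fraction: float = 0.0
    spike_rate: float = 0.5
    amplitude: float = 100.0
    decay: float = 1.0
    baseline_range: tuple[float, float] = (40.0, 120.0)
    attenuation: float = 0.35
    background_scale: float | None = None  # default 4 * cell_radius
    background_amplitude: float = 30.0
    noise_sd: float = 60.0
    seed: int = 0
    centers: tuple[tuple[float, float], ...] | None = None  # explicit layout override

    def __post_init__(self) -> None:
        if self.centers is not None:
            self.centers = tuple((float(cy), float(cx)) for cy, cx in self.centers)
            if len(self.centers) != self.n_cells:
                raise ValueError("centers must list one (row, col) per cell")
        if min(self.height, self.width, self.n_frames, self.n_cells) <= 0:
            raise ValueError("dimensions and cell count must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.spike_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise SD must be non-negative")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.decay <= 0 or self.frame_rate <= 0 or self.cell_radius <= 0:
            raise ValueError("decay, frame_rate and cell_radius must be positive")
        if self.background_scale is None:
            self.background_scale = 4.0 * self.cell_radius


@dataclass
class GroundTruth:
    """Everything the generator knows: masks, spikes, weights, noiseless video.

    ``noiseless`` equals the summed per-cell contributions plus the
    background field exactly; each cell's contribution is the outer product
    of its activity trace with its donut weight map.
    """

    masks: np.ndarray  # (n, H, W) bool
    centers: np.ndarray  # (n, 2) float
    spike_times: list[np.ndarray]  # seconds, per cell
    weights: np.ndarray  # (n, H, W) donut weights
    activities: np.ndarray  # (n, T) baseline + transients
    background: np.ndarray  # (T, H, W)
    noiseless: np.ndarray  # (T, H, W)
    noise_sd: float
    seed: int

    def cell_contribution(self, i: int) -> np.ndarray:
        """Noiseless ``(T, H, W)`` movie of cell ``i`` alone."""
        return np.einsum("t,hw->thw", self.activities[i], self.weights[i])

    def n_overlapping(self) -> int:
        """Number of cells whose mask intersects at least one other cell."""
        count = self.masks.sum(axis=0)
        return int(sum((self.masks[i] & (count - self.masks[i] > 0)).any()
                       for i in range(self.masks.shape[0])))


def poisson_spike_train(rate: float, duration: float, rng) -> np.ndarray:
    """Sorted spike times (s) of a homogeneous Poisson process."""
    if rate < 0 or duration < 0:
        raise ValueError("rate and duration must be non-negative")
    rng = np.random.default_rng(rng)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def calcium_transient_kernel(amplitude: float, decay: float, frame_rate: float) -> np.ndarray:
    """Causal single-exponential transient ``A * exp(-t/decay)``, truncated at 5 decay constants."""
    if decay <= 0 or frame_rate <= 0:
        raise ValueError("decay and frame_rate must be positive")
    t = np.arange(0.0, 5.0 * decay, 1.0 / frame_rate)
    return amplitude * np.exp(-t / decay)


def donut_profile(mask: np.ndarray, attenuation: float) -> np.ndarray:
    """Donut weights: 1 on boundary pixels, falling linearly to ``attenuation`` at the centre."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    d = ndimage.distance_transform_edt(mask)
    d_min = d[mask].min()
    d_max = d[mask].max()
    w = np.zeros(mask.shape)
    if d_max == d_min:
        w[mask] = 1.0
    else:
        w[mask] = 1.0 - (1.0 - attenuation) * (d[mask] - d_min) / (d_max - d_min)
    return w


def place_cells(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic ``(n, 2)`` centres realising the requested overlap fraction.

    Cells destined to overlap are laid out in pairs (plus one triple when
    the overlap count is odd) with centre spacing ``1.5 r`` — close enough
    that radius-``r`` discs share pixels — and groups/singles are placed on
    a lattice coarse enough that distinct groups never touch.  An explicit
    ``spec.centers`` layout overrides all of this.
    """
    if spec.centers is not None:
        return np.asarray(spec.centers, dtype=np.float64)
    n = spec.n_cells
    r = spec.cell_radius
    n_overlap = int(round(spec.overlap_fraction * n))
    if n_overlap == 1:  # a single cell cannot overlap with nothing
        n_overlap = 2
    groups: list[list[tuple[float, float]]] = []
    remaining = n_overlap
    step = 1.5 * r
    while remaining > 0:
        size = 3 if remaining % 2 == 1 else 2
        # horizontal chain with step 1.5 r: adjacent discs overlap
        groups.append([(0.0, k * step) for k in range(size)])
        remaining -= size
    groups.extend([[(0.0, 0.0)] for _ in range(n - n_overlap)])
    # shelf packing: groups laid left-to-right in rows; centre gaps between
    # distinct groups (horizontal and vertical) exceed 2r so only
    # within-group cells overlap
    margin = r + 1.0
    gap = 2 * r + 3.0
    x_max = spec.width - r - 2.0
    y_max = spec.height - r - 2.0
    centers: list[tuple[float, float]] = []
    y = margin
    x = margin
    for pts in groups:
        span = pts[-1][1]
        if x + span > x_max:
            y += gap
            x = margin
        if y > y_max or x + span > x_max:
            raise ValueError("field too small for the requested number of cells")
        centers.extend((y + dy, x + dx) for dy, dx in pts)
        x += span + gap
    return np.asarray(centers, dtype=np.float64)


def simulate_video(spec: SyntheticSpec) -> tuple[VideoStack, GroundTruth]:
    """Generate a seeded video and its complete ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w, t = spec.height, spec.width, spec.n_frames
    duration = t / spec.frame_rate
    centers = place_cells(spec)
    rr, cc = np.ogrid[:h, :w]
    masks = np.stack([(rr - cy) ** 2 + (cc - cx) ** 2 <= spec.cell_radius ** 2
                      for cy, cx in centers])
    weights = np.stack([donut_profile(m, spec.attenuation) for m in masks])
    kernel = calcium_transient_kernel(spec.amplitude, spec.decay, spec.frame_rate)
    spike_times = []
    activities = np.empty((spec.n_cells, t))
    lo, hi = spec.baseline_range
    for i in range(spec.n_cells):
        spikes = poisson_spike_train(spec.spike_rate, duration, rng)
        spike_times.append(spikes)
        binned = np.zeros(t)
        frames = np.minimum((spikes * spec.frame_rate).astype(int), t - 1)
        np.add.at(binned, frames, 1.0)
        transients = np.convolve(binned, kernel)[:t]
        activities[i] = rng.uniform(lo, hi) + transients
    noiseless = np.zeros((t, h, w))
    for i in range(spec.n_cells):
        noiseless[:, masks[i]] += np.outer(activities[i], weights[i][masks[i]])
    # background: smooth spatial field x slow positive temporal modulation,
    # independent of the cells, present only outside every cell
    spatial = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, size=(h, w)),
                                      sigma=spec.background_scale)
    smin, smax = spatial.min(), spatial.max()
    spatial = (spatial - smin) / (smax - smin) if smax > smin else np.full((h, w), 0.5)
    temporal = ndimage.gaussian_filter1d(rng.standard_normal(t), sigma=spec.frame_rate,
                                         mode="nearest")
    tsd = temporal.std()
    temporal = 1.0 + 0.3 * (temporal - temporal.mean()) / tsd if tsd > 0 else np.ones(t)
    temporal = np.clip(temporal, 0.0, None)
    outside = ~masks.any(axis=0)
    background = np.zeros((t, h, w))
    background[:, outside] = spec.background_amplitude * np.outer(temporal, spatial[outside])
    noiseless = noiseless + background
    video = noiseless if spec.noise_sd == 0 else \
        noiseless + rng.normal(0.0, spec.noise_sd, size=noiseless.shape)
    gt = GroundTruth(masks=masks, centers=centers, spike_times=spike_times,
                     weights=weights, activities=activities, background=background,
                     noiseless=noiseless, noise_sd=spec.noise_sd, seed=spec.seed)
    return VideoStack(video, frame_rate=spec.frame_rate), gt


def demix25_spec(seed: int = 0, noise_sd: float = 60.0) -> SyntheticSpec:
    """The 25-cell demixing benchmark: 17 cells overlap a neighbour.

    One triple and seven pairs of radius-6 donut cells overlap; eight cells
    are isolated.  Transient amplitude 100 a.u. with noise SD in the same
    units (60 by default — the moderate-noise regime).
    """
    return SyntheticSpec(height=100, width=100, n_frames=150, frame_rate=10.0,
                         n_cells=25, cell_radius=6.0, overlap_fraction=17 / 25,
                         spike_rate=0.5, amplitude=100.0, decay=1.0,
                         baseline_range=(40.0, 120.0), attenuation=0.35,
                         background_amplitude=30.0, noise_sd=noise_sd, seed=seed)
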