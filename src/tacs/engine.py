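"""Coupled level-set evolution engine.

Each candidate cell carries a level set field ``phi`` that is positive in
the cell interior, negative outside, and whose zero level set is the active
contour.  Contours evolve by discretised gradient descent on

    E = lambda * E_ext + mu * R

where ``E_ext`` scores, with a dissimilarity metric ``D``, how well each
pixel's time course is explained by the average time course of the
subregion it lies in (interior, local background, or — for pixels shared by
several cells — the *sum* of the overlapping interiors), and ``R`` is the
double-well distance regulariser that keeps ``phi`` close to a signed
distance function near its contour.  Overlap between interiors is never
penalised: a pixel belongs to every cell whose summed interior time courses
best explain it, which is what demixes overlapping cells.

Contours are updated consecutively within a sweep, then undersized or
oversized contours are pruned and close, highly correlated contours are
merged.  A contour has converged when its interior changes by fewer than
``rho`` pixels for ``n_con`` consecutive sweeps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dissimilarity import METRICS, dissimilarity_many

__all__ = [
    "AlgorithmParams",
    "LevelSetState",
    "RegionFeatures",
    "Segmentation",
    "SweepEvent",
    "signed_distance",
    "region_timecourses",
    "dirac_delta",
    "external_velocity",
    "regularizer_gradient",
    "external_energy",
    "evolve_step",
    "has_converged",
    "prune",
    "merge_threshold_from_snr",
    "try_merge",
    "segment",
]

logger = logging.getLogger(__name__)

ACTIVE = "active"
CONVERGED = "converged"
PRUNED = "pruned"
MERGED = "merged"


@dataclass
class AlgorithmParams:
    """Tunable parameters of the evolution.

    Only two of these need user attention on a new dataset: ``r``, the
    expected cell radius in pixels, and ``lam``, the weight of the data
    (external) term relative to the regulariser.  The remaining defaults
    follow the standard choices for this scheme: timestep ``delta_tau=10``
    with ``mu=0.2/delta_tau`` (so ``mu*delta_tau=0.2`` satisfies the CFL
    stability bound ``< 0.25``), Dirac half-width ``epsilon=2`` px,
    ``n_max=100`` sweeps, convergence window ``n_con=40`` sweeps with
    tolerance ``rho=2`` px, and size thresholds 3 px and ``3*pi*r**2`` px.
    """

    r: float
    lam: float = 3.0
    delta_tau: float = 10.0
    mu: float = 0.02
    epsilon: float = 2.0
    alpha: float = 0.5
    n_max: int = 100
    n_con: int = 40
    rho: int = 2
    min_area: int = 3
    max_area: float | None = None
    metric: str = "euclidean"
    merge_corr_threshold: float = 0.8
    merge_dist: float | None = None
    narrowband_width: float | None = None
    curvature_weight: float = 0.3
    velocity_smooth: float = 2.0
    velocity_ema: float = 0.5
    max_step: float | None = 1.0
    normalize_velocity: bool | None = None
    prune_undifferentiated: bool = False

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("expected cell radius r must be positive")
        if self.mu * self.delta_tau >= 0.25:
            raise ValueError(
                f"CFL condition violated: mu*delta_tau = {self.mu * self.delta_tau:.3g} "
                "must be < 0.25")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.max_area is None:
            self.max_area = 3.0 * math.pi * self.r ** 2
        if self.max_area <= 0 or self.min_area <= 0:
            raise ValueError("size thresholds must be positive")
        if self.narrowband_width is None:
            self.narrowband_width = 2.0 * self.r
        if self.merge_dist is None:
            self.merge_dist = float(self.r)
        if not 0 < self.merge_corr_threshold < 1:
            raise ValueError("merge_corr_threshold must lie in (0, 1)")
        if self.normalize_velocity is None:
            # Euclidean dissimilarities carry the video's intensity units and
            # must be rescaled; 1 - correlation is already bounded in [0, 2]
            self.normalize_velocity = self.metric == "euclidean"


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: positive inside.

    The boundary is taken to run between pixel centres, so adjacent
    interior/exterior pixels sit at +-0.5 and the discrete gradient
    magnitude is 1 across the interface (not 2, as the raw difference of
    the two distance transforms would give).
    """
    mask = np.asarray(mask, bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, inside - 0.5, 0.5 - outside)


@dataclass
class LevelSetState:
    """One cell's level set field and bookkeeping.

    ``interior`` is always ``phi > 0``; ``narrowband`` is the annular
    exterior within ``narrowband_width`` (default ``2r``) of the interior
    and supplies the local background feature.
    """

    phi: np.ndarray
    interior: np.ndarray
    narrowband: np.ndarray
    stable_iters: int = 0
    status: str = ACTIVE
    n_sweeps: int = 0
    label: int = -1
    v_prev: np.ndarray | None = None  # smoothed velocity of the previous sweep

    @classmethod
    def from_mask(cls, mask: np.ndarray, narrowband_width: float, label: int = -1) -> "LevelSetState":
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("cannot build a level set from an empty mask")
        phi = signed_distance(mask)
        nb = _narrowband_from_interior(mask, narrowband_width)
        return cls(phi=phi, interior=mask, narrowband=nb, label=label)

    @property
    def alive(self) -> bool:
        return self.status in (ACTIVE, CONVERGED)

    @property
    def area(self) -> int:
        return int(self.interior.sum())

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.interior)
        return float(rr.mean()), float(cc.mean())


def _narrowband_from_interior(interior: np.ndarray, width: float) -> np.ndarray:
    if not interior.any():
        return np.zeros_like(interior, bool)
    dist = ndimage.distance_transform_edt(~interior)
    return (dist > 0) & (dist <= width)


@dataclass
class RegionFeatures:
    """Average interior (``f_in``) and local background (``f_out``) time courses.

    ``f_in_mask``/``f_out_mask`` record which pixels each average was taken
    over (needed for exact leave-one-out evaluation in the velocity), and
    ``n_in``/``n_out`` their sizes.
    """

    f_in: np.ndarray
    f_out: np.ndarray | None = None
    f_in_mask: np.ndarray | None = None
    f_out_mask: np.ndarray | None = None
    n_in: int = 0
    n_out: int = 0


@dataclass
class SweepEvent:
    """One structured log entry from the evolution loop."""

    sweep: int
    kind: str  # "prune" | "merge" | "converged"
    labels: tuple[int, ...]
    detail: str = ""


class Segmentation:
    """The collection of (possibly overlapping) level set states.

    The overlap map ``C(x)`` — which cells' interiors contain pixel ``x`` —
    is implied by the interiors of the *alive* (active or converged)
    states; pruned and merged states never contribute.
    """

    def __init__(self, states: list[LevelSetState]):
        self.states = states
        self.events: list[SweepEvent] = []
        self.n_sweeps_run: int = 0

    def alive_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.alive]

    def surviving_states(self) -> list[LevelSetState]:
        return [s for s in self.states if s.alive]

    def interior_count(self) -> np.ndarray:
        """Number of alive interiors covering each pixel."""
        shape = self.states[0].interior.shape
        count = np.zeros(shape, dtype=np.int32)
        for i in self.alive_indices():
            count += self.states[i].interior
        return count

    def any_interior(self) -> np.ndarray:
        return self.interior_count() > 0


def region_timecourses(video, seg: Segmentation, i: int,
                       interior_count: np.ndarray | None = None) -> RegionFeatures:
    """Average interior and narrowband time courses for cell ``i``.

    ``f_in`` averages pixels *exclusively* in cell ``i``'s interior (so
    overlap pixels, which carry summed signal, do not contaminate it); if no
    exclusive pixel exists the whole interior is used.  ``f_out`` averages
    the narrowband pixels that lie in no cell's interior — the local
    background, free of any neighbour's cellular signal.

    ``interior_count`` (number of alive interiors covering each pixel) may
    be passed in to avoid recomputing the overlap map for every cell.
    """
    state = seg.states[i]
    if not state.interior.any():
        raise ValueError(f"cell {i} has an empty interior")
    if interior_count is None:
        interior_count = seg.interior_count()
    exclusive = state.interior & (interior_count == 1)
    if not exclusive.any():
        exclusive = state.interior
    f_in = video.data[:, exclusive].mean(axis=1)
    nb_free = state.narrowband & (interior_count == 0)
    if not nb_free.any():
        nb_free = state.narrowband
    if not nb_free.any():
        raise RuntimeError(f"cell {i} has an empty narrowband")
    f_out = video.data[:, nb_free].mean(axis=1)
    return RegionFeatures(f_in=f_in, f_out=f_out,
                          f_in_mask=exclusive, f_out_mask=nb_free,
                          n_in=int(exclusive.sum()), n_out=int(nb_free.sum()))


def dirac_delta(phi: np.ndarray, epsilon: float) -> np.ndarray:
    """Cosine-bump approximation of the Dirac delta, supported on ``|phi| <= epsilon``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    phi = np.asarray(phi, np.float64)
    out = np.zeros_like(phi)
    band = np.abs(phi) <= epsilon
    out[band] = (1.0 + np.cos(np.pi * phi[band] / epsilon)) / (2.0 * epsilon)
    return out


def _loo_targets(feature: np.ndarray, n: int, traces: np.ndarray,
                 member: np.ndarray) -> np.ndarray:
    """Per-pixel feature targets with the pixel's own trace left out.

    ``member`` flags the trace columns that entered the average ``feature``
    (over ``n`` pixels); for those, the exact leave-one-out average
    ``(n*f - I_x)/(n - 1)`` is used so a pixel is never compared against a
    feature containing its own noise.
    """
    targets = np.repeat(feature[:, None], traces.shape[1], axis=1)
    if n >= 2 and member.any():
        targets[:, member] = (n * feature[:, None] - traces[:, member]) / (n - 1)
    return targets


def external_velocity(video, seg: Segmentation, i: int, metric: str,
                      features: dict[int, RegionFeatures],
                      epsilon: float = 2.0) -> np.ndarray:
    """Data-driven velocity of cell ``i``, evaluated on the Dirac band only.

    At a band pixel outside every other interior the velocity is
    ``D(I, f_in_i) - D(I, f_out_i)``: negative (inclusion) when the pixel
    resembles the interior more than the local background.  At a band pixel
    inside other cells it is ``D(I, f_in_i + sum_j f_in_j) - D(I, sum_j f_in_j)``
    over the other members ``j``: negative when the *sum* including cell
    ``i`` explains the pixel better, which lets contours expand into
    genuinely shared pixels.  Band pixels that themselves entered a region
    average are compared against the exact leave-one-out version of that
    average (see :func:`_loo_targets`).  Returns a full field that is zero
    outside the band.
    """
    state = seg.states[i]
    band = np.abs(state.phi) <= epsilon
    out = np.zeros(state.phi.shape)
    if not band.any():
        return out
    traces = video.data[:, band]  # (T, n)
    others = [j for j in seg.alive_indices() if j != i]
    feat_i = features[i]
    n = traces.shape[1]
    if others:
        membership = np.stack([seg.states[j].interior[band] for j in others])  # (m, n)
        shared = membership.any(axis=0)
    else:
        membership = None
        shared = np.zeros(n, bool)
    v = np.empty(n)
    solo = ~shared
    if solo.any():
        in_member = (feat_i.f_in_mask[band] if feat_i.f_in_mask is not None
                     else np.zeros(n, bool))[solo]
        out_member = (feat_i.f_out_mask[band] if feat_i.f_out_mask is not None
                      else np.zeros(n, bool))[solo]
        t_solo = traces[:, solo]
        f_in_t = _loo_targets(feat_i.f_in, feat_i.n_in, t_solo, in_member)
        f_out_t = _loo_targets(feat_i.f_out, feat_i.n_out, t_solo, out_member)
        v[solo] = (dissimilarity_many(t_solo, f_in_t, metric)
                   - dissimilarity_many(t_solo, f_out_t, metric))
    if shared.any():
        f_others = np.stack([features[j].f_in for j in others])  # (m, T)
        s = f_others.T @ membership[:, shared]  # (T, n_shared) summed neighbour features
        v[shared] = (dissimilarity_many(traces[:, shared], feat_i.f_in[:, None] + s, metric)
                     - dissimilarity_many(traces[:, shared], s, metric))
    out[band] = v
    return out


def _double_well_dp(s: np.ndarray) -> np.ndarray:
    """d_p(s) = p'(s)/s for the double-well potential with minima at 0 and 1."""
    dp = np.empty_like(s)
    low = s <= 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dp[low] = np.where(s[low] > 0, np.sin(2 * np.pi * s[low]) / (2 * np.pi * s[low]), 1.0)
        dp[~low] = (s[~low] - 1.0) / s[~low]
    return dp


def double_well_potential(s: np.ndarray) -> np.ndarray:
    """The potential p(s) itself (used for energy-descent diagnostics)."""
    s = np.asarray(s, np.float64)
    low = s <= 1.0
    p = np.empty_like(s)
    p[low] = (1.0 - np.cos(2 * np.pi * s[low])) / (2 * np.pi) ** 2
    p[~low] = 0.5 * (s[~low] - 1.0) ** 2
    return p


def _grad_replicate(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences with replicate (Neumann) boundaries."""
    pad = np.pad(a, 1, mode="edge")
    gr = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    gc = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    return gr, gc


def regularizer_gradient(phi: np.ndarray, mu: float = 1.0) -> np.ndarray:
    """``mu * dR/dphi`` for the double-well distance regulariser.

    ``R = integral p(|grad phi|)`` with the double-well ``p``; its
    variational derivative is ``-div(d_p(|grad phi|) grad phi)``, so the
    descent update drives ``|grad phi|`` to 1 near the contour and 0 far
    from it, maintaining a signed-distance profile without periodic
    re-initialisation.  Central differences, replicate boundaries.
    """
    phi = np.asarray(phi, np.float64)
    gr, gc = _grad_replicate(phi)
    s = np.hypot(gr, gc)
    dp = _double_well_dp(s)
    div_r, _ = _grad_replicate(dp * gr)
    _, div_c = _grad_replicate(dp * gc)
    return -mu * (div_r + div_c)


def smooth_on_band(v: np.ndarray, band: np.ndarray, sigma: float) -> np.ndarray:
    """Normalised Gaussian smoothing of a velocity field restricted to its band.

    The per-pixel velocity estimate carries sampling noise from the finite
    number of frames; averaging it over neighbouring band pixels suppresses
    that noise while preserving the local mean that actually drives the
    contour.  Pixels outside the band contribute nothing (mask-normalised
    convolution), so the band's edge values are not diluted by the zeros
    surrounding them.
    """
    if sigma <= 0:
        return v
    w = ndimage.gaussian_filter(band.astype(np.float64), sigma)
    num = ndimage.gaussian_filter(np.where(band, v, 0.0), sigma)
    out = np.zeros_like(v)
    inside = band & (w > 1e-12)
    out[inside] = num[inside] / w[inside]
    return out


def curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature ``div(grad phi / |grad phi|)`` of the level sets of ``phi``.

    Central differences with replicate boundaries; the gradient magnitude is
    floored at a small value so flat regions return ~0 curvature.
    """
    gr, gc = _grad_replicate(phi)
    mag = np.sqrt(gr ** 2 + gc ** 2 + 1e-10)
    div_r, _ = _grad_replicate(gr / mag)
    _, div_c = _grad_replicate(gc / mag)
    return div_r + div_c


def external_energy(video, seg: Segmentation, metric: str) -> float:
    """The data term of the cost over the current partition.

    Sums, over the union of interiors, the dissimilarity between each pixel
    and the summed interior features of the cells covering it; and, over
    the exterior (union of narrowbands minus all interiors), the
    dissimilarity to the local background feature of the nearest cell.
    With a single cell this is exactly the two-region interior/background
    energy.
    """
    alive = seg.alive_indices()
    if not alive:
        raise ValueError("external_energy requires at least one alive cell")
    feats = {i: region_timecourses(video, seg, i) for i in alive}
    shape = seg.states[alive[0]].interior.shape
    any_int = seg.any_interior()
    total = 0.0
    # interior term: per-pixel sum of member features
    if any_int.any():
        membership = np.stack([seg.states[i].interior[any_int] for i in alive])  # (m, n)
        f_all = np.stack([feats[i].f_in for i in alive])  # (m, T)
        targets = f_all.T @ membership  # (T, n)
        traces = video.data[:, any_int]
        total += float(dissimilarity_many(traces, targets, metric).sum())
    # exterior term: nearest cell's local background feature
    nb_union = np.zeros(shape, bool)
    for i in alive:
        nb_union |= seg.states[i].narrowband
    exterior = nb_union & ~any_int
    if exterior.any():
        phis = np.stack([seg.states[i].phi[exterior] for i in alive])  # (m, n)
        owner = np.argmax(phis, axis=0)
        traces = video.data[:, exterior]
        for k, i in enumerate(alive):
            sel = owner == k
            if sel.any():
                total += float(dissimilarity_many(traces[:, sel], feats[i].f_out, metric).sum())
    return total


def evolve_step(state: LevelSetState, v: np.ndarray, params: AlgorithmParams) -> int:
    """One discretised gradient-flow update of ``phi``; returns pixels changed.

    ``phi <- phi - delta_tau * (lam * delta_eps(phi) * V + mu * dR/dphi)``,
    applied on a window around the contour (the Dirac factor makes the data
    term local; the regulariser only matters near the band).  The interior
    and narrowband are recomputed from the new ``phi``.
    """
    if state.status != ACTIVE:
        raise ValueError("evolve_step requires an active state")
    support = state.interior | state.narrowband
    rr, cc = np.nonzero(support)
    margin = int(np.ceil(params.epsilon)) + 2
    h, w = state.phi.shape
    r0, r1 = max(rr.min() - margin, 0), min(rr.max() + margin + 1, h)
    c0, c1 = max(cc.min() - margin, 0), min(cc.max() + margin + 1, w)
    win = (slice(r0, r1), slice(c0, c1))
    phi_w = state.phi[win]
    delta = dirac_delta(phi_w, params.epsilon)
    reg = regularizer_gradient(phi_w, params.mu)
    localized = params.lam * delta * v[win]
    if params.curvature_weight:
        # contour-smoothing (length-minimising) component of the regulariser;
        # collapses small noise-supported contours that the data term cannot sustain
        localized -= params.curvature_weight * delta * curvature(phi_w)
    step = params.delta_tau * localized
    if params.max_step is not None:
        # cap the contour displacement per sweep so phi never develops cliffs
        # that would empty the Dirac band and freeze the evolution
        step = np.clip(step, -params.max_step, params.max_step)
    phi_new = phi_w - step - params.delta_tau * reg
    if not np.all(np.isfinite(phi_new)):
        raise FloatingPointError("level set update produced non-finite phi")
    old_interior = state.interior
    state.phi = state.phi.copy()
    state.phi[win] = phi_new
    state.interior = state.phi > 0
    changed = int(np.count_nonzero(state.interior ^ old_interior))
    state.narrowband = _narrowband_from_interior(state.interior, params.narrowband_width)
    return changed


def has_converged(state: LevelSetState, params: AlgorithmParams) -> bool:
    """True once the interior changed by fewer than ``rho`` pixels for ``n_con`` sweeps."""
    return state.stable_iters >= params.n_con


def prune(seg: Segmentation, params: AlgorithmParams, sweep: int = 0) -> Segmentation:
    """Remove alive contours whose area left the ``[min_area, max_area]`` range."""
    for i in seg.alive_indices():
        area = seg.states[i].area
        if area < params.min_area or area > params.max_area:
            seg.states[i].status = PRUNED
            seg.events.append(SweepEvent(sweep, "prune", (seg.states[i].label,),
                                         f"area={area}"))
    return seg


def merge_threshold_from_snr(snr_db: float) -> float:
    """Expected correlation of two noisy copies of one cell's signal at a given SNR.

    ``1 / (1 + 10**(-snr_db/10))`` — the correlation between two averages of
    disjoint pixel sets of the same cell, whose common component is the
    cellular signal and whose independent components are noise.  Strictly
    increasing in SNR; used to convert a measured SNR into a merge threshold.
    """
    snr_db = float(snr_db)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    return 1.0 / (1.0 + 10.0 ** (-snr_db / 10.0))


def _boundary_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum pixel distance between two interiors (0 if they touch/overlap)."""
    dist = ndimage.distance_transform_edt(~a)
    return float(dist[b].min())


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rr, cc = np.nonzero(mask)
    return rr.min(), rr.max(), cc.min(), cc.max()


def _bbox_gap(a, b) -> float:
    """Lower bound on the distance between two masks from their bounding boxes."""
    dr = max(b[0] - a[1], a[0] - b[1], 0)
    dc = max(b[2] - a[3], a[2] - b[3], 0)
    return float(np.hypot(dr, dc))


def try_merge(seg: Segmentation, video, params: AlgorithmParams, sweep: int = 0,
              features: dict[int, RegionFeatures] | None = None) -> Segmentation:
    """Merge close, highly correlated contour pairs into a single level set.

    Two alive cells merge when their interiors come within one cell radius
    (minimum boundary-to-boundary distance) and their interior time courses
    correlate at or above the merge threshold.  Pairs are processed greedily
    in descending correlation, each state merging at most once per sweep;
    the replacement is a fresh signed-distance level set over the union of
    the two interiors, with convergence counters reset.
    """
    alive = seg.alive_indices()
    if len(alive) < 2:
        return seg
    feats = features if features is not None else \
        {i: region_timecourses(video, seg, i) for i in alive}
    boxes = {i: _bbox(seg.states[i].interior) for i in alive}
    candidates = []
    for a_idx in range(len(alive)):
        for b_idx in range(a_idx + 1, len(alive)):
            i, j = alive[a_idx], alive[b_idx]
            if _bbox_gap(boxes[i], boxes[j]) > params.merge_dist:
                continue
            if _boundary_distance(seg.states[i].interior, seg.states[j].interior) > params.merge_dist:
                continue
            fi, fj = feats[i].f_in, feats[j].f_in
            di = fi - fi.mean()
            dj = fj - fj.mean()
            denom = np.linalg.norm(di) * np.linalg.norm(dj)
            corr = float(np.dot(di, dj) / denom) if denom > 0 else 0.0
            if corr >= params.merge_corr_threshold:
                candidates.append((corr, i, j))
    used: set[int] = set()
    for corr, i, j in sorted(candidates, reverse=True):
        if i in used or j in used:
            continue
        used.update((i, j))
        union = seg.states[i].interior | seg.states[j].interior
        new_label = max(s.label for s in seg.states) + 1
        new_state = LevelSetState.from_mask(union, params.narrowband_width, label=new_label)
        seg.states[i].status = MERGED
        seg.states[j].status = MERGED
        seg.states.append(new_state)
        seg.events.append(SweepEvent(sweep, "merge",
                                     (seg.states[i].label, seg.states[j].label, new_label),
                                     f"corr={corr:.3f}"))
    return seg


def segment(video, candidates, params: AlgorithmParams) -> Segmentation:
    """Run the full evolution loop from a list of candidate ROIs.

    Level sets are initialised from each candidate mask; in each sweep every
    active contour is updated consecutively in ascending index order using
    the latest neighbour states (converged contours are frozen but keep
    contributing to overlap maps, feature sums and merging), then pruning
    and merging run.  The loop stops when all alive contours have converged
    or after ``n_max`` sweeps.
    """
    from .initialize import init_level_set  # local import to avoid a cycle

    if len(candidates) == 0:
        raise ValueError("segment requires at least one candidate ROI")
    states = []
    for label, cand in enumerate(candidates):
        st = init_level_set(cand, params.r, narrowband_width=params.narrowband_width)
        st.label = label
        states.append(st)
    seg = Segmentation(states)
    prune(seg, params, sweep=0)
    for sweep in range(1, params.n_max + 1):
        alive = seg.alive_indices()
        if not alive:
            break
        count = seg.interior_count()
        feats = {i: region_timecourses(video, seg, i, interior_count=count)
                 for i in alive}
        for i in alive:
            state = seg.states[i]
            if state.status != ACTIVE:
                continue
            v = external_velocity(video, seg, i, params.metric, feats,
                                  epsilon=params.epsilon)
            if params.normalize_velocity:
                # bound the dissimilarity scale before smoothing so the local
                # average is a stable vote, not a cancellation of huge terms
                vmax = np.abs(v).max()
                if vmax > 0:
                    v = v / vmax
            if params.velocity_smooth:
                v = smooth_on_band(v, np.abs(state.phi) <= params.epsilon,
                                   params.velocity_smooth)
            if params.velocity_ema and state.v_prev is not None:
                # damp sweep-to-sweep oscillation of contested boundary pixels;
                # exact at fixed points, where the velocity field is static
                v = (1.0 - params.velocity_ema) * v + params.velocity_ema * state.v_prev
            state.v_prev = v
            old_interior = state.interior
            changed = evolve_step(state, v, params)
            count += state.interior.astype(np.int32) - old_interior.astype(np.int32)
            state.n_sweeps = sweep
            if changed < params.rho:
                state.stable_iters += 1
            else:
                state.stable_iters = 0
            if not state.interior.any():
                state.status = PRUNED
                seg.events.append(SweepEvent(sweep, "prune", (state.label,), "area=0"))
                continue
            if has_converged(state, params):
                state.status = CONVERGED
                seg.events.append(SweepEvent(sweep, "converged", (state.label,)))
        prune(seg, params, sweep=sweep)
        try_merge(seg, video, params, sweep=sweep, features=feats)
        seg.n_sweeps_run = sweep
        if all(seg.states[i].status == CONVERGED for i in seg.alive_indices()):
            break
    if params.prune_undifferentiated:
        for i in seg.alive_indices():
            f = region_timecourses(video, seg, i)
            di = f.f_in - f.f_in.mean()
            do = f.f_out - f.f_out.mean()
            denom = np.linalg.norm(di) * np.linalg.norm(do)
            corr = float(np.dot(di, do) / denom) if denom > 0 else 0.0
            if corr >= params.merge_corr_threshold:
                seg.states[i].status = PRUNED
                seg.events.append(SweepEvent(seg.n_sweeps_run, "prune",
                                             (seg.states[i].label,),
                                             f"undifferentiated corr={corr:.3f}"))
    if not seg.surviving_states():
        logger.warning("all contours were pruned; segmentation is empty")
    return seg
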