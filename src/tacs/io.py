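"""Video input/output and 2-D summary images.

A calcium imaging video is held as a :class:`VideoStack`: a ``(T, H, W)``
array of fluorescence intensities in which every pixel ``x`` carries a
length-``T`` time course ``I(x)``.  Summary images (temporal mean, temporal
maximum and the local correlation image) condense the stack into 2-D maps
used for seeding contours and for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import tifffile

__all__ = [
    "VideoStack",
    "SummaryImages",
    "read_video",
    "write_video",
    "write_summary_images",
    "downsample_time",
    "summary_images",
]


class VideoFormatError(ValueError):
    """Raised when a file cannot be interpreted as a supported video."""


@dataclass
class VideoStack:
    """A ``(T, H, W)`` fluorescence video.

    Parameters
    ----------
    data
        Frame-major intensity array.  Stored as float64; values are kept
        exactly as read (no normalisation).
    frame_rate
        Acquisition rate in Hz.  Optional; only needed when converting
        frame indices to seconds (e.g. spike-time metrics).
    """

    data: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"video must be (T, H, W); got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("video contains non-finite values")
        if self.data.shape[1] < 3 or self.data.shape[2] < 3:
            raise ValueError("video frames must be at least 3x3 pixels")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def timecourses(self, mask: np.ndarray) -> np.ndarray:
        """Return the ``(T, n)`` time courses of the pixels in a boolean mask."""
        return self.data[:, np.asarray(mask, bool)]


@dataclass
class SummaryImages:
    """Per-pixel temporal mean, maximum and local correlation maps."""

    mean_image: np.ndarray
    max_image: np.ndarray
    correlation_image: np.ndarray | None = None


def read_video(path, dataset: str | None = None, frame_rate: float | None = None) -> VideoStack:
    """Read a multi-page TIFF or an HDF5 dataset into a :class:`VideoStack`.

    Parameters
    ----------
    path
        File path; format is inferred from the suffix (``.tif``/``.tiff``
        vs ``.h5``/``.hdf5``).
    dataset
        HDF5 dataset name.  If omitted, the file must contain exactly one
        3-D dataset.
    """
    p = str(path)
    suffix = p.rsplit(".", 1)[-1].lower() if "." in p else ""
    try:
        if suffix in ("tif", "tiff"):
            data = tifffile.imread(p)
        elif suffix in ("h5", "hdf5", "hdf"):
            with h5py.File(p, "r") as fh:
                if dataset is None:
                    names = [k for k, v in fh.items()
                             if isinstance(v, h5py.Dataset) and v.ndim == 3]
                    if len(names) != 1:
                        raise VideoFormatError(
                            f"{p}: specify `dataset`; found 3-D datasets {names}")
                    dataset = names[0]
                data = fh[dataset][()]
        else:
            raise VideoFormatError(f"unsupported video format: {p!r}")
    except (OSError, KeyError) as exc:
        raise VideoFormatError(f"could not read video {p!r}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    return VideoStack(data, frame_rate=frame_rate)


def write_video(path, video: VideoStack) -> None:
    """Write a video as a float multi-page TIFF or an HDF5 ``/video`` dataset."""
    p = str(path)
    suffix = p.rsplit(".", 1)[-1].lower()
    if suffix in ("tif", "tiff"):
        tifffile.imwrite(p, video.data.astype(np.float64))
    elif suffix in ("h5", "hdf5", "hdf"):
        with h5py.File(p, "w") as fh:
            fh.create_dataset("video", data=video.data.astype(np.float64))
    else:
        raise VideoFormatError(f"unsupported video format: {p!r}")


def write_summary_images(prefix, summaries: SummaryImages) -> None:
    """Write each summary image as a single-page float TIFF ``<prefix>_<name>.tif``."""
    for name in ("mean_image", "max_image", "correlation_image"):
        img = getattr(summaries, name)
        if img is not None:
            tifffile.imwrite(f"{prefix}_{name}.tif", np.asarray(img, np.float64))


def downsample_time(video: VideoStack, k: int) -> VideoStack:
    """Average every ``k`` consecutive frames; trailing remainder frames are dropped.

    Temporal downsampling shortens the video and raises SNR without touching
    the spatial content; the segmentation makes no assumption about transient
    shape, so it is unaffected beyond the noise reduction.
    """
    k = int(k)
    if k < 1:
        raise ValueError("k must be a positive integer")
    t = video.n_frames
    if k > t:
        raise ValueError(f"k={k} exceeds the number of frames ({t})")
    if k == 1:
        return VideoStack(video.data.copy(), frame_rate=video.frame_rate)
    t_out = t // k
    data = video.data[: t_out * k].reshape(t_out, k, *video.frame_shape).mean(axis=1)
    rate = None if video.frame_rate is None else video.frame_rate / k
    return VideoStack(data, frame_rate=rate)


def summary_images(video: VideoStack, correlation: bool = True) -> SummaryImages:
    """Compute mean, maximum and (optionally) the local correlation image.

    The correlation image assigns to each pixel the average Pearson
    correlation between its time course and those of its 8-connected
    neighbours; border pixels average over their existing neighbours only.
    Zero-variance time courses are maximally uninformative and contribute a
    correlation of 0.
    """
    data = video.data
    mean_img = data.mean(axis=0)
    max_img = data.max(axis=0)
    corr_img = None
    if correlation:
        if video.n_frames < 2:
            raise ValueError("correlation image requires at least 2 frames")
        t = video.n_frames
        centred = data - mean_img
        sd = centred.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centred / sd, 0.0)
        h, w = video.frame_shape
        num = np.zeros((h, w))
        cnt = np.zeros((h, w))
        shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                  if (dr, dc) != (0, 0)]
        for dr, dc in shifts:
            src = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
            dst = (slice(max(-dr, 0), h + min(-dr, 0)), slice(max(-dc, 0), w + min(-dc, 0)))
            # corr(x, y) = <z_x, z_y>/T; zero-variance pixels have z == 0 and
            # therefore contribute 0, but still count as neighbours.
            num[dst] += np.einsum("tij,tij->ij", z[(slice(None),) + dst], z[(slice(None),) + src])
            cnt[dst] += 1.0
        corr_img = num / (t * cnt)
    return SummaryImages(mean_image=mean_img, max_image=max_img, correlation_image=corr_img)
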