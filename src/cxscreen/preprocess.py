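"""Raw movie stacks -> per-repeat ΔF/F0 traces.

The pipeline mirrors standard practice for slow sample drift in long
two-photon experiments: per-run average images are registered to a reference
by correlation-based sub-pixel translation; a single region of interest is
segmented once per experiment by 2-means clustering of the overall mean
image (by average intensity only, never activity, so responsive and
non-responsive runs are treated identically); the background ``B`` is the
mean intensity of the dimmest 10% of pixels of the mean image; the baseline
``F0`` is the median ROI fluorescence over the dimmest 3% of frames pooled
across the whole experiment (baseline fluorescence can vary widely over an
experiment, so F0 is experiment-global); and finally

    ΔF/F0 = (F − F0) / (F0 − B).

ROI mask, B and F0 are computed once per experiment and reused for every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation
from sklearn.cluster import KMeans

__all__ = [
    "DffTrace",
    "register_runs",
    "segment_roi",
    "estimate_background",
    "extract_roi_trace",
    "compute_f0",
    "compute_dff",
    "preprocess_experiment",
]

#: Fraction of dimmest pixels defining the background.
BACKGROUND_PIXEL_FRACTION = 0.10
#: Fraction of dimmest frames defining F0.
F0_FRAME_FRACTION = 0.03


@dataclass
class DffTrace:
    """A ΔF/F0 trace with the scalars that produced it."""

    values: np.ndarray
    f0: float
    background: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F0 trace contains non-finite values")


def register_runs(
    movies: Sequence[np.ndarray],
    upsample_factor: int = 10,
    max_shift_fraction: float = 0.25,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Align run movies by the translation between their average images.

    The average image of each run is registered to the average image of the
    first run by correlation-based sub-pixel registration (Fourier
    upsampling).  Only whole-run translations are corrected; there is no
    within-run motion correction.  Returns the aligned movies (float arrays)
    and the per-run (dy, dx) shifts that were applied.
    """
    if not movies:
        raise ValueError("register_runs requires at least one movie")
    averages = [np.asarray(m, dtype=float).mean(axis=0) for m in movies]
    reference = averages[0]
    aligned: list[np.ndarray] = []
    shifts = np.zeros((len(movies), 2))
    for i, (movie, avg) in enumerate(zip(movies, averages)):
        shift, _, _ = phase_cross_correlation(
            reference, avg, upsample_factor=upsample_factor)
        shifts[i] = shift
        limit = max_shift_fraction * np.array(reference.shape)
        if np.any(np.abs(shift) > limit):
            warnings.warn(
                f"run {i}: estimated shift {tuple(shift)} exceeds "
                f"{max_shift_fraction:.0%} of the frame; registration may "
                "have failed", stacklevel=2)
        aligned.append(_apply_shift(np.asarray(movie, dtype=float), shift))
    return aligned, shifts


def _apply_shift(movie: np.ndarray, shift: np.ndarray) -> np.ndarray:
    if np.allclose(shift, 0):
        return movie
    out = np.empty_like(movie)
    for i, frame in enumerate(movie):
        out[i] = np.fft.ifftn(fourier_shift(np.fft.fftn(frame), shift)).real
    return out


def segment_roi(mean_image: np.ndarray) -> np.ndarray:
    """Foreground mask by 2-means clustering of pixel intensities.

    Initial centroids are the minimum and maximum intensity, making the
    segmentation deterministic; the cluster with the higher mean is the
    foreground.  Raises on a (near-)constant image, which has no
    foreground/background structure.
    """
    img = np.asarray(mean_image, dtype=float)
    lo, hi = img.min(), img.max()
    if not np.isfinite([lo, hi]).all() or np.isclose(hi, lo, rtol=1e-12, atol=1e-12):
        raise ValueError("mean image has no intensity structure to segment")
    pixels = img.reshape(-1, 1)
    km = KMeans(n_clusters=2, init=np.array([[lo], [hi]]), n_init=1).fit(pixels)
    labels = km.labels_.reshape(img.shape)
    foreground = int(np.argmax(km.cluster_centers_.ravel()))
    return labels == foreground


def estimate_background(
    mean_image: np.ndarray,
    fraction: float = BACKGROUND_PIXEL_FRACTION,
    reducer: str = "mean",
) -> float:
    """Background B: intensity of the dimmest ``fraction`` of pixels.

    The set is reduced by its mean by default (``reducer`` may be
    ``"median"``).
    """
    flat = np.sort(np.asarray(mean_image, dtype=float).ravel())
    k = max(1, int(round(fraction * flat.size)))
    dimmest = flat[:k]
    if reducer == "mean":
        return float(dimmest.mean())
    if reducer == "median":
        return float(np.median(dimmest))
    raise ValueError(f"unknown reducer {reducer!r}")


def extract_roi_trace(movie: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean fluorescence over the ROI for each frame."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return np.asarray(movie, dtype=float)[:, mask].mean(axis=1)


def compute_f0(
    roi_traces: Sequence[np.ndarray],
    fraction: float = F0_FRAME_FRACTION,
) -> float:
    """Baseline F0: median ROI fluorescence of the dimmest frames.

    Frames are pooled across all runs of the experiment and ranked by their
    mean ROI fluorescence; F0 is the median over the dimmest ``fraction`` of
    them.  With too few frames to populate that fraction, the dimmest single
    frame is used (with a warning).
    """
    pooled = np.sort(np.concatenate([np.asarray(t, dtype=float).ravel()
                                     for t in roi_traces]))
    if pooled.size == 0:
        raise ValueError("no frames to compute F0 from")
    k = int(np.floor(fraction * pooled.size))
    if k < 1:
        warnings.warn(
            f"only {pooled.size} frames: fewer than 1/{fraction:.0%} needed "
            "for the dim-frame quantile; falling back to the dimmest frame",
            stacklevel=2)
        k = 1
    return float(np.median(pooled[:k]))


def compute_dff(F: np.ndarray, f0: float, background: float) -> DffTrace:
    """ΔF/F0 = (F − F0) / (F0 − B), elementwise.

    Raises when F0 ≤ B, which would make the normaliser non-positive.
    """
    if f0 <= background:
        raise ValueError(
            f"F0 ({f0:.6g}) must exceed the background ({background:.6g}); "
            "the ΔF/F0 normaliser would be non-positive")
    values = (np.asarray(F, dtype=float) - f0) / (f0 - background)
    return DffTrace(values=values, f0=f0, background=background)


def preprocess_experiment(
    movies: Sequence[np.ndarray],
    n_repeats: int = 4,
    upsample_factor: int = 10,
) -> tuple[list[list[np.ndarray]], dict]:
    """Full preprocessing of one experiment's run movies.

    Registers the runs, segments the experiment-wide ROI, estimates B and
    F0 once, and converts every run to ΔF/F0.  Each run movie is assumed to
    hold ``n_repeats`` equal-length repeats concatenated in time.

    Returns (per-run lists of per-repeat ΔF/F0 arrays, report) where the
    report records the shifts, background, F0 and ROI size.
    """
    aligned, shifts = register_runs(movies, upsample_factor=upsample_factor)
    mean_image = np.mean([m.mean(axis=0) for m in aligned], axis=0)
    mask = segment_roi(mean_image)
    background = estimate_background(mean_image)
    roi_traces = [extract_roi_trace(m, mask) for m in aligned]
    f0 = compute_f0(roi_traces)
    dff_runs: list[list[np.ndarray]] = []
    for trace in roi_traces:
        dff = compute_dff(trace, f0, background).values
        if trace.size % n_repeats:
            raise ValueError(
                f"run length {trace.size} is not divisible into "
                f"{n_repeats} repeats")
        dff_runs.append(list(dff.reshape(n_repeats, -1)))
    report = {
        "shifts": shifts.tolist(),
        "background": background,
        "f0": f0,
        "roi_pixels": int(mask.sum()),
        "upsample_factor": upsample_factor,
    }
    return dff_runs, report
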