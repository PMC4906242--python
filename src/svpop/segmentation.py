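"""Identify responsive boutons from the first-stimulation response map.

Pipeline: optional integer re-alignment of stage drift, per-pixel response
map (peak minus baseline), relative thresholding, 4-connected labeling,
slight dilation with nearest-component collision handling, and size gating.
The resulting label map is reused for both AP trains of a movie so the same
boutons are analyzed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .protocol import StimProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "ResponseMap",
    "BoutonMap",
    "realign",
    "response_map",
    "segment",
]


@dataclass
class AlignmentResult:
    shifts: np.ndarray  # (T, 2) estimated integer drift (drow, dcol) per frame
    flagged: np.ndarray  # (T,) bool, True where drift exceeded max_shift
    reference_frame: int
    max_shift: int


@dataclass
class ResponseMap:
    f_baseline: np.ndarray  # per-pixel mean of pre-stimulation frames
    f_peak: np.ndarray  # per-pixel peak of smoothed first-train frames
    df: np.ndarray  # f_peak - f_baseline
    baseline_frames: np.ndarray
    train_frames: np.ndarray
    peak_window: int


@dataclass
class BoutonMap:
    labels: np.ndarray  # int label image, 0 = background
    areas: np.ndarray  # (N,) pixel counts, index = label - 1
    centroids: np.ndarray  # (N, 2) (row, col), 0-based
    threshold: float
    min_rel_df: float
    dilation_radius: int
    size_gate: tuple[int, int]

    @property
    def n_boutons(self) -> int:
        return len(self.areas)

    def pixel_lists(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(rows, cols) arrays per label, in label order."""
        return [np.nonzero(self.labels == k + 1) for k in range(self.n_boutons)]


def _translate(frame: np.ndarray, drow: int, dcol: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    rs, re = max(0, drow), min(h, h + drow)
    cs, ce = max(0, dcol), min(w, w + dcol)
    out[rs:re, cs:ce] = frame[rs - drow : re - drow, cs - dcol : ce - dcol]
    return out


def realign(
    stack: np.ndarray,
    max_shift: int = 5,
    reference_frame: int = 0,
) -> tuple[np.ndarray, AlignmentResult]:
    """Correct whole-frame integer x-y drift against a reference frame.

    Each frame's translation is estimated by cross-correlation and rounded to
    whole pixels; the frame is shifted back, exposed edges filled with the
    frame median.  Frames whose estimated drift exceeds ``max_shift`` are
    flagged and left in place.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (T, H, W) with at least 2 frames")
    ref = stack[reference_frame].astype(float)
    n = stack.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    flagged = np.zeros(n, dtype=bool)
    aligned = stack.astype(float).copy()
    for t in range(n):
        if t == reference_frame:
            continue
        # returned shift registers the moving frame onto the reference,
        # i.e. it is the negative of the drift
        reg, _, _ = phase_cross_correlation(
            ref, stack[t].astype(float), upsample_factor=1, normalization=None
        )
        drow, dcol = int(round(-reg[0])), int(round(-reg[1]))
        if max(abs(drow), abs(dcol)) > max_shift:
            flagged[t] = True
            logger.warning("frame %d drift (%d, %d) exceeds max_shift=%d; left unshifted",
                           t, drow, dcol, max_shift)
            continue
        shifts[t] = (drow, dcol)
        if drow or dcol:
            aligned[t] = _translate(aligned[t], -drow, -dcol, float(np.median(aligned[t])))
    return aligned, AlignmentResult(shifts, flagged, reference_frame, max_shift)


def response_map(
    stack: np.ndarray,
    protocol: StimProtocol,
    peak_window: int = 3,
) -> ResponseMap:
    """Per-pixel baseline and first-train peak of a (possibly aligned) stack.

    Baseline is the mean over pre-stimulation frames; the peak is the maximum
    of a ``peak_window``-frame moving average over the first-train window,
    which suppresses single-frame noise spikes.
    """
    stack = np.asarray(stack, dtype=float)
    pre = protocol.prestim_frames()
    train = protocol.train_frames(0)
    if pre.size < 3:
        raise ValueError("need at least 3 pre-stimulation frames")
    if train.size < 3:
        raise ValueError("need at least 3 first-train frames")
    if train[-1] >= stack.shape[0]:
        raise ValueError("protocol windows extend past the movie")
    f_baseline = stack[pre].mean(axis=0)
    smoothed = ndimage.uniform_filter1d(stack, size=peak_window, axis=0, mode="nearest")
    f_peak = smoothed[train].max(axis=0)
    df = f_peak - f_baseline
    if not np.all(np.isfinite(df)):
        raise ValueError("non-finite values in response map")
    return ResponseMap(f_baseline, f_peak, df, pre, train, peak_window)


def segment(
    rmap: ResponseMap,
    threshold: float = 1.0,
    min_rel_df: float = 0.05,
    dilation_radius: int = 1,
    size_gate: tuple[int, int] = (8, 150),
    baseline_floor: float = 1.0,
    smooth_sigma: float = 0.0,
) -> BoutonMap:
    """Threshold the response map into a bouton label image.

    Pixels with ``df >= threshold * F_baseline`` are binarized and 4-connected
    components extracted; components whose mean relative response falls below
    ``min_rel_df`` are discarded; survivors are dilated by a disk, contested
    pixels going to the nearest original component (ties to the lower label
    id); the size gate applies after dilation.  Relative thresholding makes
    the result invariant to rescaling all intensities (above the small
    ``baseline_floor`` guard used for near-zero-baseline pixels).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a_min, a_max = size_gate
    if a_min > a_max:
        raise ValueError("size gate lower bound exceeds upper bound")

    df_map = rmap.df
    f_base = rmap.f_baseline
    if smooth_sigma > 0:
        # optional spatial smoothing for weak-response experiments; linear,
        # so scale invariance of the relative threshold is preserved
        df_map = ndimage.gaussian_filter(df_map, smooth_sigma)
        f_base = ndimage.gaussian_filter(f_base, smooth_sigma)
    base = np.maximum(f_base, baseline_floor)
    binary = df_map >= threshold * base
    labels0 = cc_label(binary, connectivity=1)
    n0 = labels0.max()
    if n0 == 0:
        return BoutonMap(
            labels=np.zeros_like(labels0),
            areas=np.zeros(0, dtype=int),
            centroids=np.zeros((0, 2)),
            threshold=threshold,
            min_rel_df=min_rel_df,
            dilation_radius=dilation_radius,
            size_gate=size_gate,
        )

    # discard weak components (mean relative response below the cut)
    rel = df_map / base
    mean_rel = ndimage.labeled_comprehension(
        rel, labels0, np.arange(1, n0 + 1), np.mean, float, np.nan
    )
    keep = np.nonzero(mean_rel >= min_rel_df)[0] + 1
    kept = np.isin(labels0, keep) if keep.size else np.zeros_like(binary)
    labels1 = cc_label(kept, connectivity=1)  # relabels 1..K in raster order
    k1 = labels1.max()
    if k1 == 0:
        return BoutonMap(
            labels=np.zeros_like(labels0),
            areas=np.zeros(0, dtype=int),
            centroids=np.zeros((0, 2)),
            threshold=threshold,
            min_rel_df=min_rel_df,
            dilation_radius=dilation_radius,
            size_gate=size_gate,
        )

    if dilation_radius > 0:
        union = ndimage.binary_dilation(labels1 > 0, structure=disk(dilation_radius))
        ur, uc = np.nonzero(union)
        # nearest-original-component assignment; argmin ties fall to the
        # lowest label id because distances are stacked in id order
        dists = np.empty((k1, ur.size))
        for k in range(k1):
            dmap = ndimage.distance_transform_edt(labels1 != k + 1)
            dists[k] = dmap[ur, uc]
        winner = np.argmin(dists, axis=0) + 1
        labels2 = np.zeros_like(labels1)
        labels2[ur, uc] = winner
    else:
        labels2 = labels1

    # size gate, then final relabeling in raster order of first pixel
    areas = np.bincount(labels2.ravel(), minlength=k1 + 1)[1:]
    ok = np.nonzero((areas >= a_min) & (areas <= a_max))[0] + 1
    out = np.zeros_like(labels2)
    final_areas = []
    final_centroids = []
    new_id = 0
    flat = labels2.ravel()
    vals, first_idx = np.unique(flat, return_index=True)
    first_pixel = dict(zip(vals.tolist(), first_idx.tolist()))
    order = sorted(ok, key=lambda x: first_pixel[x])
    for lab in order:
        new_id += 1
        mask = labels2 == lab
        out[mask] = new_id
        rr, cc = np.nonzero(mask)
        final_areas.append(rr.size)
        final_centroids.append((rr.mean(), cc.mean()))
    return BoutonMap(
        labels=out,
        areas=np.asarray(final_areas, dtype=int),
        centroids=np.asarray(final_centroids).reshape(-1, 2),
        threshold=threshold,
        min_rel_df=min_rel_df,
        dilation_radius=dilation_radius,
        size_gate=size_gate,
    )
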