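"""Segmentation, track linking, exclusion rules and speed/shape metrics.

Reproduces the under-agarose migration readout: triangle auto-threshold on the
cytoplasmic-dye channel, binary opening, size-gated particle detection
(38-60 µm² inclusive), greedy mutual-nearest-neighbour frame-to-frame linking,
exclusion of propidium-iodide-positive (dead) cells and of tracks shorter than
a fraction of the video length (1/2 under agarose, 1/3 in collagen), and
mean-speed / circularity metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import measure, morphology

from .imaging_io import CellMovie, TrackTable

__all__ = [
    "ShapeMetrics",
    "Detection",
    "triangle_threshold",
    "segment_cells",
    "detect_movie",
    "link_tracks",
    "filter_tracks",
    "track_speed",
    "mask_metrics",
]


@dataclass
class ShapeMetrics:
    """Area, perimeter and the ImageJ circularity shape descriptor."""

    area_um2: float
    perimeter_um: float
    circularity: float  # 4*pi*A / P^2; 1 for a circle


@dataclass
class Detection:
    """One segmented cell in one frame."""

    frame: int
    label: int
    x_um: float
    y_um: float
    metrics: ShapeMetrics
    viable_positive: bool = False


def triangle_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold by the triangle geometric construction on the histogram.

    A line is drawn from the histogram peak to the far end of the tail on the
    longer side; the threshold is the bin whose histogram point lies at the
    maximum perpendicular distance from that line.  Returns the threshold as
    an intensity value (bin centre).
    """
    image = np.asarray(image)
    vmin, vmax = float(image.min()), float(image.max())
    if vmin == vmax:
        raise ValueError("triangle threshold is undefined for a constant image")
    hist, edges = np.histogram(image.ravel(), bins=nbins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nonzero = np.nonzero(hist)[0]
    first, last = nonzero[0], nonzero[-1]
    # Far tail end: the side with the longer baseline from the peak.
    end = last if (last - peak) >= (peak - first) else first
    if end == peak:
        return float(centers[peak])
    lo, hi = (peak, end) if end > peak else (end, peak)
    idx = np.arange(lo, hi + 1)
    # Normalized coordinates so bin width and count scale do not bias the
    # perpendicular distance.
    x = (idx - peak) / (end - peak)
    y = hist[idx] / hist[peak]
    # Distance from (x, y) to the line joining (0, 1) and (1, 0): |x + y - 1|.
    dist = np.abs(x + y - 1.0)
    best = idx[int(np.argmax(dist))]
    return float(centers[best])


def mask_metrics(mask: np.ndarray, pixel_size_um: float) -> ShapeMetrics:
    """Area, contour-polygon perimeter and circularity of one binary mask.

    The marching-squares contour staircases on smooth outlines and would
    overestimate a disc's perimeter by ~5%; a Douglas-Peucker simplification
    at sub-pixel tolerance removes the pixelation while keeping true corners,
    so discs score circularity ~1 and squares ~pi/4.
    """
    mask = np.asarray(mask, dtype=bool)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("empty mask")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    perim_px = 0.0
    for c in contours:
        poly = measure.approximate_polygon(c, tolerance=0.7)
        perim_px = max(perim_px, float(
            np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()))
    area = area_px * pixel_size_um**2
    perim = perim_px * pixel_size_um
    return ShapeMetrics(area, perim, 4.0 * math.pi * area / perim**2)


def _boundary_band(mask: np.ndarray) -> np.ndarray:
    return mask & ~morphology.erosion(mask, morphology.disk(1))


def _snap_to_ridge(mask: np.ndarray, frame: np.ndarray, max_erosions: int = 6
                   ) -> np.ndarray:
    """Erode a filled ring mask until its boundary sits on the stain ridge.

    A thresholded membrane stain overshoots the cell outline by the faint
    outer tail of the ring; successive radius-1 erosions are scored by the
    mean frame intensity on the mask boundary, and the deepest erosion within
    1% of the best score is returned (boundary centred on the ridge).
    """
    masks, scores = [], []
    m = mask
    for k in range(max_erosions + 1):
        if k:
            m = morphology.erosion(m, morphology.disk(1))
            if not m.any():
                break
        masks.append(m)
        scores.append(float(frame[_boundary_band(m)].mean()))
    best = max(scores)
    k_sel = max(i for i, s in enumerate(scores) if s >= 0.99 * best)
    return masks[k_sel]


def _ring_metrics(mask: np.ndarray, pixel_size_um: float) -> ShapeMetrics:
    """Metrics of a ridge-snapped mask, corrected for boundary straddling.

    The snapped boundary band straddles the membrane ridge, so half the band
    lies outside the true outline: the band-pixel count is debited by half
    and a convex half-pixel (pi) is taken off the contour perimeter, keeping
    circularity = 4*pi*A/P^2 on the corrected pair.
    """
    raw = mask_metrics(mask, pixel_size_um)
    n_band = int(_boundary_band(mask).sum())
    area = raw.area_um2 - 0.5 * n_band * pixel_size_um**2
    perim = max(raw.perimeter_um - math.pi * pixel_size_um, pixel_size_um)
    return ShapeMetrics(area, perim, 4.0 * math.pi * area / perim**2)


def segment_cells(frame: np.ndarray, pixel_size_um: float,
                  area_range_um2: tuple[float, float] = (38.0, 60.0),
                  threshold: float | None = None,
                  fill_holes: bool = True,
                  ring_stain: bool | str = "auto",
                  ) -> tuple[np.ndarray, list[tuple[int, ShapeMetrics]]]:
    """Segment cells in one frame and size-gate them.

    Triangle threshold -> hole filling -> binary opening (radius-1 disc) ->
    8-connected components -> keep labels with area inside ``area_range_um2``
    (inclusive at both bounds).  Hole filling happens before the opening so
    the radius-1 opening cannot fragment a thin membrane-stain ring.

    ``ring_stain`` selects boundary handling: a cytoplasmic dye thresholds to
    the cell footprint directly, whereas a membrane stain thresholds to a ring
    whose filled outline overshoots by the stain's outer tail; for rings the
    mask is eroded back onto the intensity ridge and its metrics corrected for
    the boundary band (see :func:`_snap_to_ridge`).  ``"auto"`` treats a label
    as ring-stained when its interior is much dimmer than its boundary.

    Returns the retained label image and ``(label, metrics)`` pairs; an empty
    result is not an error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if threshold is None:
        try:
            threshold = triangle_threshold(frame)
        except ValueError:
            return np.zeros(frame.shape, dtype=int), []
    binary = frame > threshold
    if fill_holes:
        from scipy.ndimage import binary_fill_holes
        binary = binary_fill_holes(binary)
    binary = morphology.opening(binary, morphology.disk(1))
    labels = measure.label(binary, connectivity=2)
    lo, hi = area_range_um2
    kept = np.zeros(labels.shape, dtype=int)
    results: list[tuple[int, ShapeMetrics]] = []
    next_label = 0
    for region in measure.regionprops(labels):
        sl = tuple(slice(max(s.start - 8, 0), s.stop + 8) for s in region.slice)
        sub = labels[sl] == region.label
        sub_frame = frame[sl]
        is_ring = ring_stain
        if ring_stain == "auto":
            # A membrane stain peaks on a ring strictly inside the thresholded
            # outline and is dim in the middle; a cytoplasmic dye is bright
            # throughout.
            interior = morphology.erosion(sub, morphology.disk(2))
            is_ring = bool(
                interior.any()
                and sub_frame[interior].mean() < 0.4 * sub_frame[sub].max()
            )
        if is_ring:
            sub = _snap_to_ridge(sub, sub_frame)
            metrics = _ring_metrics(sub, pixel_size_um)
        else:
            metrics = mask_metrics(sub, pixel_size_um)
        if lo <= metrics.area_um2 <= hi:
            next_label += 1
            kept[sl][sub] = next_label
            results.append((next_label, metrics))
    return kept, results


def detect_movie(movie: CellMovie, detect_channel: str = "membrane",
                 viability_channel: str | None = "viability",
                 area_range_um2: tuple[float, float] = (38.0, 60.0),
                 ) -> pd.DataFrame:
    """Segment every frame of a movie into a detection table.

    The dead-cell call per detection: mean viability-channel intensity inside
    the mask above the triangle threshold of that channel (skipped when the
    channel is absent or constant).
    """
    px = movie.pixel_size_um
    stack = movie.channel(detect_channel)
    via = None
    via_thresh = 0.0
    if viability_channel and viability_channel in movie.channel_names:
        via = movie.channel(viability_channel)
        try:
            via_thresh = triangle_threshold(via)
        except ValueError:
            via = None
    rows = []
    for f in range(movie.n_frames):
        labels, results = segment_cells(stack[f], px, area_range_um2)
        for label, metrics in results:
            mask = labels == label
            ys, xs = np.nonzero(mask)
            viable_positive = bool(
                via is not None and via[f][mask].mean() > via_thresh
            )
            rows.append({
                "frame": f, "label": label,
                "x_um": xs.mean() * px, "y_um": ys.mean() * px,
                "area_um2": metrics.area_um2,
                "circularity": metrics.circularity,
                "viable": int(viable_positive),
            })
    return pd.DataFrame(
        rows, columns=["frame", "label", "x_um", "y_um", "area_um2",
                       "circularity", "viable"])


def _greedy_pairs(prev: np.ndarray, curr: np.ndarray, max_disp: float
                  ) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbour assignment under a displacement gate.

    Pairs are taken globally smallest-distance first (ties break to the
    smaller previous index, then smaller current index), which makes every
    accepted pair a mutual nearest neighbour among the unassigned.
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = cdist(prev, curr)
    pairs: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_c: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > max_disp:
            break
        if i in used_p or j in used_c:
            continue
        pairs.append((int(i), int(j)))
        used_p.add(int(i))
        used_c.add(int(j))
    return pairs


def link_tracks(detections: pd.DataFrame, max_disp_um: float | None = None
                ) -> TrackTable:
    """Link per-frame detections into tracks by greedy mutual nearest
    neighbour under ``max_disp_um``; unmatched detections start new tracks.
    No gap closing: a cell missing in one frame terminates its track.

    When ``max_disp_um`` is None it defaults to 3x the median per-frame
    displacement estimated from an ungated first pass.
    """
    det = detections.sort_values(["frame"]).reset_index(drop=True)
    if max_disp_um is None:
        first = link_tracks(det, max_disp_um=np.inf)
        steps = []
        for tid in first.track_ids:
            sub = first.track(tid)
            if len(sub) > 1:
                steps.extend(np.hypot(np.diff(sub["x_um"]),
                                      np.diff(sub["y_um"])))
        max_disp_um = 3.0 * float(np.median(steps)) if steps else np.inf

    frames = sorted(det["frame"].unique())
    track_of: dict[int, int] = {}  # detection row -> track id
    next_tid = 0
    prev_rows: list[int] = []
    for k, f in enumerate(frames):
        rows = det.index[det["frame"] == f].tolist()
        if k == 0 or (frames[k - 1] != f - 1):
            pairs = []
        else:
            prev_xy = det.loc[prev_rows, ["x_um", "y_um"]].to_numpy()
            curr_xy = det.loc[rows, ["x_um", "y_um"]].to_numpy()
            pairs = _greedy_pairs(prev_xy, curr_xy, max_disp_um)
        matched_curr = set()
        for i, j in pairs:
            track_of[rows[j]] = track_of[prev_rows[i]]
            matched_curr.add(j)
        for j, row in enumerate(rows):
            if j not in matched_curr:
                track_of[row] = next_tid
                next_tid += 1
        prev_rows = rows

    out = det.copy()
    out["track_id"] = [track_of[i] for i in out.index]
    if "viable" not in out.columns:
        out["viable"] = 0
    table = out[["track_id", "frame", "x_um", "y_um", "viable"]]
    table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackTable(table)


def filter_tracks(table: TrackTable, n_frames: int, min_fraction: float = 0.5
                  ) -> TrackTable:
    """Apply the study's track exclusion rules.

    Removes (a) viability-positive tracks (propidium-iodide-containing dead
    cells; a track counts as dead when more than half its detections are
    viability-positive) and (b) tracks strictly shorter than
    ``min_fraction * n_frames`` frames — ``min_fraction`` 1/2 for the
    under-agarose assay, 1/3 for collagen.  A track of exactly the boundary
    length is kept.  Idempotent.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    df = table.df
    if df.empty:
        return TrackTable(df.copy())
    keep = []
    min_len = min_fraction * n_frames
    for tid, sub in df.groupby("track_id"):
        dead = sub["viable"].mean() > 0.5
        if not dead and len(sub) >= min_len:
            keep.append(tid)
    return TrackTable(df[df["track_id"].isin(keep)].reset_index(drop=True))


def track_speed(track: pd.DataFrame, dt_s: float) -> float:
    """Mean speed of one track: path length over elapsed time, in µm/min.

    This is the TrackMate-style mean speed (sum of consecutive displacements
    divided by total duration), not net displacement over duration.
    """
    if len(track) < 2:
        raise ValueError("speed needs a track with >= 2 points")
    track = track.sort_values("frame")
    path = float(np.hypot(np.diff(track["x_um"]), np.diff(track["y_um"])).sum())
    minutes = (track["frame"].iloc[-1] - track["frame"].iloc[0]) * dt_s / 60.0
    return path / minutes
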