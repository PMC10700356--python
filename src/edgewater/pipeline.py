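"""Movie-level pipelines chaining segmentation with the per-cell estimators.

These are the stages the command line exposes: track (detect, link, filter,
speed), profile (per-cell polarity readouts), spacing (leading-edge
membrane-to-F-actin distances) and flow (kymograph slope), each consuming a
:class:`~edgewater.imaging_io.CellMovie` and emitting a tidy table.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .edge_spacing import (actin_peak_distance, choose_frame,
                           perpendicular_profiles, trace_and_straighten_edge)
from .imaging_io import CellMovie, TrackTable
from .polarity_profiles import (length_profile, mpact_polarity,
                                perimeter_polarization, sample_perimeter)
from .retro_flow import build_kymograph, estimate_flow
from .track_shape import detect_movie, filter_tracks, link_tracks, track_speed

__all__ = ["track_movie", "profile_movie", "spacing_movie", "flow_movie"]


def track_movie(movie: CellMovie, min_fraction: float = 0.5,
                max_disp_um: float | None = None,
                detect_channel: str = "membrane",
                ) -> tuple[TrackTable, pd.DataFrame]:
    """Detect, link and filter tracks; returns the table and per-track metrics."""
    detections = detect_movie(movie, detect_channel=detect_channel)
    table = link_tracks(detections, max_disp_um)
    table = filter_tracks(table, movie.n_frames, min_fraction)
    rows = []
    for tid in table.track_ids:
        sub = table.track(tid)
        rows.append({
            "track_id": tid,
            "n_frames": len(sub),
            "speed_um_min": track_speed(sub, movie.dt_s),
        })
    metrics = pd.DataFrame(rows, columns=["track_id", "n_frames", "speed_um_min"])
    return table, metrics


def _segment_frame(movie: CellMovie, frame: int, channel: str = "membrane"):
    from .track_shape import segment_cells
    return segment_cells(movie.channel(channel)[frame], movie.pixel_size_um)


def _nearest_label(labels: np.ndarray, x_px: float, y_px: float) -> int:
    """Label whose centroid is nearest to (x, y); 0 if no labels."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    best, best_d = 0, np.inf
    for lab in ids:
        ys, xs = np.nonzero(labels == lab)
        d = math.hypot(xs.mean() - x_px, ys.mean() - y_px)
        if d < best_d:
            best, best_d = int(lab), d
    return best


def profile_movie(movie: CellMovie, tracks: TrackTable,
                  mpact_channel: str = "reporter",
                  caax_channel: str = "membrane") -> pd.DataFrame:
    """Per-cell polarity readouts along each track.

    For every track the analysis frame is the track midpoint, the migration
    direction comes from the net start-to-end displacement, and the cell mask
    is the size-gated particle nearest the tracked position.  Emits one row
    per cell with the MPAct/CaaX front-3/back-3 polarity and the
    25%-perimeter polarization of the reporter.
    """
    px = movie.pixel_size_um
    rows = []
    for tid in tracks.track_ids:
        sub = tracks.track(tid)
        dx = sub["x_um"].iloc[-1] - sub["x_um"].iloc[0]
        dy = sub["y_um"].iloc[-1] - sub["y_um"].iloc[0]
        if dx == 0 and dy == 0:
            continue
        direction = math.atan2(dy, dx)
        mid = sub.iloc[len(sub) // 2]
        frame = int(mid["frame"])
        labels, _ = _segment_frame(movie, frame, caax_channel)
        lab = _nearest_label(labels, mid["x_um"] / px, mid["y_um"] / px)
        if lab == 0:
            continue
        mask = labels == lab
        try:
            mp = length_profile(movie.channel(mpact_channel)[frame], mask,
                                direction)
            cx = length_profile(movie.channel(caax_channel)[frame], mask,
                                direction)
            _, polarity = mpact_polarity(mp, cx)
            perim = perimeter_polarization(
                sample_perimeter(movie.channel(mpact_channel)[frame], mask))
        except ValueError:
            continue
        rows.append({
            "track_id": tid, "frame": frame, "direction_rad": direction,
            "mpact_polarity": polarity,
            "perimeter_polarization": perim.ratio,
        })
    return pd.DataFrame(rows, columns=["track_id", "frame", "direction_rad",
                                       "mpact_polarity",
                                       "perimeter_polarization"])


def spacing_movie(movie: CellMovie, seed: int = 0, window_nm: float = 400.0,
                  pm_channel: str = "membrane", actin_channel: str = "actin",
                  ) -> pd.DataFrame:
    """Leading-edge membrane-to-peak-F-actin spacing per cell, one frame.

    The frame is a seeded uniform choice (recorded in the output); per-cell
    migration direction is the centroid displacement to the matched particle
    in the next frame.  Cells without a match, or whose leading-edge arc is
    too short, are skipped.
    """
    frame = choose_frame(max(movie.n_frames - 1, 1), seed)
    px = movie.pixel_size_um
    labels, _ = _segment_frame(movie, frame, pm_channel)
    labels_next, _ = _segment_frame(movie, frame + 1, pm_channel) \
        if movie.n_frames > 1 else (labels, None)
    pm_img = movie.channel(pm_channel)[frame]
    ac_img = movie.channel(actin_channel)[frame]
    rows = []
    for lab in np.unique(labels)[1:]:
        mask = labels == lab
        ys, xs = np.nonzero(mask)
        cx, cy = xs.mean(), ys.mean()
        nxt = _nearest_label(labels_next, cx, cy)
        if nxt == 0:
            continue
        ys2, xs2 = np.nonzero(labels_next == nxt)
        dx, dy = xs2.mean() - cx, ys2.mean() - cy
        if dx == 0 and dy == 0:
            continue
        direction = math.atan2(dy, dx)
        try:
            pm_band, ac_band = trace_and_straighten_edge(pm_img, ac_img, mask,
                                                         direction)
            stack = perpendicular_profiles(pm_band, ac_band, px)
            result = actin_peak_distance(stack, window_nm)
        except ValueError:
            continue
        rows.append({
            "label": int(lab), "frame": frame, "direction_rad": direction,
            "spacing_nm": result.mean_nm, "n_lines": result.n_lines_used,
        })
    return pd.DataFrame(rows, columns=["label", "frame", "direction_rad",
                                       "spacing_nm", "n_lines"])


def flow_movie(movie: CellMovie, channel: str | int = 0, width_px: int = 5,
               ) -> pd.DataFrame:
    """Retrograde-flow estimate from a kymograph along the image mid-line.

    Intended for TIRF-like movies of non-translocating cells where the
    F-actin texture slips along the x axis; the sampling line spans the image
    horizontally through the centre.
    """
    h, w = movie.shape_yx
    line = np.array([[2.0, h / 2.0], [w - 3.0, h / 2.0]])
    kymo = build_kymograph(movie, line, width_px, channel)
    est = estimate_flow(kymo)
    return pd.DataFrame([{
        "flow_um_min": est.flow_um_min,
        "slope_px_per_frame": est.slope_px_per_frame,
        "flagged": est.flagged,
    }])
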