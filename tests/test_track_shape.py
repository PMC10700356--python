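"""Segmentation, triangle threshold, linking, exclusion rules and metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage import draw, filters

from edgewater.imaging_io import TrackTable
from edgewater.track_shape import (filter_tracks, link_tracks, mask_metrics,
                                   segment_cells, track_speed,
                                   triangle_threshold)


def disc_mask(radius: int, shape=(128, 128)):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((shape[0] // 2, shape[1] // 2), radius)
    mask[rr, cc] = True
    return mask


class TestTriangleThreshold:
    def test_two_level_image_threshold_between_levels(self):
        img = np.full((100, 100), 10.0)
        img[60:, :30] = 200.0  # minority bright class, peak at 10
        thr = triangle_threshold(img)
        assert 10.0 < thr < 200.0

    def test_linear_ramp_matches_exhaustive_scan(self):
        # Independent oracle: scan all 256 candidate bins and maximize the
        # perpendicular distance from the peak-to-tail line directly.
        rng = np.random.default_rng(3)
        img = rng.triangular(0.0, 0.0, 1.0, size=(200, 200))
        hist, edges = np.histogram(img, bins=256, range=(img.min(), img.max()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = int(np.argmax(hist))
        end = 255 if (255 - peak) >= peak else 0
        best_d, best_i = -1.0, peak
        for i in range(min(peak, end), max(peak, end) + 1):
            x = (i - peak) / (end - peak)
            y = hist[i] / hist[peak]
            d = abs(x + y - 1.0) / math.sqrt(2.0)
            if d > best_d:
                best_d, best_i = d, i
        assert triangle_threshold(img) == pytest.approx(centers[best_i])

    def test_agrees_with_skimage_reference(self):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(100, 10, 5000),
                              rng.normal(600, 40, 500)]).reshape(55, 100)
        ours = triangle_threshold(img)
        reference = filters.threshold_triangle(img)
        bin_width = (img.max() - img.min()) / 256
        assert abs(ours - reference) <= 2 * bin_width

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            triangle_threshold(np.ones((10, 10)))


class TestSegmentation:
    def test_area_gate_inclusive_bounds(self):
        # Four solid blobs of exactly 30, 38, 60 and 61 µm² at 0.5 µm pixels;
        # the blobs are rectangles dilated by the radius-1 disc, so the
        # pipeline's binary opening leaves them pixel-identical and the
        # inclusive [38, 60] gate keeps exactly the 38 and 60 µm² ones.
        from skimage.morphology import dilation, disk
        px = 0.5  # 0.25 µm² per pixel
        rects = {30: (2, 29), 38: (10, 11), 60: (2, 59), 61: (6, 29)}
        img = np.zeros((90, 80))
        y = 4
        for area, (a, b) in rects.items():
            blob = dilation(np.pad(np.ones((a, b), dtype=bool), 1),
                            footprint=disk(1).astype(bool))
            assert blob.sum() * px**2 == area
            h, w = blob.shape
            img[y:y + h, 4:4 + w][blob] = 100.0
            y += h + 6
        labels, results = segment_cells(img, px, area_range_um2=(38.0, 60.0))
        assert len(results) == 2
        kept_areas = sorted(m.area_um2 for _, m in results)
        assert kept_areas == [38.0, 60.0]

    def test_blank_frame_yields_no_labels(self):
        labels, results = segment_cells(np.zeros((32, 32)), 0.1)
        assert labels.max() == 0 and results == []

    def test_generated_cells_all_detected(self, isim_movie_depleted):
        cfg, movie, truth = isim_movie_depleted
        _, results = segment_cells(movie.channel("membrane")[0],
                                   cfg.pixel_size_um)
        assert len(results) == len(truth)

    def test_membrane_ring_mask_area_within_5pct(self, isim_movie_depleted):
        cfg, movie, truth = isim_movie_depleted
        _, results = segment_cells(movie.channel("membrane")[0],
                                   cfg.pixel_size_um,
                                   area_range_um2=(20.0, 90.0))
        est = sorted(m.area_um2 for _, m in results)
        gt = sorted(c.area_um2 for c in truth.cells)
        for e, g in zip(est, gt):
            assert e == pytest.approx(g, rel=0.05)


class TestShapeMetrics:
    def test_digitized_disc_circularity(self):
        metrics = mask_metrics(disc_mask(25), 0.1)
        assert metrics.circularity >= 0.95

    def test_square_circularity_near_pi_over_4(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:60, 10:60] = True
        metrics = mask_metrics(mask, 0.1)
        assert metrics.circularity == pytest.approx(math.pi / 4, abs=0.03)

    def test_circularity_scale_invariant(self):
        small = mask_metrics(disc_mask(12), 0.1).circularity
        large = mask_metrics(disc_mask(40, shape=(128, 128)), 0.1).circularity
        assert small == pytest.approx(large, abs=0.02)

    def test_elongation_decreases_circularity(self):
        mask = np.zeros((60, 120), dtype=bool)
        rr, cc = draw.ellipse(30, 60, 10, 40)
        mask[rr, cc] = True
        assert mask_metrics(mask, 0.1).circularity \
            < mask_metrics(disc_mask(20), 0.1).circularity


def _detections(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


class TestLinking:
    def test_two_well_separated_cells_two_tracks(self):
        rows = []
        for f in range(5):
            rows.append((f, 0.0 + f, 0.0))
            rows.append((f, 20.0 + f, 0.0))
        table = link_tracks(_detections(rows), max_disp_um=5.0)
        assert len(table.track_ids) == 2
        for tid in table.track_ids:
            xs = table.track(tid)["x_um"].to_numpy()
            assert np.all(np.diff(xs) == 1.0)  # no identity switches

    def test_disappearance_ends_track_reappearance_starts_new(self):
        rows = [(0, 0.0, 0.0), (1, 1.0, 0.0),
                (3, 3.0, 0.0), (4, 4.0, 0.0)]  # missing at frame 2
        table = link_tracks(_detections(rows), max_disp_um=5.0)
        assert len(table.track_ids) == 2
        lengths = sorted(len(table.track(t)) for t in table.track_ids)
        assert lengths == [2, 2]

    def test_gate_blocks_implausible_jumps(self):
        rows = [(0, 0.0, 0.0), (1, 50.0, 0.0)]
        table = link_tracks(_detections(rows), max_disp_um=5.0)
        assert len(table.track_ids) == 2

    def test_every_generated_cell_yields_one_track(self, widefield_movie):
        from edgewater.track_shape import detect_movie
        cfg, movie, truth = widefield_movie
        table = link_tracks(detect_movie(movie))
        assert len(table.track_ids) == len(truth)


def _track_df(track_id, n, viable=0, start=0):
    return pd.DataFrame({
        "track_id": track_id, "frame": np.arange(start, start + n),
        "x_um": np.linspace(0, n, n), "y_um": 0.0, "viable": viable,
    })


class TestTrackFiltering:
    def test_half_length_rule_strict_less_than(self):
        table = TrackTable(pd.concat([_track_df(0, 19), _track_df(1, 20)]))
        kept = filter_tracks(table, n_frames=40, min_fraction=0.5)
        assert list(kept.track_ids) == [1]

    def test_third_length_rule(self):
        table = TrackTable(pd.concat([_track_df(0, 13), _track_df(1, 14)]))
        kept = filter_tracks(table, n_frames=40, min_fraction=1 / 3)
        assert list(kept.track_ids) == [1]

    def test_dead_cells_removed_regardless_of_length(self):
        table = TrackTable(pd.concat([_track_df(0, 40, viable=1),
                                      _track_df(1, 40)]))
        kept = filter_tracks(table, n_frames=40, min_fraction=0.5)
        assert list(kept.track_ids) == [1]

    def test_empty_table_passes_through(self):
        kept = filter_tracks(TrackTable(), n_frames=40)
        assert len(kept) == 0

    def test_idempotent(self):
        table = TrackTable(pd.concat([_track_df(0, 19), _track_df(1, 30),
                                      _track_df(2, 40, viable=1)]))
        once = filter_tracks(table, 40, 0.5)
        twice = filter_tracks(once, 40, 0.5)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestTrackSpeed:
    def test_three_four_five_triangle(self):
        track = pd.DataFrame({"track_id": 0, "frame": [0, 1],
                              "x_um": [0.0, 3.0], "y_um": [0.0, 4.0]})
        assert track_speed(track, dt_s=15.0) == pytest.approx(20.0)

    def test_stationary_track_zero(self):
        track = pd.DataFrame({"track_id": 0, "frame": [0, 1, 2],
                              "x_um": 1.0, "y_um": 1.0})
        assert track_speed(track, dt_s=15.0) == 0.0

    def test_path_length_not_net_displacement(self):
        track = pd.DataFrame({"track_id": 0, "frame": [0, 1, 2],
                              "x_um": [0.0, 5.0, 0.0], "y_um": 0.0})
        assert track_speed(track, dt_s=30.0) == pytest.approx(10.0)

    def test_single_point_rejected(self):
        track = pd.DataFrame({"track_id": 0, "frame": [0],
                              "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ValueError):
            track_speed(track, dt_s=15.0)

    def test_speed_recovery_on_generated_movie(self, widefield_movie):
        from edgewater.track_shape import detect_movie
        cfg, movie, truth = widefield_movie
        table = filter_tracks(link_tracks(detect_movie(movie)),
                              movie.n_frames, 0.5)
        live = sorted(c.speed_um_min for c in truth.cells if not c.is_dead)
        est = sorted(track_speed(table.track(t), movie.dt_s)
                     for t in table.track_ids)
        assert len(est) == len(live)
        rel_err = [abs(e - g) / g for e, g in zip(est, live)]
        assert np.median(rel_err) < 0.05
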