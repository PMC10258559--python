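import math

import numpy as np
import pandas as pd
import pytest

from migvar import (
    ALL_FEATURES,
    DYNAMIC_REGION_FEATURES,
    SEGMENTATION_FEATURES,
    dynamic_regions,
    extract_features,
    static_features,
    track_cells,
)
from migvar.synthetic import random_mask_movie_spec, generate_mask_movie

from _oracles import greedy_link_oracle, pixel_set_regions


def _square_masks(size=20, side=10, origin=(5, 5)):
    img = np.zeros((size, size), dtype=np.uint16)
    y0, x0 = origin
    img[y0 : y0 + side, x0 : x0 + side] = 1
    nuc = np.zeros_like(img)
    nuc[y0 + 3 : y0 + 7, x0 + 3 : x0 + 7] = 1
    return img, nuc


class TestStaticFeatures:
    def test_filled_square(self):
        img, nuc = _square_masks()
        f = static_features(img, nuc, pixel_size=1.0)
        assert f.loc[1, "cell_area"] == 100.0
        assert f.loc[1, "cell_extent"] == 1.0
        assert f.loc[1, "nucleus_area"] == 16.0
        assert f.loc[1, "nucleus_cell_area_ratio"] == pytest.approx(0.16)

    def test_rasterised_disk_close_to_analytic_circle(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = (((xx - 32) ** 2 + (yy - 32) ** 2) <= 20**2).astype(np.uint16)
        nuc = (((xx - 32) ** 2 + (yy - 32) ** 2) <= 8**2).astype(np.uint16)
        f = static_features(img, nuc, pixel_size=1.0)
        assert abs(f.loc[1, "cell_area"] - math.pi * 400) / (math.pi * 400) < 0.02
        assert f.loc[1, "cell_form_factor"] >= 0.95
        assert f.loc[1, "cell_form_factor"] <= 1.0
        assert f.loc[1, "cell_eccentricity"] < 0.1

    def test_random_blob_area_matches_pixel_count(self, rng):
        img = np.zeros((50, 50), dtype=np.uint16)
        blob = rng.random((20, 20)) > 0.4
        img[10:30, 10:30][blob] = 1
        nuc = np.zeros_like(img)
        nuc[18:22, 18:22] = 1
        f = static_features(img, nuc, pixel_size=0.8260)
        assert f.loc[1, "cell_area"] == pytest.approx(blob.sum() * 0.8260**2)

    def test_orphan_nucleus_flagged(self):
        img, nuc = _square_masks()
        nuc2 = nuc.copy()
        nuc2[0:2, 0:2] = 7  # nucleus label with no cell
        f = static_features(img, nuc2, pixel_size=1.0)
        assert f.loc[7, "flag"] == "orphan_nucleus"
        assert f.loc[1, "flag"] == ""

    def test_physical_units_scale_with_pixel_size(self):
        img, nuc = _square_masks()
        f1 = static_features(img, nuc, 1.0)
        f2 = static_features(img, nuc, 2.0)
        assert f2.loc[1, "cell_area"] == 4 * f1.loc[1, "cell_area"]
        assert f2.loc[1, "cell_perimeter"] == 2 * f1.loc[1, "cell_perimeter"]

    def test_rejects_nonpositive_pixel_size(self):
        img, nuc = _square_masks()
        with pytest.raises(ValueError):
            static_features(img, nuc, 0.0)


class TestDynamicRegions:
    def test_identical_frames_zero(self):
        img, _ = _square_masks()
        d = dynamic_regions(img, img, img, 1.0)
        assert (d.loc[1, ["protrusion_area", "retraction_area", "shortlived_area"]] == 0).all()

    def test_transient_bump_counts_in_all_three(self):
        base, _ = _square_masks(size=32)
        curr = base.copy()
        curr[5:9, 15:25] = 1  # 40-px bump present only now
        d = dynamic_regions(base, curr, base, 1.0)
        assert d.loc[1, "protrusion_area"] == 40.0
        assert d.loc[1, "retraction_area"] == 40.0
        assert d.loc[1, "shortlived_area"] == 40.0

    def test_movie_edges_are_missing(self):
        img, _ = _square_masks()
        first = dynamic_regions(None, img, img, 1.0)
        last = dynamic_regions(img, img, None, 1.0)
        assert np.isnan(first.loc[1, "protrusion_area"])
        assert np.isnan(first.loc[1, "shortlived_area"])
        assert last.loc[1, "protrusion_area"] == 0.0
        assert np.isnan(last.loc[1, "retraction_area"])

    def test_whole_cell_appearance_flagged(self):
        img, _ = _square_masks()
        empty = np.zeros_like(img)
        d = dynamic_regions(empty, img, empty, 1.0)
        assert d.loc[1, "flag"] == "whole_cell_appearance"
        assert np.isnan(d.loc[1, "protrusion_area"])

    def test_shifted_disk_matches_pixel_set_oracle(self, rng):
        for _ in range(5):
            spec = random_mask_movie_spec(rng, n_frames=4, image_size=(72, 72))
            movie, _ = generate_mask_movie(spec)
            masks = list(movie.cells)
            for lab in (1, 2):
                oracle = pixel_set_regions(masks, lab)
                for t in range(1, 3):
                    d = dynamic_regions(masks[t - 1], masks[t], masks[t + 1], 1.0)
                    prot, ret, short = oracle[t]
                    assert d.loc[lab, "protrusion_area"] == prot
                    assert d.loc[lab, "retraction_area"] == ret
                    assert d.loc[lab, "shortlived_area"] == short

    def test_shortlived_bounded_by_protrusion_and_retraction(self, rng):
        for _ in range(10):
            spec = random_mask_movie_spec(rng, n_frames=5, image_size=(72, 72))
            movie, _ = generate_mask_movie(spec)
            feats = extract_features(movie)
            mid = feats.dropna(subset=["shortlived_area"])
            assert (
                mid["shortlived_area"]
                <= mid[["protrusion_area", "retraction_area"]].min(axis=1) + 1e-12
            ).all()


class TestTracking:
    def test_static_nucleus_single_trajectory(self):
        det = pd.DataFrame(
            {"frame": range(10), "label": [1] * 10, "x": [5.0] * 10, "y": [5.0] * 10}
        )
        trs = track_cells(det, max_link_distance=20.0)
        assert len(trs) == 1 and len(trs[0]) == 10

    def test_two_distant_nuclei_no_identity_swap(self):
        rows = []
        for t in range(6):
            rows.append({"frame": t, "label": 1, "x": 2.0 * t, "y": 0.0})
            rows.append({"frame": t, "label": 2, "x": 100.0 + 2.0 * t, "y": 0.0})
        trs = track_cells(pd.DataFrame(rows), max_link_distance=20.0)
        assert len(trs) == 2
        xs0 = [p[0] for p in trs[0].positions]
        assert max(xs0) - min(xs0) == pytest.approx(10.0)  # stayed on one nucleus

    def test_jump_beyond_gate_starts_new_track(self):
        det = pd.DataFrame(
            {"frame": [0, 1, 2], "label": [1, 1, 1],
             "x": [0.0, 2.0, 52.0], "y": [0.0, 0.0, 0.0]}
        )
        trs = track_cells(det, max_link_distance=20.0)
        assert sorted(len(t) for t in trs) == [1, 2]

    def test_links_match_assignment_oracle(self, rng):
        # <=4 nuclei per frame, random walks: frame-to-frame links equal the
        # exhaustive distance-ordered assignment
        pts = rng.uniform(10, 90, size=(4, 2))
        prev = pts.copy()
        det_rows = [
            {"frame": 0, "label": i + 1, "x": p[0], "y": p[1]} for i, p in enumerate(pts)
        ]
        moved = prev + rng.normal(0, 3, size=prev.shape)
        det_rows += [
            {"frame": 1, "label": i + 1, "x": p[0], "y": p[1]} for i, p in enumerate(moved)
        ]
        trs = track_cells(pd.DataFrame(det_rows), max_link_distance=15.0)
        links = {}
        for tr in trs:
            if len(tr) == 2:
                links[tuple(np.round(tr.positions[1], 6))] = tuple(np.round(tr.positions[0], 6))
        oracle = greedy_link_oracle(
            prev, list(range(4)), moved, [1, 2, 3, 4], 15.0
        )
        expected = {
            tuple(np.round(moved[j], 6)): tuple(np.round(prev[pid], 6))
            for j, pid in oracle.items()
        }
        assert links == expected

    def test_empty_movie(self):
        det = pd.DataFrame(columns=["frame", "label", "x", "y"])
        assert track_cells(det, 10.0) == []


class TestExtraction:
    def test_feature_inventory(self, two_cell_movie):
        movie, _ = two_cell_movie
        feats = extract_features(movie)
        assert len(ALL_FEATURES) == 18
        assert len(SEGMENTATION_FEATURES) == 15
        assert set(SEGMENTATION_FEATURES) < set(ALL_FEATURES)
        assert set(ALL_FEATURES) <= set(feats.columns)

    def test_reproduces_ground_truth_areas_and_centroids(self, two_cell_movie):
        movie, truth = two_cell_movie
        feats = extract_features(movie)
        m = feats.merge(truth.table, on=["label", "frame"], suffixes=("", "_true"))
        assert np.allclose(m["cell_area"], m["area"])
        assert np.allclose(m["nucleus_area"], m["nucleus_area_true"])
        # centroid within half a pixel of the rendered truth
        assert (m["cell_centroid_x"] - m["centroid_x"]).abs().max() <= 0.5
        assert (m["cell_centroid_y"] - m["centroid_y"]).abs().max() <= 0.5
        for col in DYNAMIC_REGION_FEATURES:
            assert np.allclose(
                m[col].fillna(-1.0), m[f"{col}_true"].fillna(-1.0)
            )

    def test_speed_matches_script_for_bumpless_cell(self, two_cell_movie):
        movie, truth = two_cell_movie
        feats = extract_features(movie)
        static = feats[feats.label == 2]["cell_speed"].dropna()
        assert np.allclose(static, 0.0)
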