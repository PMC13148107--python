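"""Image quantification against brute-force oracles and planted geometry."""

import numpy as np
import pytest

from inversepair.containers import ImageStack
from inversepair.errors import ValidationError
from inversepair.image_quant import (
    max_project,
    measure_roi_intensity,
    otsu_threshold,
    quantify_binding,
    segment_controls,
    segment_transfected,
    summarize_binding,
)
from inversepair.synthetic import gen_cell_image

import pandas as pd


def otsu_sigma_by_cut(image, n_bins=256):
    """Between-class variance for every histogram cut point (exhaustive search).

    Returns (bin centers, sigma) where sigma[i] is the objective when class 0
    holds bins 0..i (threshold at centers[i]).
    """
    hist, edges = np.histogram(image.ravel(), bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    sigma = np.full(n_bins, -np.inf)
    for cut in range(1, n_bins):
        w0, w1 = hist[:cut].sum(), hist[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:cut] * centers[:cut]).sum() / w0
        m1 = (hist[cut:] * centers[cut:]).sum() / w1
        sigma[cut - 1] = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
    return centers, sigma


class TestMaxProject:
    def test_single_plane_identity_and_duplicate_idempotence(self):
        plane = np.arange(12.0).reshape(3, 4)
        stack = ImageStack(channels={"a": np.stack([plane, plane])}, pixel_size_um=0.2)
        out = max_project(stack)
        np.testing.assert_array_equal(out.channels["a"], plane)

    def test_matches_elementwise_loop_oracle(self, rng):
        cube = rng.uniform(0, 255, size=(4, 6, 5))
        stack = ImageStack(channels={"a": cube}, pixel_size_um=0.2)
        out = max_project(stack).channels["a"]
        for r in range(6):
            for c in range(5):
                assert out[r, c] == max(cube[z, r, c] for z in range(4))


class TestOtsu:
    def test_two_level_image_threshold_separates_modes(self):
        img = np.array([[50.0] * 8, [200.0] * 8])
        thr = otsu_threshold(img)
        assert 50 < thr < 200

    def test_achieves_bruteforce_maximum(self, rng):
        # the returned cut point attains the exhaustive-search maximum of the
        # between-class variance (ties on empty-gap plateaus are all optimal)
        for _ in range(5):
            img = np.concatenate(
                [rng.normal(40, 10, 400), rng.normal(180, 20, 300)]
            ).reshape(20, 35)
            img = np.clip(img, 0, 255)
            thr = otsu_threshold(img)
            centers, sigma = otsu_sigma_by_cut(img)
            achieved = sigma[np.argmin(np.abs(centers - thr))]
            assert achieved >= sigma.max() * (1 - 1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValidationError):
            otsu_threshold(np.full((5, 5), 7.0))

    def test_noiseless_disk_mask_equals_plant(self):
        stack, truth = gen_cell_image(n_transfected=1, n_control=0, noise_sd=0.0, seed=1)
        fl = stack.channels["fl"]
        thr = otsu_threshold(fl)
        mask = fl > thr
        cell = truth.cells[0]
        rr, cc = np.ogrid[: fl.shape[0], : fl.shape[1]]
        planted = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= (
            cell.body_radius_um / stack.pixel_size_um
        ) ** 2
        np.testing.assert_array_equal(mask, planted)


class TestSegmentation:
    def test_disjoint_disks_give_one_roi_each(self):
        img = np.full((100, 100), 10.0)
        for r, c in [(20, 20), (20, 70), (70, 45)]:
            rr, cc = np.ogrid[:100, :100]
            img[(rr - r) ** 2 + (cc - c) ** 2 <= 64] = 200.0
        _, rois = segment_transfected(img, pixel_size_um=0.2)
        assert len(rois) == 3

    def test_labels_match_flood_fill_oracle(self, rng):
        from scipy import ndimage

        img = np.where(rng.random((40, 40)) < 0.3, 200.0, 10.0)
        labels, rois = segment_transfected(img, pixel_size_um=0.2)
        oracle, n = ndimage.label(img > 100, structure=np.ones((3, 3)))
        assert len(rois) == n
        # same partition: each oracle component maps to exactly one label
        for k in range(1, n + 1):
            assert len(np.unique(labels[oracle == k])) == 1

    def test_circularity_disk_vs_line(self):
        img = np.full((64, 64), 10.0)
        rr, cc = np.ogrid[:64, :64]
        img[(rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2] = 200.0
        _, [disk_roi] = segment_transfected(img, pixel_size_um=0.2)
        assert disk_roi.circularity > 0.9
        line = np.full((10, 120), 10.0)
        line[5, 5:105] = 200.0
        _, [line_roi] = segment_transfected(line, pixel_size_um=0.2)
        assert line_roi.circularity < 0.3

    def test_dilated_control_overlapping_fl_mask_dropped(self):
        shape = (80, 80)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        fl_mask = (rr - 40) ** 2 + (cc - 20) ** 2 <= 15**2
        nuclear = np.full(shape, 10.0)
        # nucleus 3 px away from the FL disk: a 1.25 um (=6 px) dilation reaches it
        near = (rr - 40) ** 2 + (cc - 45) ** 2 <= 7**2
        far = (rr - 40) ** 2 + (cc - 68) ** 2 <= 7**2
        nuclear[near | far] = 180.0
        _, rois = segment_controls(
            nuclear, fl_mask, pixel_size_um=0.2, area_range_um2=(0.1, 1e9), min_circ=0.0
        )
        centers = [r.pixels.mean(axis=0) for r in rois]
        assert len(rois) == 1
        assert abs(centers[0][1] - 68) < 2

    def test_gate_monotonicity_never_adds_rois(self):
        stack, _ = gen_cell_image(
            n_transfected=2, n_control=4, offgate_radii_um=(1.2, 3.2), seed=5
        )
        fl = stack.channels["fl"]
        labels_t, _ = segment_transfected(fl, stack.pixel_size_um)
        base = segment_controls(
            stack.channels["nuclear"], labels_t > 0, stack.pixel_size_um
        )[1]
        narrow = segment_controls(
            stack.channels["nuclear"], labels_t > 0, stack.pixel_size_um,
            area_range_um2=(10.0, 20.0), min_circ=0.95,
        )[1]
        assert {r.label for r in narrow} <= {r.label for r in base}


class TestEndToEnd:
    def test_noiseless_scene_recovered_exactly(self):
        stack, truth = gen_cell_image(
            n_transfected=4,
            n_control=5,
            offgate_radii_um=(1.2, 3.2),
            n_bars=1,
            noise_sd=0.0,
            seed=1,
        )
        table = quantify_binding(stack)
        assert (table["roi_class"] == "transfected").sum() == 4
        assert (table["roi_class"] == "control").sum() == 5  # off-gate + bar rejected
        ecd = {"transfected": 120.0, "control": 15.0}
        for _, row in table.iterrows():
            assert row["mean_ecd"] == ecd[row["roi_class"]]
        controls = table[table["roi_class"] == "control"]
        assert ((controls["area_um2"] >= 7.8) & (controls["area_um2"] <= 23.4)).all()
        assert (controls["circularity"] > 0.9).all()

    def test_single_pixel_roi_mean_is_its_value(self):
        from inversepair.image_quant import RoiRecord

        chan = np.arange(9.0).reshape(3, 3)
        roi = RoiRecord(
            label=1, roi_class="control", pixel_count=1, area_um2=0.04,
            circularity=1.0, pixels=np.array([[1, 2]]),
        )
        [out] = measure_roi_intensity([roi], chan, "ecd")
        assert out.mean_intensity["ecd"] == chan[1, 2]


class TestSummarize:
    def test_one_experiment_pairs_group_means(self):
        df = pd.DataFrame(
            {
                "experiment": ["e1"] * 4,
                "group": ["control", "control", "transfected", "transfected"],
                "value": [8.0, 12.0, 45.0, 55.0],
            }
        )
        means, paired = summarize_binding(df)
        row = paired.set_index("experiment").loc["e1"]
        assert row["control"] == 10.0 and row["transfected"] == 50.0

    def test_matches_groupby_oracle_and_drops_incomplete(self, rng):
        rows = []
        for e in ("e1", "e2", "e3"):
            for g in ("control", "transfected"):
                for _ in range(5):
                    rows.append((e, g, rng.uniform(0, 100)))
        rows.append(("e4", "control", 1.0))  # missing transfected
        df = pd.DataFrame(rows, columns=["experiment", "group", "value"])
        with pytest.warns(UserWarning, match="e4"):
            means, paired = summarize_binding(df)
        assert set(paired["experiment"]) == {"e1", "e2", "e3"}
        for (e, g), grp in df[df.experiment != "e4"].groupby(["experiment", "group"]):
            expected = sum(grp["value"]) / len(grp)
            got = means[(means.experiment == e) & (means.group == g)]["value"].iloc[0]
            assert got == pytest.approx(expected)
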