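"""Cell segmentation, positivity calls, TPS/CPS and colocalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import afstain as a
from afstain.quantify import (
    QuantConfig,
    assign_tumor_membership,
    quantify_mif,
)


def draw_nuclei(centers, shape=(128, 128), radius=5.0, amp=200.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        img += amp * np.clip(radius + 0.5 - d, 0, 1)
    return ndimage.gaussian_filter(img, 1.0)


def toy_cells(flags):
    """CellTable from (x, y, in_tumor, pdl1_pos, cd3_pos, cd8_pos) tuples."""
    rows = []
    for i, (x, y, tum, pdl1, cd3, cd8) in enumerate(flags, start=1):
        rows.append(
            {
                "id": i, "x": float(x), "y": float(y), "area_um2": 10.0,
                "mean_PD-L1": 100.0 * pdl1, "mean_CD3": 100.0 * cd3,
                "mean_CD8": 100.0 * cd8,
                "positive_PD-L1": bool(pdl1), "positive_CD3": bool(cd3),
                "positive_CD8": bool(cd8), "in_tumor": bool(tum),
            }
        )
    return a.CellTable(df=pd.DataFrame(rows),
                       label_image=np.zeros((64, 64), np.int32),
                       pixel_size_um=1.0)


class TestSegmentCells:
    def test_blank_dapi_gives_zero_cells(self):
        cells = a.segment_cells(np.zeros((64, 64)))
        assert len(cells) == 0

    def test_well_separated_nuclei_counted_exactly(self):
        rng = np.random.default_rng(0)
        centers = [(16 + 24 * i, 16 + 24 * j) for i in range(5) for j in range(5)]
        jitter = [(x + rng.uniform(-2, 2), y + rng.uniform(-2, 2))
                  for x, y in centers][:40]
        dapi = draw_nuclei(jitter, shape=(144, 144))
        cells = a.segment_cells(dapi, QuantConfig(dapi_threshold=40.0))
        assert len(cells) == len(jitter)

    def test_touching_pair_split_into_two(self):
        dapi = draw_nuclei([(60, 64), (69, 64)], radius=5.0)
        cells = a.segment_cells(dapi, QuantConfig(dapi_threshold=40.0))
        assert len(cells) == 2

    def test_phantom_nucleus_count_matches_ground_truth(self, phantom, mif):
        cells = a.segment_cells(mif.channel("DAPI"),
                                QuantConfig(dapi_threshold=40.0))
        assert len(cells) == len(phantom.nuclei)

    def test_negative_dapi_rejected(self):
        with pytest.raises(ValueError):
            a.segment_cells(np.full((8, 8), -1.0))


class TestSegmentTumor:
    def test_flat_panck_gives_empty_mask(self):
        assert not a.segment_tumor(np.zeros((64, 64))).any()

    def test_disk_tumor_iou_above_090(self):
        # clean disk-shaped tumor region with bright cell bodies
        yy, xx = np.mgrid[0:192, 0:192]
        disk = (xx - 96) ** 2 + (yy - 96) ** 2 < 60**2
        panck = 60.0 * disk
        rng = np.random.default_rng(0)
        for _ in range(20):
            cx, cy = rng.integers(40, 152, 2)
            if disk[cy, cx]:
                d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
                panck += 120 * np.clip(8.5 - d, 0, 1)
        panck = ndimage.gaussian_filter(panck, 1.0)
        mask = a.segment_tumor(panck)
        assert (mask & disk).sum() / (mask | disk).sum() > 0.9

    def test_phantom_tumor_mask_iou(self, phantom, mif):
        # irregular blob boundary + rendering PSF limit the overlap
        mask = a.segment_tumor(mif.channel("PanCK"))
        inter = (mask & phantom.tumor_mask).sum()
        union = (mask | phantom.tumor_mask).sum()
        assert inter / union > 0.8

    def test_invariant_to_intensity_scale(self, mif):
        m1 = a.segment_tumor(mif.channel("PanCK"))
        m2 = a.segment_tumor(mif.channel("PanCK") * 2.0)
        assert np.array_equal(m1, m2)


class TestClassifyPositive:
    def test_threshold_extremes(self, mif):
        cells = a.segment_cells(mif.channel("DAPI"),
                                QuantConfig(dapi_threshold=40.0))
        all_pos = a.classify_positive(cells, mif.channel("CD3"), "CD3", 0.0)
        assert all_pos.df["positive_CD3"].all()
        none_pos = a.classify_positive(
            cells, mif.channel("CD3"), "CD3",
            mif.channel("CD3").max() + 1.0,
        )
        assert not none_pos.df["positive_CD3"].any()

    def test_mid_gap_threshold_recovers_expressing_cells(self, phantom, mif):
        cells = a.segment_cells(mif.channel("DAPI"),
                                QuantConfig(dapi_threshold=40.0))
        cells = a.classify_positive(cells, mif.channel("CD3"), "CD3", 20.0)
        truth = sum(1 for e in phantom.marker_expression if e["CD3"] > 0)
        assert int(cells.df["positive_CD3"].sum()) == truth

    def test_shape_mismatch_rejected(self, mif):
        cells = a.segment_cells(mif.channel("DAPI"),
                                QuantConfig(dapi_threshold=40.0))
        with pytest.raises(ValueError):
            a.classify_positive(cells, np.zeros((3, 3)), "CD3", 1.0)


class TestMeasureRoi:
    def region(self):
        return np.ones((64, 64), bool)

    def test_tps_hand_count(self):
        # 10 tumor cells, 3 PD-L1+ tumor, 0 PD-L1+ immune -> TPS 30, CPS 30
        flags = [(i, 1, True, i < 3, False, False) for i in range(10)]
        cells = toy_cells(flags)
        ms = a.measure_roi(cells, self.region(), None, self.region(), "tissue")
        assert ms.values["tps_percent"] == pytest.approx(30.0)
        assert ms.values["cps_percent"] == pytest.approx(30.0)

    def test_cps_counts_immune_cells(self):
        flags = [(i, 1, True, i < 3, False, False) for i in range(10)]
        flags += [(i, 30, False, True, True, False) for i in range(2)]
        cells = toy_cells(flags)
        ms = a.measure_roi(cells, self.region(), None, self.region(), "tissue")
        assert ms.values["tps_percent"] == pytest.approx(30.0)
        assert ms.values["cps_percent"] == pytest.approx(50.0)

    def test_cps_capped_at_100(self):
        flags = [(0, 1, True, True, False, False)]
        flags += [(i, 30, False, True, False, False) for i in range(1, 5)]
        ms = a.measure_roi(toy_cells(flags), self.region(), None,
                           self.region(), "tissue")
        assert ms.values["cps_percent"] == 100.0

    def test_no_tumor_cells_gives_explicit_undefined(self):
        flags = [(i, 1, False, False, True, False) for i in range(5)]
        ms = a.measure_roi(toy_cells(flags), self.region(), None,
                           self.region(), "tissue")
        assert "tps_percent" not in ms.values
        assert "no tumor cells" in ms.undefined["tps_percent"]

    def test_empty_roi_densities_zero_percentages_undefined(self):
        flags = [(1, 1, True, True, False, False)]
        empty = np.zeros((64, 64), bool)
        ms = a.measure_roi(toy_cells(flags), empty, None, empty, "real_tumor")
        assert ms.values["dapi_cell_density"] == 0.0
        assert "tps_percent" in ms.undefined

    def test_respective_tumor_requires_virtual_mask(self):
        flags = [(1, 1, True, True, False, False)]
        with pytest.raises(ValueError):
            a.measure_roi(toy_cells(flags), self.region(), None,
                          self.region(), "respective_tumor")

    def test_density_scales_with_pixel_size(self):
        flags = [(i, j, False, False, True, False)
                 for i in range(0, 60, 12) for j in range(0, 60, 12)]
        c1 = toy_cells(flags)
        c2 = toy_cells(flags)
        c2.pixel_size_um = 2.0  # coarser grid: same cells, 4x area
        m1 = a.measure_roi(c1, self.region(), None, self.region(), "tissue")
        m2 = a.measure_roi(c2, self.region(), None, self.region(), "tissue")
        assert m1.values["CD3_cell_density"] == pytest.approx(
            4.0 * m2.values["CD3_cell_density"]
        )


class TestColocalization:
    def test_no_cd8_means_zero_coloc(self):
        flags = [(i, 1, False, False, True, False) for i in range(5)]
        out = a.colocalization_counts(toy_cells(flags))
        assert out["cd3_cd8"][0] == 0

    def test_cytotoxic_subset_counted(self):
        flags = [(i, 1, False, False, True, i < 10) for i in range(20)]
        out = a.colocalization_counts(toy_cells(flags))
        assert out["cd3_cd8"][0] == 10

    def test_coloc_bounded_by_single_marker_counts(self):
        rng = np.random.default_rng(0)
        flags = [(i, 1, False, rng.random() < 0.5, rng.random() < 0.5,
                  rng.random() < 0.5) for i in range(50)]
        cells = toy_cells(flags)
        out = a.colocalization_counts(cells)
        assert out["cd3_cd8"][0] <= min(cells.df["positive_CD3"].sum(),
                                        cells.df["positive_CD8"].sum())
        assert out["cd3_pdl1"][0] <= min(cells.df["positive_CD3"].sum(),
                                         cells.df["positive_PD-L1"].sum())

    def test_unknown_pair_rejected(self):
        flags = [(1, 1, False, False, True, False)]
        with pytest.raises(ValueError):
            a.colocalization_counts(toy_cells(flags),
                                    pairs={"bad": ("CD3", "FOXP3")})


class TestFullSuite:
    def test_cd8_background_inflates_cd8_more_than_coloc(self, phantom):
        cfg = QuantConfig(dapi_threshold=40.0,
                          marker_thresholds={"PD-L1": 20.0, "CD3": 20.0,
                                             "CD8": 12.0})
        clean = a.render_mif(phantom, a.RenderConfig(noise_sd=0.0))
        noisy = a.render_mif(
            phantom,
            a.RenderConfig(noise_sd=0.0, cd8_nonspecific_amplitude=25.0),
        )
        names = ("DAPI", "PanCK", "PD-L1", "CD3", "CD8")
        ch_c = {n: clean.channel(n) for n in names}
        ch_n = {n: noisy.channel(n) for n in names}
        _, res_c = quantify_mif(ch_c, cfg, rois=("tissue",))
        _, res_n = quantify_mif(ch_n, cfg, rois=("tissue",))
        cd8_inflation = (res_n["tissue"].values["CD8_cell_density"]
                         - res_c["tissue"].values["CD8_cell_density"])
        coloc_inflation = (res_n["tissue"].values["cd3_cd8_cell_density"]
                           - res_c["tissue"].values["cd3_cd8_cell_density"])
        assert cd8_inflation > 0  # nonspecific background adds false positives
        assert abs(coloc_inflation) <= cd8_inflation

    def test_self_concordant_measurements(self, mif):
        names = ("DAPI", "PanCK", "PD-L1", "CD3", "CD8")
        ch = {n: mif.channel(n) for n in names}
        cfg = QuantConfig(dapi_threshold=40.0)
        _, r1 = quantify_mif(ch, cfg)
        _, r2 = quantify_mif(ch, cfg)
        for roi in r1:
            assert r1[roi].values == r2[roi].values


def test_assign_tumor_membership_by_centroid():
    flags = [(5, 5, False, False, False, False),
             (40, 40, False, False, False, False)]
    cells = toy_cells(flags)
    mask = np.zeros((64, 64), bool)
    mask[:20, :20] = True
    cells = assign_tumor_membership(cells, mask)
    assert cells.df["in_tumor"].tolist() == [True, False]
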