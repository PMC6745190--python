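"""Legend remapping, raster I/O and area accounting."""

import numpy as np
import pandas as pd
import pytest

from ecoserv import AreaTable, CategoricalRaster, ClassLegend, area_change_pct, load_raster, tabulate_areas, write_raster
from ecoserv.classes import CLASSES, NODATA
from ecoserv.raster import LegendCoverageError

from conftest import make_raster


class TestClassLegend:
    def test_identity_legend_remaps_codes_to_classes(self):
        legend = ClassLegend.identity()
        out = legend.remap(np.full((3, 3), 3))
        assert (out == CLASSES.index("grassland")).all()

    def test_remap_is_idempotent_for_identity_coded_raster(self):
        legend = ClassLegend.identity()
        raw = np.array([[1, 2], [7, 0]])
        once = legend.remap(raw)
        # shifting back to 1-based codes and remapping again is a no-op
        again = legend.remap(np.where(once == NODATA, 0, once + 1))
        assert (once == again).all()

    def test_unmapped_code_raises_naming_the_code(self):
        legend = ClassLegend.identity()
        with pytest.raises(LegendCoverageError, match="999"):
            legend.remap(np.array([[1, 999]]))

    def test_hand_counted_remap_with_nodata(self):
        legend = ClassLegend({10: "cropland", 210: "water"}, frozenset({0}))
        out = legend.remap(np.array([[10, 10], [210, 0]]))
        counts = CategoricalRaster(out).class_counts()
        assert counts["cropland"] == 2
        assert counts["water"] == 1
        assert (out == NODATA).sum() == 1

    def test_legend_rejects_unknown_class_names(self):
        with pytest.raises(ValueError, match="unknown classes"):
            ClassLegend({1: "ocean"})

    def test_non_integer_band_is_a_format_error(self):
        with pytest.raises(TypeError, match="not integer"):
            ClassLegend.identity().remap(np.array([[1.5, 2.0]]))


class TestAreaAccounting:
    def test_area_is_count_times_cell_area(self):
        vals = np.full((10, 10), CLASSES.index("grassland"), dtype=np.int16)
        vals.ravel()[:40] = CLASSES.index("cropland")
        areas = tabulate_areas(make_raster(vals, cell_area_ha=9.0))
        assert areas["cropland"] == pytest.approx(360.0)
        assert areas["grassland"] == pytest.approx(540.0)

    def test_all_nodata_raster_has_zero_areas(self):
        areas = tabulate_areas(make_raster(np.full((4, 4), NODATA)))
        assert (areas == 0).all()

    def test_tabulated_synthetic_areas_are_exact(self):
        from ecoserv import LandscapeSpec, generate_initial

        r = generate_initial(LandscapeSpec(rows=50, cols=50, patchiness=0, seed=1, cell_area_ha=9.0))
        assert tabulate_areas(r).sum() == pytest.approx(50 * 50 * 9.0)
        assert (tabulate_areas(r) == r.class_counts() * 9.0).all()

    def test_packaged_1995_areas(self, areas):
        row = areas.areas_1e4_ha.loc[1995]
        assert row["cropland"] == pytest.approx(7595.03)
        assert row["grassland"] == pytest.approx(20560.52)
        assert row["urban"] == pytest.approx(27.57)

    def test_totals_conserved_across_years(self, areas):
        totals = areas.totals()
        assert np.allclose(totals, 40010.48e4, rtol=1e-6)

    @pytest.mark.parametrize(
        "y1,y2,cls,expected",
        [
            (1995, 2035, "cropland", 22.10),
            (1995, 2015, "water", -21.80),
            (1995, 2035, "bare", -9.42),
        ],
    )
    def test_change_percent_matches_published_rates(self, areas, y1, y2, cls, expected):
        pct = area_change_pct(areas, y1, y2)
        assert pct[cls] == pytest.approx(expected, abs=0.005)

    def test_change_percent_zero_for_equal_areas(self, areas):
        same = AreaTable.from_rows({1: areas.row(1995), 2: areas.row(1995)})
        assert (area_change_pct(same, 1, 2) == 0).all()

    def test_zero_baseline_flags_undefined_not_zero(self):
        row1 = pd.Series(0.0, index=list(CLASSES))
        row1["grassland"] = 10.0
        row2 = row1.copy()
        row2["cropland"] = 5.0
        table = AreaTable.from_rows({1: row1, 2: row2})
        with pytest.warns(UserWarning, match="undefined"):
            pct = area_change_pct(table, 1, 2)
        assert np.isnan(pct["cropland"])
        assert "cropland" in pct.attrs["undefined"]

    def test_area_table_csv_round_trip(self, areas, tmp_path):
        p = areas.to_csv(tmp_path / "areas.csv")
        back = AreaTable.from_csv(p)
        pd.testing.assert_frame_equal(back.areas_1e4_ha, areas.areas_1e4_ha)


class TestMaskHarmonization:
    def test_union_of_nodata_applied_to_both(self, masked_pair):
        a, b = masked_pair
        ha, hb = CategoricalRaster.harmonize(a, b)
        assert (ha.mask == hb.mask).all()
        assert ha.n_valid == 14  # 16 cells minus the two holes
        # conservation over the common mask
        assert ha.class_areas_ha().sum() == hb.class_areas_ha().sum()

    def test_disjoint_masks_error(self):
        a = make_raster(np.array([[0, NODATA]], dtype=np.int16))
        b = make_raster(np.array([[NODATA, 0]], dtype=np.int16))
        with pytest.raises(ValueError, match="no valid cells"):
            CategoricalRaster.harmonize(a, b)

    def test_shape_mismatch_error(self, checkerboard):
        with pytest.raises(ValueError, match="shapes differ"):
            CategoricalRaster.harmonize(checkerboard, make_raster(np.zeros((2, 2))))


class TestRasterIO:
    @pytest.mark.parametrize("fmt", ["asc", "tif"])
    def test_round_trip_preserves_values_and_mask(self, fmt, tmp_path):
        vals = np.array([[0, 1, 2], [NODATA, 6, 3]], dtype=np.int16)
        r = CategoricalRaster(vals, cell_area_ha=9.0, year=1995, origin=(10.0, 20.0), cell_size=300.0)
        p = write_raster(r, tmp_path / f"r.{fmt}")
        back = load_raster(p, cell_area_ha=9.0, year=1995)
        assert (back.values == vals).all()
        assert back.mask.sum() == 5

    def test_tif_carries_metadata(self, tmp_path):
        r = CategoricalRaster(np.zeros((2, 2), dtype=np.int16), cell_area_ha=9.0, year=2005, crs="EPSG:4326")
        back = load_raster(write_raster(r, tmp_path / "r.tif"))
        assert back.year == 2005
        assert back.crs == "EPSG:4326"
        assert back.cell_area_ha == 9.0

    def test_load_with_legend_remaps_raw_codes(self, tmp_path):
        raw = CategoricalRaster(np.array([[0, 1]], dtype=np.int16))
        # write class indices 0/1, then read pretending they are raw codes 0/1
        p = write_raster(raw, tmp_path / "r.asc", nodata=-9999)
        legend = ClassLegend({0: "water", 1: "urban"})
        back = load_raster(p, legend)
        assert back.values.tolist() == [[CLASSES.index("water"), CLASSES.index("urban")]]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            load_raster(tmp_path / "r.png")
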