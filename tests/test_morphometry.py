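"""Areas, best-fit ellipses, circularity conventions, Wilson ratios, t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from multinuc import (
    assign_nuclei_to_cells,
    best_fit_ellipse,
    circularity,
    compute_cell_metrics,
    generate_cell_field,
    group_compare,
    records_from_label_mask,
    region_area,
)
from multinuc.synthetic import CellFieldSpec


def _ellipse_mask(a, b, phi=0.0, pad=6):
    n = int(2 * a) + 2 * pad
    rr, cc = np.mgrid[0:n, 0:n]
    dy, dx = rr - n / 2, cc - n / 2
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestRegionArea:
    def test_filled_square(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 5:105] = True
        assert region_area(mask, 1.0) == 10_000.0

    def test_unit_square_polygon_shoelace(self):
        assert region_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)

    def test_rasterized_ellipse_close_to_closed_form(self):
        mask = _ellipse_mask(50, 30)
        assert region_area(mask) == pytest.approx(math.pi * 50 * 30, rel=0.02)

    def test_pixel_size_scaling(self):
        mask = np.ones((10, 10), bool)
        assert region_area(mask, 0.5) == pytest.approx(25.0)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            region_area(np.zeros((5, 5), bool))


class TestBestFitEllipse:
    def test_disk_axes_equal_diameter(self, disk_mask):
        fit = best_fit_ellipse(disk_mask)
        assert fit.major_px == pytest.approx(100, rel=0.02)
        assert fit.minor_px == pytest.approx(100, rel=0.02)

    def test_ellipse_axes(self):
        fit = best_fit_ellipse(_ellipse_mask(50, 30))
        assert fit.major_px == pytest.approx(100, rel=0.02)
        assert fit.minor_px == pytest.approx(60, rel=0.02)

    def test_rotation_invariance(self):
        m0 = best_fit_ellipse(_ellipse_mask(50, 30)).major_px
        m37 = best_fit_ellipse(_ellipse_mask(50, 30, math.radians(37))).major_px
        assert m37 == pytest.approx(m0, rel=0.01)

    def test_degenerate_region_errors(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 3] = True
        with pytest.raises(ValueError):
            best_fit_ellipse(mask)


class TestCircularity:
    def test_disk_roundness_is_one(self):
        R = 7.0
        assert circularity(math.pi * R**2, 2 * R) == pytest.approx(1.0, abs=1e-12)

    def test_two_to_one_ellipse_is_half(self):
        a, b = 8.0, 4.0
        assert circularity(math.pi * a * b, 2 * a) == pytest.approx(0.5, abs=1e-12)

    def test_literal_convention_disk_pi_squared(self):
        R = 7.0
        assert circularity(math.pi * R**2, 2 * R, "literal_eq") == \
            pytest.approx(math.pi**2, abs=1e-9)

    def test_conventions_related_by_pi_squared_exactly(self):
        for S, M in [(100.0, 20.0), (57.3, 11.1), (math.pi, 2.0)]:
            assert circularity(S, M, "literal_eq") == \
                pytest.approx(math.pi**2 * circularity(S, M, "roundness"), rel=1e-15)

    def test_scale_invariance_on_rasterized_shape(self):
        small = _ellipse_mask(30, 18)
        big = _ellipse_mask(60, 36)
        a1 = circularity(region_area(small), best_fit_ellipse(small).major_px)
        a2 = circularity(region_area(big), best_fit_ellipse(big).major_px)
        assert a1 == pytest.approx(a2, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circularity(0.0, 1.0)
        with pytest.raises(ValueError):
            circularity(1.0, 1.0, "perimeter")


@pytest.fixture(scope="module")
def metrics(field_88):
    spec, _, cmask, nmask, truth = field_88
    recs = records_from_label_mask(nmask, spec.pixel_size_um)
    asg = assign_nuclei_to_cells(recs, cmask)
    cells, nucs = compute_cell_metrics(cmask, nmask, asg, spec.pixel_size_um)
    return truth, cells, nucs


class TestCellMetrics:

    def test_cell_metrics_match_truth(self, metrics):
        truth, cells, _ = metrics
        merged = cells.merge(truth.cells, on="cell_id")
        np.testing.assert_allclose(merged["S_cell_px2"], merged["area_px2"],
                                   rtol=0.02)
        np.testing.assert_allclose(merged["M_cell_px"], merged["major_px"],
                                   rtol=0.02)
        np.testing.assert_allclose(merged["alpha_cell"], merged["circularity"],
                                   rtol=0.03)

    def test_group_flags_match_truth(self, metrics):
        truth, cells, _ = metrics
        merged = cells.merge(truth.cells, on="cell_id")
        assert ((merged["group"] == "multi") == merged["multinucleated"]).all()

    def test_summed_ratio_additivity_exact(self, metrics):
        _, cells, nucs = metrics
        summed = nucs.groupby("cell_id")["ratio_pct"].sum()
        merged = cells.set_index("cell_id").loc[summed.index, "summed_ratio_pct"]
        np.testing.assert_allclose(summed.to_numpy(), merged.to_numpy(), atol=1e-12)

    def test_both_conventions_reported(self, metrics):
        _, cells, nucs = metrics
        for df, col in [(cells, "alpha_cell"), (nucs, "alpha_nucleus")]:
            np.testing.assert_allclose(df[f"{col}_literal"],
                                       math.pi**2 * df[f"{col}_roundness"],
                                       rtol=1e-12)

    def test_cell_without_nucleus_excluded_with_warning(self):
        cmask = np.zeros((40, 80), np.uint16)
        cmask[5:35, 5:35] = 1
        cmask[5:35, 45:75] = 2
        nmask = np.zeros_like(cmask)
        nmask[15:25, 15:25] = 1
        asg = pd.DataFrame({"nucleus_id": [1], "cell_id": [1]})
        with pytest.warns(UserWarning, match="no assigned nucleus"):
            cells, _ = compute_cell_metrics(cmask, nmask, asg)
        assert cells["cell_id"].tolist() == [1]


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"group": ["mono"] * 3 + ["multi"] * 3,
                           "x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = group_compare(df, "x")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        df = pd.DataFrame({"group": ["mono"] * 3 + ["multi"] * 3,
                           "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        res = group_compare(df, "x")
        # pooled t with df = 4: t = -3/sqrt(2/3) = -3.674, p = 0.0214
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0214, abs=1e-3)
        assert res.significant

    def test_small_group_errors(self):
        df = pd.DataFrame({"group": ["mono", "multi", "multi"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            group_compare(df, "x")

    def test_direction_recovered_from_generated_fields(self):
        """Multinucleated nuclei configured at half the mono nuclear area
        must come out significantly smaller."""
        common = dict(n_cells=50, cell_area_um2=(1500.0, 200.0),
                      cell_area_bounds_um2=(1000.0, 2000.0))
        _, cm1, nm1, _ = generate_cell_field(CellFieldSpec(
            frac_multinucleated=0.0, mono_ratio_pct=(6.0, 1.0), seed=21, **common))
        _, cm2, nm2, _ = generate_cell_field(CellFieldSpec(
            frac_multinucleated=1.0, per_nucleus_ratio_pct=(3.0, 0.5), seed=22,
            **common))
        parts = []
        for cm, nm in [(cm1, nm1), (cm2, nm2)]:
            recs = records_from_label_mask(nm)
            asg = assign_nuclei_to_cells(recs, cm)
            parts.append(compute_cell_metrics(cm, nm, asg)[1])
        nucs = pd.concat(parts, ignore_index=True)
        res = group_compare(nucs, "S_nucleus_um2")
        assert res.significant
        assert res.mean_b < res.mean_a  # multi nuclei smaller
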