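"""SMLM table operations and Voronoi density analysis."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import nucfate as nf
from nucfate.errors import FormatError, TessellationError, ValidationError
from nucfate.smlm import FWHM_FACTOR, shoelace_area

pytestmark = []


def loc_table(rows):
    """rows of (frame, x, y[, sigma[, intensity]])"""
    rows = [tuple(r) + (60.0, 1000.0)[len(r) - 3 :] for r in rows]
    return pd.DataFrame(
        rows, columns=["frame", "x_nm", "y_nm", "sigma_nm", "intensity_photons"]
    )


class TestLocalizationCSV:
    def test_roundtrip(self, tmp_path, stage1_merged):
        path = tmp_path / "locs.csv"
        table = stage1_merged[["frame", "x_nm", "y_nm", "sigma_nm", "intensity_photons"]]
        nf.write_localization_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert "x [nm]" in header and "intensity [photon]" in header
        back = nf.read_localization_csv(path)
        for col in table.columns:
            assert np.allclose(back[col], table[col])

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text('"frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]"\n')
        assert len(nf.read_localization_csv(p)) == 0

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text('"frame","x [nm]","y [nm]"\n1,2,3\n')
        with pytest.raises(FormatError, match="sigma_nm"):
            nf.read_localization_csv(p)

    def test_non_numeric_row_cited(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            '"frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]"\n'
            "1,10.0,20.0,60.0,900\n"
            "2,oops,21.0,61.0,901\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            nf.read_localization_csv(p)

    def test_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "extra.csv"
        p.write_text(
            '"frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]","uncertainty [nm]"\n'
            "1,10.0,20.0,60.0,900,9.5\n"
        )
        table = nf.read_localization_csv(p)
        assert "uncertainty [nm]" in table.columns


class TestFilterByFwhm:
    @pytest.mark.parametrize(
        "fwhm,kept", [(64.0, False), (65.0, True), (150.0, True), (225.0, True), (226.0, False)]
    )
    def test_boundaries(self, fwhm, kept):
        t = loc_table([(1, 0.0, 0.0, fwhm / FWHM_FACTOR)])
        assert len(nf.filter_by_fwhm(t)) == (1 if kept else 0)


class TestMergeBlinking:
    def test_consecutive_frames_within_20nm_merge(self):
        t = loc_table([(1, 0.0, 0.0), (2, 15.0, 0.0)])
        assert len(nf.merge_blinking(t)) == 1

    def test_single_off_frame_bridged(self):
        t = loc_table([(1, 0.0, 0.0), (3, 5.0, 0.0)])
        assert len(nf.merge_blinking(t)) == 1

    def test_two_off_frames_split(self):
        t = loc_table([(1, 0.0, 0.0), (4, 15.0, 0.0)])
        assert len(nf.merge_blinking(t)) == 2

    def test_beyond_distance_split(self):
        t = loc_table([(1, 0.0, 0.0), (2, 25.0, 0.0)])
        assert len(nf.merge_blinking(t)) == 2

    def test_unlimited_frames_per_molecule(self):
        t = loc_table([(f, float(f % 3), 0.0) for f in range(1, 51)])
        merged = nf.merge_blinking(t)
        assert len(merged) == 1
        assert merged["n_events"].iloc[0] == 50
        assert merged["frame"].iloc[0] == 1

    def test_merged_position_is_intensity_weighted(self):
        t = loc_table([(1, 0.0, 0.0, 60.0, 100.0), (2, 10.0, 0.0, 60.0, 300.0)])
        merged = nf.merge_blinking(t)
        assert merged["x_nm"].iloc[0] == pytest.approx(7.5)
        assert merged["intensity_photons"].iloc[0] == pytest.approx(400.0)

    def test_idempotent_on_unambiguous_chains(self):
        # molecules spaced far beyond the merge distance: chains are
        # unambiguous and a second merge pass changes nothing
        rng = np.random.default_rng(2)
        rows = []
        for m in range(60):
            x, y = 500.0 * (m % 8), 500.0 * (m // 8)
            f0 = int(rng.integers(1, 400))
            for j in range(int(rng.integers(1, 5))):
                rows.append((f0 + j, x + rng.normal(0, 3), y + rng.normal(0, 3)))
        t = loc_table(sorted(rows)).sort_values("frame", kind="stable").reset_index(drop=True)
        once = nf.merge_blinking(t)
        twice = nf.merge_blinking(once)
        assert len(once) == 60
        assert len(twice) == len(once)
        assert np.allclose(twice[["x_nm", "y_nm"]], once[["x_nm", "y_nm"]])

    def test_contracting(self, stage1_merged):
        # merging can only reduce the row count
        again = nf.merge_blinking(stage1_merged)
        assert len(again) <= len(stage1_merged)

    def test_recovers_molecule_count_approximately(self):
        table = nf.generate_localizations(nf.StageProfile.stage(1), 1000, seed=3)
        merged = nf.merge_blinking(table)
        truth = table["molecule_id"].nunique()
        assert abs(len(merged) - truth) / truth < 0.12


class TestCrop:
    def test_inside_unchanged_boundary_kept(self):
        t = loc_table([(1, 0.0, 0.0), (2, 100.0, 50.0), (3, -1.0, 0.0)])
        out = nf.crop_to_nucleus(t, (0.0, 100.0), (0.0, 50.0))
        assert len(out) == 2  # boundary points retained, outside dropped

    def test_matches_brute_force(self, stage1_merged):
        t = stage1_merged
        out = nf.crop_to_nucleus(t, (-2000, 2000), (-1500, 2500))
        expect = [
            i
            for i in range(len(t))
            if -2000 <= t["x_nm"].iloc[i] <= 2000 and -1500 <= t["y_nm"].iloc[i] <= 2500
        ]
        assert len(out) == len(expect)

    def test_infinite_range_rejected(self):
        with pytest.raises(ValidationError):
            nf.crop_to_nucleus(loc_table([(1, 0, 0)]), (0, np.inf), (0, 1))


class TestToPolar:
    def test_symmetric_points(self):
        t = loc_table([(1, 5.0, 0.0), (2, -5.0, 0.0), (3, 0.0, 5.0), (4, 0.0, -5.0)])
        polar = nf.to_polar(t)
        assert np.allclose(polar.r_nm, 5.0)
        assert polar.origin == (0.0, 0.0)

    def test_centroid_reconstruction(self, stage1_merged):
        polar = nf.to_polar(stage1_merged)
        x = polar.r_nm * np.cos(polar.theta)
        y = polar.r_nm * np.sin(polar.theta)
        assert abs(x.mean()) < 1e-9 and abs(y.mean()) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            nf.to_polar(loc_table([]))


class TestShoelace:
    def test_known_polygons(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert shoelace_area(square) == pytest.approx(1.0)
        tri = np.array([[0, 0], [4, 0], [0, 3]])
        assert shoelace_area(tri) == pytest.approx(6.0)

    @given(
        st.integers(3, 12),
        st.floats(0.1, 50.0),
        st.integers(0, 10_000),
    )
    def test_matches_fan_triangulation(self, k, scale, seed):
        """Shoelace area equals a triangle-fan decomposition on random
        convex polygons."""
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, k))
        if len(np.unique(angles)) < 3:
            return
        pts = scale * np.c_[np.cos(angles), np.sin(angles)] * rng.uniform(
            0.5, 1.0
        )
        fan = 0.0
        for i in range(1, len(pts) - 1):
            a, b, c = pts[0], pts[i], pts[i + 1]
            fan += 0.5 * abs(
                (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            )
        assert shoelace_area(pts) == pytest.approx(fan, rel=1e-9, abs=1e-12)


class TestVoronoiDensity:
    def test_five_point_hand_case(self):
        """Unit-square corners + center: the center cell is the square with
        vertices at the edge midpoints (perpendicular-bisector construction),
        area exactly 0.5, density 2."""
        t = loc_table(
            [(1, 0.0, 0.0), (1, 1.0, 0.0), (1, 0.0, 1.0), (1, 1.0, 1.0), (1, 0.5, 0.5)]
        )
        res = nf.voronoi_density(t)
        centre = res.table.iloc[4]
        assert not centre["boundary_excluded"]
        assert centre["cell_area_nm2"] == pytest.approx(0.5)
        assert centre["raw_density"] == pytest.approx(2.0)
        assert res.n_boundary_excluded == 4

    def test_regular_grid_interior_cells(self):
        s = 3.0
        xs, ys = np.meshgrid(np.arange(12), np.arange(12))
        t = pd.DataFrame(
            {
                "frame": 1,
                "x_nm": xs.ravel() * s,
                "y_nm": ys.ravel() * s,
                "sigma_nm": 60.0,
                "intensity_photons": 1.0,
            }
        )
        res = nf.voronoi_density(t)
        interior = (
            (t["x_nm"] > s) & (t["x_nm"] < 10 * s) & (t["y_nm"] > s) & (t["y_nm"] < 10 * s)
        )
        areas = res.table.loc[interior, "cell_area_nm2"]
        assert np.allclose(areas, s**2, rtol=1e-9)

    def test_areas_match_monte_carlo_oracle(self):
        """Bounded-cell shoelace areas agree with a nearest-generator
        Monte-Carlo integration within 0.5%."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1000, (200, 2))
        t = pd.DataFrame(
            {"frame": 1, "x_nm": pts[:, 0], "y_nm": pts[:, 1], "sigma_nm": 60.0,
             "intensity_photons": 1.0}
        )
        res = nf.voronoi_density(t)
        from scipy.spatial import Voronoi

        vor = Voronoi(pts)
        tree = cKDTree(pts)
        ok = ~res.table["boundary_excluded"].to_numpy()
        idx = np.flatnonzero(ok)[:20]
        for i in idx:
            area = res.table["cell_area_nm2"].iloc[i]
            poly = vor.vertices[vor.regions[vor.point_region[i]]]
            lo = poly.min(axis=0) - 1.0
            hi = poly.max(axis=0) + 1.0
            m = 400_000
            samples = np.c_[
                rng.uniform(lo[0], hi[0], m), rng.uniform(lo[1], hi[1], m)
            ]
            _, owner = tree.query(samples)
            box = (hi[0] - lo[0]) * (hi[1] - lo[1])
            mc = (owner == i).mean() * box
            assert mc == pytest.approx(area, rel=0.005)

    def test_boundedness_partition(self, stage1_merged):
        res = nf.voronoi_density(stage1_merged)
        t = res.table
        bounded = ~t["boundary_excluded"]
        assert (t.loc[bounded, "cell_area_nm2"] > 0).all()
        assert t.loc[~bounded, "cell_area_nm2"].isna().all()
        assert np.allclose(
            t.loc[bounded, "raw_density"] * t.loc[bounded, "cell_area_nm2"], 1.0
        )

    def test_core_cells_tile_their_box(self):
        """With a margin of surrounding points, the cells of generators in
        the core box tile approximately the box area."""
        rng = np.random.default_rng(7)
        L = 1000.0
        pts = rng.uniform(-0.3 * L, 1.3 * L, (900, 2))
        t = pd.DataFrame(
            {"frame": 1, "x_nm": pts[:, 0], "y_nm": pts[:, 1], "sigma_nm": 60.0,
             "intensity_photons": 1.0}
        )
        res = nf.voronoi_density(t)
        core = (
            (t["x_nm"] >= 0) & (t["x_nm"] <= L) & (t["y_nm"] >= 0) & (t["y_nm"] <= L)
        ) & ~res.table["boundary_excluded"]
        total = res.table.loc[core, "cell_area_nm2"].sum()
        assert 0.85 * L**2 < total < 1.15 * L**2

    def test_duplicates_jittered_with_warning(self):
        t = loc_table(
            [(1, 0.0, 0.0), (1, 0.0, 0.0), (1, 10.0, 0.0), (1, 0.0, 10.0), (1, 10.0, 10.0)]
        )
        with pytest.warns(UserWarning, match="duplicated"):
            res = nf.voronoi_density(t)
        assert res.n_loc == 5

    def test_collinear_rejected(self):
        t = loc_table([(1, float(i), 0.0) for i in range(5)])
        with pytest.raises(TessellationError):
            nf.voronoi_density(t)

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            nf.voronoi_density(loc_table([(1, 0, 0), (1, 1, 0), (1, 0, 1)]))


class TestNormalizeLog:
    def test_arithmetic_examples(self):
        t = loc_table([(1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1), (1, 0.5, 0.5)])
        res = nf.voronoi_density(t)
        res.n_loc = 10**5
        res.table.loc[4, "raw_density"] = 1e-3
        nf.normalize_log(res)
        assert res.table.loc[4, "log10_norm_density"] == pytest.approx(-8.0)

    def test_identity_case(self):
        t = loc_table([(1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1), (1, 0.5, 0.5)])
        res = nf.voronoi_density(t)
        res.n_loc = 1
        res.table.loc[4, "raw_density"] = 1.0
        nf.normalize_log(res)
        assert res.table.loc[4, "log10_norm_density"] == pytest.approx(0.0)


class TestHistograms:
    def test_pdf_area_is_one(self, stage1_merged):
        res = nf.normalize_log(nf.voronoi_density(stage1_merged))
        hists = nf.density_pdf({"s1": res.log10_norm_density})
        assert hists["s1"].area == pytest.approx(1.0, abs=1e-6)

    def test_single_bin_value(self):
        hists = nf.density_pdf({"g": np.full(50, -7.55)}, bins=50)
        h = hists["g"]
        width = np.diff(h.edges)[0]
        assert h.values.max() == pytest.approx(1.0 / width)
        assert h.area == pytest.approx(1.0, abs=1e-6)

    def test_same_distribution_similar_histograms(self):
        rng = np.random.default_rng(8)
        a = rng.normal(-7.5, 0.4, 40_000)
        b = rng.normal(-7.5, 0.4, 10_000)
        hists = nf.density_pdf({"a": a, "b": b})
        assert np.abs(hists["a"].values - hists["b"].values).max() < 0.1

    def test_empty_group_omitted(self):
        with pytest.warns(UserWarning, match="empty"):
            hists = nf.density_pdf({"g": np.array([])})
        assert hists == {}

    def test_2d_volume_and_clipping(self, stage1_merged):
        polar = nf.to_polar(stage1_merged)
        res = nf.normalize_log(nf.voronoi_density(stage1_merged))
        h = nf.radius_density_pdf(polar, res)
        assert h.volume == pytest.approx(1.0, abs=1e-6)
        assert h.color_clip == (1e-5, 1e-3)

    def test_2d_ring_mode_at_4000nm(self):
        rng = np.random.default_rng(9)
        n = 4000
        theta = rng.uniform(0, 2 * np.pi, n)
        r = rng.normal(4000, 60, n)
        pts = pd.DataFrame(
            {"frame": 1, "x_nm": r * np.cos(theta), "y_nm": r * np.sin(theta),
             "sigma_nm": 60.0, "intensity_photons": 1.0}
        )
        polar = nf.to_polar(pts)
        res = nf.normalize_log(nf.voronoi_density(pts))
        h = nf.radius_density_pdf(polar, res)
        marginal = h.values.sum(axis=1)
        mode_bin = int(np.argmax(marginal))
        centres = 0.5 * (h.r_edges[:-1] + h.r_edges[1:])
        assert abs(centres[mode_bin] - 4000) <= np.diff(h.r_edges)[0]

    def test_out_of_limit_values_conserved(self):
        vals = np.array([-12.0, -7.5, -3.0, -7.4])
        hists = nf.density_pdf({"g": vals}, bins=10)
        assert hists["g"].area == pytest.approx(1.0, abs=1e-6)


class TestSummarizeGroup:
    def test_examples_and_brute_force(self, stage1_merged):
        res = nf.normalize_log(nf.voronoi_density(stage1_merged))
        s = nf.summarize_group(res, group="stage1")
        vals = res.log10_norm_density
        assert s.mean_log10_norm_density == pytest.approx(vals.mean())
        assert s.sd_log10_norm_density == pytest.approx(vals.std(ddof=1))
        assert s.n_nuclei == 1 and s.group == "stage1"

    def test_two_values(self):
        res = nf.normalize_log(
            nf.voronoi_density(
                loc_table([(1, 0, 0), (1, 40, 0), (1, 0, 40), (1, 40, 40), (1, 20, 20)])
            )
        )
        res.table["log10_norm_density"] = [np.nan, np.nan, np.nan, np.nan, -7.5]
        s = nf.summarize_group(res)
        assert s.mean_log10_norm_density == pytest.approx(-7.5)
        assert s.sd_log10_norm_density == 0.0
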