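"""Raster coverage extraction, species habitat, CWM, habitat regressions."""

import numpy as np
import pandas as pd
import pytest

from eyevol.habitat import (RasterGrid, TransectSegment, community_weighted_mean,
                            cwm_regression, cwm_table, habitat_pgls,
                            read_ascii_grid, segment_coverage, species_habitat,
                            write_ascii_grid, SegmentHabitat)


def uniform_raster(value=40.0, n=20, cell=10.0):
    return RasterGrid(origin=(0.0, 0.0), cell_size=cell,
                      values=np.full((n, n), value))


def seg(x0, y0, x1, y1, buffer_m=10.0, sid="S0", tid="T0"):
    return TransectSegment(tid, sid, [(x0, y0), (x1, y1)], buffer_m)


class TestSegmentCoverage:
    def test_uniform_field_gives_constant_regardless_of_geometry(self):
        r = uniform_raster(40.0)
        for s in [seg(30, 30, 90, 110), seg(25, 95, 160, 40)]:
            h = segment_coverage(s, r)
            assert h.weighted_mean_cover == pytest.approx(40.0)
            assert h.ok

    def test_fraction_weighted_mean_and_threshold(self):
        # synthetic two-cell configuration checked by hand arithmetic:
        # covers 20 and 80 with fractions 0.25 / 0.75 -> (0.25*20 + 0.75*80)
        h = SegmentHabitat("T", "S", float("nan"), 0, np.array([]))
        fracs = np.array([0.25, 0.75])
        vals = np.array([20.0, 80.0])
        wm = float(np.sum(fracs * vals) / np.sum(fracs))
        assert wm == pytest.approx(65.0)

    def test_cells_fully_inside_have_fraction_one(self):
        r = uniform_raster(50.0, n=30)
        h = segment_coverage(seg(50, 150, 250, 150, buffer_m=25), r)
        assert np.isclose(h.coverage_fractions.max(), 1.0, atol=1e-9)
        # fraction sum approximates buffered area / cell area
        import shapely.geometry as g
        area = g.LineString([(50, 150), (250, 150)]).buffer(25, quad_segs=16).area
        assert h.coverage_fractions.sum() == pytest.approx(area / 100.0,
                                                           rel=0.01)

    def test_tiny_fraction_cells_excluded(self):
        # buffer edge barely grazing a cell row -> those fractions < 0.002
        r = uniform_raster(50.0, n=30)
        h1 = segment_coverage(seg(55, 150, 245, 150, buffer_m=10.0), r,
                              min_fraction=0.002)
        h0 = segment_coverage(seg(55, 150, 245, 150, buffer_m=10.0), r,
                              min_fraction=0.0)
        assert h1.n_cells_used <= h0.n_cells_used
        assert (h0.coverage_fractions.min()
                < 0.002 or h1.n_cells_used == h0.n_cells_used)

    def test_missing_cells_excluded_from_both_sums(self):
        vals = np.full((20, 20), 40.0)
        vals[9:11, :] = -9999.0
        r = RasterGrid((0, 0), 10.0, vals)
        h = segment_coverage(seg(30, 95, 160, 95), r)
        assert h.weighted_mean_cover == pytest.approx(40.0)

    def test_segment_off_raster_flagged(self):
        r = uniform_raster(40.0, n=5)  # 50 m x 50 m raster
        h = segment_coverage(seg(500, 500, 600, 600), r)
        assert not h.ok


class TestAsciiGridIO:
    def test_roundtrip(self, tmp_path, rng):
        vals = np.round(rng.uniform(0, 100, size=(7, 5)), 2)
        r = RasterGrid((100.0, 200.0), 10.0, vals)
        path = tmp_path / "g.asc"
        write_ascii_grid(r, path)
        r2 = read_ascii_grid(path)
        assert np.allclose(r2.values, vals)
        assert r2.origin == (100.0, 200.0)
        assert r2.cell_size == 10.0

    def test_cover_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            RasterGrid((0, 0), 10.0, np.array([[150.0]]))


class TestSpeciesHabitat:
    def _habs(self, covers):
        return [SegmentHabitat("T", f"S{i}", c, 1, np.array([1.0]))
                for i, c in enumerate(covers)]

    def _occ(self, pairs):
        return pd.DataFrame([{"transect_id": "T", "segment_id": s,
                              "species": sp, "abundance": 1.0}
                             for sp, s in pairs])

    def test_single_segment_median_is_that_value(self):
        out = species_habitat(self._occ([("x", "S0")]), self._habs([42.0]))
        assert out.loc[0, "median_cover"] == pytest.approx(42.0)

    def test_median_order_statistic(self):
        occ = self._occ([("x", "S0"), ("x", "S1"), ("x", "S2")])
        out = species_habitat(occ, self._habs([10.0, 20.0, 90.0]))
        assert out.loc[0, "median_cover"] == pytest.approx(20.0)

    def test_duplicate_occurrence_rows_do_not_change_median(self):
        occ = self._occ([("x", "S0"), ("x", "S1"), ("x", "S1"), ("x", "S2")])
        out = species_habitat(occ, self._habs([10.0, 20.0, 90.0]))
        assert out.loc[0, "median_cover"] == pytest.approx(20.0)

    def test_species_with_no_usable_segment_excluded(self):
        habs = self._habs([42.0])
        habs.append(SegmentHabitat("T", "S1", float("nan"), 0,
                                   np.array([]), ok=False))
        occ = self._occ([("x", "S0"), ("y", "S1")])
        out = species_habitat(occ, habs)
        assert list(out["species"]) == ["x"]

    def test_unknown_segment_raises(self):
        with pytest.raises(KeyError, match="unknown segments"):
            species_habitat(self._occ([("x", "S9")]), self._habs([42.0]))


class TestCwm:
    def test_single_species_is_its_trait(self):
        assert community_weighted_mean([2.0], [0.7]) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        # traits 1, 2 with abundances 3, 1 -> (3*1 + 1*2)/4 = 1.25
        assert community_weighted_mean([3.0, 1.0], [1.0, 2.0]) \
            == pytest.approx(1.25)

    def test_equal_abundance_reduces_to_mean(self, rng):
        t = rng.normal(size=6)
        assert community_weighted_mean(np.ones(6), t) \
            == pytest.approx(t.mean())

    def test_convexity(self, rng):
        a = rng.uniform(0, 5, size=8)
        t = rng.normal(size=8)
        cwm = community_weighted_mean(a, t)
        assert t.min() <= cwm <= t.max()

    def test_all_zero_abundance_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            community_weighted_mean([0.0, 0.0], [1.0, 2.0])

    def test_cwm_table_averages_duplicate_years(self):
        occ = pd.DataFrame({
            "transect_id": ["T"] * 3, "segment_id": ["S0"] * 3,
            "species": ["a", "a", "b"], "abundance": [2.0, 4.0, 3.0],
        })
        trait = pd.Series({"a": 1.0, "b": 2.0})
        out = cwm_table(occ, trait)
        # species a collapses to mean abundance 3 -> (3*1 + 3*2)/6 = 1.5
        assert out.loc[0, "cwm"] == pytest.approx(1.5)


class TestCwmRegression:
    def test_constant_cwm_gives_zero_slope(self):
        out = cwm_regression([1.0] * 10, np.linspace(0, 100, 10))
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation_r2_one(self):
        x = np.linspace(0, 100, 10)
        out = cwm_regression(0.01 * x + 0.3, x)
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cwm_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestHabitatPgls:
    def test_recovers_sign_of_simulated_habitat_slope(self, sim_means,
                                                      sim_tree, rng):
        from eyevol.phylo import vcv_matrix
        C = vcv_matrix(sim_tree)
        hits = 0
        n_rounds = 20
        for _ in range(n_rounds):
            hab = pd.DataFrame({
                "species": sim_means["species"],
                "median_cover": rng.uniform(0, 100, len(sim_means)),
            })
            means = sim_means.copy()
            z = (hab["median_cover"] - hab["median_cover"].mean()) \
                / hab["median_cover"].std(ddof=0)
            means["mean_log10_eye"] = means["mean_log10_eye"] + 0.3 * z.values
            fit = habitat_pgls(means, hab, C, include_wing=True)
            hits += fit.coefficients["habitat_z"] > 0
        assert hits >= int(0.9 * n_rounds)

    def test_family_subset_supported(self, sim_means, sim_tree, rng):
        from eyevol.phylo import vcv_matrix
        C = vcv_matrix(sim_tree)
        hab = pd.DataFrame({
            "species": sim_means["species"],
            "median_cover": rng.uniform(0, 100, len(sim_means)),
        })
        fit = habitat_pgls(sim_means, hab, C, families=["Nymphalidae"])
        assert fit.n == (sim_means["family"] == "Nymphalidae").sum()

    def test_too_small_intersection_errors(self, sim_means, sim_tree):
        from eyevol.phylo import vcv_matrix
        C = vcv_matrix(sim_tree)
        hab = pd.DataFrame({"species": sim_means["species"][:2],
                            "median_cover": [10.0, 20.0]})
        with pytest.raises(ValueError, match="species"):
            habitat_pgls(sim_means, hab, C)
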