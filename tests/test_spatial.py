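"""DDF with border correction, 2D projection and relative density maps."""

import numpy as np
import pytest

from gcckit import polymer, spatial
from gcckit.coloc import LocusSet
from gcckit.core import GenomicInterval
from gcckit.polymer import ModelSpec, build_chains
from gcckit.spatial import (MapGrid, compute_ddf, ddf_area_statistic,
                            ddf_from_points, density_map, dempf_value,
                            map_loci_to_granules, project_2d,
                            relative_density, sphere_intersection_volume)


def uniform_sphere(rng, n, radius):
    u = rng.random(n) ** (1 / 3)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return radius * u[:, None] * v


@pytest.fixture(scope="module")
def g1_spec():
    return ModelSpec.for_phase("G1")


class TestGranuleMapping:
    def test_locus_spanning_two_granules(self, genome):
        spec = ModelSpec(bp_per_granule=10_000)
        gm = build_chains(genome, spec)
        lset = LocusSet("x", [GenomicInterval("chrI", 9_000, 11_000, "l")])
        got = map_loci_to_granules(lset, gm)
        assert got.tolist() == [0, 1]

    def test_empty_set(self, genome):
        gm = build_chains(genome, ModelSpec(bp_per_granule=10_000))
        assert len(map_loci_to_granules(LocusSet("e", []), gm)) == 0

    def test_matches_brute_force(self, genome, annotations):
        gm = build_chains(genome, ModelSpec(bp_per_granule=10_000))
        got = set(map_loci_to_granules(annotations["LTR"], gm).tolist())
        brute = set()
        for iv in annotations["LTR"].loci:
            for g in range(len(gm)):
                if (gm.chrom[g] == iv.chrom and gm.start[g] < iv.end
                        and iv.start < gm.end[g]):
                    brute.add(g)
        assert got == brute


class TestShellVolumes:
    def test_interior_shell_closed_form(self):
        # shell fully inside the nucleus: plain shell volume
        R, dR, a = 100.0, 30.0, 200.0
        vol = (sphere_intersection_volume(R + dR, a, 1000.0)
               - sphere_intersection_volume(R, a, 1000.0))
        expected = 4 / 3 * np.pi * ((R + dR) ** 3 - R ** 3)
        assert vol == pytest.approx(expected, rel=1e-12)

    def test_enclosing_ball_caps_at_nucleus(self):
        assert sphere_intersection_volume(5000.0, 100.0, 1000.0) == \
               pytest.approx(4 / 3 * np.pi * 1000.0 ** 3)

    def test_disjoint_is_zero(self):
        assert sphere_intersection_volume(10.0, 2000.0, 1000.0) == 0.0

    def test_monte_carlo_cross_check(self):
        # lens volume against rejection sampling for a straddling ball
        rng = np.random.default_rng(0)
        r_ball, a, rn = 600.0, 800.0, 1000.0
        pts = uniform_sphere(rng, 200_000, rn)
        frac = (np.linalg.norm(pts - [0, 0, a], axis=1) < r_ball).mean()
        mc = frac * 4 / 3 * np.pi * rn ** 3
        assert sphere_intersection_volume(r_ball, a, rn) == \
               pytest.approx(mc, rel=0.02)


class TestDdf:
    def test_two_points_single_shell(self):
        pts = np.array([[0, 0, -50.0], [0, 0, 250.0]])
        curve = ddf_from_points(pts, 1000.0, 100.0)
        occupied = np.nonzero(np.nan_to_num(curve.values) > 0)[0]
        assert occupied.tolist() == [3]  # distance 300 -> shell [300, 400)

    def test_uniform_points_flat(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = uniform_sphere(rng, 400, 1000.0)
            vals.append(ddf_from_points(pts, 1000.0, 50.0).values)
        mean = np.nanmean(np.array(vals), axis=0)
        edges = np.arange(0.0, 2050.0, 50.0)
        sel = (edges[:-1] >= 50) & (edges[:-1] < 1000)
        assert np.nanmax(np.abs(mean[sel] - 1)) < 0.1

    def test_border_correction_removes_large_r_bias(self):
        rng = np.random.default_rng(3)
        pts = uniform_sphere(rng, 800, 1000.0)
        corrected = ddf_from_points(pts, 1000.0, 100.0)
        raw = ddf_from_points(pts, 1000.0, 100.0, border_correction=False)
        sel = slice(8, 12)  # shells at 800-1200, heavily border-affected
        assert np.nanmean(raw.values[sel]) < 0.7
        assert abs(np.nanmean(corrected.values[sel]) - 1) < 0.15

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ddf_from_points(np.zeros((1, 3)), 100.0, 10.0)

    def test_structure_interface(self, genome, annotations):
        spec = ModelSpec.for_genome(genome, "G1", bp_per_granule=10_000,
                                    sweeps=0)
        gm = build_chains(genome, spec)
        st = polymer.run_mc(spec, "confined", gm, seed=0)
        subset = map_loci_to_granules(annotations["LTR"], gm)
        curve = compute_ddf(st, subset, spec)
        assert curve.n_elements == len(subset)
        assert curve.edges[1] - curve.edges[0] == spec.granule_diameter


class TestDdfAreaStatistic:
    @staticmethod
    def _flat_curve(edges, value):
        return spatial.DDFCurve(edges, np.full(len(edges) - 1, value), 10,
                                1.0)

    def test_identity_ensembles(self):
        edges = np.arange(0.0, 500.0, 50.0)
        a = [self._flat_curve(edges, 1.2) for _ in range(5)]
        b = [self._flat_curve(edges, 1.2) for _ in range(5)]
        _, _, t, p = ddf_area_statistic(a, b, 100.0)
        assert np.isnan(t) or abs(t) < 1e-9  # zero variance, zero difference

    def test_uniform_curve_zero_area(self):
        edges = np.arange(0.0, 500.0, 50.0)
        assert self._flat_curve(edges, 1.0).area_vs_one(0.0) == 0.0

    def test_signed_area_from_start_distance(self):
        edges = np.arange(0.0, 300.0, 100.0)
        c = self._flat_curve(edges, 1.5)
        assert c.area_vs_one(100.0) == pytest.approx(0.5 * 100.0)

    def test_separated_ensembles_significant(self):
        rng = np.random.default_rng(5)
        edges = np.arange(0.0, 500.0, 50.0)
        a = [self._flat_curve(edges, 1.5 + 0.05 * rng.normal())
             for _ in range(20)]
        b = [self._flat_curve(edges, 1.0 + 0.05 * rng.normal())
             for _ in range(20)]
        _, _, _, p = ddf_area_statistic(a, b, 100.0)
        assert p < 0.001

    def test_mismatched_shells_rejected(self):
        a = [self._flat_curve(np.arange(0.0, 500.0, 50.0), 1.0)] * 2
        b = [self._flat_curve(np.arange(0.0, 500.0, 25.0), 1.0)] * 2
        with pytest.raises(ValueError):
            ddf_area_statistic(a, b, 100.0)


class TestProjection:
    def test_spb_projects_to_negative_pole(self, g1_spec):
        zr = project_2d(g1_spec.spb[None, :], g1_spec)
        assert zr[0, 0] == pytest.approx(-g1_spec.nuclear_radius)
        assert zr[0, 1] == pytest.approx(0.0)

    def test_axis_midpoint_zero_radius(self, g1_spec):
        zr = project_2d(np.array([[0.0, 0.0, 123.0]]), g1_spec)
        assert zr[0, 0] == pytest.approx(123.0)
        assert zr[0, 1] == pytest.approx(0.0)

    def test_pythagoras(self, g1_spec):
        rng = np.random.default_rng(2)
        pts = uniform_sphere(rng, 100, g1_spec.nuclear_radius)
        zr = project_2d(pts, g1_spec)
        assert np.allclose(zr[:, 0] ** 2 + zr[:, 1] ** 2,
                           (pts ** 2).sum(axis=1))


class TestDensityMap:
    def test_grid_defaults_match_phase_geometry(self):
        g1 = MapGrid.for_phase("G1")
        g2 = MapGrid.for_phase("G2")
        assert (g1.n_z, g1.n_r, g1.delta, g1.sigma) == (266, 266, 10.0, 15.0)
        assert (g2.n_z, g2.n_r, g2.delta, g2.sigma) == (342, 342, 10.0, 45.0)
        spec = ModelSpec.for_phase("G1")
        assert MapGrid.for_spec(spec) == g1

    def test_single_granule_peak(self):
        grid = MapGrid(40, 40, 10.0, 15.0)
        # place the granule exactly on a pixel coordinate
        z, r = grid.z_coords[20], grid.r_coords[10]
        m = density_map([np.array([[z, r]])], np.array([0]), grid)
        assert m.frequency[20, 10] == pytest.approx(1 / (2 * np.pi * 15.0 ** 2))
        assert m.frequency.max() == m.frequency[20, 10]

    def test_gaussian_mass_conserved(self):
        grid = MapGrid(60, 60, 10.0, 15.0)
        rng = np.random.default_rng(1)
        zr = np.column_stack([rng.uniform(-100, 100, 5),
                              rng.uniform(100, 200, 5)])
        m = density_map([zr], np.arange(5), grid, exponent="gaussian")
        assert m.frequency.sum() * grid.delta ** 2 == pytest.approx(5.0,
                                                                    rel=0.01)

    def test_printed_exponent_mass(self):
        # with the printed 2*sigma exponent each granule integrates to
        # 1/sigma instead of 1
        grid = MapGrid(60, 60, 2.0, 15.0)
        zr = np.array([[0.0, 60.0]])
        m = density_map([zr], np.arange(1), grid, exponent="printed")
        assert m.frequency.sum() * grid.delta ** 2 == pytest.approx(
            1 / 15.0, rel=0.02)

    def test_identical_structures_mean_invariant(self):
        grid = MapGrid(30, 30, 10.0, 15.0)
        zr = np.array([[10.0, 50.0], [-40.0, 80.0]])
        one = density_map([zr], np.arange(2), grid)
        two = density_map([zr, zr], np.arange(2), grid)
        assert np.allclose(one.frequency, two.frequency)

    def test_rotation_invariance(self, g1_spec):
        rng = np.random.default_rng(4)
        pts = uniform_sphere(rng, 50, 0.8 * g1_spec.nuclear_radius)
        grid = MapGrid(40, 40, 70.0, 15.0)
        base = density_map([project_2d(pts, g1_spec)], np.arange(50), grid)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = density_map([project_2d(pts @ rot.T, g1_spec)],
                              np.arange(50), grid)
        assert np.allclose(base.frequency, rotated.frequency)


class TestRelativeDensity:
    def test_dempf_is_peripheral_single_granule_peak(self):
        grid = MapGrid(40, 40, 10.0, 15.0)
        d = dempf_value(grid)
        assert d > 0

    def test_element_equals_total_below_one(self):
        grid = MapGrid(30, 30, 10.0, 15.0)
        rng = np.random.default_rng(6)
        zr = np.column_stack([rng.uniform(-100, 100, 20),
                              rng.uniform(0, 140, 20)])
        total = density_map([zr], np.arange(20), grid)
        rel = relative_density(total, total)
        inside = total.density > 0
        assert (rel.relative[inside] < 1).all()

    def test_empty_pixels_zero(self):
        grid = MapGrid(30, 30, 10.0, 15.0)
        zr = np.array([[0.0, 50.0]])
        element = density_map([zr], np.arange(1), grid)
        total = density_map([zr], np.arange(1), grid)
        rel = relative_density(element, total)
        corner = rel.relative[0, -1]
        assert corner == pytest.approx(0.0, abs=1e-12)

    def test_uniform_subset_flat_ratio(self):
        # a random half of a uniform point set has relative density about
        # (subset fraction) x total/(total+dempf) on interior pixels
        rng = np.random.default_rng(7)
        spec = ModelSpec(nuclear_radius=300.0)
        grid = MapGrid(60, 60, 10.0, 15.0)
        zr_all = [project_2d(uniform_sphere(rng, 400, 280.0), spec)
                  for _ in range(20)]
        zr_half = [zr[:200] for zr in zr_all]
        total = density_map(zr_all, None, grid)
        element = density_map(zr_half, None, grid)
        rel = relative_density(element, total)
        interior = (np.abs(grid.z_coords)[:, None] < 150) & \
                   (grid.r_coords[None, :] > 30) & \
                   (grid.r_coords[None, :] < 150)
        vals = rel.relative[interior]
        assert abs(np.median(vals) - 0.5 * np.median(
            total.density[interior] / (total.density[interior] + rel.dempf))) \
            < 0.1

    def test_grid_mismatch_rejected(self):
        a = density_map([np.array([[0.0, 10.0]])], None,
                        MapGrid(20, 20, 10.0, 15.0))
        b = density_map([np.array([[0.0, 10.0]])], None,
                        MapGrid(30, 30, 10.0, 15.0))
        with pytest.raises(ValueError):
            relative_density(a, b)
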