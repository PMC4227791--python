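"""Spatial statistics over nuclear structure ensembles.

Two complementary summaries of where a set of granules sits in the
nucleus:

* the density distribution function (DDF) — for each distance shell
  (R, R+dR) the pair density of the granule set divided by its overall
  density N/V.  Uniformly arranged points give DDF = 1; clustering gives
  values above 1.  Shell volumes are corrected analytically where the
  shell spills over the nuclear border (sphere-sphere lens volumes), which
  removes the downward bias a raw pair-density ratio shows at large R.

* rotationally symmetric 2D density maps — because the tethering
  restraints and interactions are invariant to rotation about the
  SPB-nucleolus axis, structures project onto the (z, r) half-plane
  without loss.  Granules are spread with a Gaussian kernel onto a pixel
  grid (Frequency), divided by the cylindrical-ring volume of each pixel
  (Density), and normalized by the whole-genome density plus a small
  regularizer Dempf (Relative Density) so compaction effects cancel.

Note on the kernel: the frequency formula used here keeps the prefactor
1/(2*pi*sigma^2) but divides the exponent by 2*sigma rather than the
Gaussian 2*sigma^2; this follows the printed definition the package
reproduces.  ``exponent="gaussian"`` switches to the standard form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .coloc import LocusSet
from .polymer import Ensemble, GranuleMap, ModelSpec, Structure

logger = logging.getLogger("gcckit")


@dataclass
class DDFCurve:
    """Border-corrected density distribution function on contiguous shells."""

    edges: np.ndarray            # len k+1; shell s spans [edges[s], edges[s+1])
    values: np.ndarray           # len k; NaN where no shell volume is available
    n_elements: int
    nuclear_volume: float

    @property
    def shell_starts(self) -> np.ndarray:
        return self.edges[:-1]

    def area_vs_one(self, start_distance: float, signed: bool = True) -> float:
        """Area between the curve and the uniform level 1 beyond a distance.

        Signed by default (clustering pushes the area positive); set
        ``signed=False`` for the absolute area.
        """
        dr = np.diff(self.edges)
        mask = (self.edges[:-1] >= start_distance) & np.isfinite(self.values)
        dev = self.values[mask] - 1.0
        if not signed:
            dev = np.abs(dev)
        return float((dev * dr[mask]).sum())


@dataclass
class MapGrid:
    """Pixel grid of a rotationally symmetric (z, r) density map."""

    n_z: int
    n_r: int
    delta: float                 # pixel size, nm (same in z and r)
    sigma: float                 # kernel width parameter (granule radius, nm)

    @property
    def nuclear_radius(self) -> float:
        return self.n_z * self.delta / 2

    @property
    def z_coords(self) -> np.ndarray:
        return -self.nuclear_radius + np.arange(self.n_z) * self.delta

    @property
    def r_coords(self) -> np.ndarray:
        return np.arange(self.n_r) * self.delta

    @classmethod
    def for_phase(cls, phase: str) -> "MapGrid":
        if phase == "G1":
            return cls(266, 266, 10.0, 15.0)
        if phase == "G2":
            return cls(342, 342, 10.0, 45.0)
        raise ValueError("maps are defined for phases G1 and G2")

    @classmethod
    def for_spec(cls, spec: "ModelSpec", delta: float = 10.0) -> "MapGrid":
        """Square grid spanning the nuclear diameter of a model spec.

        Reproduces the phase defaults for the full-scale geometry (266 px
        for a 1330 nm G1 nucleus, 342 px for a 1710 nm G2 nucleus) and
        scales with the nucleus for reduced model systems; sigma is the
        granule radius.
        """
        n = int(round(2 * spec.nuclear_radius / delta))
        return cls(n, n, delta, spec.granule_radius)


@dataclass
class DensityMap:
    """Frequency / Density (and optionally Relative Density) over a grid."""

    grid: MapGrid
    frequency: np.ndarray        # shape (n_z, n_r)
    density: np.ndarray
    n_structures: int
    relative: np.ndarray | None = None
    dempf: float | None = None


# ---------------------------------------------------------------------------
# Granule selection
# ---------------------------------------------------------------------------

def map_loci_to_granules(locus_set: LocusSet,
                         granules: GranuleMap) -> np.ndarray:
    """Indices of granules whose bp window overlaps >= 1 bp of any locus."""
    selected: set[int] = set()
    for iv in locus_set.loci:
        if iv.chrom not in granules.chain_start:
            continue
        end = min(iv.end, granules.genome.lengths[iv.chrom])
        selected.update(int(g) for g in
                        granules.granules_overlapping(iv.chrom, iv.start, end))
    return np.array(sorted(selected), dtype=np.int64)


def random_control_subset(granules: GranuleMap, size: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random granule subset of a given size (the interactions control)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return np.sort(rng.choice(len(granules), size=size, replace=False))


# ---------------------------------------------------------------------------
# Density distribution function
# ---------------------------------------------------------------------------

def sphere_intersection_volume(r_ball: np.ndarray, a: np.ndarray,
                               r_nucleus: float) -> np.ndarray:
    """Volume of a ball of radius ``r_ball`` centered at distance ``a``
    from the nuclear center, intersected with the nuclear ball.

    Standard sphere-sphere lens geometry, fully vectorized; exact for every
    configuration (ball inside, straddling, or enclosing the nucleus).
    """
    r_ball, a = np.broadcast_arrays(np.asarray(r_ball, float),
                                    np.asarray(a, float))
    rn = float(r_nucleus)
    out = np.zeros(r_ball.shape)
    full_ball = a + r_ball <= rn
    out[full_ball] = 4.0 / 3.0 * np.pi * r_ball[full_ball] ** 3
    full_nucleus = a + rn <= r_ball
    out[full_nucleus] = 4.0 / 3.0 * np.pi * rn ** 3
    lens = ~(full_ball | full_nucleus) & (a < r_ball + rn) & (r_ball > 0)
    if lens.any():
        r1, aa = r_ball[lens], a[lens]
        out[lens] = (np.pi * (r1 + rn - aa) ** 2
                     * (aa ** 2 + 2 * aa * rn - 3 * rn ** 2
                        + 2 * aa * r1 + 6 * rn * r1 - 3 * r1 ** 2)
                     / (12 * aa))
    return out


def ddf_from_points(points: np.ndarray, r_nucleus: float, dR: float,
                    r_max: float | None = None,
                    border_correction: bool = True) -> DDFCurve:
    """DDF of a point set inside a sphere centered at the origin.

    For every ordered pair the companion point contributes to the shell
    containing their distance; each center's shell volume is the analytic
    intersection of the spherical shell with the nucleus (the border
    correction), or the raw shell volume when the correction is disabled.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n < 2:
        raise ValueError("DDF undefined for fewer than two elements")
    if dR <= 0:
        raise ValueError("dR must be positive")
    r_max = 2 * r_nucleus if r_max is None else r_max
    edges = np.arange(0.0, r_max + dR, dR)
    k = len(edges) - 1

    d = pdist(points)
    counts, _ = np.histogram(d, bins=edges)
    counts = counts * 2.0  # ordered pairs: each center counts its companions

    a = np.linalg.norm(points, axis=1)
    if border_correction:
        vol_edges = sphere_intersection_volume(
            edges[None, :], a[:, None], r_nucleus)  # (n, k+1)
        shell_vol = np.diff(vol_edges, axis=1).sum(axis=0)
    else:
        shell_vol = n * 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    V = 4.0 / 3.0 * np.pi * r_nucleus ** 3
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (counts / shell_vol) / (n / V)
    values[shell_vol <= 0] = np.nan
    return DDFCurve(edges, values, n, V)


def compute_ddf(structure: Structure, subset: np.ndarray, spec: ModelSpec,
                dR: float | None = None,
                border_correction: bool = True) -> DDFCurve:
    """DDF of a granule subset of one structure.

    Shell width defaults to one granule diameter, matching the resolution
    of the model; curves run out to the nuclear diameter.
    """
    subset = np.asarray(subset)
    if len(subset) < 2:
        raise ValueError("DDF undefined for a subset of fewer than 2 granules")
    dR = spec.granule_diameter if dR is None else dR
    return ddf_from_points(structure.coords[subset], spec.nuclear_radius, dR,
                           border_correction=border_correction)


def ensemble_ddfs(ensemble: Ensemble, subset: np.ndarray,
                  dR: float | None = None) -> list[DDFCurve]:
    return [compute_ddf(s, subset, ensemble.spec, dR)
            for s in ensemble.structures]


def ddf_area_statistic(ddfs_a: Sequence[DDFCurve], ddfs_b: Sequence[DDFCurve],
                       start_distance: float, signed: bool = True
                       ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-structure DDF areas of two ensembles and their unpaired t-test.

    The area between each curve and the uniform level 1 is accumulated from
    ``start_distance`` outward (three granule diameters excludes short-range
    linear clustering along the chain); a two-tailed unpaired t-test
    compares the two area samples.
    """
    if len(ddfs_a) < 2 or len(ddfs_b) < 2:
        raise ValueError("need at least two structures per ensemble")
    ref = ddfs_a[0].edges
    for c in list(ddfs_a) + list(ddfs_b):
        if len(c.edges) != len(ref) or not np.allclose(c.edges, ref):
            raise ValueError("DDF curves must share identical shells")
    areas_a = np.array([c.area_vs_one(start_distance, signed) for c in ddfs_a])
    areas_b = np.array([c.area_vs_one(start_distance, signed) for c in ddfs_b])
    t, p = stats.ttest_ind(areas_a, areas_b)
    return areas_a, areas_b, float(t), float(p)


# ---------------------------------------------------------------------------
# 2D projection and density maps
# ---------------------------------------------------------------------------

def project_2d(points: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Project points onto the (z, r) half-plane of the SPB-nucleolus axis.

    z is the scalar projection onto the unit axis running from the SPB
    (negative pole) to the nucleolus (positive pole), origin at the nuclear
    center; r is the nonnegative distance to the axis.
    """
    axis = spec.nucleolus_center - spec.spb
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate SPB-nucleolus axis")
    axis = axis / norm
    center = (spec.nucleolus_center + spec.spb) / 2
    rel = np.atleast_2d(points) - center
    z = rel @ axis
    r = np.linalg.norm(rel - np.outer(z, axis), axis=1)
    return np.column_stack([z, r])


def density_map(ensemble: Ensemble | Sequence[np.ndarray], subset: np.ndarray,
                grid: MapGrid, spec: ModelSpec | None = None,
                exponent: str = "printed",
                truncation_sigmas: float = 4.0) -> DensityMap:
    """Gaussian-kernel (z, r) density of a granule subset over an ensemble.

    ``ensemble`` is either an :class:`Ensemble` (granule positions are
    projected first) or a sequence of per-structure ``(m, 2)`` arrays of
    already-projected (z, r) coordinates.  Frequency at a pixel is the
    kernel sum over subset granules averaged over structures; Density
    divides by the volume of the cylindrical ring the pixel represents.
    The kernel is truncated beyond ``truncation_sigmas * sigma``; the
    truncated mass is negligible for both exponent conventions.
    """
    if exponent not in ("printed", "gaussian"):
        raise ValueError("exponent must be 'printed' or 'gaussian'")
    if isinstance(ensemble, Ensemble):
        if spec is None:
            spec = ensemble.spec
        zr_list = [project_2d(s.coords[subset], spec)
                   for s in ensemble.structures]
    else:
        zr_list = [np.atleast_2d(zr) for zr in ensemble]
        if any(len(z) == 0 for z in zr_list):
            raise ValueError("empty granule subset")
    n_structures = len(zr_list)
    sigma = grid.sigma
    denom = 2 * sigma if exponent == "printed" else 2 * sigma ** 2
    prefactor = 1.0 / (2 * np.pi * sigma ** 2)
    zc, rc = grid.z_coords, grid.r_coords
    freq = np.zeros((grid.n_z, grid.n_r))
    trunc = truncation_sigmas * sigma

    for zr in zr_list:
        for zg, rg in zr:
            zi_lo = int(np.searchsorted(zc, zg - trunc, side="left"))
            zi_hi = int(np.searchsorted(zc, zg + trunc, side="right"))
            ri_lo = int(np.searchsorted(rc, rg - trunc, side="left"))
            ri_hi = int(np.searchsorted(rc, rg + trunc, side="right"))
            if zi_lo >= zi_hi or ri_lo >= ri_hi:
                continue
            dz2 = (zc[zi_lo:zi_hi, None] - zg) ** 2
            dr2 = (rc[None, ri_lo:ri_hi] - rg) ** 2
            freq[zi_lo:zi_hi, ri_lo:ri_hi] += prefactor * np.exp(
                -(dz2 + dr2) / denom)
    freq /= n_structures

    ring = np.pi * grid.delta * ((rc + grid.delta) ** 2 - rc ** 2)
    density = freq / ring[None, :]
    return DensityMap(grid, freq, density, n_structures)


def dempf_value(grid: MapGrid, exponent: str = "printed") -> float:
    """Density of one granule placed at the nuclear periphery (z=0, r=R).

    This is the small additive regularizer that stabilizes relative
    densities in the low-density zone near the envelope.
    """
    zr = [np.array([[0.0, grid.nuclear_radius]])]
    single = density_map(zr, np.array([0]), grid, exponent=exponent)
    return float(single.density.max())


def relative_density(element_map: DensityMap, total_map: DensityMap,
                     dempf: float | None = None,
                     exponent: str = "printed") -> DensityMap:
    """Element density normalized by total chromatin density plus Dempf.

    Pixels where both densities vanish get a relative density of zero.
    """
    if (element_map.grid != total_map.grid):
        raise ValueError("grid mismatch between element and total maps")
    if dempf is None:
        dempf = dempf_value(element_map.grid, exponent)
    rel = element_map.density / (total_map.density + dempf)
    return DensityMap(element_map.grid, element_map.frequency,
                      element_map.density, element_map.n_structures,
                      relative=rel, dempf=dempf)


# ---------------------------------------------------------------------------
# Text output
# ---------------------------------------------------------------------------

def write_ddf_tsv(curve: DDFCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("R\tR_plus_dR\tDDF\n")
        for s, e, v in zip(curve.edges[:-1], curve.edges[1:], curve.values):
            fh.write(f"{s:.3f}\t{e:.3f}\t{v:.6f}\n")


def write_map_tsv(dmap: DensityMap, path, which: str = "density") -> None:
    arr = {"frequency": dmap.frequency, "density": dmap.density,
           "relative": dmap.relative}[which]
    if arr is None:
        raise ValueError(f"map has no {which} layer")
    np.savetxt(path, arr, delimiter="\t")
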