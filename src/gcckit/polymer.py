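"""Coarse-grained Monte Carlo models of chromosomes in a spherical nucleus.

Chromosomes are chains of spherical granules (one granule per fixed bp
window) confined to a nucleus of radius R and excluded from a nucleolar
sphere sitting at the envelope pole opposite the spindle pole body (SPB).
Three nested model regimes are simulated with a Metropolis scheme at kT=1:

* confined      — excluded volume, chain connectivity, nuclear confinement
                  and nucleolar exclusion only;
* constrained   — adds biological tethers: centromeres to the SPB,
                  telomeres of the two long chromosomes to the nuclear
                  envelope near the nucleolar pole, the rDNA-flanking ends
                  of the third chromosome to the nucleolar surface (the
                  Rabl configuration);
* interactions  — adds attractive restraints derived from a random subset
                  of captured interactions, drawn with probability
                  proportional to capture frequency.

Hard constraints (containment, nucleolar exclusion, bond-length band,
excluded volume) are enforced by move rejection; soft terms (harmonic
bonds, flat-bottom tethers and interaction restraints) enter the
Metropolis acceptance.  Ensembles of independent structures represent the
cell population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .core import FragmentMap, GenomeAssembly, InteractionNetwork
logger = logging.getLogger("gcckit")

MODEL_TYPES = ("confined", "constrained", "interactions")


@dataclass(frozen=True)
class ModelSpec:
    """Geometry, force constants and Monte Carlo parameters of one model.

    Nuclear radii default to 1330 nm (G1) and 1710 nm (G2); granule
    diameters to 30 nm (G1) and 60 nm (G2), the G2 granule representing the
    replicated fiber.  The SPB sits at the -z pole of the envelope and the
    nucleolus (radius R/3) at the +z pole, diametrically opposite.  All
    energies are in units of kT.
    """

    phase: str = "G1"
    nuclear_radius: float = 1330.0
    granule_diameter: float = 30.0
    bp_per_granule: int = 10_000
    nucleolus_radius: float | None = None      # default R/3
    k_bond: float | None = None                # default 10 / d0^2
    k_tether: float = 1e-4                     # 1 kT / (100 nm)^2
    k_interaction: float = 1e-4
    contact_distance: float | None = None      # default 2 granule diameters
    tether_tolerance: float = 200.0
    step_sigma: float | None = None            # default 0.5 * diameter
    sweeps: int = 5000
    bond_band: tuple[float, float] = (0.5, 1.5)  # x granule diameter
    min_separation_factor: float = 0.8
    interaction_fraction: float = 0.10
    ensemble_size: int = 500

    def __post_init__(self) -> None:
        if self.nuclear_radius <= self.granule_diameter / 2:
            raise ValueError("nucleus smaller than a granule")
        if self.bp_per_granule <= 0:
            raise ValueError("bp_per_granule must be positive")

    @classmethod
    def for_phase(cls, phase: str, **kw) -> "ModelSpec":
        defaults = {"G1": dict(nuclear_radius=1330.0, granule_diameter=30.0),
                    "G2": dict(nuclear_radius=1710.0, granule_diameter=60.0)}
        if phase not in defaults:
            raise ValueError("modeled phases are G1 and G2")
        return cls(phase=phase, **{**defaults[phase], **kw})

    @classmethod
    def for_genome(cls, genome, phase: str = "G1",
                   bp_per_granule: int = 10_000, **kw) -> "ModelSpec":
        """Model spec with the nucleus scaled to the genome being modeled.

        The fission-yeast geometry pairs a ~38 um chromatin contour (12.6 Mb
        at 10 kb per 30 nm granule) with a 1330 nm nuclear radius, a
        contour-to-radius ratio near 30.  For smaller (synthetic) genomes
        the nuclear radius is scaled to preserve that ratio, so chains can
        still span the SPB-nucleolus axis and adopt a Rabl configuration.
        """
        base = cls.for_phase(phase)
        d = kw.get("granule_diameter", base.granule_diameter)
        n_granules = sum(-(-length // bp_per_granule)
                         for _, length in genome.chromosomes)
        radius = max(n_granules * d / 30.0, 8.0 * d)
        kw.setdefault("nuclear_radius", radius)
        kw.setdefault("tether_tolerance", radius / 4)
        # keep the thermal tether excursion a fixed fraction of the nucleus
        kw.setdefault("k_tether", (8.0 / radius) ** 2)
        kw.setdefault("k_interaction", (8.0 / radius) ** 2)
        return cls.for_phase(phase, bp_per_granule=bp_per_granule, **kw)

    # -- derived geometry ---------------------------------------------------
    @property
    def granule_radius(self) -> float:
        return self.granule_diameter / 2

    @property
    def d0(self) -> float:
        """Bond rest length: touching granules."""
        return self.granule_diameter

    @property
    def spb(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.nuclear_radius])

    @property
    def nucleolus_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.nuclear_radius])

    @property
    def nucleolus_r(self) -> float:
        return (self.nuclear_radius / 3 if self.nucleolus_radius is None
                else self.nucleolus_radius)

    @property
    def kb(self) -> float:
        return 10.0 / self.d0 ** 2 if self.k_bond is None else self.k_bond

    @property
    def dc(self) -> float:
        return (2 * self.granule_diameter if self.contact_distance is None
                else self.contact_distance)

    @property
    def sigma_move(self) -> float:
        return 0.5 * self.granule_diameter if self.step_sigma is None else self.step_sigma


class GranuleMap:
    """Mapping between granules and genomic windows.

    Each chromosome becomes ``ceil(length / bp_per_granule)`` consecutive
    granules; any bp position maps to exactly one granule.
    """

    def __init__(self, genome: GenomeAssembly, bp_per_granule: int):
        self.bp_per_granule = int(bp_per_granule)
        chroms, starts, ends = [], [], []
        self.chain_start: dict[str, int] = {}
        for chrom, length in genome.chromosomes:
            self.chain_start[chrom] = len(chroms)
            for s in range(0, length, self.bp_per_granule):
                chroms.append(chrom)
                starts.append(s)
                ends.append(min(s + self.bp_per_granule, length))
        self.chrom = np.array(chroms)
        self.start = np.array(starts, dtype=np.int64)
        self.end = np.array(ends, dtype=np.int64)
        # integer chain id per granule; bonds exist within a chain only
        names = list(genome.names)
        self.chain_id = np.array([names.index(c) for c in chroms], dtype=np.int64)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.start)

    def granule_of(self, chrom: str, pos: int) -> int:
        if not (0 <= pos < self.genome.lengths[chrom]):
            raise ValueError(f"position {chrom}:{pos} out of bounds")
        return self.chain_start[chrom] + pos // self.bp_per_granule

    def granules_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        lo = self.chain_start[chrom] + start // self.bp_per_granule
        hi = self.chain_start[chrom] + (end - 1) // self.bp_per_granule
        return np.arange(lo, hi + 1)

    def chain_bounds(self) -> list[tuple[int, int]]:
        bounds = []
        for cid in np.unique(self.chain_id):
            idx = np.nonzero(self.chain_id == cid)[0]
            bounds.append((int(idx[0]), int(idx[-1]) + 1))
        return bounds


def build_chains(genome: GenomeAssembly, spec: ModelSpec) -> GranuleMap:
    """Coarse-grain the genome into granule chains."""
    return GranuleMap(genome, spec.bp_per_granule)


@dataclass
class Tether:
    """Flat-bottom harmonic anchor of one granule to a fixed point."""

    granule: int
    anchor: np.ndarray
    tolerance: float
    k: float


@dataclass
class RestraintSet:
    """Attractive flat-bottom restraints between granule pairs."""

    i: np.ndarray
    j: np.ndarray
    target: np.ndarray          # contact distance per pair
    k: np.ndarray
    n_dropped_same_granule: int = 0

    def __len__(self) -> int:
        return len(self.i)

    @classmethod
    def empty(cls) -> "RestraintSet":
        z = np.zeros(0)
        return cls(z.astype(np.int64), z.astype(np.int64), z, z)


@dataclass
class Structure:
    """One 3D conformation: per-granule coordinates in nm."""

    coords: np.ndarray
    granules: GranuleMap

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.granules), 3):
            raise ValueError("coordinate array does not match the granule map")


@dataclass
class Ensemble:
    """Structures generated under one (ModelSpec, model type)."""

    structures: list[Structure]
    granules: GranuleMap
    spec: ModelSpec
    model_type: str

    def __len__(self) -> int:
        return len(self.structures)

    def coords(self) -> np.ndarray:
        return np.stack([s.coords for s in self.structures])


# ---------------------------------------------------------------------------
# Tethers
# ---------------------------------------------------------------------------

def default_tethers(granules: GranuleMap, spec: ModelSpec,
                    centromeres: Mapping[str, int] | None = None) -> list[Tether]:
    """Rabl-configuration tethers for the default nuclear geometry.

    Centromeres (chromosome midpoints unless positions are given) anchor to
    the SPB; the telomeric chain ends of every chromosome but the last
    anchor to envelope points in the hemisphere near the nucleolus; the
    chain ends of the last chromosome (which carries the rDNA arrays)
    anchor to the nucleolar surface.
    """
    R = spec.nuclear_radius
    tethers: list[Tether] = []
    names = granules.genome.names
    bounds = granules.chain_bounds()

    # envelope anchor points for telomeres: 55 degrees off the nucleolar pole,
    # azimuthally spread so anchors do not coincide
    theta = math.radians(55.0)
    n_tel = 2 * max(len(names) - 1, 1)
    az = [2 * math.pi * k / n_tel for k in range(n_tel)]
    tel_anchor = [np.array([R * math.sin(theta) * math.cos(a),
                            R * math.sin(theta) * math.sin(a),
                            R * math.cos(theta)]) for a in az]

    k_az = 0
    for ci, (chrom, (lo, hi)) in enumerate(zip(names, bounds)):
        length = granules.genome.lengths[chrom]
        cen_pos = (centromeres or {}).get(chrom, length // 2)
        cen_g = granules.granule_of(chrom, cen_pos)
        tethers.append(Tether(cen_g, spec.spb, spec.tether_tolerance,
                              spec.k_tether))
        if ci < len(names) - 1:
            tethers.append(Tether(lo, tel_anchor[k_az], spec.tether_tolerance,
                                  spec.k_tether))
            k_az += 1
            tethers.append(Tether(hi - 1, tel_anchor[k_az],
                                  spec.tether_tolerance, spec.k_tether))
            k_az += 1
        else:
            # rDNA-flanking chain ends to the nucleolar surface
            surface = spec.nucleolus_center - np.array(
                [0.0, 0.0, spec.nucleolus_r + spec.granule_radius])
            tethers.append(Tether(lo, surface, spec.tether_tolerance,
                                  spec.k_tether))
            tethers.append(Tether(hi - 1, surface, spec.tether_tolerance,
                                  spec.k_tether))
    return tethers


# ---------------------------------------------------------------------------
# Interaction restraints
# ---------------------------------------------------------------------------

def sample_interaction_subset(net: InteractionNetwork, fragments: FragmentMap,
                              granules: GranuleMap,
                              fraction: float = 0.10,
                              seed: int | np.random.Generator = 0,
                              spec: ModelSpec | None = None) -> RestraintSet:
    """Frequency-weighted random subset of interactions as restraints.

    Draws ``round(fraction * |net|)`` distinct interactions without
    replacement with selection probability proportional to capture
    frequency (exponential-race weighted sampling; the returned order is
    the sequential draw order).  Fragment midpoints map each end to a
    granule; pairs collapsing onto one granule are dropped and tallied.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    items = list(net.items())
    if not items:
        return RestraintSet.empty()
    w = np.array([f for _, f in items], dtype=float)
    k = int(round(fraction * len(items)))
    keys = rng.exponential(size=len(items)) / w
    order = np.argsort(keys)[:k]

    if spec is None:
        raise ValueError("spec required to set the contact distance")
    gi, gj = [], []
    dropped = 0
    for idx in order:
        (a, b), _ = items[idx]
        fa, fb = fragments.by_id[a], fragments.by_id[b]
        ga = granules.granule_of(fa.chrom, (fa.start + fa.end) // 2)
        gb = granules.granule_of(fb.chrom, (fb.start + fb.end) // 2)
        if ga == gb:
            dropped += 1
            continue
        gi.append(ga)
        gj.append(gb)
    if dropped:
        logger.info("sample_interaction_subset: dropped %d same-granule pairs",
                    dropped)
    n = len(gi)
    return RestraintSet(np.array(gi, dtype=np.int64), np.array(gj, dtype=np.int64),
                        np.full(n, spec.dc), np.full(n, spec.k_interaction),
                        dropped)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def _hard_violation(coords: np.ndarray, granules: GranuleMap,
                    spec: ModelSpec) -> bool:
    R_in = spec.nuclear_radius - spec.granule_radius
    if (np.einsum("ij,ij->i", coords, coords) > R_in ** 2 + 1e-9).any():
        return True
    d_nuc = np.linalg.norm(coords - spec.nucleolus_center, axis=1)
    if (d_nuc < spec.nucleolus_r + spec.granule_radius - 1e-9).any():
        return True
    bonded = granules.chain_id[:-1] == granules.chain_id[1:]
    d_bond = np.linalg.norm(np.diff(coords, axis=0), axis=1)[bonded]
    lo, hi = spec.bond_band
    if ((d_bond < lo * spec.d0 - 1e-9) | (d_bond > hi * spec.d0 + 1e-9)).any():
        return True
    # excluded volume between non-bonded granules
    n = len(coords)
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        min_sep = spec.min_separation_factor * spec.granule_diameter
        iu, ju = np.triu_indices(n, k=1)
        neighbor = (ju - iu == 1) & (granules.chain_id[iu] == granules.chain_id[ju])
        if (d2[iu, ju][~neighbor] < min_sep ** 2 - 1e-9).any():
            return True
    return False


def energy(structure: Structure, spec: ModelSpec, model_type: str,
           restraints: RestraintSet | None = None,
           tethers: Sequence[Tether] | None = None) -> float:
    """Total soft energy (kT); infinite when a hard constraint is violated.

    Confined models carry only the bond terms (the hard constraints act by
    rejection); constrained models add the tethers, interactions models add
    both tethers and pair restraints.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    coords = structure.coords
    granules = structure.granules
    if _hard_violation(coords, granules, spec):
        return float("inf")
    bonded = granules.chain_id[:-1] == granules.chain_id[1:]
    d_bond = np.linalg.norm(np.diff(coords, axis=0), axis=1)[bonded]
    e = float((spec.kb * (d_bond - spec.d0) ** 2).sum())
    if model_type in ("constrained", "interactions") and tethers:
        for t in tethers:
            excess = np.linalg.norm(coords[t.granule] - t.anchor) - t.tolerance
            if excess > 0:
                e += t.k * excess ** 2
    if model_type == "interactions" and restraints is not None and len(restraints):
        d = np.linalg.norm(coords[restraints.i] - coords[restraints.j], axis=1)
        excess = np.maximum(d - restraints.target, 0.0)
        e += float((restraints.k * excess ** 2).sum())
    return e


# ---------------------------------------------------------------------------
# Monte Carlo kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(coords, chain_id, R_in, nucleolus_z, nucleolus_excl,
               d0, band_lo, band_hi, min_sep, k_bond,
               tether_idx, tether_anchor, tether_tol, tether_k,
               rest_off, rest_nbr, rest_target, rest_k,
               step, n_moves, seed):  # pragma: no cover - exercised via run_mc
    np.random.seed(seed)
    n = coords.shape[0]
    min_sep2 = min_sep * min_sep
    lo2 = (band_lo * d0) ** 2
    hi2 = (band_hi * d0) ** 2
    accepted = 0
    for _ in range(n_moves):
        g = np.random.randint(0, n)
        px = coords[g, 0] + step * np.random.randn()
        py = coords[g, 1] + step * np.random.randn()
        pz = coords[g, 2] + step * np.random.randn()
        # containment
        if px * px + py * py + pz * pz > R_in * R_in:
            continue
        # nucleolar exclusion (nucleolus centered on the +z axis)
        dz = pz - nucleolus_z
        if px * px + py * py + dz * dz < nucleolus_excl * nucleolus_excl:
            continue
        # bond band with chain neighbours
        ok = True
        for nb in (g - 1, g + 1):
            if 0 <= nb < n and chain_id[nb] == chain_id[g]:
                ddx = px - coords[nb, 0]
                ddy = py - coords[nb, 1]
                ddz = pz - coords[nb, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 < lo2 or d2 > hi2:
                    ok = False
                    break
        if not ok:
            continue
        # excluded volume against every non-bonded granule
        for o in range(n):
            if o == g:
                continue
            if abs(o - g) == 1 and chain_id[o] == chain_id[g]:
                continue
            ddx = px - coords[o, 0]
            ddy = py - coords[o, 1]
            ddz = pz - coords[o, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz < min_sep2:
                ok = False
                break
        if not ok:
            continue
        # soft energy difference
        de = 0.0
        for nb in (g - 1, g + 1):
            if 0 <= nb < n and chain_id[nb] == chain_id[g]:
                ddx = px - coords[nb, 0]
                ddy = py - coords[nb, 1]
                ddz = pz - coords[nb, 2]
                d_new = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                ddx = coords[g, 0] - coords[nb, 0]
                ddy = coords[g, 1] - coords[nb, 1]
                ddz = coords[g, 2] - coords[nb, 2]
                d_old = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                de += k_bond * ((d_new - d0) ** 2 - (d_old - d0) ** 2)
        ti = tether_idx[g]
        if ti >= 0:
            ax, ay, az = tether_anchor[ti, 0], tether_anchor[ti, 1], tether_anchor[ti, 2]
            d_new = math.sqrt((px - ax) ** 2 + (py - ay) ** 2 + (pz - az) ** 2)
            d_old = math.sqrt((coords[g, 0] - ax) ** 2 + (coords[g, 1] - ay) ** 2
                              + (coords[g, 2] - az) ** 2)
            e_new = max(d_new - tether_tol[ti], 0.0) ** 2
            e_old = max(d_old - tether_tol[ti], 0.0) ** 2
            de += tether_k[ti] * (e_new - e_old)
        for r in range(rest_off[g], rest_off[g + 1]):
            o = rest_nbr[r]
            d_new = math.sqrt((px - coords[o, 0]) ** 2 + (py - coords[o, 1]) ** 2
                              + (pz - coords[o, 2]) ** 2)
            d_old = math.sqrt((coords[g, 0] - coords[o, 0]) ** 2
                              + (coords[g, 1] - coords[o, 1]) ** 2
                              + (coords[g, 2] - coords[o, 2]) ** 2)
            e_new = max(d_new - rest_target[r], 0.0) ** 2
            e_old = max(d_old - rest_target[r], 0.0) ** 2
            de += rest_k[r] * (e_new - e_old)
        if de <= 0.0 or np.random.random() < math.exp(-de):
            coords[g, 0] = px
            coords[g, 1] = py
            coords[g, 2] = pz
            accepted += 1
    return accepted


def _restraint_csr(n: int, restraints: RestraintSet | None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if restraints is None or len(restraints) == 0:
        return (np.zeros(n + 1, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(0), np.zeros(0))
    g = np.concatenate([restraints.i, restraints.j])
    o = np.concatenate([restraints.j, restraints.i])
    t = np.concatenate([restraints.target, restraints.target])
    k = np.concatenate([restraints.k, restraints.k])
    order = np.argsort(g, kind="stable")
    g, o, t, k = g[order], o[order], t[order], k[order]
    off = np.zeros(n + 1, dtype=np.int64)
    np.add.at(off, g + 1, 1)
    off = np.cumsum(off)
    return off, o.astype(np.int64), t.astype(float), k.astype(float)


def _chain_guide(lo: int, hi: int, tethers: Sequence[Tether],
                 spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-granule guide points interpolating a chain's tether anchors.

    Chains with tethers are draped along the piecewise-linear path through
    their anchors (telomere -> centromere -> telomere gives the Rabl V);
    untethered chains get a single random interior guide point.  Anchors
    are pulled inside the admissible shell first.
    """
    R_in = spec.nuclear_radius - spec.granule_radius
    own = sorted([t for t in tethers if lo <= t.granule < hi],
                 key=lambda t: t.granule)

    def inside(p: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(p)
        if r > R_in - spec.d0:
            p = p / r * (R_in - spec.d0)
        return p

    guide = np.empty((hi - lo, 3))
    if not own:
        direction = rng.normal(size=3)
        center = direction / np.linalg.norm(direction) * rng.uniform(0, 0.6 * R_in)
        guide[:] = center
        return guide
    knots_g = [t.granule for t in own]
    knots_p = [inside(np.asarray(t.anchor, float)) for t in own]
    for g in range(lo, hi):
        if g <= knots_g[0]:
            guide[g - lo] = knots_p[0]
        elif g >= knots_g[-1]:
            guide[g - lo] = knots_p[-1]
        else:
            k = next(i for i in range(len(knots_g) - 1)
                     if knots_g[i] <= g <= knots_g[i + 1])
            span = knots_g[k + 1] - knots_g[k]
            f = (g - knots_g[k]) / span
            guide[g - lo] = (1 - f) * knots_p[k] + f * knots_p[k + 1]
    return guide


def _grow_initial(granules: GranuleMap, spec: ModelSpec,
                  tethers: Sequence[Tether],
                  rng: np.random.Generator, max_retries: int = 100) -> np.ndarray:
    """Guided self-avoiding-walk initial configuration.

    Each chain is grown step by step at bond length d0, with step
    directions biased toward per-granule guide points interpolated through
    the chain's tether anchors, so tethered chains start near their Rabl
    arrangement and only local relaxation is left to the Monte Carlo.
    """
    n = len(granules)
    R_in = spec.nuclear_radius - spec.granule_radius
    min_sep = spec.min_separation_factor * spec.granule_diameter
    nuc_excl = spec.nucleolus_r + spec.granule_radius
    coords = np.full((n, 3), np.nan)
    placed: list[int] = []

    def valid(p: np.ndarray) -> bool:
        # steps have length exactly d0 > min_sep, so the bonded neighbour
        # passes the separation check and needs no special-casing
        if p @ p > R_in ** 2:
            return False
        if np.linalg.norm(p - spec.nucleolus_center) < nuc_excl:
            return False
        if placed:
            d2 = ((coords[placed] - p) ** 2).sum(axis=1)
            if (d2 < min_sep ** 2).any():
                return False
        return True

    for lo, hi in granules.chain_bounds():
        for _attempt in range(max_retries):
            guide = _chain_guide(lo, hi, tethers, spec, rng)
            n_before = len(placed)
            ok = True
            for g in range(lo, hi):
                p = None
                if g == lo:
                    for _ in range(200):
                        cand = guide[0] + rng.normal(scale=spec.d0, size=3)
                        if valid(cand):
                            p = cand
                            break
                else:
                    for trial in range(200):
                        toward = guide[g - lo] - coords[g - 1]
                        norm = np.linalg.norm(toward)
                        noise = 0.7 + 0.02 * trial  # widen on retries
                        direction = (toward / norm if norm > 1e-9
                                     else rng.normal(size=3))
                        direction = direction + rng.normal(scale=noise, size=3)
                        direction /= np.linalg.norm(direction)
                        cand = coords[g - 1] + spec.d0 * direction
                        if valid(cand):
                            p = cand
                            break
                if p is None:
                    ok = False
                    break
                coords[g] = p
                placed.append(g)
            if ok:
                break
            del placed[n_before:]
            coords[lo:hi] = np.nan
        else:
            raise RuntimeError(
                f"failed to build an initial configuration for chain {lo}:{hi}")
    return coords


def run_mc(spec: ModelSpec, model_type: str, granules: GranuleMap,
           restraints: RestraintSet | None = None,
           tethers: Sequence[Tether] | None = None,
           seed: int = 0, return_acceptance: bool = False):
    """Metropolis simulation of one structure.

    Single-granule Gaussian displacement moves at kT=1; hard constraints by
    rejection.  With zero sweeps the (valid) initial self-avoiding-walk
    configuration is returned unchanged.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    if model_type == "interactions" and restraints is None:
        raise ValueError("interactions model requires restraints")
    if model_type == "confined":
        active_tethers: Sequence[Tether] = []
    else:
        active_tethers = (default_tethers(granules, spec)
                          if tethers is None else tethers)
    rng = np.random.default_rng(seed)
    coords = _grow_initial(granules, spec, active_tethers, rng)

    n = len(granules)
    tether_idx = np.full(n, -1, dtype=np.int64)
    anchors = np.zeros((max(len(active_tethers), 1), 3))
    tols = np.zeros(max(len(active_tethers), 1))
    ks = np.zeros(max(len(active_tethers), 1))
    for ti, t in enumerate(active_tethers):
        tether_idx[t.granule] = ti
        anchors[ti] = t.anchor
        tols[ti] = t.tolerance
        ks[ti] = t.k
    use_rest = restraints if model_type == "interactions" else None
    off, nbr, targ, rk = _restraint_csr(n, use_rest)

    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    accepted = _mc_kernel(
        coords, granules.chain_id,
        spec.nuclear_radius - spec.granule_radius,
        float(spec.nucleolus_center[2]),
        spec.nucleolus_r + spec.granule_radius,
        spec.d0, spec.bond_band[0], spec.bond_band[1],
        spec.min_separation_factor * spec.granule_diameter, spec.kb,
        tether_idx, anchors, tols, ks, off, nbr, targ, rk,
        spec.sigma_move, spec.sweeps * n, kernel_seed)
    structure = Structure(coords, granules)
    if return_acceptance:
        frac = accepted / max(spec.sweeps * n, 1)
        return structure, frac
    return structure


def generate_ensemble(spec: ModelSpec, model_type: str, granules: GranuleMap,
                      net: InteractionNetwork | None = None,
                      fragments: FragmentMap | None = None,
                      tethers: Sequence[Tether] | None = None,
                      restraints: RestraintSet | None = None,
                      n_structures: int | None = None,
                      seed: int = 0) -> Ensemble:
    """Ensemble of independent structures under one model regime.

    For the interactions model a fresh frequency-weighted subset of the
    network is drawn for each structure (pass ``restraints`` to pin one
    subset across the whole ensemble instead).
    """
    if model_type == "interactions" and restraints is None and (
            net is None or fragments is None):
        raise ValueError("interactions model requires a network and fragments "
                         "or an explicit restraint set")
    n_structures = spec.ensemble_size if n_structures is None else n_structures
    sub_seeds = np.random.SeedSequence(seed).generate_state(2 * n_structures)
    structures = []
    for s in range(n_structures):
        r = restraints
        if model_type == "interactions" and r is None:
            rng = np.random.default_rng(int(sub_seeds[2 * s]) % 2 ** 31)
            r = sample_interaction_subset(net, fragments, granules,
                                          spec.interaction_fraction, rng, spec)
        structures.append(run_mc(spec, model_type, granules, r, tethers,
                                 seed=int(sub_seeds[2 * s + 1]) % 2 ** 31))
    return Ensemble(structures, granules, spec, model_type)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_structure_tsv(structure: Structure, path) -> None:
    g = structure.granules
    with open(path, "w") as fh:
        fh.write("granule_id\tchrom\tstart\tend\tx\ty\tz\n")
        for i in range(len(g)):
            x, y, z = structure.coords[i]
            fh.write(f"{i}\t{g.chrom[i]}\t{g.start[i]}\t{g.end[i]}\t"
                     f"{x:.3f}\t{y:.3f}\t{z:.3f}\n")


def pair_distances(ensemble: Ensemble, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Per-structure mean distance over the given granule pairs."""
    out = np.empty(len(ensemble))
    for s, st in enumerate(ensemble.structures):
        out[s] = np.linalg.norm(st.coords[i] - st.coords[j], axis=1).mean()
    return out
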