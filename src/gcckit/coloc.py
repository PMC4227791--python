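"""Permutation tests for spatial colocalization of locus sets.

A locus set (LTRs, a transcript-defined gene set, ...) "self-colocalizes"
when interactions in the capture network join two fragments that each
overlap a locus of the set.  Whether the observed colocalization frequency
is unusual is judged against two empirical nulls built from random locus
sets of identical number and lengths: conserved-random (CR) sets keep the
per-chromosome locus counts, random (R) sets redraw the chromosome of each
locus proportional to chromosome length.  A result is called significant
only when both nulls agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    FragmentMap,
    GenomeAssembly,
    GenomicInterval,
    InteractionNetwork,
)

logger = logging.getLogger("gcckit")

#: intra-chromosomal colocalization beyond this gap is called long-range
LONG_RANGE_BP = 50_000


@dataclass(frozen=True)
class LocusSet:
    """Named collection of genomic intervals."""

    name: str
    loci: tuple[GenomicInterval, ...]

    def __init__(self, name: str, loci: Sequence[GenomicInterval]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "loci", tuple(loci))

    def __len__(self) -> int:
        return len(self.loci)

    def validate_bounds(self, genome: GenomeAssembly) -> None:
        for iv in self.loci:
            if iv.chrom not in genome.lengths or iv.end > genome.lengths[iv.chrom]:
                raise ValueError(f"locus {iv} outside genome bounds")


@dataclass
class ColocResult:
    """Outcome of one colocalization test."""

    locus_set: str
    phase: str
    observed: int
    null_cr: np.ndarray
    null_r: np.ndarray
    p_high_cr: float
    p_low_cr: float
    p_high_r: float
    p_low_r: float
    verdict: str                      # significant-high|significant-low|not-different|not-detected
    inter_fraction: float
    intra_fraction: float
    long_range_intra_fraction: float  # of intra colocalization, gap > threshold

    def to_dict(self) -> dict:
        return {
            "locus_set": self.locus_set, "phase": self.phase,
            "observed": self.observed, "verdict": self.verdict,
            "p_high_cr": self.p_high_cr, "p_low_cr": self.p_low_cr,
            "p_high_r": self.p_high_r, "p_low_r": self.p_low_r,
            "inter_fraction": self.inter_fraction,
            "intra_fraction": self.intra_fraction,
            "long_range_intra_fraction": self.long_range_intra_fraction,
        }


class _NetworkIndex:
    """Vectorized view of a network against a tiling fragment map.

    Precomputes, per chromosome, the fragment start arrays and, per
    interaction, the fragment array indices, chromosomes and linear gap, so
    a locus set's colocalization frequency is a few array operations.
    """

    def __init__(self, net: InteractionNetwork, fragments: FragmentMap):
        self.fragments = fragments
        frs = fragments.fragments
        self.n_frag = len(frs)
        self._pos = {f.id: k for k, f in enumerate(frs)}
        items = list(net.items())
        self.fa = np.array([self._pos[a] for (a, b), _ in items], dtype=np.int64)
        self.fb = np.array([self._pos[b] for (a, b), _ in items], dtype=np.int64)
        chroms = np.array([f.chrom for f in frs])
        starts = np.array([f.start for f in frs])
        ends = np.array([f.end for f in frs])
        if len(items):
            self.intra = chroms[self.fa] == chroms[self.fb]
            lo = np.minimum(self.fa, self.fb)
            hi = np.maximum(self.fa, self.fb)
            self.gap = np.where(self.intra,
                                np.abs(starts[hi] - ends[lo]), -1)
        else:
            self.intra = np.zeros(0, dtype=bool)
            self.gap = np.zeros(0, dtype=np.int64)
        # per-chromosome tiling index for locus -> fragment range lookup
        self.chrom_names = list(dict.fromkeys(f.chrom for f in frs))
        self._chrom_starts: dict[str, np.ndarray] = {}
        self._chrom_offset: dict[str, int] = {}
        self._chrom_len: dict[str, int] = {}
        k = 0
        for chrom in self.chrom_names:
            sub = [f for f in frs if f.chrom == chrom]
            self._chrom_starts[chrom] = np.array([f.start for f in sub])
            self._chrom_offset[chrom] = k
            self._chrom_len[chrom] = sub[-1].end
            k += len(sub)

    def loci_as_arrays(self, loci: Sequence[GenomicInterval]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        chrom_idx = np.array([self.chrom_names.index(iv.chrom)
                              if iv.chrom in self.chrom_names else -1
                              for iv in loci], dtype=np.int64)
        starts = np.array([iv.start for iv in loci], dtype=np.int64)
        ends = np.array([iv.end for iv in loci], dtype=np.int64)
        return chrom_idx, starts, ends

    def locus_fragment_hits(self, chrom_idx: np.ndarray, starts: np.ndarray,
                            ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-fragment overlap count and single-overlapping-locus id.

        Loci are given as parallel arrays (chromosome index into
        ``chrom_names``, start, end).  Returns ``(count, single_id)`` arrays
        over fragments; ``single_id`` holds the locus index when exactly one
        locus overlaps, else -1.  Uses the tiling property: a locus overlaps
        a contiguous run of fragments, accumulated via difference arrays.
        """
        n = self.n_frag
        diff = np.zeros(n + 1, dtype=np.int64)
        idsum = np.zeros(n + 1, dtype=np.int64)
        for ci, chrom in enumerate(self.chrom_names):
            sel = np.nonzero(chrom_idx == ci)[0]
            if len(sel) == 0:
                continue
            fs = self._chrom_starts[chrom]
            off = self._chrom_offset[chrom]
            s = starts[sel]
            e = np.minimum(ends[sel], self._chrom_len[chrom])
            lo = np.maximum(np.searchsorted(fs, s, side="right") - 1, 0) + off
            hi = np.searchsorted(fs, e, side="left") + off
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
            np.add.at(idsum, lo, sel)
            np.add.at(idsum, hi, -sel)
        count = np.cumsum(diff[:-1])
        single = np.where(count == 1, np.cumsum(idsum[:-1]), -1)
        return count, single

    def coloc_mask(self, loci: Sequence[GenomicInterval]) -> np.ndarray:
        """Boolean mask over interactions counted as colocalization."""
        return self.coloc_mask_arrays(*self.loci_as_arrays(loci))

    def coloc_mask_arrays(self, chrom_idx: np.ndarray, starts: np.ndarray,
                          ends: np.ndarray) -> np.ndarray:
        count, single = self.locus_fragment_hits(chrom_idx, starts, ends)
        hit = (count[self.fa] > 0) & (count[self.fb] > 0)
        same_single = ((count[self.fa] == 1) & (count[self.fb] == 1)
                       & (single[self.fa] == single[self.fb]))
        return hit & ~same_single


def colocalization_frequency(locus_set: LocusSet, net: InteractionNetwork,
                             fragments: FragmentMap) -> int:
    """Number of interactions joining two fragments that overlap the set.

    Each end must overlap >= 1 bp of some locus; interactions whose two
    fragments overlap only one and the same locus are excluded (a single
    region folding onto itself is not colocalization of two regions).
    """
    if len(locus_set) == 0:
        return 0
    index = _NetworkIndex(net, fragments)
    return int(index.coloc_mask(locus_set.loci).sum())


def random_locus_sets(locus_set: LocusSet, genome: GenomeAssembly,
                      n_random: int, mode: str,
                      seed: int | np.random.Generator = 0) -> list[LocusSet]:
    """Random locus sets matched in number and lengths to the original.

    mode "CR" (conserved random) keeps each locus on its own chromosome;
    mode "R" redraws the chromosome proportional to chromosome length
    (among chromosomes long enough to host the locus), then places the
    start uniformly.
    """
    if mode not in ("CR", "R"):
        raise ValueError("mode must be 'CR' or 'R'")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = genome.names
    lengths = np.array([genome.lengths[c] for c in names], dtype=float)
    sets = []
    for k in range(n_random):
        loci = []
        for iv in locus_set.loci:
            if mode == "CR":
                chrom = iv.chrom
            else:
                ok = lengths >= iv.length
                if not ok.any():
                    raise ValueError(f"locus of length {iv.length} fits no chromosome")
                p = np.where(ok, lengths, 0.0)
                chrom = names[rng.choice(len(names), p=p / p.sum())]
            room = genome.lengths[chrom] - iv.length
            if room < 0:
                raise ValueError(f"locus of length {iv.length} exceeds {chrom}")
            start = int(rng.integers(0, room + 1))
            loci.append(GenomicInterval(chrom, start, start + iv.length, iv.name))
        sets.append(LocusSet(f"{locus_set.name}_{mode}_{k}", loci))
    return sets


def _draw_random_arrays(index: "_NetworkIndex", lengths: np.ndarray,
                        orig_chrom_idx: np.ndarray, genome: GenomeAssembly,
                        mode: str, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One random locus set as (chrom_idx, start, end) arrays.

    Distributionally identical to :func:`random_locus_sets` but avoids
    per-locus object construction in the permutation loop.
    """
    names = index.chrom_names
    chrom_lengths = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    if mode == "CR":
        chrom_idx = orig_chrom_idx
    else:
        fit = chrom_lengths[None, :] >= lengths[:, None]
        if not fit.all(axis=1).any() and (~fit.any(axis=1)).any():
            raise ValueError("a locus fits no chromosome")
        p = np.where(fit, chrom_lengths[None, :], 0).astype(float)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(len(lengths))
        chrom_idx = (np.cumsum(p, axis=1) > u[:, None]).argmax(axis=1)
    room = chrom_lengths[chrom_idx] - lengths
    starts = (rng.random(len(lengths)) * (room + 1)).astype(np.int64)
    return chrom_idx, starts, starts + lengths


def empirical_p(observed: int, null: np.ndarray) -> tuple[float, float]:
    """Add-one empirical tail probabilities (never exactly zero)."""
    n = len(null)
    p_high = (1 + int((null >= observed).sum())) / (n + 1)
    p_low = (1 + int((null <= observed).sum())) / (n + 1)
    return p_high, p_low


def coloc_test(locus_set: LocusSet, net: InteractionNetwork,
               genome: GenomeAssembly, fragments: FragmentMap,
               n_random: int = 1000, alpha: float = 0.05,
               seed: int = 0, long_range_bp: int = LONG_RANGE_BP) -> ColocResult:
    """Both-methods colocalization test of one locus set against one network.

    Draws ``n_random`` CR and R random locus sets, computes empirical
    two-tail p-values with the add-one correction, and calls the verdict
    significant only when both null models agree at level ``alpha``.
    Also reports how the observed colocalization splits into inter- and
    intrachromosomal interactions and, within intra, the fraction spanning
    more than ``long_range_bp``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    locus_set.validate_bounds(genome)
    index = _NetworkIndex(net, fragments)
    mask = index.coloc_mask(locus_set.loci)
    observed = int(mask.sum())

    rng = np.random.default_rng(seed)
    orig_chrom_idx, orig_starts, orig_ends = index.loci_as_arrays(locus_set.loci)
    lengths = orig_ends - orig_starts
    nulls = {}
    for mode in ("CR", "R"):
        vals = np.empty(n_random, dtype=np.int64)
        for k in range(n_random):
            ci, s, e = _draw_random_arrays(index, lengths, orig_chrom_idx,
                                           genome, mode, rng)
            vals[k] = int(index.coloc_mask_arrays(ci, s, e).sum())
        nulls[mode] = vals
    p_high_cr, p_low_cr = empirical_p(observed, nulls["CR"])
    p_high_r, p_low_r = empirical_p(observed, nulls["R"])

    if observed == 0:
        verdict = "not-detected"
    elif p_high_cr <= alpha and p_high_r <= alpha:
        verdict = "significant-high"
    elif p_low_cr <= alpha and p_low_r <= alpha:
        verdict = "significant-low"
    else:
        verdict = "not-different"

    if observed > 0:
        n_intra = int((mask & index.intra).sum())
        inter_fraction = (observed - n_intra) / observed
        intra_fraction = n_intra / observed
        if n_intra > 0:
            long_range = int((mask & index.intra & (index.gap > long_range_bp)).sum())
            long_range_intra_fraction = long_range / n_intra
        else:
            long_range_intra_fraction = 0.0
    else:
        inter_fraction = intra_fraction = long_range_intra_fraction = 0.0

    return ColocResult(locus_set.name, net.phase, observed,
                       nulls["CR"], nulls["R"],
                       p_high_cr, p_low_cr, p_high_r, p_low_r, verdict,
                       inter_fraction, intra_fraction,
                       long_range_intra_fraction)


def expected_fdr(n_tests: int, n_significant: int,
                 alpha: float = 0.05) -> float:
    """Expected false discovery rate of a family of per-test-alpha calls.

    ``n_tests * alpha`` is the expected number of false positives among
    tests with a detectable signal (not-detected verdicts are excluded by
    the caller before counting), divided by the number of significant
    calls.  Returns NaN when nothing was significant.
    """
    if n_significant < 0 or n_tests < 0:
        raise ValueError("counts must be nonnegative")
    if n_significant == 0:
        return float("nan")
    return n_tests * alpha / n_significant
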