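"""Network-level statistics for phase-resolved interaction networks.

Covers the significance machinery around the capture counts: the
frequency cut-off controlling the false detection rate against a ligation-
noise background, collector's (rarefaction) curves probing sampling
saturation, comparison of the three phase networks against randomly
resampled networks, Venn partitions of the phase networks, and the
loop-length distribution of intrachromosomal interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FragmentMap, InteractionNetwork

logger = logging.getLogger("gcckit")

VENN_REGIONS = ("G1", "G2", "M", "G1&G2", "G1&M", "G2&M", "G1&G2&M")


@dataclass
class VennPartition:
    """Counts of interactions per Venn region, inter and intra separately."""

    inter: dict[str, int]
    intra: dict[str, int]
    phases: tuple[str, ...] = ("G1", "G2", "M")

    def total(self, which: str) -> int:
        return sum(getattr(self, which).values())

    def to_dict(self) -> dict:
        return {"inter": dict(self.inter), "intra": dict(self.intra)}


@dataclass
class LoopLengthDistribution:
    """Loop lengths (bp) of intrachromosomal interactions plus a histogram."""

    lengths: np.ndarray
    bin_width: int
    bin_starts: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class RandomNetworkReport:
    """Chi-square comparison of observed vs resampled Venn region counts."""

    which: str                   # "inter" or "intra"
    observed: dict[str, int]
    expected: dict[str, float]
    statistic: float
    p_value: float
    df: int
    n_random: int
    with_replacement: bool


# ---------------------------------------------------------------------------
# FDR cut-off
# ---------------------------------------------------------------------------

def _endpoint_permutation_expected(net: InteractionNetwork,
                                   n_permutations: int,
                                   seed: int) -> np.ndarray:
    """Expected tail counts E[#pairs with frequency >= f] under re-pairing.

    The noise model re-pairs the multiset of fragment endpoints observed in
    the network (each captured event contributes its two endpoints), which
    preserves per-fragment coverage while destroying pair identity.  The
    empirical tail is Poisson-smoothed beyond the largest frequency any
    permutation produced, using the mean per-pair event rate.
    """
    events = [(a, b) for (a, b), f in net.items() for _ in range(f)]
    ends = np.array([e for ab in events for e in ab], dtype=np.int64)
    rng = np.random.default_rng(seed)
    max_f = int(net.frequencies().max()) if len(net) else 1
    tail = np.zeros(max_f + 2)
    n_pairs_total = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ends)
        a = np.minimum(perm[0::2], perm[1::2])
        b = np.maximum(perm[0::2], perm[1::2])
        keep = a != b
        pairs = a[keep] * (ends.max() + 1) + b[keep]
        _, counts = np.unique(pairs, return_counts=True)
        n_pairs_total += len(counts)
        binc = np.bincount(np.minimum(counts, max_f + 1), minlength=max_f + 2)
        tail += np.cumsum(binc[::-1])[::-1]
    expected = tail / n_permutations
    # Poisson smoothing of the empty tail
    mean_pairs = n_pairs_total / n_permutations
    if mean_pairs > 0:
        lam = (len(ends) / 2) / mean_pairs
        for f in range(1, max_f + 2):
            if expected[f] == 0:
                expected[f] = mean_pairs * stats.poisson.sf(f - 1, lam)
    return expected  # expected[f] = E[#pairs with freq >= f], f = 0..max_f+1


def fdr_cutoff(net: InteractionNetwork, target_fdr: float = 0.05,
               background: str | Sequence[float] | None = "endpoint-permutation",
               n_permutations: int = 100, seed: int = 0) -> int:
    """Smallest frequency whose expected/observed tail ratio meets the target.

    Returns the least integer f with
    ``E[#pairs at frequency >= f under noise] / #observed pairs at >= f
    <= target_fdr``.  ``background`` is the endpoint-permutation noise model
    by default, an explicit tail-count array (index f -> expected count at
    frequency >= f), or None for a noise-free background (cut-off 1).
    If no frequency attains the target, returns max observed frequency + 1
    with a warning.
    """
    if len(net) == 0:
        raise ValueError("empty network")
    freqs = net.frequencies()
    max_f = int(freqs.max())
    if background is None:
        return 1
    if isinstance(background, str):
        if background != "endpoint-permutation":
            raise ValueError(f"unknown background model {background!r}")
        expected = _endpoint_permutation_expected(net, n_permutations, seed)
    else:
        expected = np.asarray(background, dtype=float)
    observed_tail = np.array([(freqs >= f).sum() for f in range(max_f + 1)])
    for f in range(1, max_f + 1):
        exp_f = expected[f] if f < len(expected) else 0.0
        if observed_tail[f] > 0 and exp_f / observed_tail[f] <= target_fdr:
            return f
    warnings.warn("FDR target unattainable; returning max frequency + 1")
    return max_f + 1


# ---------------------------------------------------------------------------
# Collector's curve
# ---------------------------------------------------------------------------

def collectors_curve(total_net: InteractionNetwork, cutoff: int,
                     fractions: Sequence[float] = tuple(np.arange(1, 11) / 10),
                     replicates: int = 100, seed: int = 0) -> pd.DataFrame:
    """Rarefaction of the event list against an artificial spike-in.

    The network is expanded to an event list (each interaction repeated by
    its frequency) plus one artificial interaction at exactly the cut-off
    frequency.  For each fraction, that many events are sampled without
    replacement; interactions sampled strictly more often than the
    artificial one count as random-significant.  Reported is the mean (over
    replicates) percentage of the full network's significant interactions
    (frequency >= cutoff) recovered as random-significant.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    items = list(total_net.items())
    n_int = len(items)
    freqs = np.array([f for _, f in items] + [cutoff])
    event_owner = np.repeat(np.arange(n_int + 1), freqs)
    significant = np.nonzero(freqs[:n_int] >= cutoff)[0]
    if len(significant) == 0:
        raise ValueError("no significant interactions at this cutoff")
    rng = np.random.default_rng(seed)

    rows = []
    for frac in fractions:
        k = int(round(frac * len(event_owner)))
        recov = np.zeros(replicates)
        for r in range(replicates):
            take = rng.choice(len(event_owner), size=k, replace=False)
            counts = np.bincount(event_owner[take], minlength=n_int + 1)
            art = counts[n_int]
            recov[r] = (counts[significant] > art).mean() * 100.0
        rows.append({"fraction": frac, "mean_percent_recovered": recov.mean(),
                     "sd_percent_recovered": recov.std(ddof=1) if replicates > 1 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Venn partitions and random-network sampling
# ---------------------------------------------------------------------------

def venn_partition(nets: Mapping[str, InteractionNetwork],
                   fragments: FragmentMap) -> VennPartition:
    """Membership-based Venn region counts, inter and intra separately.

    Membership is by unordered fragment-pair identity; frequencies are
    ignored.  Region counts within inter (resp. intra) sum to the size of
    the union of the three phase networks restricted to inter (intra).
    """
    phases = tuple(nets)
    sets = {ph: nets[ph].pairs for ph in phases}
    inter: dict[str, int] = {}
    intra: dict[str, int] = {}
    universe = set().union(*sets.values())
    for region in _regions(phases):
        members = set(universe)
        for ph in phases:
            members &= sets[ph] if ph in region else (universe - sets[ph])
        n_intra = sum(1 for (a, b) in members
                      if fragments.chrom_of(a) == fragments.chrom_of(b))
        key = "&".join(region)
        intra[key] = n_intra
        inter[key] = len(members) - n_intra
    return VennPartition(inter, intra, phases)


def _regions(phases: Sequence[str]) -> list[tuple[str, ...]]:
    # explicit enumeration keeps the canonical region order
    p = list(phases)
    return [(p[0],), (p[1],), (p[2],),
            (p[0], p[1]), (p[0], p[2]), (p[1], p[2]),
            (p[0], p[1], p[2])]


def random_network_test(total_nets: Mapping[str, InteractionNetwork],
                        cutoff: int, fragments: FragmentMap,
                        n_random: int = 1000, with_replacement: bool = False,
                        seed: int = 0) -> tuple[RandomNetworkReport, RandomNetworkReport]:
    """Observed vs resampled Venn region counts, chi-square per inter/intra.

    Events from the three total (unfiltered) networks are pooled; each
    random replicate redraws per-phase networks of the original event
    counts from the pool — with replacement (non-reducing pool) or without
    (the pool reduces as events are drawn).  The significance cut-off is
    then applied to each random network, Venn region counts computed, and
    the observed counts compared with the replicate means by chi-square
    over the seven regions (cells with expected < 1 are pooled first).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    phases = tuple(total_nets)
    pair_list: list[tuple[int, int]] = []
    owner_events: dict[str, int] = {}
    pool = []
    pair_index: dict[tuple[int, int], int] = {}
    for ph in phases:
        n_events = 0
        for (a, b), f in total_nets[ph].items():
            idx = pair_index.setdefault((a, b), len(pair_index))
            pool.extend([idx] * f)
            n_events += f
        owner_events[ph] = n_events
    pool = np.array(pool, dtype=np.int64)
    pairs = np.array(sorted(pair_index, key=pair_index.get), dtype=np.int64)
    n_pairs = len(pairs)

    observed_nets = {ph: InteractionNetwork(
        ph, {k: f for k, f in total_nets[ph].items() if f >= cutoff})
        for ph in phases}
    observed = venn_partition(observed_nets, fragments)

    rng = np.random.default_rng(seed)
    sums = {w: np.zeros(7) for w in ("inter", "intra")}
    sizes = [owner_events[ph] for ph in phases]
    for _ in range(n_random):
        if with_replacement:
            draws = [rng.choice(pool, size=s, replace=True) for s in sizes]
        else:
            perm = rng.permutation(pool)
            edges = np.cumsum([0] + sizes)
            draws = [perm[edges[i]:edges[i + 1]] for i in range(len(phases))]
        rand_nets = {}
        for ph, d in zip(phases, draws):
            counts = np.bincount(d, minlength=n_pairs)
            sig = np.nonzero(counts >= cutoff)[0]
            rand_nets[ph] = InteractionNetwork(
                ph, {(int(pairs[i][0]), int(pairs[i][1])): int(counts[i])
                     for i in sig})
        vp = venn_partition(rand_nets, fragments)
        for w in ("inter", "intra"):
            sums[w] += np.array([getattr(vp, w)[r] for r in _region_keys(phases)])

    reports = []
    for w in ("inter", "intra"):
        exp = sums[w] / n_random
        obs = np.array([getattr(observed, w)[r] for r in _region_keys(phases)],
                       dtype=float)
        stat, p, df = _pooled_chi_square(obs, exp)
        reports.append(RandomNetworkReport(
            w, dict(zip(_region_keys(phases), obs.astype(int))),
            dict(zip(_region_keys(phases), exp)), stat, p, df,
            n_random, with_replacement))
    return tuple(reports)


def _region_keys(phases: Sequence[str]) -> list[str]:
    return ["&".join(r) for r in _regions(phases)]


def _pooled_chi_square(obs: np.ndarray, exp: np.ndarray
                       ) -> tuple[float, float, int]:
    """Chi-square after pooling cells with expected < 1 into one cell."""
    small = exp < 1.0
    if small.any():
        logger.info("chi-square: pooling %d low-expectation cells",
                    int(small.sum()))
        obs = np.append(obs[~small], obs[small].sum())
        exp = np.append(exp[~small], exp[small].sum())
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    if len(exp) < 2:
        return 0.0, 1.0, 0
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(exp) - 1
    return stat, float(stats.chi2.sf(stat, df)), df


# ---------------------------------------------------------------------------
# Loop lengths
# ---------------------------------------------------------------------------

def loop_lengths(intra_net: InteractionNetwork, fragments: FragmentMap,
                 bin_width: int = 10_000) -> LoopLengthDistribution:
    """L = F2_start - F1_end with fragments ordered so F1_end <= F2_start.

    Defined for intrachromosomal interactions only; the tiling property
    guarantees the ordering exists.  Histogram bins are half-open
    ``[k*bin_width, (k+1)*bin_width)``.
    """
    lengths = []
    for (a, b), _ in intra_net.items():
        fa, fb = fragments.by_id[a], fragments.by_id[b]
        if fa.chrom != fb.chrom:
            raise ValueError(f"interaction ({a},{b}) is interchromosomal")
        first, second = (fa, fb) if fa.start <= fb.start else (fb, fa)
        if second.start < first.end:
            raise ValueError("overlapping fragments violate the tiling contract")
        lengths.append(abs(second.start - first.end))
    lengths = np.array(sorted(lengths), dtype=np.int64)
    if len(lengths):
        n_bins = int(lengths.max() // bin_width) + 1
        counts, edges = np.histogram(
            lengths, bins=np.arange(n_bins + 1) * bin_width)
    else:
        counts, edges = np.zeros(0, dtype=int), np.zeros(1)
    return LoopLengthDistribution(lengths, bin_width, edges[:-1].astype(np.int64),
                                  counts.astype(np.int64))
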