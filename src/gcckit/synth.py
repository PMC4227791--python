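"""Synthetic genomes, annotations, interaction networks and expression tables.

Every downstream stage of the package is testable without external data:
this module builds a small multi-chromosome genome carrying an AseI-like
restriction map, locus annotations (LTRs enriched on the third chromosome,
telomeres, centromeres, rDNA-flanking windows, repeat tracks), per-phase
interaction networks with a distance-decay background plus planted
inter/intrachromosomal clusters, and phase-resolved expression tables with
planted top/bottom and fold-change gene sets.

All generators are pure functions of ``(spec, seed)``; independent named RNG
substreams keep the pieces reusable without cross-talk.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ExpressionTable,
    FragmentMap,
    GenomeAssembly,
    GenomicInterval,
    InteractionNetwork,
    PHASES,
    ASEI_SITE,
)
from .coloc import LocusSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Named RNG substream derived from a master seed.

    The stream key hashes the (seed, names...) tuple so that e.g. the
    genome and the G2 network draw from unrelated streams of one master seed.
    """
    key = [int(seed)] + [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class PlantedCluster:
    """A locus set whose self-interactions are boosted in given phases."""

    locus_set: str
    phases: tuple[str, ...] = PHASES
    multiplier: float = 20.0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic data.

    Defaults emulate a miniature fission-yeast-like genome: three
    chromosomes, a six-cutter restriction map at its expected density, LTRs
    concentrated on the third chromosome, an ~85% intrachromosomal
    interaction mass with power-law distance decay, and strong planted
    LTR-LTR and telomere-telomere colocalization in all phases.
    """

    seed: int = 0
    chromosome_lengths: tuple[tuple[str, int], ...] = (
        ("chrI", 500_000), ("chrII", 400_000), ("chrIII", 300_000))
    site_density: float = 1.0 / 2000.0   # expected restriction sites per bp
    n_ltr: int = 60
    ltr_length: int = 400
    n_genes: int = 400
    gene_length: int = 1500
    telomere_window: int = 20_000
    centromere_window: int = 10_000
    rdna_flank_window: int = 10_000
    repeat_length: int = 8_000
    planted: tuple[PlantedCluster, ...] = (
        PlantedCluster("LTR", PHASES, 20.0),
        PlantedCluster("telomere", PHASES, 20.0),
    )
    decay_exponent: float = 1.0          # gamma of the intra distance decay
    decay_softening_bp: int = 20_000     # flattens the decay at short range
    intra_fraction: float = 0.85         # expected intrachromosomal pair mass
    depth: int = 30_000                  # total captured pair count per phase
    phases: tuple[str, ...] = PHASES
    expression_log_mean: float = 2.0
    expression_log_sd: float = 0.8
    phase_noise_sd: float = 0.04         # log-scale, clipped at 2.5 sd
    n_extreme: int = 20                  # planted top / bottom genes (5%)
    n_differential: int = 10             # planted >=2.5x genes per transition
    differential_fold: float = 2.5

    def __post_init__(self) -> None:
        for name, value in (("n_ltr", self.n_ltr), ("n_genes", self.n_genes),
                            ("depth", self.depth)):
            if value < 0 or (name != "depth" and value == 0):
                raise ValueError(f"{name} must be positive")

    def to_yaml(self) -> str:
        d = {
            "seed": self.seed,
            "chromosome_lengths": [list(c) for c in self.chromosome_lengths],
            "site_density": self.site_density,
            "n_ltr": self.n_ltr, "ltr_length": self.ltr_length,
            "n_genes": self.n_genes, "gene_length": self.gene_length,
            "planted": [{"locus_set": p.locus_set, "phases": list(p.phases),
                         "multiplier": p.multiplier} for p in self.planted],
            "decay_exponent": self.decay_exponent,
            "intra_fraction": self.intra_fraction,
            "depth": self.depth,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(text)
        if "chromosome_lengths" in d:
            d["chromosome_lengths"] = tuple(
                (str(n), int(l)) for n, l in d["chromosome_lengths"])
        if "planted" in d:
            d["planted"] = tuple(
                PlantedCluster(p["locus_set"], tuple(p["phases"]),
                               float(p["multiplier"])) for p in d["planted"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(spec: SyntheticSpec, site: str = ASEI_SITE) -> GenomeAssembly:
    """Random sequences with restriction sites planted at Poisson positions.

    Site positions follow a Poisson process of rate ``spec.site_density``;
    accidental occurrences of the site elsewhere in the random sequence are
    scrubbed so the realized restriction map is exactly the planted one.
    """
    rng = substream(spec.seed, "genome")
    site_b = np.frombuffer(site.encode(), dtype="S1")
    sequences: dict[str, str] = {}
    for chrom, length in spec.chromosome_lengths:
        seq = rng.choice(_BASES, size=length)
        n_sites = rng.poisson(length * spec.site_density)
        if n_sites > 0:
            # keep planted sites clear of the ends and of each other
            lo, hi = len(site), length - 2 * len(site)
            pos = np.sort(rng.choice(np.arange(lo, hi), size=min(n_sites, hi - lo),
                                     replace=False))
            pos = pos[np.concatenate(([True], np.diff(pos) > 2 * len(site)))]
        else:
            pos = np.array([], dtype=int)
        for p in pos:
            seq[p:p + len(site)] = site_b
        _scrub_accidental_sites(seq, site_b, set(int(p) for p in pos), rng)
        sequences[chrom] = seq.tobytes().decode()
    return GenomeAssembly.from_sequences(
        sequences, order=[c for c, _ in spec.chromosome_lengths])


def _scrub_accidental_sites(seq: np.ndarray, site: np.ndarray,
                            planted: set[int], rng: np.random.Generator,
                            max_rounds: int = 50) -> None:
    text = seq.tobytes()
    pat = site.tobytes()
    for _ in range(max_rounds):
        hits = []
        i = text.find(pat)
        while i != -1:
            if i not in planted:
                hits.append(i)
            i = text.find(pat, i + 1)
        if not hits:
            return
        for h in hits:
            mid = h + len(pat) // 2
            current = seq[mid]
            choices = _BASES[_BASES != current]
            seq[mid] = rng.choice(choices)
        text = seq.tobytes()
    raise RuntimeError("could not scrub accidental restriction sites")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotations(spec: SyntheticSpec,
                         genome: GenomeAssembly) -> dict[str, LocusSet]:
    """Locus sets mirroring the fission-yeast annotation classes used here.

    Telomeres are the terminal windows of every chromosome, centromeres a
    mid-chromosome window, rDNA-flanking windows sit inside the ends of the
    third chromosome, LTRs are short elements placed with a strong bias
    toward the third chromosome, and two repeat regions (third chromosome)
    exercise the fragment-uniqueness flag.
    """
    rng = substream(spec.seed, "annotations")
    names = genome.names
    chr3 = names[-1]
    tel, cen, rdna, repeats, ltrs, genes = [], [], [], [], [], []

    for chrom, length in genome.chromosomes:
        w = min(spec.telomere_window, length // 4)
        tel.append(GenomicInterval(chrom, 0, w, f"tel_{chrom}_L"))
        tel.append(GenomicInterval(chrom, length - w, length, f"tel_{chrom}_R"))
        mid = length // 2
        half = spec.centromere_window // 2
        cen.append(GenomicInterval(chrom, mid - half, mid + half, f"cen_{chrom}"))

    L3 = genome.lengths[chr3]
    w, fw = min(spec.telomere_window, L3 // 4), spec.rdna_flank_window
    rdna.append(GenomicInterval(chr3, w, w + fw, "rdna_flank_L"))
    rdna.append(GenomicInterval(chr3, L3 - w - fw, L3 - w, "rdna_flank_R"))
    repeats.append(GenomicInterval(chr3, L3 // 3, L3 // 3 + spec.repeat_length,
                                   "repeat_1"))
    repeats.append(GenomicInterval(chr3, L3 * 2 // 3,
                                   L3 * 2 // 3 + spec.repeat_length, "repeat_2"))

    # LTRs: half on the third chromosome, the rest split by length
    n_chr3 = spec.n_ltr // 2
    others = names[:-1]
    other_lengths = np.array([genome.lengths[c] for c in others], dtype=float)
    counts = {chr3: n_chr3}
    remaining = spec.n_ltr - n_chr3
    alloc = np.floor(remaining * other_lengths / other_lengths.sum()).astype(int)
    alloc[0] += remaining - alloc.sum()
    for c, k in zip(others, alloc):
        counts[c] = int(k)
    i = 0
    for chrom in names:
        length = genome.lengths[chrom]
        starts = rng.integers(0, length - spec.ltr_length, size=counts[chrom])
        for s in np.sort(starts):
            ltrs.append(GenomicInterval(chrom, int(s), int(s) + spec.ltr_length,
                                        f"LTR{i:04d}"))
            i += 1

    # genes: allocated to chromosomes proportional to length, placed uniformly
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    g_alloc = np.floor(spec.n_genes * lengths / lengths.sum()).astype(int)
    g_alloc[0] += spec.n_genes - g_alloc.sum()
    gi = 0
    for (chrom, length), k in zip(genome.chromosomes, g_alloc):
        starts = np.sort(rng.integers(0, length - spec.gene_length, size=int(k)))
        for s in starts:
            genes.append(GenomicInterval(chrom, int(s),
                                         int(s) + spec.gene_length,
                                         f"g{gi:04d}"))
            gi += 1

    return {
        "telomere": LocusSet("telomere", tel),
        "centromere": LocusSet("centromere", cen),
        "rdna_flank": LocusSet("rdna_flank", rdna),
        "repeat": LocusSet("repeat", repeats),
        "LTR": LocusSet("LTR", ltrs),
        "genes": LocusSet("genes", genes),
    }


def mark_unique_fragments(fragments: FragmentMap,
                          repeats: LocusSet) -> FragmentMap:
    """Clear the uniqueness flag of fragments fully inside a repeat region."""
    from dataclasses import replace
    new = []
    for f in fragments:
        buried = any(iv.chrom == f.chrom and iv.start <= f.start
                     and f.end <= iv.end for iv in repeats.loci)
        new.append(replace(f, unique=not buried) if buried else f)
    return FragmentMap(new)


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

def generate_network(spec: SyntheticSpec, fragments: FragmentMap,
                     annotations: Mapping[str, LocusSet],
                     phase: str) -> InteractionNetwork:
    """Multinomial draw of captured pairs over a decaying background.

    Candidate pairs are all unordered distinct fragment pairs.  Weights are
    ``(L + softening)^-gamma`` within chromosomes (L the linear gap between
    the fragments) and a constant between chromosomes, calibrated so the
    expected intrachromosomal pair mass equals ``spec.intra_fraction``.
    Pairs whose two fragments both overlap a planted locus set active in
    this phase have their weight multiplied by the planted effect.
    """
    rng = substream(spec.seed, "network", phase)
    frs = fragments.fragments
    n = len(frs)
    chrom_codes = np.array([hash(f.chrom) for f in frs])
    starts = np.array([f.start for f in frs])
    ends = np.array([f.end for f in frs])

    iu, ju = np.triu_indices(n, k=1)
    same = chrom_codes[iu] == chrom_codes[ju]
    # fragments are in genome order, so within a chromosome j follows i
    gap = np.where(same, np.maximum(starts[ju] - ends[iu], 0), 0)
    w = np.ones(len(iu))
    w[same] = (gap[same] + float(spec.decay_softening_bp)) ** (-spec.decay_exponent)

    # planted cluster boosts
    for cluster in spec.planted:
        if phase not in cluster.phases or cluster.multiplier == 1.0:
            continue
        loci = annotations[cluster.locus_set]
        mask = _fragment_overlap_mask(fragments, loci)
        both = mask[iu] & mask[ju]
        w[both] *= cluster.multiplier

    # calibrate inter mass so expected intra fraction matches the spec
    s_intra = w[same].sum()
    n_inter = int((~same).sum())
    if n_inter and spec.intra_fraction < 1:
        p = spec.intra_fraction
        w[~same] *= s_intra * (1 - p) / (p * w[~same].sum())

    if spec.depth == 0:
        return InteractionNetwork(phase)
    counts = rng.multinomial(spec.depth, w / w.sum())
    nz = np.nonzero(counts)[0]
    freq = {(int(frs[iu[k]].id), int(frs[ju[k]].id)): int(counts[k]) for k in nz}
    return InteractionNetwork(phase, freq)


def _fragment_overlap_mask(fragments: FragmentMap, loci: LocusSet) -> np.ndarray:
    index = {f.id: k for k, f in enumerate(fragments.fragments)}
    mask = np.zeros(len(fragments), dtype=bool)
    for iv in loci.loci:
        for f in fragments.fragments_overlapping(iv.chrom, iv.start, iv.end):
            mask[index[f.id]] = True
    return mask


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(spec: SyntheticSpec, genes: LocusSet,
                        replicate: int = 0) -> ExpressionTable:
    """Log-normal expression with planted extreme and differential genes.

    Planted top/bottom genes sit far outside the log-normal bulk (bulk
    log-levels are clipped at 3 sd) so the nominal 5% extreme sets are
    recovered exactly; planted differential genes change by exactly
    ``spec.differential_fold`` between consecutive phases of the cycle
    G1->G2->M, while per-phase noise is clipped at 2.5 sd so no bulk gene
    can cross a 2-fold threshold and no planted gene can fall below it.
    Planted memberships are recorded on ``table.planted``.
    """
    rng = substream(spec.seed, "expression")
    n = len(genes.loci)
    if spec.n_extreme * 2 + spec.n_differential * 3 > n:
        raise ValueError("not enough genes for the planted sets")
    ids = np.array([iv.name for iv in genes.loci])
    order = rng.permutation(n)
    k, d = spec.n_extreme, spec.n_differential
    top = order[:k]
    bottom = order[k:2 * k]
    diff = {t: order[2 * k + i * d: 2 * k + (i + 1) * d]
            for i, t in enumerate(("G1->G2", "G2->M", "M->G1"))}

    base = np.exp(spec.expression_log_mean + np.clip(
        rng.normal(0, spec.expression_log_sd, size=n), -3 * spec.expression_log_sd,
        3 * spec.expression_log_sd))
    base[top] = rng.uniform(500.0, 1000.0, size=k)
    base[bottom] = rng.uniform(0.002, 0.01, size=k)

    # per-phase design multipliers implementing the planted fold changes
    mult = {ph: np.ones(n) for ph in spec.phases}
    f = spec.differential_fold
    mult["G2"][diff["G1->G2"]] = f          # up G1->G2, back down G2->M
    mult["M"][diff["G2->M"]] = f            # up G2->M, back down M->G1
    mult["G1"][diff["M->G1"]] = f           # up M->G1, down G1->G2

    rng_rep = substream(spec.seed, "expression-noise", replicate)
    levels = {}
    for ph in spec.phases:
        noise = np.clip(rng_rep.normal(0, spec.phase_noise_sd, size=n),
                        -2.5 * spec.phase_noise_sd, 2.5 * spec.phase_noise_sd)
        levels[ph] = base * mult[ph] * np.exp(noise)

    frame = pd.DataFrame({
        "gene": ids,
        "chrom": [iv.chrom for iv in genes.loci],
        "start": [iv.start for iv in genes.loci],
        "end": [iv.end for iv in genes.loci],
        **{ph: levels[ph] for ph in spec.phases},
    })
    table = ExpressionTable(frame, spec.phases)
    table.planted = {
        **{f"top_{ph}": set(ids[top]) for ph in spec.phases},
        **{f"bottom_{ph}": set(ids[bottom]) for ph in spec.phases},
    }
    for t, idx in diff.items():
        table.planted[f"up_{t}"] = set(ids[idx])
    # each planted up set is, by cyclic design, the down set of the next leg
    table.planted["down_G2->M"] = table.planted["up_G1->G2"]
    table.planted["down_M->G1"] = table.planted["up_G2->M"]
    table.planted["down_G1->G2"] = table.planted["up_M->G1"]
    return table
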